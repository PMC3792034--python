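"""Concentration-response fitting and LC50 estimation for sediment nickel.

The response is live P0 adults recovered per well (0-10 animals), modelled
as a function of total-recoverable sediment nickel (µg/g dry weight).
Four curve families are fitted by least squares: 2nd- and 3rd-degree
polynomials (reported in ecotoxicology tables as "binomial"/"trinomial"
trendlines), a natural-log curve a·ln(x)+b, and a shifted exponential
A·e^(kx) fitted to y+1 so the decay never has to cross zero.

The LC50 is not a probit/logit quantile here: it is the concentration at
which the fitted curve intersects a horizontal line at half the mean
control recovery (the "y = 5 animals" line when controls average ten).
For the shifted-exponential family the target line is raised by one to
match the y+1 fitting scale.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq

from .endpoints import EndpointSummary
from .models import TreatmentSpec, WellOutcome

log = logging.getLogger(__name__)

#: Reported as "not attained" in tables: no intersection in the search range.
NOT_ATTAINED = None

ROOT_XTOL = 1e-6       # µg/g, absolute tolerance of numeric root-finding
_SCAN_POINTS = 20001   # grid density of the bracketing scan


class CurveFamily(str, enum.Enum):
    QUADRATIC = "quadratic"
    CUBIC = "cubic"
    LOGARITHMIC = "logarithmic"
    EXPONENTIAL_SHIFTED = "exponential_shifted"

    @classmethod
    def parse(cls, name: str) -> "CurveFamily":
        """Accept the trendline-table aliases binomial/trinomial/log/exp."""
        aliases = {
            "binomial": cls.QUADRATIC,
            "trinomial": cls.CUBIC,
            "quad": cls.QUADRATIC,
            "log": cls.LOGARITHMIC,
            "exp": cls.EXPONENTIAL_SHIFTED,
            "exponential": cls.EXPONENTIAL_SHIFTED,
        }
        key = name.strip().lower()
        if key in aliases:
            return aliases[key]
        return cls(key)


POLYNOMIAL_FAMILIES = (CurveFamily.QUADRATIC, CurveFamily.CUBIC)


@dataclass(frozen=True)
class DoseResponsePoint:
    """One well: sediment nickel (µg/g) vs live P0 adults recovered."""

    concentration: float
    response: float

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive (controls carry "
                             "measured background nickel)")
        if self.response < 0:
            raise ValueError("response must be non-negative")


@dataclass
class DoseResponseFit:
    """A fitted curve of one family, with LC50 once estimated.

    ``coefficients`` are highest-order first for the polynomial families
    (a, b, c for ax²+bx+c), (a, b) for a·ln(x)+b, and (A, k) for the
    shifted exponential A·e^(kx) fitted against y+1.  ``r_squared`` is
    computed on the fitting scale (ln(y+1) for the exponential family,
    raw y otherwise); the exponential fit also records the raw-scale R².
    """

    family: CurveFamily
    coefficients: tuple[float, ...]
    r_squared: float
    x_max: float
    y_target: Optional[float] = None
    lc50: Optional[float] = None
    r_squared_raw: Optional[float] = None
    n_points: int = 0

    def predict(self, x: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
        """Fitted response at concentration ``x`` (raw y scale)."""
        x = np.asarray(x, dtype=float)
        if self.family in POLYNOMIAL_FAMILIES:
            out = np.polyval(self.coefficients, x)
        elif self.family is CurveFamily.LOGARITHMIC:
            a, b = self.coefficients
            out = a * np.log(x) + b
        else:
            amp, k = self.coefficients
            out = amp * np.exp(k * x) - 1.0  # back to the raw y scale
        return float(out) if out.ndim == 0 else out

    def formula(self) -> str:
        c = self.coefficients
        if self.family is CurveFamily.QUADRATIC:
            return f"y = {c[0]:.6g}*x^2 + {c[1]:.6g}*x + {c[2]:.6g}"
        if self.family is CurveFamily.CUBIC:
            return (f"y = {c[0]:.6g}*x^3 + {c[1]:.6g}*x^2 + {c[2]:.6g}*x "
                    f"+ {c[3]:.6g}")
        if self.family is CurveFamily.LOGARITHMIC:
            return f"y = {c[0]:.6g}*ln(x) + {c[1]:.6g}"
        return f"y+1 = {c[0]:.6g}*e^({c[1]:.6g}*x)"


def _ols(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares solve plus R² on the given scale."""
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        if ss_res > 1e-10 * max(1.0, float(y @ y)):
            raise ValueError("response has zero variance but nonzero residuals")
        return beta, 1.0
    return beta, 1.0 - ss_res / ss_tot


def fit_dose_response(
    points: Sequence[DoseResponsePoint],
    family: Union[CurveFamily, str],
) -> DoseResponseFit:
    """Least-squares fit of one curve family to per-well points."""
    family = CurveFamily.parse(family) if isinstance(family, str) else family
    x = np.array([p.concentration for p in points], dtype=float)
    y = np.array([p.response for p in points], dtype=float)

    n_coef = {CurveFamily.QUADRATIC: 3, CurveFamily.CUBIC: 4,
              CurveFamily.LOGARITHMIC: 2, CurveFamily.EXPONENTIAL_SHIFTED: 2}[family]
    if len(np.unique(x)) < n_coef:
        raise ValueError(
            f"{family.value} needs >= {n_coef} distinct concentrations, "
            f"got {len(np.unique(x))}"
        )

    raw_r2 = None
    if family in POLYNOMIAL_FAMILIES:
        degree = n_coef - 1
        design = np.vander(x, degree + 1)
        beta, r2 = _ols(design, y)
        coefs = tuple(float(b) for b in beta)
    elif family is CurveFamily.LOGARITHMIC:
        design = np.column_stack([np.log(x), np.ones_like(x)])
        beta, r2 = _ols(design, y)
        coefs = (float(beta[0]), float(beta[1]))
    else:
        # spreadsheet-trendline convention: linear fit of ln(y+1) on x
        z = np.log(y + 1.0)
        design = np.column_stack([x, np.ones_like(x)])
        beta, r2 = _ols(design, z)
        coefs = (float(math.exp(beta[1])), float(beta[0]))
        pred = coefs[0] * np.exp(coefs[1] * x) - 1.0
        ss_tot = float(((y - y.mean()) ** 2).sum())
        raw_r2 = (1.0 - float(((y - pred) ** 2).sum()) / ss_tot
                  if ss_tot > 0 else 1.0)

    return DoseResponseFit(
        family=family, coefficients=coefs, r_squared=float(r2),
        x_max=float(x.max()), r_squared_raw=raw_r2, n_points=len(points),
    )


def control_target(
    control_wells: Sequence[WellOutcome],
    rounding: bool = False,
) -> float:
    """Half the mean live-P0 recovery of control wells — the LC50 line.

    With ``rounding`` (replication mode), the half-mean is rounded half
    away from zero to the nearest whole animal, matching the integer
    target lines used when reading intersections off trendline charts.
    """
    if not control_wells:
        raise ValueError("control_target needs at least one control well")
    mean_live = sum(w.n_live_adults for w in control_wells) / len(control_wells)
    if mean_live == 0:
        raise ValueError("LC50 undefined without surviving controls")
    target = 0.5 * mean_live
    if rounding:
        return float(math.floor(target + 0.5))
    return target


def _smallest_positive(roots: Iterable[float], upper: float) -> Optional[float]:
    ok = [r for r in roots if ROOT_XTOL < r <= upper]
    return min(ok) if ok else NOT_ATTAINED


def lc50(
    fit: DoseResponseFit,
    y_target: float,
    search_max: Optional[float] = None,
) -> Optional[float]:
    """Smallest positive concentration where the fit crosses ``y_target``.

    The search range defaults to 1.5x the highest fitted concentration;
    crossings beyond it (or none at all) report as not attained (None).
    For the shifted-exponential family the intersection is taken on the
    y+1 scale: A·e^(kx) = y_target + 1.
    """
    if search_max is None:
        search_max = 1.5 * fit.x_max
    c = fit.coefficients

    if fit.family is CurveFamily.QUADRATIC:
        a, b, const = c[0], c[1], c[2] - y_target
        if a == 0:
            return _smallest_positive([-const / b] if b else [], search_max)
        disc = b * b - 4 * a * const
        if disc < 0:
            return NOT_ATTAINED
        sq = math.sqrt(disc)
        return _smallest_positive([(-b - sq) / (2 * a), (-b + sq) / (2 * a)],
                                  search_max)
    if fit.family is CurveFamily.LOGARITHMIC:
        a, b = c
        if a == 0:
            return NOT_ATTAINED
        return _smallest_positive([math.exp((y_target - b) / a)], search_max)
    if fit.family is CurveFamily.EXPONENTIAL_SHIFTED:
        amp, k = c
        shifted = y_target + 1.0
        if k == 0 or shifted <= 0 or amp <= 0:
            return NOT_ATTAINED
        return _smallest_positive([math.log(shifted / amp) / k], search_max)

    # cubic: bracketing scan then Brent's method
    def f(x: float) -> float:
        return float(np.polyval(c, x)) - y_target

    xs = np.linspace(ROOT_XTOL, search_max, _SCAN_POINTS)
    vals = np.polyval(c, xs) - y_target
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            return float(xs[i])
        if vals[i] * vals[i + 1] < 0:
            return float(brentq(f, xs[i], xs[i + 1], xtol=ROOT_XTOL))
    if vals[-1] == 0.0:
        return float(xs[-1])
    return NOT_ATTAINED


def estimate_lc50(
    fit: DoseResponseFit,
    y_target: float,
    search_max: Optional[float] = None,
) -> DoseResponseFit:
    """Return a copy of ``fit`` with ``y_target`` and ``lc50`` filled in."""
    return replace(fit, y_target=y_target,
                   lc50=lc50(fit, y_target, search_max))


def lc50_range(
    fits: Iterable[DoseResponseFit],
) -> Optional[tuple[float, float]]:
    """(min, max) LC50 over the polynomial families only.

    Reported toxicity ranges rest on the quadratic/cubic fits, which
    consistently carry the highest R²; log and exponential fits are
    excluded here.
    """
    values = [f.lc50 for f in fits
              if f.family in POLYNOMIAL_FAMILIES and f.lc50 is not None]
    if not values:
        return NOT_ATTAINED
    return (min(values), max(values))


def points_from_wells(
    wells: Iterable[WellOutcome],
    treatments: Iterable[TreatmentSpec],
) -> list[DoseResponsePoint]:
    """Per-well dose-response points: treatment TR-Ni vs live adults."""
    conc = {t.treatment_id: t.tr_ni for t in treatments}
    pts = []
    for w in wells:
        if w.treatment_id not in conc:
            raise ValueError(f"well {w.well_id!r}: unknown treatment "
                             f"{w.treatment_id!r}")
        pts.append(DoseResponsePoint(concentration=conc[w.treatment_id],
                                     response=float(w.n_live_adults)))
    return pts


COVARIATE_NAMES = ("toc", "avs", "cec", "ph", "orp", "clay", "silt", "sand")


@dataclass
class CovariateScreenRow:
    factors: tuple[str, ...]
    r_squared: Optional[float]   # None when the design was collinear
    collinear: bool = False


def covariate_screen(
    summaries: Sequence[EndpointSummary],
    specs: Sequence[TreatmentSpec],
    max_factors: int = 3,
    covariates: Sequence[str] = COVARIATE_NAMES,
) -> list[CovariateScreenRow]:
    """Screen sediment properties for association with mean P0 recovery.

    Fits ordinary least squares of treatment-mean recovery on every
    subset of at most ``max_factors`` covariates; returns each subset's
    R², sorted descending.  Rank-deficient (collinear) subsets are
    flagged and skipped rather than fitted.
    """
    by_id = {t.treatment_id: t for t in specs}
    rows = [(s, by_id[s.treatment_id]) for s in summaries
            if s.treatment_id in by_id]
    usable = [name for name in covariates
              if all(getattr(t, name) is not None for _, t in rows)]
    if len(rows) < max_factors + 2:
        raise ValueError(
            f"covariate screen needs >= {max_factors + 2} treatments with "
            f"complete covariates, got {len(rows)}"
        )
    y = np.array([s.mean_p0_recovery for s, _ in rows], dtype=float)

    results: list[CovariateScreenRow] = []
    for k in range(1, max_factors + 1):
        for subset in itertools.combinations(usable, k):
            design = np.column_stack(
                [np.ones(len(rows))]
                + [np.array([getattr(t, name) for _, t in rows], dtype=float)
                   for name in subset]
            )
            if np.linalg.matrix_rank(design) < design.shape[1]:
                log.warning("covariate subset %s is collinear; skipped", subset)
                results.append(CovariateScreenRow(subset, None, collinear=True))
                continue
            _, r2 = _ols(design, y)
            results.append(CovariateScreenRow(subset, float(r2)))
    results.sort(key=lambda r: (-(r.r_squared if r.r_squared is not None
                                  else -math.inf), r.factors))
    return results
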