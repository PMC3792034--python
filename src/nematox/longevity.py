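"""Adult survivorship curves from destructive daily harvests, with LT50.

One well per treatment is sacrificed per day over a 22-day window, so
each day's fraction alive is an independent binomial cohort rather than
a censored follow-up series (which is why this module fits trendline
cubics rather than Kaplan-Meier estimates).  The median survival day
(LT50) is read off the fitted cubic where it crosses a survivorship
fraction of 0.5; the smallest positive crossing is taken even when the
non-monotone cubic re-crosses later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .models import LongevityObservation

log = logging.getLogger(__name__)

LT50_XTOL = 1e-4            # days
_SCAN_POINTS = 20001
_EXTRAPOLATION_FACTOR = 3.0  # how far past the window the log-only search goes


@dataclass
class SurvivorshipFit:
    """Cubic fit of survivorship fraction vs day.

    ``lt50`` is None ("beyond window") when the cubic never reaches 0.5
    inside the observation window; any extrapolated crossing is logged
    for diagnostics but never reported.
    """

    treatment_id: str
    coefficients: tuple[float, float, float, float]  # a, b, c, d (cubic first)
    r_squared: float
    window: tuple[float, float]
    lt50: Optional[float] = None

    def predict(self, day):
        return np.polyval(self.coefficients, day)


def survivorship_series(
    observations: Sequence[LongevityObservation],
) -> list[tuple[int, float]]:
    """(day, fraction alive) points in day order; no smoothing applied."""
    seen: set[int] = set()
    treatments = {o.sediment_treatment for o in observations}
    if len(treatments) > 1:
        raise ValueError(f"mixed treatments in one series: {sorted(treatments)}")
    pts = []
    for o in sorted(observations, key=lambda o: o.day):
        if o.day in seen:
            raise ValueError(f"duplicate observation for day {o.day}")
        seen.add(o.day)
        pts.append((o.day, o.fraction_alive))
    return pts


def fit_survivorship(
    points: Sequence[tuple[float, float]],
    treatment_id: str = "",
) -> SurvivorshipFit:
    """Ordinary least-squares cubic in day, R² on the raw fractions."""
    days = np.array([p[0] for p in points], dtype=float)
    frac = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(days)) < 4:
        raise ValueError("cubic survivorship fit needs >= 4 distinct days")
    design = np.vander(days, 4)
    beta, *_ = np.linalg.lstsq(design, frac, rcond=None)
    resid = frac - design @ beta
    ss_tot = float(((frac - frac.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(resid @ resid) / ss_tot

    fitted = design @ beta
    if fitted.min() < -0.1 or fitted.max() > 1.1:
        log.warning(
            "treatment %s: fitted survivorship leaves [-0.1, 1.1] at "
            "observed days (min %.3f, max %.3f)",
            treatment_id, fitted.min(), fitted.max(),
        )
    return SurvivorshipFit(
        treatment_id=treatment_id,
        coefficients=tuple(float(b) for b in beta),
        r_squared=float(r2),
        window=(float(days.min()), float(days.max())),
    )


def _first_crossing(coefs, upper: float, target: float = 0.5) -> Optional[float]:
    def f(x: float) -> float:
        return float(np.polyval(coefs, x)) - target

    xs = np.linspace(LT50_XTOL, upper, _SCAN_POINTS)
    vals = np.polyval(coefs, xs) - target
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            return float(xs[i])
        if vals[i] * vals[i + 1] < 0:
            return float(brentq(f, xs[i], xs[i + 1], xtol=LT50_XTOL))
    return None


def lt50(fit: SurvivorshipFit) -> Optional[float]:
    """Smallest positive day where the cubic equals 0.5, inside the window.

    Returns None ("beyond window") when no crossing occurs by the last
    observed day; an extrapolated crossing, if any, is logged.
    """
    day_max = fit.window[1]
    crossing = _first_crossing(fit.coefficients, day_max)
    if crossing is not None:
        return crossing
    beyond = _first_crossing(fit.coefficients, _EXTRAPOLATION_FACTOR * day_max)
    if beyond is not None:
        log.info(
            "treatment %s: survivorship reaches 0.5 only by extrapolation, "
            "at day %.3f (window ends day %g)",
            fit.treatment_id, beyond, day_max,
        )
    return None


def estimate_lt50(fit: SurvivorshipFit) -> SurvivorshipFit:
    """Copy of ``fit`` with the LT50 filled in."""
    return replace(fit, lt50=lt50(fit))


def analyze_longevity(
    observations: Sequence[LongevityObservation],
) -> list[SurvivorshipFit]:
    """Series -> cubic fit -> LT50, one fit per treatment present."""
    groups: dict[str, list[LongevityObservation]] = {}
    for o in observations:
        groups.setdefault(o.sediment_treatment, []).append(o)
    fits = []
    for tid, obs in groups.items():
        pts = survivorship_series(obs)
        fits.append(estimate_lt50(fit_survivorship(pts, treatment_id=tid)))
    return fits
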