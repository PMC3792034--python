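"""Synthetic bioassay generator with known ground truth.

Emulates the stochastic structure of the whole-sediment assay: ten
synchronized larvae per well, six replicate wells in each of two trials
per treatment, concentration-dependent binomial survival to adulthood,
overdispersed per-adult progeny counts, and destructive daily harvests
of larger cohorts over a 22-day longevity window.  The true LC50 is
computable in closed form from the survival-curve parameters, which is
what makes parameter-recovery tests possible.

Determinism: one global seed governs everything; each well and each
daily harvest draws from its own substream derived from (seed, index),
so the output is identical regardless of generation order.
"""

from __future__ import annotations

import math
from typing import Annotated, Literal, Optional, Union

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .dose_response import CurveFamily, DoseResponseFit, lc50
from .models import LongevityObservation, Species, TreatmentSpec, WellOutcome

#: Measured total-recoverable nickel of the high-binding spiked series
#: (µg/g dry weight), control background first — the default dose grid.
DEFAULT_DOSES = (59.7, 156.0, 369.0, 1040.0, 2680.0, 7660.0)


class LogisticSurvival(BaseModel):
    """p(dose) = p0 / (1 + (dose/lc50)^slope); p = p0/2 exactly at lc50."""

    kind: Literal["logistic"] = "logistic"
    p0: float = Field(1.0, gt=0, le=1)       # control survival probability
    lc50: float = Field(..., gt=0)           # µg/g, true median-lethal dose
    slope: float = Field(2.0, gt=0)

    def survival(self, dose: float) -> float:
        return self.p0 / (1.0 + (dose / self.lc50) ** self.slope)


class PolynomialSurvival(BaseModel):
    """Survival from an explicit polynomial in dose, on the animals scale.

    ``coefficients`` (highest order first) give expected live animals per
    well of ``n_added``; the per-animal probability is that value divided
    by ``n_added``, clamped to [0, 1].
    """

    kind: Literal["polynomial"] = "polynomial"
    coefficients: tuple[float, ...]
    n_added: int = Field(10, gt=0)
    y_target: Optional[float] = None  # half-of-control line for true_lc50

    def survival(self, dose: float) -> float:
        return float(np.polyval(self.coefficients, dose)) / self.n_added


SurvivalCurve = Annotated[Union[LogisticSurvival, PolynomialSurvival],
                          Field(discriminator="kind")]


class LongevityTruth(BaseModel):
    """Constant daily hazard per treatment: S(day) = exp(-h * day)."""

    hazards: dict[str, float] = {"S-0": math.log(2) / 16.0}
    n_initial: int = Field(55, gt=0)
    days: int = Field(22, ge=4, le=22)


class SimulationConfig(BaseModel):
    seed: int = 0
    doses: tuple[float, ...] = DEFAULT_DOSES
    wells_per_dose: int = Field(12, gt=0)  # 6 replicate wells x 2 trials
    n_added: int = Field(10, gt=0)
    species: Species = Species.C_ELEGANS
    survival: SurvivalCurve = LogisticSurvival(lc50=1200.0)
    progeny_mean_per_adult: float = Field(3.0, ge=0)
    progeny_dose_multiplier: dict[float, float] = {}
    progeny_dispersion: float = Field(2.0, ge=1.0)  # variance-to-mean ratio
    longevity: LongevityTruth = LongevityTruth()

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be positive (controls carry "
                             "background nickel, never 0)")
        for d in self.doses:
            p = self.survival.survival(d)
            if not -0.25 <= p <= 1.25:
                raise ValueError(
                    f"survival curve gives p = {p:.3f} at dose {d:g}, too far "
                    "outside [0, 1] to be a credible clamped probability"
                )
        return self

    def treatment_specs(self) -> list[TreatmentSpec]:
        """One synthetic sediment treatment per dose, control first."""
        return [
            TreatmentSpec(
                treatment_id=f"S-{i}", sediment_id="S",
                spike_level=min(i, 5), tr_ni=float(d),
            )
            for i, d in enumerate(self.doses)
        ]


def _clamped_p(config: SimulationConfig, dose: float) -> float:
    return min(1.0, max(0.0, config.survival.survival(dose)))


def _progeny_draw(rng: np.random.Generator, mean: float, vmr: float) -> int:
    """Overdispersed count with the given mean and variance/mean ratio."""
    if mean <= 0:
        return 0
    if vmr <= 1.0:
        return int(rng.poisson(mean))
    # gamma-Poisson mixture: var = mean * vmr
    shape = mean / (vmr - 1.0)
    return int(rng.poisson(rng.gamma(shape, vmr - 1.0)))


def simulate_sediment_assay(config: SimulationConfig) -> list[WellOutcome]:
    """Well-level outcomes with binomial survival and overdispersed broods.

    Live adults ~ Binomial(n_added, p(dose)); unrecovered corpses mean
    ``n_dead`` undercounts deaths (a uniform 50% corpse-recovery rate is
    applied).  Trial ids alternate per half of the wells at each dose.
    """
    duration = 96 if config.species is Species.C_ELEGANS else 120
    wells: list[WellOutcome] = []
    widx = 0
    half = config.wells_per_dose // 2
    for i, dose in enumerate(config.doses):
        p = _clamped_p(config, dose)
        lam = (config.progeny_mean_per_adult
               * config.progeny_dose_multiplier.get(dose, 1.0))
        for j in range(config.wells_per_dose):
            rng = np.random.default_rng([config.seed, widx])
            live = int(rng.binomial(config.n_added, p))
            dead = int(rng.binomial(config.n_added - live, 0.5))
            progeny = _progeny_draw(rng, live * lam, config.progeny_dispersion)
            wells.append(WellOutcome(
                well_id=f"w{widx}", treatment_id=f"S-{i}",
                species=config.species,
                trial_id="t1" if j < half else "t2",
                n_added=config.n_added, n_live_adults=live,
                n_dead=dead, n_progeny=progeny, duration_h=duration,
            ))
            widx += 1
    return wells


def simulate_longevity(config: SimulationConfig) -> list[LongevityObservation]:
    """Destructive daily harvests: each day an independent binomial cohort."""
    obs: list[LongevityObservation] = []
    trt = config.longevity
    for ti, (treatment, h) in enumerate(sorted(trt.hazards.items())):
        if h < 0:
            raise ValueError(f"hazard for {treatment!r} must be >= 0")
        for day in range(1, trt.days + 1):
            rng = np.random.default_rng([config.seed, ti, day])
            s = math.exp(-h * day)
            obs.append(LongevityObservation(
                sediment_treatment=treatment, day=day,
                n_initial=trt.n_initial,
                n_live=int(rng.binomial(trt.n_initial, s)),
            ))
    return obs


def true_lc50(config: SimulationConfig) -> Optional[float]:
    """Closed-form dose where survival reaches half of control survival.

    Logistic curves invert algebraically (the lc50 parameter itself).
    Polynomial curves delegate to the dose-response root-finder on the
    true coefficients, against ``y_target`` (default: half the curve's
    value at the lowest, i.e. control, dose).
    """
    curve = config.survival
    if isinstance(curve, LogisticSurvival):
        return curve.lc50
    family = {3: CurveFamily.QUADRATIC, 4: CurveFamily.CUBIC}.get(
        len(curve.coefficients))
    if family is None:
        raise ValueError("polynomial truth must be quadratic or cubic")
    target = curve.y_target
    if target is None:
        target = 0.5 * float(np.polyval(curve.coefficients, min(config.doses)))
    fit = DoseResponseFit(family=family, coefficients=curve.coefficients,
                          r_squared=1.0, x_max=max(config.doses))
    return lc50(fit, target, search_max=1.5 * max(config.doses))


def load_flat_config(path) -> SimulationConfig:
    """Read a flat key=value file into a :class:`SimulationConfig`.

    Recognised keys mirror the top-level config fields; ``doses`` and
    survival-curve parameters use dotted names, e.g.::

        seed = 7
        doses = 59.7, 156, 369, 1040, 2680, 7660
        wells_per_dose = 12
        survival.kind = logistic
        survival.lc50 = 1200
        survival.slope = 2.0
    """
    flat: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            flat[key.strip()] = value.strip()

    data: dict = {}
    survival: dict = {}
    for key, value in flat.items():
        if key.startswith("survival."):
            field_name = key.split(".", 1)[1]
            survival[field_name] = (value if field_name == "kind"
                                    else _parse_scalar(value))
        elif key in ("doses",):
            data[key] = tuple(float(v) for v in value.split(","))
        elif key in ("seed", "wells_per_dose", "n_added"):
            data[key] = int(value)
        elif key in ("progeny_mean_per_adult", "progeny_dispersion"):
            data[key] = float(value)
        elif key == "species":
            data[key] = Species(value)
        else:
            raise ValueError(f"unknown simulation config key {key!r}")
    if survival:
        data["survival"] = survival
    return SimulationConfig(**data)


def _parse_scalar(value: str):
    if "," in value:
        return tuple(float(v) for v in value.split(","))
    try:
        return float(value)
    except ValueError:
        return value
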