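"""Domain types for whole-sediment and aqueous nickel bioassays.

The unit of replication throughout is the test well: ten synchronized
larvae are added to each well of a 12-well plate, grown for one life
cycle (96 h for *C. elegans*, 120 h for *P. pacificus*), and recovered.
Treatments are sediments (un-spiked controls or nickel-spiked series) or
nickel-chloride test waters; their chemistry travels with the treatment
record so dose-response fits and covariate screens can look it up.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator


class Medium(str, enum.Enum):
    SEDIMENT = "sediment"
    WATER = "water"


class Species(str, enum.Enum):
    C_ELEGANS = "C_elegans"
    P_PACIFICUS = "P_pacificus"


class TreatmentSpec(BaseModel):
    """One sediment or water treatment and its physico-chemical context.

    ``tr_ni`` is total-recoverable nickel in µg/g dry weight — the dose
    axis for sediment fits.  Controls carry their *measured* background
    nickel (e.g. 59.7 µg/g for un-spiked WB, 8.9 for SR), never zero, so
    logarithmic dose models stay defined at every treatment.  ``pw_ni``
    is nickel in pore water or overlying water, µg/L.  Missing covariates
    are ``None``, never 0: a dash in a chemistry table means "not
    measured", not "absent".
    """

    model_config = ConfigDict(frozen=True)

    treatment_id: str
    sediment_id: str
    spike_level: int
    medium: Medium = Medium.SEDIMENT
    tr_ni: Optional[float] = None
    pw_ni: Optional[float] = None
    toc: Optional[float] = None
    avs: Optional[float] = None
    cec: Optional[float] = None
    ph: Optional[float] = None
    orp: Optional[float] = None
    clay: Optional[float] = None
    silt: Optional[float] = None
    sand: Optional[float] = None
    log_kd: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "TreatmentSpec":
        if not 0 <= self.spike_level <= 5:
            raise ValueError(f"spike_level must be 0-5, got {self.spike_level}")
        if self.medium is Medium.SEDIMENT:
            if self.tr_ni is None or self.tr_ni <= 0:
                raise ValueError(
                    f"sediment treatment {self.treatment_id!r} needs tr_ni > 0 "
                    "(controls carry measured background nickel, never 0)"
                )
        parts = (self.clay, self.silt, self.sand)
        if all(p is not None for p in parts):
            total = sum(parts)  # type: ignore[arg-type]
            if not 98.0 <= total <= 102.0:
                raise ValueError(
                    f"particle-size fractions of {self.treatment_id!r} sum to "
                    f"{total:g}%, outside [98, 102]"
                )
        return self

    @property
    def is_control(self) -> bool:
        return self.spike_level == 0


class WellOutcome(BaseModel):
    """Counts recovered from one test well at the end of the assay.

    Corpse recovery is incomplete, so ``n_live_adults + n_dead`` may fall
    short of ``n_added``; it can never exceed it.
    """

    model_config = ConfigDict(frozen=True)

    well_id: str
    treatment_id: str
    species: Species
    trial_id: str
    n_added: int
    n_live_adults: int
    n_dead: int = 0
    n_progeny: int = 0
    duration_h: int = 96

    @model_validator(mode="after")
    def _check(self) -> "WellOutcome":
        for name in ("n_added", "n_live_adults", "n_dead", "n_progeny"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_live_adults > self.n_added:
            raise ValueError(
                f"well {self.well_id!r}: live exceeds added "
                f"({self.n_live_adults} > {self.n_added})"
            )
        if self.n_live_adults + self.n_dead > self.n_added:
            raise ValueError(
                f"well {self.well_id!r}: live + dead exceeds added "
                f"({self.n_live_adults} + {self.n_dead} > {self.n_added})"
            )
        return self


class LongevityObservation(BaseModel):
    """One destructive daily harvest in an adult-survivorship assay.

    Each day a whole well is sacrificed, so every observation is an
    independent cohort; there is exactly one observation per
    (treatment, day).
    """

    model_config = ConfigDict(frozen=True)

    sediment_treatment: str
    day: int
    n_initial: int
    n_live: int

    @model_validator(mode="after")
    def _check(self) -> "LongevityObservation":
        if not 1 <= self.day <= 22:
            raise ValueError(f"day must be within 1-22, got {self.day}")
        if self.n_initial <= 0:
            raise ValueError("n_initial must be positive")
        if not 0 <= self.n_live <= self.n_initial:
            raise ValueError(
                f"day {self.day}: n_live {self.n_live} outside "
                f"[0, {self.n_initial}]"
            )
        return self

    @property
    def fraction_alive(self) -> float:
        return self.n_live / self.n_initial
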