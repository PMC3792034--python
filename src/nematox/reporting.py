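"""Analysis reports and the reference-replication check.

``replicate_reference`` re-derives every reported LC50 and LT50 from the
packaged best-fit coefficients: each dose-response curve is intersected
with its half-of-control target line (raised by one for the shifted
exponential) and each survivorship cubic with the 0.5 fraction line,
then compared with the reported value.  Deviations beyond the tolerance
flag the row — the CLI turns that into a nonzero exit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from typing import Optional

import pandas as pd

from . import dose_response as dr
from . import longevity as lg
from .io import fixture_path

try:
    __version__ = _pkg_version("nematox")
except PackageNotFoundError:  # running from a source tree
    __version__ = "0+unknown"

REPLICATION_TOLERANCE = 0.005  # relative


@dataclass
class ReplicationRow:
    label: str                 # e.g. "WB_Ce/quadratic" or "WB-0"
    quantity: str              # "lc50" (µg/g) or "lt50" (days)
    reported: float
    recomputed: Optional[float]
    abs_diff: Optional[float] = None
    rel_diff: Optional[float] = None
    within_tolerance: bool = False

    def __post_init__(self) -> None:
        if self.recomputed is not None:
            self.abs_diff = abs(self.recomputed - self.reported)
            self.rel_diff = self.abs_diff / abs(self.reported)
            self.within_tolerance = self.rel_diff <= REPLICATION_TOLERANCE


@dataclass
class ReplicationReport:
    rows: list[ReplicationRow]
    tolerance: float = REPLICATION_TOLERANCE

    @property
    def ok(self) -> bool:
        return all(r.within_tolerance for r in self.rows)

    @property
    def failures(self) -> list[ReplicationRow]:
        return [r for r in self.rows if not r.within_tolerance]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.rows])


def load_reference_dose_response() -> pd.DataFrame:
    """Published best-fit dose-response curves with targets and LC50s."""
    return pd.read_csv(fixture_path("reference_dose_response_fits"))


def load_reference_survivorship() -> pd.DataFrame:
    """Published survivorship cubics with reported 50%-survival days."""
    return pd.read_csv(fixture_path("reference_survivorship_fits"))


def _coefficients(row: pd.Series) -> tuple[float, ...]:
    return tuple(float(row[p]) for p in ("p1", "p2", "p3", "p4")
                 if pd.notna(row.get(p)))


def reference_dose_response_fits() -> list[tuple[str, dr.DoseResponseFit]]:
    """(label, fit-with-LC50) for every packaged reference curve."""
    out = []
    for _, row in load_reference_dose_response().iterrows():
        fit = dr.DoseResponseFit(
            family=dr.CurveFamily.parse(row["family"]),
            coefficients=_coefficients(row),
            r_squared=float(row["reported_r_squared"]),
            x_max=float(row["search_max"]) / 1.5,
        )
        fit = dr.estimate_lc50(fit, float(row["y_target"]),
                               search_max=float(row["search_max"]))
        out.append((f"{row['series_id']}/{fit.family.value}", fit))
    return out


def reference_survivorship_fits() -> list[lg.SurvivorshipFit]:
    out = []
    for _, row in load_reference_survivorship().iterrows():
        fit = lg.SurvivorshipFit(
            treatment_id=str(row["treatment_id"]),
            coefficients=_coefficients(row),
            r_squared=float(row["reported_r_squared"]),
            window=(1.0, float(row["day_max"])),
        )
        out.append(lg.estimate_lt50(fit))
    return out


def replicate_reference() -> ReplicationReport:
    """Recompute all 12 LC50s and 4 LT50s from packaged coefficients."""
    rows: list[ReplicationRow] = []
    ref_dr = load_reference_dose_response()
    for (label, fit), (_, raw) in zip(reference_dose_response_fits(),
                                      ref_dr.iterrows()):
        rows.append(ReplicationRow(
            label=label, quantity="lc50",
            reported=float(raw["reported_lc50"]), recomputed=fit.lc50,
        ))
    ref_sv = load_reference_survivorship()
    for fit, (_, raw) in zip(reference_survivorship_fits(), ref_sv.iterrows()):
        rows.append(ReplicationRow(
            label=fit.treatment_id, quantity="lt50",
            reported=float(raw["reported_lt50"]), recomputed=fit.lt50,
        ))
    return ReplicationReport(rows=rows)


@dataclass
class AnalysisReport:
    """Machine-readable bundle of one analysis run.

    The config digest is a SHA-256 over the canonical JSON of the inputs,
    so identical inputs and seed reproduce byte-identical reports; no
    timestamps are embedded.
    """

    seed: Optional[int] = None
    inputs: dict = field(default_factory=dict)
    endpoint_summaries: list[dict] = field(default_factory=list)
    dose_response_fits: list[dict] = field(default_factory=list)
    survivorship_fits: list[dict] = field(default_factory=list)
    group_comparisons: list[dict] = field(default_factory=list)

    @property
    def config_digest(self) -> str:
        blob = json.dumps({"seed": self.seed, "inputs": self.inputs},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_json(self) -> str:
        payload = {
            "version": __version__,
            "seed": self.seed,
            "config_digest": self.config_digest,
            "inputs": self.inputs,
            "endpoint_summaries": self.endpoint_summaries,
            "dose_response_fits": self.dose_response_fits,
            "survivorship_fits": self.survivorship_fits,
            "group_comparisons": self.group_comparisons,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def dose_response_fit_record(label: str, fit: dr.DoseResponseFit) -> dict:
    return {
        "label": label,
        "family": fit.family.value,
        "formula": fit.formula(),
        "coefficients": list(fit.coefficients),
        "r_squared": fit.r_squared,
        "r_squared_raw": fit.r_squared_raw,
        "y_target": fit.y_target,
        "lc50": fit.lc50 if fit.lc50 is not None else "not attained",
        "n_points": fit.n_points,
    }


def survivorship_fit_record(fit: lg.SurvivorshipFit) -> dict:
    return {
        "treatment_id": fit.treatment_id,
        "coefficients": list(fit.coefficients),
        "r_squared": fit.r_squared,
        "window": list(fit.window),
        "lt50": fit.lt50 if fit.lt50 is not None else "beyond window",
    }
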