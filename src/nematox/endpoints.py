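"""Per-well and per-treatment assay endpoints.

Three endpoints drive every downstream analysis: P0 recovery (live adults
recovered out of larvae added), F1 progeny per well, and the fecundity
index — recovered progeny per recovered live adult, computed per well and
treated as a single data point so the well, not the animal, is the unit
of replication.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Union

from .models import Species, WellOutcome

log = logging.getLogger(__name__)

ZeroRecoveryPolicy = Literal["zero", "exclude"]


@dataclass
class EndpointSummary:
    """Treatment-level endpoint means plus the per-well fecundity indices."""

    treatment_id: str
    species: Species
    n_wells: int
    mean_p0_recovery: float       # live adults per well
    mean_p0_fraction: float       # proportion of added larvae recovered live
    mean_progeny: float           # F1 larvae per well
    fecundity_indices: list[float] = field(default_factory=list)
    n_undefined_indices: int = 0  # wells with progeny but no live adults


def fecundity_index(
    well: WellOutcome,
    zero_recovery: ZeroRecoveryPolicy = "zero",
) -> Optional[float]:
    """Progeny recovered per live adult recovered, for one well.

    A well with no live adults and no progeny contributes an index of 0
    under the default policy (``"exclude"`` drops it instead).  A well
    with progeny but no live adults has no denominator; it returns
    ``None`` and is excluded from group statistics.
    """
    if well.n_live_adults > 0:
        return well.n_progeny / well.n_live_adults
    if well.n_progeny == 0:
        return 0.0 if zero_recovery == "zero" else None
    log.info(
        "well %s: %d progeny but no live adults; fecundity index undefined",
        well.well_id, well.n_progeny,
    )
    return None


def summarize_treatment(
    wells: Sequence[WellOutcome],
    zero_recovery: ZeroRecoveryPolicy = "zero",
) -> EndpointSummary:
    """Collapse one treatment's wells into an :class:`EndpointSummary`.

    Means are over wells; the per-well fecundity indices are retained so
    group comparisons can use n = number of wells.
    """
    if not wells:
        raise ValueError("summarize_treatment needs at least one well")
    ids = {(w.treatment_id, w.species) for w in wells}
    if len(ids) > 1:
        raise ValueError(f"mixed treatments/species in one summary: {sorted(ids)}")

    n = len(wells)
    indices: list[float] = []
    n_undef = 0
    for w in wells:
        idx = fecundity_index(w, zero_recovery)
        if idx is None:
            n_undef += 1
        else:
            indices.append(idx)
    return EndpointSummary(
        treatment_id=wells[0].treatment_id,
        species=wells[0].species,
        n_wells=n,
        mean_p0_recovery=sum(w.n_live_adults for w in wells) / n,
        mean_p0_fraction=sum(w.n_live_adults / w.n_added for w in wells) / n,
        mean_progeny=sum(w.n_progeny for w in wells) / n,
        fecundity_indices=indices,
        n_undefined_indices=n_undef,
    )


def summarize_all(
    wells: Iterable[WellOutcome],
    zero_recovery: ZeroRecoveryPolicy = "zero",
) -> list[EndpointSummary]:
    """One summary per (treatment, species), in first-seen order."""
    groups: dict[tuple[str, Species], list[WellOutcome]] = {}
    for w in wells:
        groups.setdefault((w.treatment_id, w.species), []).append(w)
    return [summarize_treatment(g, zero_recovery) for g in groups.values()]


def write_summary(
    summaries: Sequence[EndpointSummary],
    path,
    fmt: Literal["csv", "json"] = "csv",
) -> None:
    rows = [
        {
            "treatment_id": s.treatment_id,
            "species": s.species.value,
            "n_wells": s.n_wells,
            "mean_p0_recovery": s.mean_p0_recovery,
            "mean_p0_fraction": s.mean_p0_fraction,
            "mean_progeny": s.mean_progeny,
            "mean_fecundity_index": (
                sum(s.fecundity_indices) / len(s.fecundity_indices)
                if s.fecundity_indices else None
            ),
            "n_undefined_indices": s.n_undefined_indices,
        }
        for s in summaries
    ]
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]),
                                    lineterminator="\n")
            writer.writeheader()
            writer.writerows(rows)
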