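"""CSV readers/writers for well tables, treatment chemistry, and longevity series.

All tables are RFC-4180 CSV, UTF-8, header row required.  Loaders validate
every row through the domain types and reject bad input with the row number
and offending field.  The well-table writer emits a canonical form such
that ``write(load(x))`` reproduces ``x`` byte-identically.
"""

from __future__ import annotations

import csv
import io as _io
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from pydantic import ValidationError

from .models import LongevityObservation, Medium, TreatmentSpec, WellOutcome

PathLike = Union[str, Path]

WELL_COLUMNS = [
    "well_id", "treatment_id", "species", "trial_id",
    "n_added", "n_live_adults", "n_dead", "n_progeny", "duration_h",
]

TREATMENT_COLUMNS = [
    "treatment_id", "sediment_id", "spike_level", "medium",
    "tr_ni", "pw_ni", "toc", "avs", "cec", "ph", "orp",
    "clay", "silt", "sand", "log_kd",
]

LONGEVITY_COLUMNS = ["sediment_treatment", "day", "n_initial", "n_live"]


class TableValidationError(ValueError):
    """A table row failed validation; names the row and field."""


def _first_error(exc: ValidationError) -> str:
    err = exc.errors()[0]
    loc = ".".join(str(p) for p in err["loc"]) or "record"
    return f"{loc}: {err['msg']}"


def _read_rows(path: PathLike, required: Sequence[str]) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise TableValidationError(
                f"{path}: header missing column(s) {missing}"
            )
        return list(reader)


def load_well_table(
    path: PathLike,
    treatments: Optional[Iterable[TreatmentSpec]] = None,
) -> list[WellOutcome]:
    """Read validated well outcomes, preserving row order.

    When ``treatments`` is given, every well's ``treatment_id`` must be
    present in it; unknown ids are rejected with the row number.
    """
    known = {t.treatment_id for t in treatments} if treatments is not None else None
    wells: list[WellOutcome] = []
    for i, row in enumerate(_read_rows(path, WELL_COLUMNS), start=2):
        try:
            well = WellOutcome(**{k: row[k] for k in WELL_COLUMNS})
        except ValidationError as exc:
            raise TableValidationError(
                f"{path} row {i}: {_first_error(exc)}"
            ) from exc
        if known is not None and well.treatment_id not in known:
            raise TableValidationError(
                f"{path} row {i}: treatment_id: unknown treatment "
                f"{well.treatment_id!r}"
            )
        wells.append(well)
    return wells


def write_well_table(wells: Iterable[WellOutcome], path: PathLike) -> None:
    """Write wells in canonical CSV form (round-trips byte-identically)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(WELL_COLUMNS)
        for w in wells:
            writer.writerow([
                w.well_id, w.treatment_id, w.species.value, w.trial_id,
                w.n_added, w.n_live_adults, w.n_dead, w.n_progeny, w.duration_h,
            ])


def load_treatment_table(path: PathLike) -> list[TreatmentSpec]:
    """Read treatment chemistry rows; empty cells become absent covariates."""
    specs: list[TreatmentSpec] = []
    for i, row in enumerate(_read_rows(path, TREATMENT_COLUMNS), start=2):
        fields = {k: (v if v not in ("", None) else None)
                  for k, v in row.items() if k in TREATMENT_COLUMNS}
        try:
            specs.append(TreatmentSpec(**fields))
        except ValidationError as exc:
            raise TableValidationError(
                f"{path} row {i}: {_first_error(exc)}"
            ) from exc
    return specs


def load_longevity_table(path: PathLike) -> list[LongevityObservation]:
    """Read destructive daily-harvest observations; duplicates rejected."""
    obs: list[LongevityObservation] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(_read_rows(path, LONGEVITY_COLUMNS), start=2):
        try:
            o = LongevityObservation(**{k: row[k] for k in LONGEVITY_COLUMNS})
        except ValidationError as exc:
            raise TableValidationError(
                f"{path} row {i}: {_first_error(exc)}"
            ) from exc
        key = (o.sediment_treatment, o.day)
        if key in seen:
            raise TableValidationError(
                f"{path} row {i}: duplicate observation for "
                f"treatment {key[0]!r} day {key[1]}"
            )
        seen.add(key)
        obs.append(o)
    return obs


def wells_to_json(wells: Iterable[WellOutcome]) -> str:
    """JSON export of validated well records (stable key order)."""
    return json.dumps(
        [json.loads(w.model_dump_json()) for w in wells],
        indent=2, sort_keys=True,
    )


# ---------------------------------------------------------------------------
# Packaged chemistry fixtures

_DATA = resources.files("nematox") / "data"

FIXTURES = {
    "sediments_unspiked": "sediments_unspiked.csv",
    "porewater_unspiked": "porewater_unspiked.csv",
    "elements_unspiked": "elements_unspiked.csv",
    "sediments_spiked": "sediments_spiked.csv",
    "reference_dose_response_fits": "reference_dose_response_fits.csv",
    "reference_survivorship_fits": "reference_survivorship_fits.csv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data table."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}")
    return Path(str(_DATA / FIXTURES[name]))


def load_unspiked_treatments() -> list[TreatmentSpec]:
    """Physico-chemical characteristics of the eight un-spiked sediments."""
    return load_treatment_table(fixture_path("sediments_unspiked"))


def load_spiked_treatments() -> list[TreatmentSpec]:
    """The WB and SR nickel-spiked series (controls plus spike levels 1-5)."""
    return load_treatment_table(fixture_path("sediments_spiked"))


def load_constituent_table(name: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a chemistry table with detection-limit censoring.

    Returns ``(values, below_detection)``: values as floats with censored
    cells at their detection limit and not-measured cells as NaN;
    ``below_detection`` flags cells reported as "<limit".
    """
    raw = pd.read_csv(fixture_path(name), index_col=0, dtype=str)
    below = raw.map(lambda v: isinstance(v, str) and v.startswith("<"))

    def _parse(v):
        if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
            return float("nan")
        return float(v.lstrip("<"))

    return raw.map(_parse), below


def water_treatments(
    concentrations: Sequence[float] = (50, 100, 200, 400, 800),
) -> list[TreatmentSpec]:
    """Nickel-chloride water-only treatments plus an un-spiked control."""
    specs = [TreatmentSpec(treatment_id="W-0", sediment_id="W",
                           spike_level=0, medium=Medium.WATER, pw_ni=0.0)]
    for level, c in enumerate(sorted(concentrations), start=1):
        specs.append(TreatmentSpec(
            treatment_id=f"W-{level}", sediment_id="W",
            spike_level=level, medium=Medium.WATER, pw_ni=float(c),
        ))
    return specs


def _roundtrip_bytes(wells: Sequence[WellOutcome]) -> bytes:
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(WELL_COLUMNS)
    for w in wells:
        writer.writerow([
            w.well_id, w.treatment_id, w.species.value, w.trial_id,
            w.n_added, w.n_live_adults, w.n_dead, w.n_progeny, w.duration_h,
        ])
    return buf.getvalue().encode("utf-8")
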