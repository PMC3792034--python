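"""One-way ANOVA, Tukey HSD, and compact-letter-display grouping.

Treatments are compared on per-well endpoint values (the well is the
unit of replication), assuming homogeneity of variance across groups —
a Levene diagnostic is logged but never gates the analysis.  Pairwise
comparisons use the studentized-range (Tukey HSD) procedure with the
Tukey-Kramer harmonic-mean adjustment for unbalanced groups.  Figure
annotations come from a compact letter display: groups sharing a letter
are pairwise non-significant at the chosen alpha.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Dict, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .endpoints import fecundity_index
from .models import WellOutcome

log = logging.getLogger(__name__)

Endpoint = Literal["p0_recovery", "progeny", "fecundity_index"]
PairKey = Tuple[str, str]


@dataclass
class GroupComparison:
    endpoint: str
    groups: list[str]
    f_statistic: float
    p_value: float
    pairwise: Dict[PairKey, float] = field(default_factory=dict)
    letters: Dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05


def _validate(groups: Mapping[str, Sequence[float]]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than two values")


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA: (F, p).

    All values enter the test — outliers are not trimmed.  Identical
    groups give F = 0.
    """
    _validate(groups)
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    try:
        _, lev_p = stats.levene(*arrays)
        log.debug("Levene homogeneity-of-variance diagnostic: p = %.4g", lev_p)
    except Exception:  # constant groups etc.; diagnostic only
        pass
    f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # zero between- and within-group variance
        return 0.0, 1.0
    return float(f), float(p)


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> Dict[PairKey, float]:
    """Tukey HSD adjusted p-values for every unordered pair of groups."""
    _validate(groups)
    names = list(groups)
    res = stats.tukey_hsd(*[np.asarray(groups[n], dtype=float) for n in names])
    pairwise: Dict[PairKey, float] = {}
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                p = float(res.pvalue[i, j])
                pairwise[(a, b)] = p
                pairwise[(b, a)] = p
    return pairwise


def compact_letter_display(
    pairwise: Mapping[PairKey, float],
    alpha: float,
    order: Sequence[str],
) -> Dict[str, str]:
    """Insert-and-absorb letter assignment.

    Guarantees exactly: two groups share a letter iff their pairwise
    p-value exceeds ``alpha``.  Non-transitive significance patterns
    (A~B, B~C, A≠C) are representable through overlapping letter sets,
    never an error.  ``order`` fixes which group gets "a" (conventionally
    group means, descending).
    """
    names = list(order)
    idx = {n: i for i, n in enumerate(names)}
    significant = [(a, b) for (a, b), p in pairwise.items()
                   if idx.get(a, 0) < idx.get(b, 0) and p <= alpha]
    significant.sort(key=lambda ab: (idx[ab[0]], idx[ab[1]]))

    columns: list[set[str]] = [set(names)]
    for a, b in significant:
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop any column contained in another
        columns = []
        for col in new_columns:
            if any(col < other for other in new_columns) or col in columns:
                continue
            columns.append(col)

    columns.sort(key=lambda col: min(idx[n] for n in col) if col else len(names))
    letters = {n: "" for n in names}
    for k, col in enumerate(columns):
        symbol = (string.ascii_lowercase[k] if k < 26
                  else string.ascii_lowercase[k // 26 - 1]
                  + string.ascii_lowercase[k % 26])
        for n in names:
            if n in col:
                letters[n] += symbol
    return letters


def _endpoint_values(wells: Sequence[WellOutcome], endpoint: Endpoint) -> list[float]:
    if endpoint == "p0_recovery":
        return [float(w.n_live_adults) for w in wells]
    if endpoint == "progeny":
        return [float(w.n_progeny) for w in wells]
    if endpoint == "fecundity_index":
        # undefined indices (progeny but no surviving adults) drop listwise
        vals = [fecundity_index(w) for w in wells]
        return [v for v in vals if v is not None]
    raise ValueError(f"unknown endpoint {endpoint!r}")


def compare_endpoint(
    wells: Sequence[WellOutcome],
    endpoint: Endpoint,
    alpha: float = 0.05,
) -> GroupComparison:
    """Group wells by treatment and run ANOVA + Tukey + letter display."""
    grouped: Dict[str, list[WellOutcome]] = {}
    for w in wells:
        grouped.setdefault(w.treatment_id, []).append(w)
    values = {tid: _endpoint_values(ws, endpoint) for tid, ws in grouped.items()}
    values = {tid: v for tid, v in values.items() if len(v) >= 2}

    f, p = one_way_anova(values)
    pairwise = tukey_hsd(values, alpha)
    order = sorted(values, key=lambda t: -float(np.mean(values[t])))
    letters = compact_letter_display(pairwise, alpha, order)
    return GroupComparison(
        endpoint=endpoint, groups=order, f_statistic=f, p_value=p,
        pairwise=pairwise, letters=letters, alpha=alpha,
    )
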