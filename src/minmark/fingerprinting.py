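"""Multilocus fingerprints, duplicate grouping and QC/QA matching.

An accession's fingerprint is its call vector over a marker panel.  Two
accessions are *unresolved* when no panel marker distinguishes them under the
chosen policy; a missing call never separates two accessions (conservative —
a no-call is an absence of evidence).  Because of missing calls the
cannot-resolve relation need not be transitive, so duplicate groups are
defined as connected components of that relation, and groups held together
only through missing-heavy intermediaries are flagged for curator attention.

The discrimination rate of a panel is the percentage of accessions whose
fingerprint is unique in the population (singleton groups), reported to two
decimals with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import DataError, IdentityError
from .genotype import GenotypeCall, GenotypeMatrix
from .panel import MarkerPanel
from .selection import DiscriminationPolicy, resolved_matrix

__all__ = [
    "FingerprintTable",
    "fingerprint_table",
    "discrimination_rate",
    "duplicate_report",
    "MatchStatus",
    "MatchVerdict",
    "match_fingerprint",
]


def _round2_half_up(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _resolved_any(calls: np.ndarray, policy: DiscriminationPolicy) -> np.ndarray:
    """OR of per-marker resolved matrices over all panel columns."""
    n = calls.shape[0]
    out = np.zeros((n, n), dtype=bool)
    for j in range(calls.shape[1]):
        out |= resolved_matrix(calls[:, j], policy)
    return out


def _components(cannot: np.ndarray) -> list[list[int]]:
    n_comp, labels = connected_components(csr_matrix(cannot), directed=False)
    groups: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        groups[lab].append(i)
    # deterministic order: by first member index
    groups.sort(key=lambda g: g[0])
    return groups


@dataclass
class FingerprintTable:
    """Per-accession fingerprints over a panel plus the duplicate-group partition.

    ``groups`` partitions the accessions into identical-fingerprint classes
    (connected components of the cannot-resolve relation); ``flagged_groups``
    marks components containing at least one internally *resolved* pair,
    i.e. held together only via missing-call bridges.
    """

    panel: list[str]
    accession_ids: list[str]
    calls: np.ndarray  # (n_accessions, n_panel) int8
    policy: DiscriminationPolicy
    groups: list[list[str]]
    flagged_groups: list[bool]

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_unique(self) -> int:
        return sum(1 for g in self.groups if len(g) == 1)

    def row(self, accession_id: str) -> np.ndarray:
        try:
            i = self.accession_ids.index(accession_id)
        except ValueError:
            raise IdentityError(f"unknown accession identifier: {accession_id!r}") from None
        return self.calls[i]

    def restrict(self, accessions: Sequence[str]) -> "FingerprintTable":
        """Recompute the table (and grouping) on a subset of accessions."""
        idx = []
        for a in accessions:
            try:
                idx.append(self.accession_ids.index(a))
            except ValueError:
                raise IdentityError(f"unknown accession identifier: {a!r}") from None
        sub = self.calls[idx]
        return _build_table(self.panel, [self.accession_ids[i] for i in idx], sub, self.policy)


def _build_table(panel, accession_ids, calls, policy) -> FingerprintTable:
    resolved = _resolved_any(calls, policy)
    n = len(accession_ids)
    cannot = ~resolved
    np.fill_diagonal(cannot, False)
    comp = _components(cannot)
    groups = [[accession_ids[i] for i in g] for g in comp]
    flagged = []
    for g in comp:
        if len(g) < 2:
            flagged.append(False)
            continue
        sub = resolved[np.ix_(g, g)]
        flagged.append(bool(sub.any()))  # some internal pair IS resolved: missing-bridged
    return FingerprintTable(list(panel), list(accession_ids), calls, policy, groups, flagged)


def fingerprint_table(
    gm: GenotypeMatrix,
    panel: MarkerPanel | Sequence[str],
    policy: DiscriminationPolicy = DiscriminationPolicy.STRICT,
) -> FingerprintTable:
    """Extract fingerprints over ``panel`` and partition into duplicate groups."""
    markers = list(panel.markers if isinstance(panel, MarkerPanel) else panel)
    cols = [gm.marker_index(m) for m in markers]
    calls = gm.calls[:, cols].copy() if cols else np.empty((gm.n_accessions, 0), dtype=np.int8)
    return _build_table(markers, gm.accession_ids, calls, DiscriminationPolicy(policy))


def discrimination_rate(ft: FingerprintTable) -> float:
    """Percentage of accessions with a unique fingerprint (2 d.p., half-up)."""
    if ft.n_accessions == 0:
        raise DataError("discrimination rate undefined for an empty table")
    return _round2_half_up(100.0 * ft.n_unique / ft.n_accessions)


def duplicate_report(
    ft: FingerprintTable,
    accession_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Non-singleton groups listed with metadata side by side, for curator review.

    One row per member of each group of size ≥ 2; no inference is made about
    why the accessions coincide.
    """
    rows = []
    for gid, (group, flag) in enumerate(zip(ft.groups, ft.flagged_groups)):
        if len(group) < 2:
            continue
        for acc in group:
            row = {"group": gid, "group_size": len(group), "accession": acc,
                   "missing_bridged": flag}
            if accession_meta is not None and acc in accession_meta.index:
                for col in accession_meta.columns:
                    row[col] = accession_meta.loc[acc, col]
            rows.append(row)
    return pd.DataFrame(rows)


class MatchStatus(str, Enum):
    MATCH = "MATCH"
    MISMATCH = "MISMATCH"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass
class MatchVerdict:
    """Outcome of comparing a query fingerprint against a registry entry."""

    status: MatchStatus
    accession_id: str | None
    n_compared: int
    n_mismatch: int
    mismatching_markers: list[str]
    best_alternatives: list[tuple[str, int]]


def _as_query_vector(query, panel: list[str]) -> np.ndarray:
    if isinstance(query, Mapping):
        return np.array(
            [int(query.get(m, GenotypeCall.MISSING)) for m in panel], dtype=np.int8
        )
    q = np.asarray(query, dtype=np.int8)
    if q.shape != (len(panel),):
        raise DataError(f"query length {q.shape} does not match panel size {len(panel)}")
    return q


def match_fingerprint(
    query,
    registry: FingerprintTable,
    tolerance: int = 0,
    min_informative: int = 1,
    expected: str | None = None,
) -> MatchVerdict:
    """QC/QA comparison of a query sample against registered fingerprints.

    Comparisons are counted only where both the query and the registry call
    are non-missing.  When ``expected`` names a registry entry, the verdict is
    about that entry (the regenerated stock vs its originator); otherwise the
    verdict is about the best-matching entry.  ``best_alternatives`` lists the
    registry entries with the fewest mismatches to support identity recovery
    after a failed QC.

    Status: AMBIGUOUS when fewer than ``min_informative`` comparisons were
    possible, else MISMATCH iff mismatches exceed ``tolerance``.
    """
    if registry.n_accessions == 0:
        raise DataError("cannot match against an empty registry")
    q = _as_query_vector(query, registry.panel)
    q_nm = q != GenotypeCall.MISSING
    reg_nm = registry.calls != GenotypeCall.MISSING
    both = reg_nm & q_nm[None, :]
    mismatch = both & (registry.calls != q[None, :])
    n_compared = both.sum(axis=1)
    n_mismatch = mismatch.sum(axis=1)

    if expected is not None:
        try:
            i = registry.accession_ids.index(expected)
        except ValueError:
            raise IdentityError(f"unknown accession identifier: {expected!r}") from None
    else:
        i = int(np.lexsort((np.arange(len(n_mismatch)), n_mismatch))[0])

    order = np.lexsort((np.arange(len(n_mismatch)), n_mismatch))
    best = [
        (registry.accession_ids[j], int(n_mismatch[j]))
        for j in order
        if j != i
    ][:5]

    mism_markers = [registry.panel[k] for k in np.flatnonzero(mismatch[i])]
    if n_compared[i] < min_informative:
        status = MatchStatus.AMBIGUOUS
    elif n_mismatch[i] > tolerance:
        status = MatchStatus.MISMATCH
    else:
        status = MatchStatus.MATCH
    return MatchVerdict(
        status=status,
        accession_id=registry.accession_ids[i],
        n_compared=int(n_compared[i]),
        n_mismatch=int(n_mismatch[i]),
        mismatching_markers=mism_markers,
        best_alternatives=best,
    )
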