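"""Greedy minimal-marker-set selection.

The goal is the smallest ordered SNP panel whose joint calls discriminate a
population of accessions.  Selection works on unresolved accession *pairs*:

1. forced markers (already-validated assays) are seeded first, in the order
   given, consuming whatever pairs they resolve;
2. if no pair has been resolved yet, the first greedy pick is the eligible
   marker with the highest minor allele frequency — the marker that splits
   the population most evenly;
3. every subsequent pick maximises *incremental discrimination*: the number
   of still-unresolved pairs the candidate distinguishes.  Ties are broken
   by marker input order, the only reproducible data-independent rule.

The loop stops when no unresolved pairs remain, no candidate resolves a new
pair, or an optional size cap is reached.  A marker perfectly correlated with
an already-selected one necessarily has zero incremental value, so LD-redundant
markers are never selected — no explicit LD filter is needed.

Two discrimination policies are offered.  STRICT (default) counts only
opposite homozygotes as distinguishing — appropriate for inbred material,
where heterozygote clusters are the least reliable KASP calls.  GENOTYPIC
counts any two distinct non-missing states.  A missing call never
discriminates under either policy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError
from .genotype import GenotypeCall, GenotypeMatrix
from .panel import MarkerPanel
from .stats import _frequency_arrays

__all__ = [
    "DiscriminationPolicy",
    "SelectionConfig",
    "pair_resolved",
    "incremental_discrimination",
    "select_minimal_markers",
    "augment_panel",
    "validate_panel",
    "PanelValidation",
]


class DiscriminationPolicy(str, Enum):
    STRICT = "STRICT"        # only opposite homozygotes discriminate
    GENOTYPIC = "GENOTYPIC"  # any two distinct non-missing states discriminate


@dataclass(frozen=True)
class SelectionConfig:
    """Options for :func:`select_minimal_markers`.

    ``forced_markers`` are seeded into the panel in the given order;
    ``excluded_markers`` are never candidates.  Ties on MAF or incremental
    count are broken by marker input order (first wins).
    """

    forced_markers: tuple[str, ...] = ()
    excluded_markers: frozenset[str] = frozenset()
    max_markers: int | None = None
    policy: DiscriminationPolicy = DiscriminationPolicy.STRICT

    def __post_init__(self) -> None:
        object.__setattr__(self, "forced_markers", tuple(str(m) for m in self.forced_markers))
        object.__setattr__(self, "excluded_markers", frozenset(str(m) for m in self.excluded_markers))
        object.__setattr__(self, "policy", DiscriminationPolicy(self.policy))
        overlap = set(self.forced_markers) & self.excluded_markers
        if overlap:
            raise ConfigurationError(f"markers both forced and excluded: {sorted(overlap)}")
        if self.max_markers is not None and self.max_markers < 0:
            raise ConfigurationError("max_markers must be non-negative")


def pair_resolved(call_a, call_b, policy: DiscriminationPolicy) -> bool:
    """Does one marker's pair of calls distinguish two accessions?

    A comparison involving a missing call is never discriminating.
    """
    a, b = int(call_a), int(call_b)
    if a == GenotypeCall.MISSING or b == GenotypeCall.MISSING:
        return False
    if DiscriminationPolicy(policy) is DiscriminationPolicy.STRICT:
        return {a, b} == {int(GenotypeCall.HOM_REF), int(GenotypeCall.HOM_ALT)}
    return a != b


def resolved_matrix(marker_calls: np.ndarray, policy: DiscriminationPolicy) -> np.ndarray:
    """Boolean (n, n) matrix: does this marker resolve accession pair (i, j)?"""
    c = np.asarray(marker_calls)
    if DiscriminationPolicy(policy) is DiscriminationPolicy.STRICT:
        r = c == GenotypeCall.HOM_REF
        a = c == GenotypeCall.HOM_ALT
        m = r[:, None] & a[None, :]
        return m | m.T
    nm = c != GenotypeCall.MISSING
    diff = c[:, None] != c[None, :]
    return diff & nm[:, None] & nm[None, :]


def incremental_discrimination(
    gm: GenotypeMatrix,
    candidate_marker: str,
    unresolved: Iterable[tuple[str, str]],
    policy: DiscriminationPolicy = DiscriminationPolicy.STRICT,
) -> int:
    """Number of given unresolved accession pairs the candidate resolves."""
    col = gm.marker_calls(candidate_marker)
    count = 0
    for a, b in unresolved:
        ia, ib = gm.accession_index(a), gm.accession_index(b)
        if pair_resolved(col[ia], col[ib], policy):
            count += 1
    return count


def _counts_per_marker(calls: np.ndarray, U: np.ndarray, policy: DiscriminationPolicy) -> np.ndarray:
    """Unresolved pairs resolved by each marker, vectorised via matmuls.

    ``U`` is the symmetric boolean unresolved-pair matrix (diagonal False).
    """
    Uf = U.astype(np.float32)
    if policy is DiscriminationPolicy.STRICT:
        R = (calls == GenotypeCall.HOM_REF).astype(np.float32)
        A = (calls == GenotypeCall.HOM_ALT).astype(np.float32)
        # pair {a,b} with a HOM_REF, b HOM_ALT contributes exactly once
        cnt = np.einsum("am,am->m", R, Uf @ A)
    else:
        NM = (calls != GenotypeCall.MISSING).astype(np.float32)
        total = np.einsum("am,am->m", NM, Uf @ NM)
        same = np.zeros(calls.shape[1], dtype=np.float64)
        for s in (GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT):
            S = (calls == s).astype(np.float32)
            same += np.einsum("am,am->m", S, Uf @ S)
        cnt = (total - same) / 2.0  # symmetric U counts each unordered pair twice
    return np.rint(cnt).astype(np.int64)


def _n_pairs(U: np.ndarray) -> int:
    return int(np.count_nonzero(U)) // 2


def select_minimal_markers(gm: GenotypeMatrix, config: SelectionConfig | None = None) -> MarkerPanel:
    """Greedy selection of a minimal discriminating marker panel.

    Returns a :class:`~minmark.panel.MarkerPanel` whose bookkeeping satisfies
    ``sum(newly_resolved) + unresolved_pairs_remaining == n(n−1)/2``.

    Raises
    ------
    IdentityError
        A forced or excluded marker is absent from the matrix.
    ConfigurationError
        Every marker is excluded, or forced/excluded sets overlap.
    """
    if config is None:
        config = SelectionConfig()
    if gm.n_accessions == 0 or gm.n_markers == 0:
        raise ConfigurationError("cannot select markers from an empty matrix")
    for m in list(config.forced_markers) + sorted(config.excluded_markers):
        gm.marker_index(m)  # raises IdentityError for unknown ids
    candidate_mask = np.array(
        [m not in config.excluded_markers for m in gm.marker_ids], dtype=bool
    )
    if not candidate_mask.any():
        raise ConfigurationError("all markers are excluded")

    n = gm.n_accessions
    total_pairs = n * (n - 1) // 2
    U = ~np.eye(n, dtype=bool)
    policy = config.policy
    calls = gm.calls

    selected: list[str] = []
    newly: list[int] = []

    def cap_reached() -> bool:
        return config.max_markers is not None and len(selected) >= config.max_markers

    # phase 0: forced markers, in order
    for m in config.forced_markers:
        if cap_reached():
            break
        M = resolved_matrix(gm.marker_calls(m), policy)
        gained = _n_pairs(U & M)
        U &= ~M
        selected.append(m)
        newly.append(gained)
        candidate_mask[gm.marker_index(m)] = False

    resolved_any = sum(newly) > 0

    # phase 1: highest-MAF first pick, when forced markers resolved nothing
    if not resolved_any and _n_pairs(U) > 0 and not cap_reached():
        counts = _counts_per_marker(calls, U, policy)
        counts[~candidate_mask] = 0
        if counts.max() > 0:
            _, _, _, _, maf = _frequency_arrays(gm)
            maf = np.where(np.isnan(maf), -1.0, maf)
            maf[(~candidate_mask) | (counts <= 0)] = -1.0
            j = int(np.argmax(maf))  # argmax keeps the first index on ties
            M = resolved_matrix(calls[:, j], policy)
            gained = _n_pairs(U & M)
            U &= ~M
            selected.append(gm.marker_ids[j])
            newly.append(gained)
            candidate_mask[j] = False

    # phase 2: pure greedy on incremental discrimination
    while _n_pairs(U) > 0 and candidate_mask.any() and not cap_reached():
        counts = _counts_per_marker(calls, U, policy)
        counts[~candidate_mask] = -1
        j = int(np.argmax(counts))
        if counts[j] <= 0:
            break  # no candidate adds value
        M = resolved_matrix(calls[:, j], policy)
        gained = _n_pairs(U & M)
        U &= ~M
        selected.append(gm.marker_ids[j])
        newly.append(gained)
        candidate_mask[j] = False

    remaining = _n_pairs(U)
    fraction = (total_pairs - remaining) / total_pairs if total_pairs else 1.0
    return MarkerPanel(
        markers=selected,
        newly_resolved=newly,
        unresolved_pairs_remaining=remaining,
        resolved_fraction=fraction,
        forced=list(config.forced_markers),
    )


def augment_panel(
    gm_new: GenotypeMatrix,
    base_panel: MarkerPanel,
    config: SelectionConfig | None = None,
) -> MarkerPanel:
    """Extend an existing panel for a new population.

    Equivalent to re-running selection with the base panel force-included, so
    the returned panel starts with the base markers in order and appends
    whatever the new population still requires.
    """
    if config is None:
        config = SelectionConfig()
    for m in base_panel.markers:
        gm_new.marker_index(m)
    forced = tuple(base_panel.markers) + tuple(
        m for m in config.forced_markers if m not in base_panel.markers
    )
    return select_minimal_markers(gm_new, replace(config, forced_markers=forced))


@dataclass
class PanelValidation:
    """Deterministic recomputation of a panel's bookkeeping on a population."""

    resolved_fraction: float
    n_pairs_total: int
    n_pairs_unresolved: int
    unresolved_pairs: list[tuple[str, str]]
    per_marker_contribution: dict[str, int]


def validate_panel(
    gm: GenotypeMatrix,
    panel: MarkerPanel | Sequence[str],
    policy: DiscriminationPolicy = DiscriminationPolicy.STRICT,
) -> PanelValidation:
    """Recompute what a panel resolves on ``gm``.

    ``per_marker_contribution`` is the incremental count of each panel marker
    applied in panel order (the same bookkeeping selection would produce had
    it picked these markers in this order).
    """
    markers = list(panel.markers if isinstance(panel, MarkerPanel) else panel)
    for m in markers:
        gm.marker_index(m)
    n = gm.n_accessions
    total_pairs = n * (n - 1) // 2
    U = ~np.eye(n, dtype=bool)
    contribution: dict[str, int] = {}
    for m in markers:
        M = resolved_matrix(gm.marker_calls(m), policy)
        contribution[m] = _n_pairs(U & M)
        U &= ~M
    iu = np.triu_indices(n, k=1)
    mask = U[iu]
    unresolved = [
        (gm.accession_ids[i], gm.accession_ids[j])
        for i, j in zip(iu[0][mask], iu[1][mask])
    ]
    remaining = len(unresolved)
    fraction = (total_pairs - remaining) / total_pairs if total_pairs else 1.0
    return PanelValidation(
        resolved_fraction=fraction,
        n_pairs_total=total_pairs,
        n_pairs_unresolved=remaining,
        unresolved_pairs=unresolved,
        per_marker_contribution=contribution,
    )
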