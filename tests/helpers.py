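"""Shared test helpers: matrix builders and independent brute-force oracles.

The oracles deliberately use the atomic :func:`pair_resolved` predicate and
plain Python enumeration, independent of the vectorised implementation paths
they are used to check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from minmark import GenotypeCall, GenotypeMatrix
from minmark.selection import DiscriminationPolicy, pair_resolved

# single-character call codes for compact matrix literals
_CODES = {
    "R": GenotypeCall.HOM_REF,
    "A": GenotypeCall.HOM_ALT,
    "H": GenotypeCall.HET,
    ".": GenotypeCall.MISSING,
}


def gm_from_rows(rows: list[str], accession_ids=None, marker_ids=None) -> GenotypeMatrix:
    """Build a matrix from strings like ["RRA.", "AAH."], one row per accession."""
    calls = np.array([[_CODES[c] for c in row] for row in rows], dtype=np.int8)
    n, m = calls.shape
    acc = accession_ids or [f"acc{i}" for i in range(n)]
    mks = marker_ids or [f"m{j}" for j in range(m)]
    return GenotypeMatrix(acc, mks, calls)


def random_gm(rng, n_acc, n_mark, het=False, missing=0.0) -> GenotypeMatrix:
    states = [GenotypeCall.HOM_REF, GenotypeCall.HOM_ALT]
    if het:
        states.append(GenotypeCall.HET)
    calls = rng.choice(np.array(states, dtype=np.int8), size=(n_acc, n_mark))
    if missing > 0:
        calls[rng.random((n_acc, n_mark)) < missing] = GenotypeCall.MISSING
    return GenotypeMatrix(
        [f"acc{i}" for i in range(n_acc)], [f"m{j}" for j in range(n_mark)], calls
    )


def marker_pair_masks(gm: GenotypeMatrix, policy: DiscriminationPolicy) -> tuple[list[int], int]:
    """Per-marker bitmask over accession pairs resolved by that marker.

    Returns (masks, n_pairs); bit ``k`` indexes the k-th pair of
    ``itertools.combinations(range(n), 2)``.
    """
    n = gm.n_accessions
    pairs = list(combinations(range(n), 2))
    masks = []
    for j in range(gm.n_markers):
        col = gm.calls[:, j]
        mask = 0
        for k, (a, b) in enumerate(pairs):
            if pair_resolved(col[a], col[b], policy):
                mask |= 1 << k
        masks.append(mask)
    return masks, len(pairs)


def brute_force_min_panel_size(gm: GenotypeMatrix, policy: DiscriminationPolicy) -> int:
    """Size of the smallest marker subset resolving every resolvable pair."""
    masks, _ = marker_pair_masks(gm, policy)
    target = 0
    for m in masks:
        target |= m
    if target == 0:
        return 0
    for size in range(1, gm.n_markers + 1):
        for combo in combinations(range(gm.n_markers), size):
            acc = 0
            for j in combo:
                acc |= masks[j]
            if acc == target:
                return size
    raise AssertionError("unreachable: full set resolves target by construction")


def brute_force_groups(gm: GenotypeMatrix, panel_markers, policy) -> list[frozenset]:
    """Duplicate groups as transitive closure of the cannot-resolve relation,
    computed pair-by-pair with the atomic predicate (union-find)."""
    n = gm.n_accessions
    cols = [gm.marker_calls(m) for m in panel_markers]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in combinations(range(n), 2):
        if not any(pair_resolved(col[a], col[b], policy) for col in cols):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(gm.accession_ids[i])
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: sorted(g)[0])
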