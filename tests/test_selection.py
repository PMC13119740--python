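"""Greedy minimal-marker selection: atomic predicate, greedy contract, oracles."""

import numpy as np
import pytest

from minmark import (
    DiscriminationPolicy,
    GenotypeCall,
    GenotypeMatrix,
    MarkerPanel,
    SelectionConfig,
    augment_panel,
    incremental_discrimination,
    pair_resolved,
    select_minimal_markers,
    validate_panel,
)
from minmark.errors import ConfigurationError, IdentityError

from helpers import (
    brute_force_min_panel_size,
    gm_from_rows,
    marker_pair_masks,
    random_gm,
)

STRICT = DiscriminationPolicy.STRICT
GENO = DiscriminationPolicy.GENOTYPIC
R, A, H, M = (
    GenotypeCall.HOM_REF,
    GenotypeCall.HOM_ALT,
    GenotypeCall.HET,
    GenotypeCall.MISSING,
)


@pytest.mark.parametrize(
    "a,b,policy,expected",
    [
        (R, A, STRICT, True),
        (A, R, STRICT, True),
        (R, H, STRICT, False),
        (R, H, GENO, True),
        (H, A, GENO, True),
        (R, R, STRICT, False),
        (R, R, GENO, False),
        (R, M, STRICT, False),
        (R, M, GENO, False),  # missing never discriminates
        (M, M, GENO, False),
        (H, H, GENO, False),
    ],
)
def test_pair_resolved_truth_table(a, b, policy, expected):
    assert pair_resolved(a, b, policy) is expected


def test_incremental_discrimination_examples():
    gm = gm_from_rows(["RR", "RR", "AR", "AR"], marker_ids=["m1", "mono"])
    all_pairs = [("acc0", "acc2"), ("acc0", "acc3"), ("acc1", "acc2"),
                 ("acc1", "acc3"), ("acc0", "acc1"), ("acc2", "acc3")]
    # calls (R,R,A,A): the four R-vs-A pairs
    assert incremental_discrimination(gm, "m1", all_pairs, STRICT) == 4
    assert incremental_discrimination(gm, "mono", all_pairs, STRICT) == 0


def test_duplicate_of_selected_marker_adds_nothing():
    gm = gm_from_rows(["RR", "RR", "AA", "AA"], marker_ids=["m1", "m1copy"])
    panel = select_minimal_markers(gm)
    # after m1 resolves its pairs, its copy has zero incremental value
    assert "m1copy" not in panel.markers or panel.newly_resolved[panel.markers.index("m1copy")] == 0


def test_two_marker_instance_selects_the_unique_minimum():
    """m1=(R,R,A,A), m2=(R,A,R,A), m3 duplicate of m1 → panel [m1, m2]."""
    gm = gm_from_rows(
        ["RRR", "RAR", "ARA", "AAA"],
        marker_ids=["m1", "m2", "m3"],
    )
    panel = select_minimal_markers(gm)
    assert panel.markers == ["m1", "m2"]
    assert panel.unresolved_pairs_remaining == 0
    assert brute_force_min_panel_size(gm, STRICT) == 2


def test_identical_accessions_remain_unresolved():
    gm = gm_from_rows(["RA", "RA", "AR"], marker_ids=["m1", "m2"])
    panel = select_minimal_markers(gm)
    assert panel.unresolved_pairs_remaining == 1  # the identical pair
    assert sum(panel.newly_resolved) + 1 == 3  # pair bookkeeping reconciles


def test_forced_marker_leads_panel_regardless_of_maf():
    gm = gm_from_rows(
        ["RRA", "RAR", "ARR", "AAA"],
        marker_ids=["best", "mid", "weak"],
    )
    panel = select_minimal_markers(gm, SelectionConfig(forced_markers=("weak",)))
    assert panel.markers[0] == "weak"


def test_first_pick_is_highest_maf():
    """The first greedy pick is the max-MAF marker (maf 0.4 beats 0.2)."""
    gm = gm_from_rows(
        ["RR", "RR", "RA", "RA", "AA"],
        marker_ids=["m_low", "m_high"],
    )
    panel = select_minimal_markers(gm)
    assert panel.markers[0] == "m_high"


def test_excluded_markers_never_selected():
    gm = gm_from_rows(["RR", "AA"], marker_ids=["m1", "m2"])
    panel = select_minimal_markers(gm, SelectionConfig(excluded_markers=frozenset({"m1"})))
    assert panel.markers == ["m2"]
    with pytest.raises(ConfigurationError):
        select_minimal_markers(gm, SelectionConfig(excluded_markers=frozenset({"m1", "m2"})))


def test_forced_and_excluded_overlap_rejected():
    with pytest.raises(ConfigurationError):
        SelectionConfig(forced_markers=("m1",), excluded_markers=frozenset({"m1"}))


def test_unknown_forced_marker_is_identity_error():
    gm = gm_from_rows(["RA", "AR"])
    with pytest.raises(IdentityError):
        select_minimal_markers(gm, SelectionConfig(forced_markers=("nope",)))


def test_max_markers_cap_respected():
    rng = np.random.default_rng(0)
    gm = random_gm(rng, 20, 30)
    panel = select_minimal_markers(gm, SelectionConfig(max_markers=2))
    assert len(panel) == 2


def test_determinism_identical_inputs_identical_panels():
    rng = np.random.default_rng(9)
    gm = random_gm(rng, 15, 25, missing=0.1)
    p1 = select_minimal_markers(gm)
    p2 = select_minimal_markers(gm)
    assert p1.markers == p2.markers and p1.newly_resolved == p2.newly_resolved


@pytest.mark.parametrize("policy", [STRICT, GENO])
def test_greedy_vs_bruteforce_on_random_instances(policy):
    """Greedy output is a valid discriminating set; size ≥ exhaustive optimum;
    completeness: every pair resolvable by the full set is resolved."""
    rng = np.random.default_rng(1234)
    gaps = []
    for _ in range(40):
        n = int(rng.integers(3, 11))
        m = int(rng.integers(2, 13))
        gm = random_gm(rng, n, m, het=(policy is GENO), missing=0.15)
        panel = select_minimal_markers(gm, SelectionConfig(policy=policy))
        masks, _ = marker_pair_masks(gm, policy)
        target = 0
        for mask in masks:
            target |= mask
        got = 0
        for mk in panel.markers:
            got |= masks[gm.marker_index(mk)]
        assert got == target  # completeness: resolves everything resolvable
        opt = brute_force_min_panel_size(gm, policy)
        assert len(panel) >= opt
        gaps.append(len(panel) - opt)
    assert min(gaps) == 0  # greedy attains the optimum on at least some instances


def test_bookkeeping_sums_to_total_pairs():
    rng = np.random.default_rng(77)
    for _ in range(10):
        gm = random_gm(rng, int(rng.integers(2, 12)), int(rng.integers(1, 10)), missing=0.2)
        panel = select_minimal_markers(gm)
        n = gm.n_accessions
        assert sum(panel.newly_resolved) + panel.unresolved_pairs_remaining == n * (n - 1) // 2


def test_log2_lower_bound_on_homozygous_data():
    """Panel size ≥ ⌈log₂ G⌉ with G full-matrix fingerprint classes (STRICT)."""
    rng = np.random.default_rng(55)
    for _ in range(20):
        gm = random_gm(rng, int(rng.integers(3, 12)), int(rng.integers(2, 14)))
        panel = select_minimal_markers(gm)
        fingerprints = {tuple(row) for row in gm.calls}
        G = len(fingerprints)
        if G > 1:
            assert len(panel) >= int(np.ceil(np.log2(G)))


def test_perfectly_correlated_candidate_has_zero_increment():
    """r² = 1 with a selected marker ⇒ incremental discrimination 0."""
    rng = np.random.default_rng(21)
    col = rng.choice(np.array([R, A], dtype=np.int8), size=10)
    swapped = (2 - col).astype(np.int8)  # perfectly anti-correlated: also r²=1
    calls = np.stack([col, col.copy(), swapped], axis=1)
    gm = GenotypeMatrix([f"a{i}" for i in range(10)], ["m1", "same", "flip"], calls)
    panel = select_minimal_markers(gm)
    unresolved_after_first = [
        (a, b)
        for i, a in enumerate(gm.accession_ids)
        for b in gm.accession_ids[i + 1:]
        if not pair_resolved(col[gm.accession_index(a)], col[gm.accession_index(b)], STRICT)
    ]
    assert incremental_discrimination(gm, "same", unresolved_after_first, STRICT) == 0
    assert incremental_discrimination(gm, "flip", unresolved_after_first, STRICT) == 0
    assert len(panel.markers) == 1


# -- augment_panel ----------------------------------------------------------


def test_augment_noop_when_base_resolves_everything():
    gm = gm_from_rows(["RR", "RA", "AR", "AA"], marker_ids=["m1", "m2"])
    base = select_minimal_markers(gm)
    assert base.unresolved_pairs_remaining == 0
    aug = augment_panel(gm, base)
    assert aug.markers == base.markers


def test_augment_with_empty_base_equals_plain_selection():
    rng = np.random.default_rng(31)
    gm = random_gm(rng, 12, 20)
    plain = select_minimal_markers(gm)
    aug = augment_panel(gm, MarkerPanel([]))
    assert aug.markers == plain.markers


def test_augment_extends_base_to_resolve_new_population():
    """8 distinct lines need ≥ ⌈log₂ 8⌉ = 3 STRICT markers; a 2-marker base
    cannot suffice and must be extended."""
    rng = np.random.default_rng(13)
    # 8 accessions with distinct 5-bit homozygous fingerprints
    bits = np.array([[(i >> k) & 1 for k in range(5)] for i in range(8)])
    calls = np.where(bits == 1, A, R).astype(np.int8)
    gm = GenotypeMatrix([f"L{i}" for i in range(8)], [f"b{k}" for k in range(5)], calls)
    base = MarkerPanel(["b0", "b1"])
    aug = augment_panel(gm, base)
    assert aug.markers[:2] == ["b0", "b1"]
    assert len(aug) >= 3
    assert aug.unresolved_pairs_remaining == 0


# -- validate_panel ----------------------------------------------------------


def test_validate_panel_full_set_equals_maximum():
    rng = np.random.default_rng(17)
    gm = random_gm(rng, 10, 8, missing=0.2)
    val_all = validate_panel(gm, list(gm.marker_ids))
    panel = select_minimal_markers(gm)
    val_panel = validate_panel(gm, panel)
    assert val_panel.resolved_fraction == val_all.resolved_fraction


def test_validate_empty_panel_resolves_nothing():
    gm = gm_from_rows(["RA", "AR"])
    val = validate_panel(gm, [])
    assert val.resolved_fraction == 0.0


def test_validate_reports_pairs_identical_across_all_markers():
    """Unresolved pairs after selection = pairs no marker at all resolves."""
    rng = np.random.default_rng(99)
    gm = random_gm(rng, 20, 30, missing=0.1)
    panel = select_minimal_markers(gm)
    val = validate_panel(gm, panel)
    unresolvable = set()
    masks, _ = marker_pair_masks(gm, STRICT)
    from itertools import combinations

    for k, (a, b) in enumerate(combinations(range(20), 2)):
        if not any(mask >> k & 1 for mask in masks):
            unresolvable.add((gm.accession_ids[a], gm.accession_ids[b]))
    assert set(map(tuple, val.unresolved_pairs)) == unresolvable


def test_validate_unknown_marker_identity_error():
    gm = gm_from_rows(["RA"])
    with pytest.raises(IdentityError):
        validate_panel(gm, ["ghost"])
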