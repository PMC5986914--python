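"""Phases 1-6: each operation against its brute-force oracle."""

import numpy as np
import pytest

import oracles
from conftest import random_sites
from tfcoop import (
    BindingSite,
    SiteSequenceMatrix,
    apc_correct,
    build_matrix,
    build_pairs,
    filter_columns,
    importance_filter,
    resolve_overlaps,
    score_pairs,
    significance,
)
from tfcoop.core import DegenerateScoresError, pmi_matrix


def site(seq="s1", motif="A", start=0, width=8, strand="+", score=0.9):
    return BindingSite(seq, motif, start, start + width, strand, score)


def occurrences(collection):
    return {
        r.key: dict(r.count_per_sequence) for r in collection.records
    }


# ---------------------------------------------------------------- matrix


def test_empty_site_list_gives_zero_matrix():
    M = build_matrix([], ["s1", "s2"], ["A", "B"])
    assert M.counts.shape == (2, 2)
    assert M.counts.sum() == 0


def test_single_site_single_count():
    M = build_matrix([site("s2", "B")], ["s1", "s2"], ["A", "B"])
    assert M.counts[1, 1] == 1 and M.counts.sum() == 1


def test_unknown_sequence_rejected():
    with pytest.raises(ValueError, match="unknown sequence"):
        build_matrix([site("nope")], ["s1"], ["A"])


def test_matrix_matches_tally_oracle(rng):
    seq_ids = [f"s{i}" for i in range(10)]
    motif_ids = [f"m{j}" for j in range(20)]
    sites = random_sites(rng, 500, seq_ids, motif_ids)
    M = build_matrix(sites, seq_ids, motif_ids)
    oracle = oracles.tally_matrix(sites, seq_ids, motif_ids)
    for i, s in enumerate(seq_ids):
        for j, m in enumerate(motif_ids):
            assert M.counts[i, j] == oracle[(s, m)]


# ---------------------------------------------------------------- column filter


def test_equal_totals_drop_nothing():
    M = SiteSequenceMatrix(["s1", "s2"], ["A", "B", "C"], np.full((2, 3), 4))
    assert filter_columns(M).motif_ids == ["A", "B", "C"]


def test_zero_total_column_always_dropped():
    counts = np.array([[3, 0, 3], [3, 0, 3]])
    M = SiteSequenceMatrix(["s1", "s2"], ["A", "Z", "C"], counts)
    assert filter_columns(M).motif_ids == ["A", "C"]


def test_quantile_rule_matches_oracle():
    totals = list(range(1, 21))
    counts = np.array(totals)[None, :]
    M = SiteSequenceMatrix(["s1"], [f"m{t}" for t in totals], counts)
    survivors = set(filter_columns(M, 0.05, 0.95).motif_ids)
    oracle = oracles.quantile_survivors(
        {f"m{t}": t for t in totals}, 0.05, 0.95
    )
    assert survivors == oracle


def test_all_columns_removed_is_an_error():
    M = SiteSequenceMatrix(["s1"], ["A"], np.array([[0]]))
    with pytest.raises(ValueError, match="relax"):
        filter_columns(M)


# ---------------------------------------------------------------- importance


def test_uniform_matrix_removes_every_site():
    seq_ids, motif_ids = ["s1", "s2"], ["A", "B"]
    M = SiteSequenceMatrix(seq_ids, motif_ids, np.full((2, 2), 3))
    sites = [site(s, m) for s in seq_ids for m in motif_ids]
    assert importance_filter(M, sites) == []


def test_diagonal_matrix_keeps_diagonal_sites():
    M = SiteSequenceMatrix(["s1", "s2"], ["A", "B"], np.array([[2, 0], [0, 2]]))
    pmi = pmi_matrix(M)
    assert pmi[0, 0] == pytest.approx(1.0)  # log2(2)
    kept = importance_filter(M, [site("s1", "A"), site("s2", "A", start=30)])
    assert [(s.sequence_id, s.motif_id) for s in kept] == [("s1", "A")]


def test_importance_matches_cell_pmi_oracle(rng):
    seq_ids = [f"s{i}" for i in range(10)]
    motif_ids = [f"m{j}" for j in range(20)]
    sites = random_sites(rng, 400, seq_ids, motif_ids)
    M = build_matrix(sites, seq_ids, motif_ids)
    counts = oracles.tally_matrix(sites, seq_ids, motif_ids)
    pmi = oracles.cell_pmi(counts, seq_ids, motif_ids)
    expected = {
        (s.sequence_id, s.motif_id, s.start, s.strand)
        for s in sites
        if pmi[(s.sequence_id, s.motif_id)] > 0
    }
    got = {
        (s.sequence_id, s.motif_id, s.start, s.strand)
        for s in importance_filter(M, sites)
    }
    assert got == expected


def test_joint_normalization_and_marginals(rng):
    # joint sums to 1; marginals are its row/column sums (100 random matrices)
    for _ in range(100):
        counts = rng.integers(0, 6, size=(5, 8))
        if counts.sum() == 0:
            continue
        F = counts.sum()
        joint = counts / F
        assert abs(joint.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(joint.sum(axis=1), counts.sum(axis=1) / F, atol=1e-9)
        np.testing.assert_allclose(joint.sum(axis=0), counts.sum(axis=0) / F, atol=1e-9)


# ---------------------------------------------------------------- overlaps


def test_disjoint_same_motif_sites_both_survive():
    sites = [site(start=10), site(start=50)]
    assert len(resolve_overlaps(sites, 500)) == 2


def test_overlap_keeps_site_nearest_tss():
    sites = [site(start=10), site(start=14)]  # centers 13.5 and 17.5
    (survivor,) = resolve_overlaps(sites, 500)
    assert survivor.start == 14


def test_tie_breaks_toward_smaller_start():
    # overlapping width-9 sites, centers 16 and 20 equidistant from TSS 18
    sites = [site(start=12, width=9), site(start=16, width=9)]
    (survivor,) = resolve_overlaps(sites, 18)
    assert survivor.start == 12


def test_random_clusters_match_bfs_argmin_oracle(rng):
    seq_ids = ["s1", "s2"]
    motif_ids = ["A", "B", "C"]
    sites = random_sites(rng, 150, seq_ids, motif_ids, seq_len=120, width=10)
    got = {
        (s.sequence_id, s.motif_id, s.start, s.strand)
        for s in resolve_overlaps(sites, 60)
    }
    assert got == oracles.overlap_survivors(sites, 60)


# ---------------------------------------------------------------- pairs


def test_distance_window_is_inclusive():
    far = [site(motif="A", start=0), site(motif="B", start=30)]  # distance 30
    assert build_pairs(far, 5, 20) == []
    at_bound = [site(motif="A", start=0), site(motif="B", start=5)]  # exactly 5
    pairs = build_pairs(at_bound, 5, 20)
    assert len(pairs) == 1 and pairs[0].center_distance == 5


def test_homotypic_pairs_excluded_by_default():
    sites = [site(motif="A", start=0), site(motif="A", start=10)]
    assert build_pairs(sites, 5, 20) == []
    assert len(build_pairs(sites, 5, 20, allow_homotypic=True)) == 1


def test_pair_enumeration_matches_double_loop_oracle(rng):
    sites = random_sites(rng, 200, ["s1"], ["A", "B", "C", "D"], seq_len=400)
    pairs = build_pairs(sites, 5, 20)
    got = {}
    for p in pairs:
        key = (p.sequence_id, tuple(sorted((p.site_a.motif_id, p.site_b.motif_id))))
        got[key] = got.get(key, 0) + 1
        assert p.site_a.start <= p.site_b.start
    assert got == dict(oracles.all_pairs(sites, 5, 20))


# ---------------------------------------------------------------- scoring


def test_two_identical_pairs_in_one_sequence_score_two():
    sites = [site(motif="A", start=0), site(motif="B", start=10),
             site(motif="A", start=40), site(motif="B", start=50)]
    coll = score_pairs(build_pairs(sites, 5, 20))
    (rec,) = coll.records
    # p(A,B) = 1, p(A) = p(B) = 1/2 -> 1 * log2(4) = 2
    assert rec.pmi_pc == pytest.approx(2.0)
    assert coll.seq_weights == {"s1": 1.0}


def test_sequence_weights_follow_pair_counts():
    sites = (
        [site("s1", "A", 0), site("s1", "B", 10), site("s1", "A", 40),
         site("s1", "B", 50), site("s1", "C", 100), site("s1", "D", 110)]
        + [site("s2", "A", 0), site("s2", "B", 10)]
    )
    coll = score_pairs(build_pairs(sites, 5, 20))
    assert coll.seq_weights["s1"] == pytest.approx(0.75)
    assert coll.seq_weights["s2"] == pytest.approx(0.25)
    assert sum(coll.seq_weights.values()) == pytest.approx(1.0, abs=1e-9)


def test_weighted_pmi_matches_straight_line_oracle(rng):
    seq_ids = [f"s{i}" for i in range(6)]
    sites = random_sites(rng, 300, seq_ids, ["A", "B", "C", "D", "E"], seq_len=300)
    pairs = build_pairs(sites, 5, 20)
    coll = score_pairs(pairs)
    oracle_scores, oracle_weights = oracles.weighted_pmi(
        [(p.sequence_id, p.site_a.motif_id, p.site_b.motif_id) for p in pairs]
    )
    assert coll.seq_weights == pytest.approx(oracle_weights)
    got = {r.key: r.pmi_pc for r in coll.records}
    assert got == pytest.approx(oracle_scores)


def test_empty_pair_list_gives_empty_collection():
    coll = score_pairs([])
    assert coll.records == [] and coll.total_pairs == 0


# ---------------------------------------------------------------- APC + z


def _collection_with_scores(scores):
    sites_by_pair = []
    coll_sites = []
    start = 0
    for (a, b) in scores:
        coll_sites += [site(motif=a, start=start), site(motif=b, start=start + 10)]
        start += 100
    coll = score_pairs(build_pairs(coll_sites, 5, 20))
    for r in coll.records:
        r.pmi_pc = scores[r.key]
    return coll


def test_constant_scores_correct_to_zero():
    keys = [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")]
    coll = _collection_with_scores({k: 0.7 for k in keys})
    apc_correct(coll)
    for r in coll.records:
        assert r.pmi_pc_apc == pytest.approx(0.0, abs=1e-12)


def test_single_pair_corrects_to_zero():
    coll = _collection_with_scores({("A", "B"): 1.3})
    apc_correct(coll)
    assert coll.records[0].pmi_pc_apc == pytest.approx(0.0, abs=1e-12)


def test_zero_overall_mean_is_degenerate():
    coll = _collection_with_scores({("A", "B"): 1.0, ("C", "D"): -1.0})
    with pytest.raises(DegenerateScoresError):
        apc_correct(coll)


def test_apc_matches_explicit_loop_oracle(rng):
    motifs = list("ABCDEF")
    keys = [(a, b) for i, a in enumerate(motifs) for b in motifs[i + 1 :]]
    scores = {k: float(rng.uniform(0.05, 1.0)) for k in keys}
    coll = _collection_with_scores(scores)
    apc_correct(coll)
    oracle = oracles.apc(scores)
    for r in coll.records:
        assert r.pmi_pc_apc == pytest.approx(oracle[r.key], abs=1e-12)


def test_zscores_of_minus1_0_1():
    coll = _collection_with_scores(
        {("A", "B"): 0.0, ("C", "D"): 0.0, ("E", "F"): 0.0}
    )
    for r, v in zip(coll.records, (-1.0, 0.0, 1.0)):
        r.pmi_pc_apc = v
    significance(coll, z_threshold=3.0)
    assert [r.z for r in coll.records] == pytest.approx([-1.0, 0.0, 1.0])
    assert all(r.label == "not_significant" for r in coll.records)


def test_equal_scores_yield_no_significant_pairs():
    coll = _collection_with_scores({("A", "B"): 0.5, ("C", "D"): 0.5})
    for r in coll.records:
        r.pmi_pc_apc = 0.5
    significance(coll)
    assert all(r.label == "not_significant" for r in coll.records)


def test_zscores_match_formula_oracle(rng):
    values = rng.normal(size=100)
    keys = [(f"m{i:03d}", f"n{i:03d}") for i in range(100)]
    coll = _collection_with_scores({k: 1.0 for k in keys})
    for r, v in zip(coll.records, values):
        r.pmi_pc_apc = float(v)
    significance(coll, z_threshold=3.0)
    oracle = oracles.zscores([float(v) for v in values])
    assert [r.z for r in coll.records] == pytest.approx(oracle)
    n_sig = sum(z >= 3.0 for z in oracle)
    assert sum(r.label == "significant" for r in coll.records) == n_sig


# ---------------------------------------------------------------- determinism


def test_pipeline_is_order_independent(rng):
    seq_ids = [f"s{i}" for i in range(5)]
    sites = random_sites(rng, 120, seq_ids, ["A", "B", "C"], seq_len=200)
    shuffled_input = list(sites)
    rng.shuffle(shuffled_input)

    def run(site_list):
        M = build_matrix(site_list, seq_ids)
        kept = importance_filter(M, site_list)
        kept = resolve_overlaps(kept, 100)
        coll = score_pairs(build_pairs(kept, 5, 20))
        apc_correct(coll)
        significance(coll)
        return coll.to_frame()

    assert run(sites).equals(run(shuffled_input))
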