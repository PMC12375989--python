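import itertools
import random

import numpy as np
import pytest

from quasiprime.ontology import (TermStats, build_ontology, cluster_terms,
                                 load_obo, select_representative,
                                 wang_similarity, winsorized_weighted_lor)


def chain_ontology():
    # A is_a B is_a R, C is_a R (siblings A-chain vs C under root R)
    return build_ontology(
        [("A", "B", "is_a"), ("B", "R", "is_a"), ("C", "R", "is_a")],
        {"A": "BP", "B": "BP", "C": "BP", "R": "BP", "Z": "MF"})


class TestWangSimilarity:
    def test_identity_is_one(self):
        assert wang_similarity("A", "A", chain_ontology()) == 1.0

    def test_parent_child_chain_closed_form(self):
        # S_A = {A:1, B:.8, R:.64}, S_B = {B:1, R:.8}
        # common {B, R}: (.8+1)+(.64+.8) = 3.24 ; SV = 2.44 + 1.8 = 4.24
        onto = build_ontology([("A", "B", "is_a")],
                              {"A": "BP", "B": "BP"})
        assert wang_similarity("A", "B", onto) == pytest.approx(1.8 / 2.8)

    def test_siblings_share_only_root(self):
        onto = build_ontology([("A", "R", "is_a"), ("B", "R", "is_a")],
                              {"A": "BP", "B": "BP", "R": "BP"})
        assert wang_similarity("A", "B", onto) == pytest.approx(
            (0.8 + 0.8) / (1.8 + 1.8))

    def test_part_of_weight_differs_from_is_a(self):
        onto = build_ontology([("A", "R", "part_of"), ("B", "R", "is_a")],
                              {"A": "BP", "B": "BP", "R": "BP"})
        assert wang_similarity("A", "B", onto) == pytest.approx(
            (0.6 + 0.8) / (1.6 + 1.8))

    def test_max_over_paths_wins_on_diamond(self):
        # A reaches R via is_a/is_a (.64) or part_of (.6): the max, .64, is used
        onto = build_ontology(
            [("A", "B", "is_a"), ("B", "R", "is_a"), ("A", "R", "part_of")],
            {"A": "BP", "B": "BP", "R": "BP"})
        # S_A = {A:1, B:.8, R:max(.64,.6)=.64}; S_R = {R:1}
        assert wang_similarity("A", "R", onto) == pytest.approx(
            (0.64 + 1.0) / ((1 + 0.8 + 0.64) + 1.0))

    def test_symmetric_and_bounded_on_random_dags(self):
        rng = random.Random(44)
        for _ in range(10):
            n = rng.randint(3, 8)
            names = [f"T{i}" for i in range(n)]
            edges = [(names[i], names[j], rng.choice(["is_a", "part_of"]))
                     for i in range(n) for j in range(i + 1, n)
                     if rng.random() < 0.4]
            # every namespace shares a root, as in GO
            edges += [(t, "ROOT", "is_a") for t in names]
            onto = build_ontology(edges, {**{t: "BP" for t in names},
                                          "ROOT": "BP"})
            for t1, t2 in itertools.combinations(names, 2):
                s12 = wang_similarity(t1, t2, onto)
                assert s12 == pytest.approx(wang_similarity(t2, t1, onto))
                assert 0.0 < s12 <= 1.0

    def test_cross_namespace_and_unknown_term_rejected(self):
        onto = chain_ontology()
        with pytest.raises(ValueError):
            wang_similarity("A", "Z", onto)
        with pytest.raises(ValueError):
            wang_similarity("A", "missing", onto)


def naive_average_linkage(dist, threshold):
    """Independent O(n^3) agglomerative average-linkage with a distance cutoff."""
    clusters = [[i] for i in range(len(dist))]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a][b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        if best[0] > threshold:
            break
        d, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return {frozenset(c) for c in clusters}


def _stats(term, p_adj=0.01, presence=50.0, lor=1.0, se=0.5):
    return TermStats(term, p_adj, presence, lor, se)


class TestClusterTerms:
    def test_identical_terms_cluster_together(self):
        onto = build_ontology([("A", "R", "is_a"), ("B", "R", "is_a"),
                               ("A2", "A", "is_a"), ("B2", "A", "is_a")],
                              {t: "BP" for t in ["A", "B", "A2", "B2", "R"]})
        reports = cluster_terms([_stats("A2"), _stats("B2")], onto, "BP")
        assert len(reports) == 1
        assert set(reports[0].members) == {"A2", "B2"}

    def test_unrelated_namespaced_roots_stay_singletons(self):
        # two separate roots: no shared ancestors -> similarity ~0, distance ~1
        onto = build_ontology([("A", "RA", "is_a"), ("B", "RB", "is_a")],
                              {t: "BP" for t in ["A", "RA", "B", "RB"]})
        reports = cluster_terms([_stats("A", p_adj=0.01), _stats("B", p_adj=0.2)],
                                onto, "BP")
        # both singletons, but only the significant one is retained
        assert [r.members for r in reports] == [("A",)]

    def test_matches_independent_linkage_oracle(self):
        rng = random.Random(66)
        names = [f"T{i}" for i in range(6)]
        edges = []
        for i, name in enumerate(names):
            for j in range(i + 1, len(names)):
                if rng.random() < 0.5:
                    edges.append((name, names[j], "is_a"))
        edges += [(n, "ROOT", "is_a") for n in names]
        onto = build_ontology(edges, {**{n: "BP" for n in names}, "ROOT": "BP"})
        ids = sorted(names)
        dist = [[1 - wang_similarity(a, b, onto) for b in ids] for a in ids]
        threshold = 0.54
        expected = naive_average_linkage(dist, threshold)
        reports = cluster_terms([_stats(n) for n in names], onto, "BP",
                                threshold=threshold)
        got = {frozenset(ids.index(m) for m in r.members) for r in reports}
        assert got == expected

    def test_input_order_does_not_change_clusters(self):
        onto = chain_ontology()
        terms = [_stats("A"), _stats("B"), _stats("C")]
        forward = cluster_terms(terms, onto, "BP")
        backward = cluster_terms(terms[::-1], onto, "BP")
        assert {r.members for r in forward} == {r.members for r in backward}

    def test_mixed_namespace_rejected(self):
        onto = chain_ontology()
        with pytest.raises(ValueError):
            cluster_terms([_stats("A"), _stats("Z")], onto, "BP")


class TestRepresentative:
    def test_lowest_adjusted_p_wins(self):
        assert select_representative(
            [_stats("A", p_adj=0.02), _stats("B", p_adj=0.01)]) == "B"

    def test_presence_breaks_p_ties(self):
        assert select_representative(
            [_stats("A", p_adj=0.01, presence=40.0),
             _stats("B", p_adj=0.01, presence=80.0)]) == "B"

    def test_lor_then_term_id_break_remaining_ties(self):
        assert select_representative(
            [_stats("A", lor=1.0), _stats("B", lor=2.0)]) == "B"
        assert select_representative([_stats("B"), _stats("A")]) == "A"

    def test_permutation_invariant(self):
        rng = random.Random(3)
        members = [_stats(f"T{i}", p_adj=rng.choice([0.01, 0.02]),
                          presence=rng.choice([10.0, 50.0]),
                          lor=rng.uniform(0, 2)) for i in range(6)]
        winners = set()
        for _ in range(10):
            rng.shuffle(members)
            winners.add(select_representative(members))
        assert len(winners) == 1


class TestWinsorizedLor:
    def test_single_member_unchanged(self):
        assert winsorized_weighted_lor([1.7], [0.3]) == pytest.approx(1.7)

    def test_all_equal_returns_common_value(self):
        assert winsorized_weighted_lor([0.8] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]) == \
            pytest.approx(0.8)

    def test_upper_tail_clamped_before_weighting(self):
        # 95th percentile of [1,1,1,1,10] (linear interpolation) = 8.2;
        # equal SEs -> mean of [1,1,1,1,8.2] = 2.44
        assert winsorized_weighted_lor([1, 1, 1, 1, 10], [0.5] * 5) == \
            pytest.approx(2.44)

    def test_length_mismatch_and_bad_se_rejected(self):
        with pytest.raises(ValueError):
            winsorized_weighted_lor([1.0, 2.0], [0.5])
        with pytest.raises(ValueError):
            winsorized_weighted_lor([1.0], [0.0])


def test_obo_loader_reads_is_a_and_part_of(tmp_path):
    obo = """format-version: 1.4

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: child
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: part
namespace: biological_process
relationship: part_of GO:0000001 ! root
"""
    path = tmp_path / "mini.obo"
    path.write_text(obo)
    onto = load_obo(str(path))
    assert onto.namespaces["GO:0000002"] == "BP"
    assert wang_similarity("GO:0000002", "GO:0000001", onto) == pytest.approx(1.8 / 2.8)
    assert wang_similarity("GO:0000003", "GO:0000001", onto) == pytest.approx(1.6 / 2.6)
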