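"""Cluster-caller correctness against an independent oracle, PSI identity
against full dynamic programming, and the grouping/homology rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olfrep._align import blosum62, global_score, random_protein
from olfrep.clusters import (
    GeneCluster,
    GeneOverlapError,
    call_clusters,
    cluster_homology,
    filter_for_display,
    identity_groups,
    psi_matrix,
    validate_cluster,
)
from conftest import make_model


# ---------------------------------------------------------------------------
# independent oracle: smallest-gap-first agglomeration over raw intervals


def oracle_partition(intervals):
    blocks = [[iv] for iv in intervals]
    while True:
        admissible = []
        for i in range(len(blocks) - 1):
            merged = blocks[i] + blocks[i + 1]
            span = merged[-1][1] - merged[0][0]
            max_gap = max(
                merged[k + 1][0] - merged[k][1] for k in range(len(merged) - 1)
            )
            if max_gap <= span / 3:
                gap = blocks[i + 1][0][0] - blocks[i][-1][1]
                admissible.append((gap, i))
        if not admissible:
            return [tuple(b) for b in blocks]
        _, i = min(admissible)
        blocks[i: i + 2] = [blocks[i] + blocks[i + 1]]


def random_instance(rng, max_genes=10):
    n = int(rng.integers(1, max_genes + 1))
    intervals = []
    cursor = 0
    for _ in range(n):
        cursor += int(rng.integers(1, 5000))
        length = int(rng.integers(100, 3000))
        intervals.append((cursor, cursor + length))
        cursor += length
    return intervals


def models_from(intervals):
    return [make_model(f"g{i}", s, e) for i, (s, e) in enumerate(intervals)]


class TestCallClusters:
    def test_single_gene_is_singleton(self):
        [c] = call_clusters(models_from([(0, 1000)]))
        assert c.members == ("g0",) and c.span == 1000

    def test_hand_example_two_plus_one(self):
        clusters = call_clusters(models_from([(0, 1000), (1500, 2500),
                                              (50_000, 51_000)]))
        assert [c.members for c in clusters] == [("g0", "g1"), ("g2",)]

    def test_hand_example_gap_exceeds_third_of_span(self):
        clusters = call_clusters(models_from([(0, 1000), (2500, 3500)]))
        assert [c.members for c in clusters] == [("g0",), ("g1",)]

    def test_overlapping_genes_rejected(self):
        with pytest.raises(GeneOverlapError):
            call_clusters(models_from([(0, 1000), (500, 1500)]))

    def test_oracle_equivalence_on_random_instances(self):
        """1000 random instances: the partition is contiguous, every block
        valid, no adjacent merge admissible, and identical to the oracle."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            intervals = random_instance(rng)
            clusters = call_clusters(models_from(intervals))
            blocks = [
                [intervals[int(m[1:])] for m in c.members] for c in clusters
            ]
            # contiguous partition in order
            flat = [iv for b in blocks for iv in b]
            assert flat == intervals
            # every block valid
            assert all(validate_cluster(b) for b in blocks)
            # maximal: no single adjacent merge is admissible
            for left, right in zip(blocks, blocks[1:]):
                assert not validate_cluster(left + right)
            assert [tuple(b) for b in blocks] == oracle_partition(intervals)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(shift=st.integers(min_value=0, max_value=10**9),
           seed=st.integers(min_value=0, max_value=1000))
    def test_translation_invariance(self, shift, seed):
        intervals = random_instance(np.random.default_rng(seed))
        shifted = [(s + shift, e + shift) for s, e in intervals]
        a = call_clusters(models_from(intervals))
        b = call_clusters(models_from(shifted))
        assert [c.members for c in a] == [c.members for c in b]


class TestValidateCluster:
    def test_examples(self):
        assert validate_cluster([(0, 1000)])
        assert validate_cluster([(0, 1000), (1500, 2500)])
        assert not validate_cluster([(0, 1000), (2500, 3500)])


class TestDisplayFilter:
    def test_five_gene_threshold(self):
        big = GeneCluster("a", "s", tuple("abcde"), 0, 10)
        small = GeneCluster("b", "s", tuple("abcd"), 0, 10)
        assert filter_for_display([big, small]) == [big]

    def test_min_one_is_identity_and_empty_passes_through(self):
        clusters = [GeneCluster("a", "s", ("x",), 0, 10)]
        assert filter_for_display(clusters, min_genes=1) == clusters
        assert filter_for_display([], min_genes=5) == []


def _nw_affine_score(a, b, open_=-11, extend=-1):
    """Reference quadratic-DP global aligner (Gotoh three-state)."""
    mat = blosum62()
    n, m = len(a), len(b)
    neg = -1e9
    M = np.full((n + 1, m + 1), neg)
    Ix = np.full((n + 1, m + 1), neg)
    Iy = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = open_ + extend * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = open_ + extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                          Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + open_, Ix[i - 1, j] + extend,
                           Iy[i - 1, j] + open_)
            Iy[i, j] = max(M[i, j - 1] + open_, Iy[i, j - 1] + extend,
                           Ix[i, j - 1] + open_)
    return max(M[n, m], Ix[n, m], Iy[n, m])


class TestPsi:
    def test_identical_sequences_are_100(self):
        psi = psi_matrix({"a": "MKVLL", "b": "MKVLL"})
        assert psi.iloc[0, 1] == 100.0

    def test_hand_example_five_of_six(self):
        psi = psi_matrix({"a": "ACDEFG", "b": "ACDEFH"})
        assert psi.iloc[0, 1] == pytest.approx(100 * 5 / 6, abs=1e-9)

    def test_matrix_symmetric_diagonal_100(self):
        rng = np.random.default_rng(3)
        proteins = {f"p{i}": random_protein(60, rng) for i in range(12)}
        psi = psi_matrix(proteins)
        assert np.allclose(psi, psi.T)
        assert np.allclose(np.diag(psi), 100.0)
        assert (psi.to_numpy() <= 100.0).all() and (psi.to_numpy() >= 0).all()

    def test_alignment_score_matches_full_dp(self):
        """The aligner behind PSI agrees with an independent quadratic-DP
        implementation on random protein pairs."""
        rng = np.random.default_rng(11)
        for _ in range(15):
            a = random_protein(int(rng.integers(20, 120)), rng)
            b = random_protein(int(rng.integers(20, 120)), rng)
            assert global_score(a, b) == pytest.approx(_nw_affine_score(a, b))

    def test_identity_exact_for_substitution_only_pairs(self):
        """Equal-length pairs (gap-free optimal alignment) give identity
        equal to the naive per-position count."""
        rng = np.random.default_rng(13)
        from olfrep._align import mutate_protein

        for _ in range(10):
            a = random_protein(80, rng)
            b = mutate_protein(a, 0.2, rng)
            naive = 100 * sum(x == y for x, y in zip(a, b)) / 80
            psi = psi_matrix({"a": a, "b": b})
            assert psi.iloc[0, 1] == pytest.approx(naive)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            psi_matrix({})
        with pytest.raises(ValueError):
            psi_matrix({"a": ""})


class TestIdentityGroups:
    def test_all_distinct_at_full_threshold(self):
        rng = np.random.default_rng(5)
        proteins = {f"p{i}": random_protein(50, rng) for i in range(6)}
        groups = identity_groups(proteins, 100.0)
        assert len(groups) == 6

    def test_identical_pair_groups_together(self):
        rng = np.random.default_rng(6)
        a = random_protein(60, rng)
        groups = identity_groups({"a": a, "b": a, "c": random_protein(60, rng)},
                                 95.0)
        sizes = sorted(len(g["members"]) for g in groups)
        assert sizes == [1, 2]

    def test_group_count_monotone_in_threshold(self):
        rng = np.random.default_rng(7)
        base = [random_protein(60, rng) for _ in range(8)]
        proteins = {}
        k = 0
        for seq in base:
            for _ in range(3):
                from olfrep._align import mutate_protein
                proteins[f"p{k}"] = mutate_protein(seq, rng.uniform(0, 0.3), rng)
                k += 1
        counts = [
            len(identity_groups(proteins, thr)) for thr in (100, 90, 70, 50, 30)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            identity_groups({"a": "MKV"}, 0.0)


class TestClusterHomology:
    def _cluster(self, cid):
        return GeneCluster(cid, "s", ("g",), 0, 10)

    def test_shared_anchor_gives_one_to_one(self):
        links = cluster_homology(
            [self._cluster("a1")], [self._cluster("b1")],
            {"a1": {"x"}, "b1": {"x"}},
        )
        assert len(links) == 1
        assert links[0].clusters_b == ("b1",) and not links[0].split

    def test_split_cluster_flagged(self):
        links = cluster_homology(
            [self._cluster("a1")],
            [self._cluster("b1"), self._cluster("b2")],
            {"a1": {"x", "y"}, "b1": {"x"}, "b2": {"y"}},
        )
        assert links[0].clusters_b == ("b1", "b2")
        assert links[0].split
        assert set(links[0].anchors) == {"x", "y"}

    def test_no_shared_anchors_empty_map(self):
        links = cluster_homology(
            [self._cluster("a1")], [self._cluster("b1")],
            {"a1": {"x"}, "b1": {"y"}},
        )
        assert links == []
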