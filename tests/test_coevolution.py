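"""Dendrograms, cophenetic correlation and the permutation test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from timeco.coevolution import (
    Dendrogram,
    complete_linkage,
    cophenetic_correlation,
    euclidean_distance_matrix,
    jaccard_distance_matrix,
    permutation_pvalue,
)
from timeco.errors import UndefinedMetricError, ValidationError
from timeco.io import write_newick


def dist_df(labels, condensed):
    mat = squareform(np.asarray(condensed, dtype=float))
    return pd.DataFrame(mat, index=labels, columns=labels)


def random_dist(rng, n):
    labels = [f"s{i}" for i in range(n)]
    return dist_df(labels, rng.uniform(0.1, 1.0, size=n * (n - 1) // 2))


class TestDistanceMatrices:
    def test_jaccard_examples(self):
        sets = {"a": {1, 2, 3}, "b": {2, 3, 4}, "c": {1, 2, 3}}
        d = jaccard_distance_matrix(sets)
        assert d.loc["a", "b"] == pytest.approx(0.5)
        assert d.loc["a", "c"] == 0.0
        assert np.allclose(d.to_numpy(), d.to_numpy().T)
        assert np.all(np.diag(d.to_numpy()) == 0)

    def test_too_few_samples(self):
        with pytest.raises(UndefinedMetricError, match=">= 3"):
            jaccard_distance_matrix({"a": {1}, "b": {2}})

    def test_euclidean_matches_pdist(self, rng):
        vec = pd.DataFrame(rng.random((5, 22)), index=[f"s{i}" for i in range(5)])
        d = euclidean_distance_matrix(vec)
        for a, b in itertools.combinations(vec.index, 2):
            assert d.loc[a, b] == pytest.approx(
                float(np.linalg.norm(vec.loc[a] - vec.loc[b]))
            )


class TestCompleteLinkage:
    def test_three_leaf_hand_agglomeration(self):
        d = dist_df(["A", "B", "C"], [0.2, 0.6, 0.8])  # AB, AC, BC
        t = complete_linkage(d)
        heights = [h for _, _, h in t.merges]
        assert heights == [pytest.approx(0.2), pytest.approx(0.8)]
        coph = t.cophenetic()
        assert coph[frozenset(("A", "B"))] == pytest.approx(0.2)
        assert coph[frozenset(("A", "C"))] == pytest.approx(0.8)
        assert coph[frozenset(("B", "C"))] == pytest.approx(0.8)

    def test_degenerate_equal_distances(self):
        d = dist_df(["A", "B", "C", "D"], [0.5] * 6)
        coph = complete_linkage(d).cophenetic()
        assert all(v == pytest.approx(0.5) for v in coph.values())

    def test_ultrametric_reproduced_exactly(self, rng):
        for n in (4, 6, 8):
            base = complete_linkage(random_dist(rng, n))
            coph = base.cophenetic()
            labels = sorted(f"s{i}" for i in range(n))
            condensed = [
                coph[frozenset(p)] for p in itertools.combinations(labels, 2)
            ]
            again = complete_linkage(dist_df(labels, condensed))
            assert again.cophenetic() == pytest.approx(coph)

    def test_matches_scipy_complete_linkage(self, rng):
        # independent oracle: scipy's cophenetic distances on the same input
        for n in (3, 5, 7, 9):
            for _ in range(10):
                d = random_dist(rng, n)
                ours = complete_linkage(d)
                labels = list(d.index)
                condensed = squareform(d.to_numpy())
                scipy_coph = cophenet(linkage(condensed, method="complete"))
                coph = ours.cophenetic()
                mine = [
                    coph[frozenset((labels[i], labels[j]))]
                    for i, j in itertools.combinations(range(n), 2)
                ]
                assert np.allclose(mine, scipy_coph)

    def test_nan_rejected(self):
        d = dist_df(["A", "B", "C"], [0.2, np.nan, 0.8])
        with pytest.raises(ValidationError, match="NaN"):
            complete_linkage(d)


class TestCopheneticCorrelation:
    def test_self_correlation_is_one(self, rng):
        for n in (3, 5, 8):
            t = complete_linkage(random_dist(rng, n))
            assert cophenetic_correlation(t, t) == pytest.approx(1.0)

    def test_antagonistic_three_leaf_case(self):
        t1 = complete_linkage(dist_df(["A", "B", "C"], [0.2, 0.8, 0.8]))
        t2 = complete_linkage(dist_df(["A", "B", "C"], [0.8, 0.2, 0.8]))
        assert cophenetic_correlation(t1, t2) == pytest.approx(-0.5)

    def test_invariant_under_consistent_relabelling(self, rng):
        d = random_dist(rng, 6)
        t1 = complete_linkage(d)
        t2 = complete_linkage(random_dist(rng, 6))
        r = cophenetic_correlation(t1, t2)
        mapping = dict(zip(d.index, np.random.default_rng(1).permutation(list(d.index))))

        def relabel(t):
            return Dendrogram(
                labels=tuple(mapping[l] for l in t.labels), merges=list(t.merges)
            )

        assert cophenetic_correlation(relabel(t1), relabel(t2)) == pytest.approx(r)

    def test_constant_tree_undefined(self):
        flat = complete_linkage(dist_df(["A", "B", "C"], [0.5, 0.5, 0.5]))
        other = complete_linkage(dist_df(["A", "B", "C"], [0.1, 0.5, 0.9]))
        with pytest.raises(UndefinedMetricError):
            cophenetic_correlation(flat, other)

    def test_leaf_set_mismatch(self, rng):
        t1 = complete_linkage(random_dist(rng, 4))
        t2 = complete_linkage(dist_df(["x", "y", "z", "w"], rng.uniform(0.1, 1, 6)))
        with pytest.raises(ValidationError):
            cophenetic_correlation(t1, t2)


class TestPermutationPvalue:
    def test_three_leaf_support_is_sixths(self, rng):
        for _ in range(10):
            t1 = complete_linkage(random_dist(rng, 3))
            t2 = complete_linkage(random_dist(rng, 3))
            _, p, exhaustive = permutation_pvalue(t1, t2)
            assert exhaustive
            assert p in {k / 6 for k in range(1, 7)}

    def test_structured_tree_self_test_significant(self):
        # caterpillar with distinct heights: only its automorphisms tie r=1
        labels = [f"s{i}" for i in range(6)]
        coph = {}
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                coph[frozenset((a, b))] = 0.1 * max(
                    int(a[1:]), int(b[1:])
                )  # merge heights 0.1..0.5, all distinct
        condensed = [
            coph[frozenset(p)] for p in itertools.combinations(labels, 2)
        ]
        t = complete_linkage(dist_df(labels, condensed))
        r, p, exhaustive = permutation_pvalue(t, t)
        assert exhaustive and r == pytest.approx(1.0)
        assert p <= 0.05

    def test_exhaustive_and_sampled_agree(self, rng):
        t1 = complete_linkage(random_dist(rng, 5))
        t2 = complete_linkage(random_dist(rng, 5))
        _, p_ex, ex = permutation_pvalue(t1, t2)
        assert ex
        n_perm = 4000
        _, p_s, ex_s = permutation_pvalue(
            t1, t2, n_perm=n_perm, seed=9, max_exhaustive=0
        )
        assert not ex_s
        se = math.sqrt(p_ex * (1 - p_ex) / n_perm)
        assert abs(p_s - p_ex) <= 2 * se + 1 / n_perm
        assert p_s >= 1 / (n_perm + 1)

    def test_sampled_mode_reproducible(self, rng):
        t1 = complete_linkage(random_dist(rng, 5))
        t2 = complete_linkage(random_dist(rng, 5))
        a = permutation_pvalue(t1, t2, n_perm=500, seed=3, max_exhaustive=0)
        b = permutation_pvalue(t1, t2, n_perm=500, seed=3, max_exhaustive=0)
        assert a == b


class TestNewick:
    def test_round_trip_preserves_cophenetic_distances(self, tmp_path, rng):
        import dendropy

        t = complete_linkage(random_dist(rng, 6))
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in tree.taxon_namespace}
        coph = t.cophenetic()
        for a, b in itertools.combinations(sorted(t.labels), 2):
            # ultrametric tree: patristic distance = 2 x merge height
            assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                2 * coph[frozenset((a, b))], rel=1e-6
            )
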