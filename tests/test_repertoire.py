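"""Diversity, sharing and pair-enumeration behaviour."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import entropy as scipy_entropy

from timeco.errors import UndefinedMetricError, ValidationError
from timeco.io import SampleRecord, TissueClass
from timeco.repertoire import (
    clonality,
    differential_vj,
    enumerate_pairs,
    hec_metrics,
    jaccard_shared,
    normalized_richness,
    pielou_evenness,
    rarefied_richness,
    shannon_entropy,
    top_n_overlap,
    vj_usage,
)
from conftest import make_table

counts_strategy = st.lists(st.integers(1, 10_000), min_size=1, max_size=50)


class TestDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 1, 1, 1], math.log(4)),
            ([7], 0.0),
            ([5, 3, 2], 1.0296530140645737),  # frozen from -sum p ln p
        ],
    )
    def test_shannon_entropy_values(self, counts, expected):
        assert shannon_entropy(counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([3, 3, 3], 0.0),
            ([9, 1], 0.5310044064107189),  # 1 - H([9,1])/ln 2, frozen
            ([42], 1.0),  # monoclonal convention
        ],
    )
    def test_clonality_values(self, counts, expected):
        assert clonality(counts) == pytest.approx(expected, abs=1e-12)

    def test_empty_input_is_undefined(self):
        for fn in (shannon_entropy, clonality, pielou_evenness):
            with pytest.raises(UndefinedMetricError):
                fn([])

    @given(counts_strategy)
    @settings(max_examples=100, derandomize=True)
    def test_entropy_bounds_and_clonality_range(self, counts):
        h = shannon_entropy(counts)
        assert -1e-12 <= h <= math.log(len(counts)) + 1e-12
        assert 0.0 <= clonality(counts) <= 1.0
        if len(counts) >= 2:
            assert clonality(counts) == pytest.approx(
                1.0 - pielou_evenness(counts), abs=1e-12
            )

    def test_entropy_matches_scipy(self, rng):
        for _ in range(100):
            counts = rng.integers(1, 500, size=rng.integers(1, 40)).tolist()
            assert shannon_entropy(counts) == pytest.approx(
                float(scipy_entropy(np.asarray(counts, dtype=float))), abs=1e-10
            )

    def test_doubling_a_clone_increases_clonality(self, rng):
        for _ in range(50):
            s = int(rng.integers(2, 30))
            base = [10] * s
            skewed = list(base)
            skewed[0] *= 2
            assert clonality(skewed) > clonality(base)


class TestHec:
    def test_all_above_threshold(self):
        t = make_table("s", {f"C{i}": c for i, c in enumerate([50, 30, 20])})
        assert hec_metrics(t) == (3, 1.0, 1.0)

    def test_none_above_threshold(self):
        t = make_table("s", {f"C{i}": 1 for i in range(2000)})
        assert hec_metrics(t)[0] == 0

    def test_single_expanded_clone(self):
        counts = {"BIG": 20}
        counts.update({f"C{i}": 1 for i in range(1980)})
        t = make_table("s", counts)
        n, clone_prop, mass_prop = hec_metrics(t)
        assert n == 1
        assert clone_prop == pytest.approx(1 / 1981)
        assert mass_prop == pytest.approx(20 / 2000)

    def test_strict_threshold_boundary(self):
        # exactly 0.1% is NOT highly expanded
        t = make_table("s", {"A": 1, "B": 999})
        assert hec_metrics(t, threshold=0.001)[0] == 1


class TestNormalizedRichness:
    def test_identity_at_full_depth(self):
        t = make_table("s", {f"C{i}": 5 for i in range(100)})
        assert normalized_richness(t, 1.0, t.total_reads, seed=0) == 100

    def test_t_cell_fraction_scaling(self):
        t = make_table("s", {f"C{i}": 5 for i in range(100)})
        assert normalized_richness(t, 0.5, t.total_reads, seed=0) == 200

    def test_depth_above_total_rejected(self):
        t = make_table("s", {"A": 3})
        with pytest.raises(ValidationError, match="lower the common"):
            normalized_richness(t, 1.0, 10, seed=0)

    def test_matches_hypergeometric_expectation_on_toy(self, rng):
        # 10-clone toy: E[richness at depth d] has a closed form
        counts = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        t = make_table("s", {f"C{i}": c for i, c in enumerate(counts)})
        total = sum(counts)
        for d in (5, 15, 30):
            expected = sum(
                1 - math.comb(total - c, d) / math.comb(total, d) for c in counts
            )
            observed = np.mean([rarefied_richness(t, d, rng) for _ in range(3000)])
            assert observed == pytest.approx(expected, rel=0.05)

    def test_monotone_in_depth(self, rng):
        counts = {f"C{i}": int(c) for i, c in enumerate(rng.integers(1, 60, size=200))}
        t = make_table("s", counts)
        means = [
            np.mean([rarefied_richness(t, d, np.random.default_rng(5)) for _ in range(20)])
            for d in (100, 400, 1600, t.total_reads)
        ]
        assert all(a <= b + 1e-9 for a, b in zip(means, means[1:]))


class TestSharing:
    def test_identical_and_disjoint(self):
        a = make_table("a", {"x": 1, "y": 2})
        b = make_table("b", {"x": 3, "y": 1})
        c = make_table("c", {"z": 1, "w": 1})
        assert jaccard_shared(a, b) == (1.0, 0.0)
        assert jaccard_shared(a, c) == (0.0, 1.0)

    def test_half_overlap(self):
        a = make_table("a", {"a": 1, "b": 1, "c": 1})
        b = make_table("b", {"b": 1, "c": 1, "d": 1})
        assert jaccard_shared(a, b)[0] == pytest.approx(0.5)

    def test_exhaustive_six_element_universe(self):
        # brute-force oracle over every pair of non-empty subsets
        universe = list("ABCDEF")
        subsets = [
            frozenset(c) for r in range(1, 7) for c in combinations(universe, r)
        ]
        for sa in subsets[:32]:
            for sb in subsets:
                a = make_table("a", {x: 1 for x in sa})
                b = make_table("b", {x: 1 for x in sb})
                jac, het = jaccard_shared(a, b)
                expected = len(sa & sb) / len(sa | sb)
                assert jac == pytest.approx(expected, abs=1e-12)
                assert het == pytest.approx(1 - expected, abs=1e-12)
                assert jaccard_shared(b, a)[0] == pytest.approx(jac, abs=1e-12)

    def test_empty_table_undefined(self):
        a = make_table("a", {"x": 1})
        from timeco.io import ClonotypeTable

        with pytest.raises(UndefinedMetricError):
            jaccard_shared(a, ClonotypeTable("b", {}))


class TestTopN:
    def test_extremes(self):
        tissue = make_table("t", {"a": 5, "b": 4, "c": 3})
        assert top_n_overlap(tissue, make_table("bl", {"a": 1, "b": 1, "c": 1})) == 100.0
        assert top_n_overlap(tissue, make_table("bl", {"z": 1})) == 0.0

    def test_partial_top4(self):
        tissue = make_table("t", {"a": 10, "b": 9, "c": 8, "d": 7, "e": 1})
        blood = make_table("bl", {"a": 1, "c": 2})
        assert top_n_overlap(tissue, blood, n=4) == pytest.approx(50.0)

    def test_empty_blood_warns_and_returns_zero(self):
        from timeco.io import ClonotypeTable

        tissue = make_table("t", {"a": 1})
        with pytest.warns(UserWarning):
            assert top_n_overlap(tissue, ClonotypeTable("bl", {})) == 0.0


class TestEnumeratePairs:
    @staticmethod
    def _patient(pid, n_normal=2, n_primary=3, n_met=3, n_blood=1):
        recs = []
        for cls, n in (
            (TissueClass.NORMAL, n_normal),
            (TissueClass.PRIMARY, n_primary),
            (TissueClass.METASTASIS, n_met),
            (TissueClass.BLOOD, n_blood),
        ):
            recs += [
                SampleRecord(f"{pid}_{cls.value}{i}", pid, cls) for i in range(n)
            ]
        return recs

    def test_category_counts_for_full_patient(self):
        pairs = enumerate_pairs(self._patient("P1"))
        counts = {}
        for p in pairs:
            counts[p.category] = counts.get(p.category, 0) + 1
        assert counts == {
            "inter-normal": 1,
            "intra-primary": 3,
            "inter-metastasis": 3,
            "inter-primary-normal": 6,
            "inter-primary-metastasis": 9,
            "inter-normal-metastasis": 6,
            "blood-normal": 2,
            "blood-primary": 3,
            "blood-metastasis": 3,
        }
        # C(8,2) non-blood pairs + 1 blood x 8 non-blood
        assert len(pairs) == math.comb(8, 2) + 8

    def test_single_sample_patient_empty(self):
        assert enumerate_pairs(self._patient("P1", 0, 1, 0, 0)) == []

    def test_no_cross_patient_pairs(self):
        pairs = enumerate_pairs(self._patient("P1") + self._patient("P2"))
        assert all(p.sample_a.split("_")[0] == p.sample_b.split("_")[0] for p in pairs)


class TestVjUsage:
    def test_frequencies_sum_to_one(self, small_cohort):
        for t in list(small_cohort.repertoires.values())[:5]:
            assert sum(vj_usage(t).values()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_groups_not_significant(self):
        tables = [
            make_table(f"s{i}", {"a": 5, "b": 3}) for i in range(3)
        ]  # all identical
        df = differential_vj(tables, tables)
        assert (df["p_adjusted"] == 1.0).all()

    def test_planted_difference_has_smallest_p(self):
        from timeco.io import ClonotypeKey, ClonotypeTable

        def sample(freq_big):
            counts = {
                ClonotypeKey("CAAAF", "TRBV1", "TRBJ1"): freq_big,
                ClonotypeKey("CAABF", "TRBV2", "TRBJ2"): 100 - freq_big,
            }
            return ClonotypeTable("s", counts)

        ga = [sample(50), sample(51), sample(49)]
        gb = [sample(1), sample(2), sample(1)]
        df = differential_vj(ga, gb)
        top = df.iloc[0]
        assert (top["v_call"], top["j_call"]) in {("TRBV1", "TRBJ1"), ("TRBV2", "TRBJ2")}
        assert df["p_adjusted"].iloc[0] == df["p_adjusted"].min()

    def test_small_group_rejected(self):
        t = make_table("s", {"a": 1})
        with pytest.raises(ValidationError):
            differential_vj([t], [t, t])
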