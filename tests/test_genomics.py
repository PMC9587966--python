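"""Mutation classes, TMB, CIS and neoantigen set extraction."""

import numpy as np
import pandas as pd
import pytest

from timeco.errors import UndefinedMetricError, ValidationError
from timeco.genomics import (
    CisResult,
    cis_score,
    classify_mutations,
    neoantigen_sets,
    tmb,
)
from timeco.io import MutationRecord, MutationTable, SegmentTable, VariantKey


def vk(i, cls="Missense_Mutation"):
    return VariantKey("chr1", 1000 + i, "A", "T", f"G{i}", cls)


def table(spec):
    """MutationTable from {variant index: (samples, classification, neo)}"""
    return MutationTable(
        MutationRecord(vk(i, cls), set(samples), neo)
        for i, (samples, cls, neo) in spec.items()
    )


class TestClassify:
    def test_definitional_example(self):
        muts = table(
            {
                1: (["s1", "s2", "s3"], "Missense_Mutation", None),
                2: (["s1", "s2"], "Missense_Mutation", None),
                3: (["s3"], "Missense_Mutation", None),
            }
        )
        counts, per_variant = classify_mutations(muts, ["s1", "s2", "s3"], "P")
        assert (counts.trunk, counts.shared, counts.private) == (1, 1, 1)
        assert per_variant[vk(1)] == "trunk"
        assert per_variant[vk(2)] == "shared"
        assert per_variant[vk(3)] == "private"

    def test_all_samples_rule_dominates_two_sample_patient(self):
        muts = table({1: (["s1", "s2"], "Missense_Mutation", None)})
        counts, per_variant = classify_mutations(muts, ["s1", "s2"], "P")
        assert counts.trunk == 1 and counts.shared == 0

    def test_outside_sample_rejected(self):
        muts = table({1: (["s1", "sX"], "Missense_Mutation", None)})
        with pytest.raises(ValidationError, match="sX"):
            classify_mutations(muts, ["s1", "s2"], "P")

    def test_random_presence_matrices_match_cardinality_tally(self, rng):
        samples = [f"s{i}" for i in range(4)]
        for _ in range(1000):
            n_var = int(rng.integers(1, 21))
            spec = {}
            for i in range(n_var):
                k = int(rng.integers(1, 5))
                carriers = rng.choice(samples, size=k, replace=False).tolist()
                spec[i] = (carriers, "Missense_Mutation", None)
            muts = table(spec)
            counts, _ = classify_mutations(muts, samples, "P")
            # brute-force oracle: tally per-variant carrier cardinality
            trunk = sum(1 for v in spec.values() if len(v[0]) == 4)
            private = sum(1 for v in spec.values() if len(v[0]) == 1)
            shared = n_var - trunk - private
            assert (counts.trunk, counts.shared, counts.private) == (
                trunk,
                shared,
                private,
            )
            assert counts.total == n_var  # conservation invariant


class TestTmb:
    def test_membership_count(self):
        muts = table(
            {
                1: (["s1"], "Missense_Mutation", None),
                2: (["s1"], "Silent", None),
                3: (["s1"], "Nonsense_Mutation", None),
                4: (["s1"], "Frame_Shift_Del", None),
                5: (["s1"], "Intron", None),
            }
        )
        assert tmb(muts, "s1") == 3

    def test_empty_and_all_silent(self):
        muts = table({1: (["s1"], "Silent", None)})
        assert tmb(muts, "s1") == 0
        assert tmb(muts, "s2") == 0

    def test_unknown_classification(self):
        muts = table({1: (["s1"], "Weird_Class", None)})
        with pytest.raises(ValidationError, match="strict"):
            tmb(muts, "s1")
        assert tmb(muts, "s1", strict=False) == 1

    def test_additive_over_disjoint_subsets(self, rng):
        classes = ["Missense_Mutation", "Silent", "Nonsense_Mutation", "Intron"]
        spec = {
            i: (["s1"], classes[int(rng.integers(4))], None) for i in range(40)
        }
        muts = table(spec)
        half_a = table({i: spec[i] for i in range(20)})
        half_b = table({i: spec[i] for i in range(20, 40)})
        assert tmb(muts, "s1") == tmb(half_a, "s1") + tmb(half_b, "s1")


def segs_from(rows):
    return SegmentTable(
        pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "adjusted_cn"])
    )


class TestCis:
    def test_half_aberrant(self):
        segs = segs_from(
            [("s1", "chr1", 0, 1000, 2.0), ("s1", "chr1", 1000, 2000, 4.0)]
        )
        r = cis_score(segs, "s1")
        assert (r.aberrant_length, r.total_length, r.cis) == (1000, 2000, 0.5)

    def test_all_normal_and_boundaries(self):
        segs = segs_from(
            [
                ("s1", "chr1", 0, 100, 2.0),
                ("s2", "chr1", 0, 100, 3.0),  # gain boundary inclusive
                ("s3", "chr1", 0, 100, 1.0),  # loss boundary inclusive
            ]
        )
        assert cis_score(segs, "s1").cis == 0.0
        assert cis_score(segs, "s2").cis == 1.0
        assert cis_score(segs, "s3").cis == 1.0

    def test_split_invariance(self, rng):
        for _ in range(50):
            cn = float(rng.uniform(0, 5))
            whole = segs_from([("s", "chr1", 0, 1000, cn), ("s", "chr2", 0, 500, 2.0)])
            cut = int(rng.integers(1, 1000))
            split = segs_from(
                [
                    ("s", "chr1", 0, cut, cn),
                    ("s", "chr1", cut, 1000, cn),
                    ("s", "chr2", 0, 500, 2.0),
                ]
            )
            assert cis_score(whole, "s").cis == pytest.approx(
                cis_score(split, "s").cis
            )

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            rows, pos = [], 0
            for _ in range(int(rng.integers(1, 12))):
                length = int(rng.integers(100, 5000))
                rows.append(("s", "chr1", pos, pos + length, float(rng.uniform(0, 5))))
                pos += length
            segs = segs_from(rows)
            expect_ab = sum(
                e - s for (_, _, s, e, cn) in rows if cn >= 3.0 or cn <= 1.0
            )
            expect_tot = sum(e - s for (_, _, s, e, _) in rows)
            r = cis_score(segs, "s")
            assert (r.aberrant_length, r.total_length) == (expect_ab, expect_tot)

    def test_no_segments_undefined(self):
        segs = segs_from([("s1", "chr1", 0, 100, 2.0)])
        with pytest.raises(UndefinedMetricError):
            cis_score(segs, "other")

    def test_genome_size_override(self):
        segs = segs_from([("s1", "chr1", 0, 1000, 4.0)])
        assert cis_score(segs, "s1", genome_size=10_000).cis == pytest.approx(0.1)


class TestNeoantigenSets:
    def test_presence_respected(self):
        muts = table(
            {
                1: (["sX", "sY"], "Missense_Mutation", True),
                2: (["sX"], "Missense_Mutation", True),
                3: (["sY"], "Missense_Mutation", False),
                4: (["sX"], "Silent", False),
            }
        )
        sets = neoantigen_sets(muts)
        assert sets["sX"] == {vk(1), vk(2)}
        assert sets["sY"] == {vk(1)}

    def test_missing_flag_rejected(self):
        muts = table({1: (["s1"], "Missense_Mutation", None)})
        with pytest.raises(ValidationError, match="is_neoantigen"):
            neoantigen_sets(muts)
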