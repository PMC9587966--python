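"""Genomic summaries: mutation classes, TMB, CIS and neoantigen sets.

For each patient, somatic variants over the *tumour* samples (primary and
metastatic; normal and blood samples are excluded from the universe) are
classified into three disjoint classes:

* trunk    - present in all of the patient's tumour samples,
* shared   - present in two or more, but not all,
* private  - present in exactly one.

TMB is the per-sample count of non-synonymous variants; CIS (chromosome
instability score) is the fraction of a sample's covered genome whose
purity-adjusted segment copy number is >= 3 or <= 1 (inclusive bounds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

from .errors import UndefinedMetricError, ValidationError
from .io import MutationTable, SegmentTable, VariantKey

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "MutationClassCounts",
    "CisResult",
    "classify_mutations",
    "tmb",
    "cis_score",
    "neoantigen_sets",
]

NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Translation_Start_Site",
    }
)

#: Classifications known to be non-coding/synonymous; anything outside the
#: union of the two sets is an unknown string (error under strict mode).
_KNOWN_OTHER_CLASSES = frozenset(
    {
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Splice_Region",
    }
)


@dataclass
class MutationClassCounts:
    patient_id: str
    trunk: int
    shared: int
    private: int

    @property
    def total(self) -> int:
        return self.trunk + self.shared + self.private


def classify_mutations(
    muts: MutationTable,
    patient_tumour_samples: Iterable[str],
    patient_id: str = "",
) -> Tuple[MutationClassCounts, Dict[VariantKey, str]]:
    """Trunk/shared/private classification over a patient's tumour samples.

    Trunk iff present in all tumour samples; private iff present in exactly
    one; shared otherwise (>= 2 but not all).  The three classes are
    disjoint and partition the patient's variants.
    """
    universe = set(patient_tumour_samples)
    if not universe:
        raise ValidationError("classification needs at least one tumour sample")
    per_variant: Dict[VariantKey, str] = {}
    trunk = shared = private = 0
    for rec in muts:
        extra = rec.samples - universe
        if extra:
            raise ValidationError(
                f"variant {rec.key} carried by sample(s) outside the patient's "
                f"tumour set: {sorted(extra)}"
            )
        k = len(rec.samples)
        if k == len(universe):
            cls = "trunk"
            trunk += 1
        elif k == 1:
            cls = "private"
            private += 1
        else:
            cls = "shared"
            shared += 1
        per_variant[rec.key] = cls
    return MutationClassCounts(patient_id, trunk, shared, private), per_variant


def tmb(muts: MutationTable, sample_id: str, strict: bool = True) -> int:
    """Tumour mutational burden: count of non-synonymous variants present
    in the sample.

    Unknown classification strings raise an error under ``strict``;
    with ``strict=False`` they are counted as non-synonymous.
    """
    n = 0
    for rec in muts.present_in(sample_id):
        cls = rec.key.classification
        if cls in NONSYNONYMOUS_CLASSES:
            n += 1
        elif cls not in _KNOWN_OTHER_CLASSES:
            if strict:
                raise ValidationError(
                    f"unknown Variant_Classification {cls!r} for {rec.key}; "
                    f"rerun with strict=False to count it as non-synonymous"
                )
            n += 1
    return n


@dataclass
class CisResult:
    sample_id: str
    aberrant_length: int
    total_length: int

    @property
    def cis(self) -> float:
        return self.aberrant_length / self.total_length


def cis_score(
    segs: SegmentTable,
    sample_id: str,
    gain_threshold: float = 3.0,
    loss_threshold: float = 1.0,
    genome_size: int | None = None,
) -> CisResult:
    """Chromosome instability score for one sample.

    A segment is aberrant iff its purity-adjusted copy number is
    >= ``gain_threshold`` or <= ``loss_threshold`` (both inclusive).  The
    denominator is the total length covered by the sample's segments
    (exome segment coverage varies between samples); pass ``genome_size``
    to use a fixed denominator instead.
    """
    df = segs.for_sample(sample_id)
    if df.empty:
        raise UndefinedMetricError(f"no segments for sample {sample_id!r}")
    lengths = (df["end"] - df["start"]).to_numpy()
    cn = df["adjusted_cn"].to_numpy()
    aberrant = (cn >= gain_threshold) | (cn <= loss_threshold)
    total = int(lengths.sum()) if genome_size is None else int(genome_size)
    return CisResult(
        sample_id=sample_id,
        aberrant_length=int(lengths[aberrant].sum()),
        total_length=total,
    )


def neoantigen_sets(muts: MutationTable) -> Dict[str, Set[VariantKey]]:
    """Per-sample sets of predicted-neoantigen variant keys.

    Requires the neoantigen flag to be populated on every variant; sets
    respect per-sample presence (a flagged variant absent from a sample is
    not in that sample's set).
    """
    unflagged = [rec.key for rec in muts if rec.is_neoantigen is None]
    if unflagged:
        raise ValidationError(
            f"is_neoantigen flag missing for {len(unflagged)} variant(s), "
            f"e.g. {unflagged[0]}"
        )
    out: Dict[str, Set[VariantKey]] = {s: set() for s in muts.samples()}
    for rec in muts:
        if rec.is_neoantigen:
            for s in rec.samples:
                out[s].add(rec.key)
    return out
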