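"""Per-sample TCR diversity measures and between-sample sharing statistics.

Diversity of a repertoire with clone counts ``n_1..n_S`` (total ``N``,
``p_i = n_i / N``) is summarised by

* richness ``S`` (number of unique clonotypes),
* Shannon entropy ``H = -sum p_i ln p_i`` (nats),
* Pielou evenness ``J = H / ln S``,
* clonality ``C = 1 - J`` (1 at a monoclonal repertoire, by convention),
* highly expanded clones (HEC): clonotypes holding strictly more than
  0.1% of the sample's reads.

Between samples of the same patient, heterogeneity is one minus the
Jaccard similarity of clonotype key sets (presence/absence; abundance is
ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import UndefinedMetricError, ValidationError
from .io import ClonotypeKey, ClonotypeTable, SampleRecord, TissueClass

__all__ = [
    "DiversityResult",
    "PairwiseComparison",
    "CATEGORIES",
    "shannon_entropy",
    "pielou_evenness",
    "clonality",
    "hec_metrics",
    "rarefied_richness",
    "normalized_richness",
    "diversity_profile",
    "jaccard_shared",
    "top_n_overlap",
    "enumerate_pairs",
    "vj_usage",
    "differential_vj",
]

#: Within-patient comparison categories, in reporting order.
CATEGORIES = (
    "inter-normal",
    "intra-primary",
    "inter-metastasis",
    "inter-primary-normal",
    "inter-primary-metastasis",
    "inter-normal-metastasis",
    "blood-normal",
    "blood-primary",
    "blood-metastasis",
)

_CLASS_PAIR_CATEGORY = {
    frozenset({TissueClass.NORMAL}): "inter-normal",
    frozenset({TissueClass.PRIMARY}): "intra-primary",
    frozenset({TissueClass.METASTASIS}): "inter-metastasis",
    frozenset({TissueClass.PRIMARY, TissueClass.NORMAL}): "inter-primary-normal",
    frozenset({TissueClass.PRIMARY, TissueClass.METASTASIS}): "inter-primary-metastasis",
    frozenset({TissueClass.NORMAL, TissueClass.METASTASIS}): "inter-normal-metastasis",
    frozenset({TissueClass.BLOOD, TissueClass.NORMAL}): "blood-normal",
    frozenset({TissueClass.BLOOD, TissueClass.PRIMARY}): "blood-primary",
    frozenset({TissueClass.BLOOD, TissueClass.METASTASIS}): "blood-metastasis",
}


def category_of(a: TissueClass, b: TissueClass) -> Optional[str]:
    """Comparison category of a pair of tissue classes (None for blood-blood)."""
    return _CLASS_PAIR_CATEGORY.get(frozenset({a, b}))


@dataclass
class DiversityResult:
    sample_id: str
    richness: int
    shannon_entropy: float
    pielou_evenness: float
    clonality: float
    hec_count: int
    hec_clone_proportion: float
    hec_mass_proportion: float
    normalized_richness: Optional[float] = None


@dataclass(frozen=True)
class PairwiseComparison:
    """One within-patient unordered sample pair, labelled with its category."""

    patient_id: str
    sample_a: str
    sample_b: str
    category: str
    metric: Optional[str] = None
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValidationError("a pairwise comparison needs two distinct samples")
        if self.sample_b < self.sample_a:  # canonical unordered representation
            a, b = self.sample_a, self.sample_b
            object.__setattr__(self, "sample_a", b)
            object.__setattr__(self, "sample_b", a)

    def with_value(self, metric: str, value: float) -> "PairwiseComparison":
        return PairwiseComparison(
            self.patient_id, self.sample_a, self.sample_b, self.category, metric, value
        )


def _as_counts(counts: Sequence[int]) -> np.ndarray:
    arr = np.asarray(list(counts), dtype=np.int64)
    if arr.size == 0:
        raise UndefinedMetricError("diversity metrics are undefined for an empty repertoire")
    if (arr < 1).any():
        raise ValidationError("clone counts must be positive integers")
    return arr


def shannon_entropy(counts: Sequence[int]) -> float:
    """Shannon entropy ``H = -sum p_i ln p_i`` in nats."""
    arr = _as_counts(counts)
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def pielou_evenness(counts: Sequence[int]) -> float:
    """Pielou evenness ``J = H / ln S``; 0 for a monoclonal repertoire."""
    arr = _as_counts(counts)
    if arr.size == 1:
        return 0.0
    return shannon_entropy(arr) / math.log(arr.size)


def clonality(counts: Sequence[int]) -> float:
    """Clonality ``C = 1 - J``.

    A monoclonal repertoire (S = 1) has C = 1: Pielou's ratio is 0/0
    there, and 1 is the limit of a two-clone repertoire as the minor
    clone vanishes.
    """
    arr = _as_counts(counts)
    if arr.size == 1:
        return 1.0
    return 1.0 - pielou_evenness(arr)


def hec_metrics(
    table: ClonotypeTable, threshold: float = 0.001
) -> Tuple[int, float, float]:
    """Highly-expanded-clone summary of a repertoire.

    A clonotype is an HEC iff count/total_reads is *strictly* greater than
    ``threshold``.  Returns (hec_count, hec_clone_proportion =
    hec_count / richness, hec_mass_proportion = HEC reads / total reads).
    """
    if table.richness == 0:
        raise UndefinedMetricError("HEC metrics undefined for an empty repertoire")
    total = table.total_reads
    hec_reads = sum(c for c in table.counts.values() if c / total > threshold)
    hec_count = sum(1 for c in table.counts.values() if c / total > threshold)
    return hec_count, hec_count / table.richness, hec_reads / total


def rarefied_richness(
    table: ClonotypeTable, target_depth: int, rng: np.random.Generator
) -> int:
    """Richness of one uniform without-replacement subsample of reads."""
    total = table.total_reads
    if target_depth > total:
        raise ValidationError(
            f"target_depth {target_depth} exceeds total reads {total} of "
            f"{table.sample_id}; lower the common rarefaction depth"
        )
    if target_depth == total:
        return table.richness
    counts = table.count_vector()
    sub = rng.multivariate_hypergeometric(counts, target_depth)
    return int(np.count_nonzero(sub))


def normalized_richness(
    table: ClonotypeTable,
    t_cell_fraction: float,
    target_depth: int,
    seed: Optional[int] = None,
    n_reps: int = 10,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Depth- and T-cell-fraction-normalized richness.

    The repertoire is rarefied to ``target_depth`` reads (seeded,
    ``n_reps`` repetitions, mean richness reported) and the result is
    divided by the sample's relative T-cell fraction.
    """
    if not (0.0 < t_cell_fraction <= 1.0):
        raise UndefinedMetricError(
            f"t_cell_fraction must be in (0, 1], got {t_cell_fraction}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    if target_depth == table.total_reads:
        mean_rich = float(table.richness)
    else:
        mean_rich = float(
            np.mean([rarefied_richness(table, target_depth, rng) for _ in range(n_reps)])
        )
    return mean_rich / t_cell_fraction


def diversity_profile(
    table: ClonotypeTable,
    t_cell_fraction: Optional[float] = None,
    rarefy_depth: Optional[int] = None,
    hec_threshold: float = 0.001,
    seed: Optional[int] = 0,
    rng: Optional[np.random.Generator] = None,
) -> DiversityResult:
    """All per-sample diversity measures in one record."""
    counts = list(table.counts.values())
    hec_count, hec_cp, hec_mp = hec_metrics(table, hec_threshold)
    norm: Optional[float] = None
    if rarefy_depth is not None and t_cell_fraction is not None:
        norm = normalized_richness(
            table, t_cell_fraction, rarefy_depth, seed=seed, rng=rng
        )
    return DiversityResult(
        sample_id=table.sample_id,
        richness=table.richness,
        shannon_entropy=shannon_entropy(counts),
        pielou_evenness=pielou_evenness(counts),
        clonality=clonality(counts),
        hec_count=hec_count,
        hec_clone_proportion=hec_cp,
        hec_mass_proportion=hec_mp,
        normalized_richness=norm,
    )


def jaccard_shared(a: ClonotypeTable, b: ClonotypeTable) -> Tuple[float, float]:
    """(Jaccard similarity, heterogeneity = 1 - Jaccard) of two repertoires.

    Computed on clonotype key sets; abundance is ignored.
    """
    if a.richness == 0 or b.richness == 0:
        raise UndefinedMetricError("Jaccard sharing undefined for an empty repertoire")
    sa, sb = a.key_set, b.key_set
    jac = len(sa & sb) / len(sa | sb)
    return jac, 1.0 - jac


def top_n_overlap(tissue: ClonotypeTable, blood: ClonotypeTable, n: int = 100) -> float:
    """Percentage of a tissue sample's top-``n`` most abundant clonotypes
    whose key is also found in the blood repertoire.

    Ties at the n-th rank are broken by descending count then lexicographic
    clonotype key, for determinism.  An empty blood table yields 0%.
    """
    if tissue.richness == 0:
        raise UndefinedMetricError("top-n overlap undefined for an empty tissue sample")
    ranked = sorted(tissue.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [k for k, _ in ranked[: min(n, len(ranked))]]
    if blood.richness == 0:
        import warnings

        warnings.warn("empty blood repertoire; top-n overlap reported as 0%")
        return 0.0
    hits = sum(1 for k in top if k in blood.counts)
    return 100.0 * hits / len(top)


def enumerate_pairs(samples: Sequence[SampleRecord]) -> List[PairwiseComparison]:
    """All unordered within-patient sample pairs, labelled by category.

    Blood samples pair only with non-blood samples of the same patient.
    Cross-patient pairs are never produced.
    """
    out: List[PairwiseComparison] = []
    by_patient: Dict[str, List[SampleRecord]] = {}
    for r in samples:
        by_patient.setdefault(r.patient_id, []).append(r)
    for patient_id, recs in by_patient.items():
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                cat = category_of(recs[i].tissue_class, recs[j].tissue_class)
                if cat is None:
                    continue
                out.append(
                    PairwiseComparison(
                        patient_id=patient_id,
                        sample_a=recs[i].sample_id,
                        sample_b=recs[j].sample_id,
                        category=cat,
                    )
                )
    return out


def vj_usage(table: ClonotypeTable) -> Dict[Tuple[str, str], float]:
    """Read-weighted V-J segment usage frequencies (sums to 1)."""
    if table.total_reads == 0:
        raise UndefinedMetricError("VJ usage undefined for an empty repertoire")
    total = table.total_reads
    freq: Dict[Tuple[str, str], float] = {}
    for key, c in table.counts.items():
        vj = (key.v_call, key.j_call)
        freq[vj] = freq.get(vj, 0.0) + c / total
    return freq


def differential_vj(
    group_a: Sequence[ClonotypeTable],
    group_b: Sequence[ClonotypeTable],
    label_a: str = "A",
    label_b: str = "B",
):
    """Per-VJ differential usage between two groups of samples.

    For every V-J pair seen in either group, per-sample frequencies (0 when
    absent) are compared with a two-sided Wilcoxon rank-sum test;
    Benjamini-Hochberg correction is applied over all V-J pairs tested.
    Returns a tidy DataFrame sorted by adjusted p.
    """
    import pandas as pd

    from .stats import bh_fdr, wilcoxon_rank_sum

    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("differential VJ usage needs >= 2 samples per group")
    usage_a = [vj_usage(t) for t in group_a]
    usage_b = [vj_usage(t) for t in group_b]
    all_vj = sorted({vj for u in usage_a + usage_b for vj in u})
    rows = []
    for vj in all_vj:
        fa = [u.get(vj, 0.0) for u in usage_a]
        fb = [u.get(vj, 0.0) for u in usage_b]
        w, p = wilcoxon_rank_sum(fa, fb)
        rows.append(
            {
                "v_call": vj[0],
                "j_call": vj[1],
                "group_a": label_a,
                "group_b": label_b,
                "mean_freq_a": float(np.mean(fa)),
                "mean_freq_b": float(np.mean(fb)),
                "statistic": w,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_fdr(df["p_value"].to_numpy())
    return df.sort_values(["p_adjusted", "p_value"], kind="stable").reset_index(drop=True)
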