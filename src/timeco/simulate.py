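"""Seeded generator of complete multi-region cohorts.

The generator emits every input the analysis consumes — AIRR clonotype
tables, a sample sheet, an infiltration fraction matrix, a TPM expression
matrix, a MAF-like mutation table and a SEG-like copy-number table — with
the statistical structure the analysis assumes:

* Zipf-distributed clone abundances, with tissue-class-specific richness
  and Zipf exponent (metastases: many clones, flat abundances; primaries:
  fewer, more skewed), observed through multinomial read sampling at a
  configurable depth.
* Clonotype sharing planted per within-patient comparison category so that
  the observed category-level Jaccard similarity hits a configured target
  (intra-primary sharing higher than inter-metastasis, as in multi-region
  tumour repertoires).  Planting is calibrated against the empirically
  measured clone-detection rate at the configured depth, because observed
  Jaccard shrinks under depth truncation.
* A blood sample that carries each tissue sample's most abundant clones at
  a class-specific rate (immune surveillance: metastases share their top
  clones with blood far more than normal tissue does).
* Dirichlet-distributed infiltration fractions with class-specific
  concentration (low concentration for metastases = high divergence).
* A constructive per-patient mutation "tree": exact numbers of trunk,
  shared and private variants, Bernoulli neoantigen flags on
  non-synonymous variants.
* A coupling parameter gamma in [0, 1] tying TCR sharing and
  shared-variant placement to a common latent divergence between tumour
  samples, so that TCR and neoantigen dendrograms co-evolve at gamma = 1
  and are independent at gamma = 0.
* Log-normal TPM with metastasis-specific location shifts for the
  immunomodulator panel (up) and T-cell effector genes (down).

Identical config + seed reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    CELL_TYPES,
    T_CELL_TYPES,
    ClonotypeKey,
    ClonotypeTable,
    MutationRecord,
    MutationTable,
    SampleRecord,
    SampleSheet,
    SegmentTable,
    TissueClass,
    VariantKey,
    load_immunomodulator_panel,
    load_trb_genes,
    write_airr_tsv,
    write_maf,
    write_matrix,
    write_sample_sheet,
    write_seg,
)
from .repertoire import category_of

__all__ = [
    "CohortConfig",
    "Cohort",
    "simulate_repertoire",
    "calibrate_mix_weight",
    "simulate_infiltration",
    "simulate_mutation_tree",
    "simulate_expression",
    "simulate_cohort",
    "substream",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named random substream derived from one master seed.

    Stage names map to stable spawn keys via a hash, so toggling one stage
    of a pipeline never perturbs another stage's draws.
    """
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# --------------------------------------------------------------------------
# configuration


@dataclass
class CohortConfig:
    """Study conditions for a synthetic multi-region cohort.

    Defaults describe a desk-scale cohort with the qualitative structure
    of a metastatic gastroesophageal adenocarcinoma study: per patient,
    2 normal / 3 primary / 3 metastatic tissue samples plus 1 blood sample;
    metastases have the richest, flattest repertoires and the most
    dispersed infiltration; intra-primary clonotype sharing (~10%) exceeds
    inter-metastasis sharing (~4.7%).
    """

    n_patients: int = 5
    samples_per_class: Dict[str, int] = field(
        default_factory=lambda: {"normal": 2, "primary": 3, "metastasis": 3, "blood": 1}
    )
    #: unique clones per repertoire, by tissue class (scaled-down cohort)
    richness: Dict[str, int] = field(
        default_factory=lambda: {
            "normal": 580,
            "primary": 600,
            "metastasis": 1200,
            "blood": 400,
        }
    )
    #: Zipf exponent of clone abundances, by class (higher = more clonal)
    zipf_s: Dict[str, float] = field(
        default_factory=lambda: {
            "normal": 1.1,
            "primary": 1.15,
            "metastasis": 0.85,
            "blood": 1.0,
        }
    )
    #: sequencing reads per sample
    depth: int = 6000
    #: target observed Jaccard similarity per comparison category
    category_jaccard: Dict[str, float] = field(
        default_factory=lambda: {
            "inter-normal": 0.10,
            "intra-primary": 0.10,
            "inter-metastasis": 0.0467,
            "inter-primary-normal": 0.08,
            "inter-primary-metastasis": 0.0426,
            "inter-normal-metastasis": 0.0399,
            "blood-normal": 0.01,
            "blood-primary": 0.02,
            "blood-metastasis": 0.02,
        }
    )
    #: probability that a tissue sample's top clone is carried by blood
    blood_top_rate: Dict[str, float] = field(
        default_factory=lambda: {"normal": 0.19, "primary": 0.38, "metastasis": 0.565}
    )
    blood_top_n: int = 100
    #: Dirichlet concentration of infiltration fractions, by class
    dirichlet_concentration: Dict[str, float] = field(
        default_factory=lambda: {"normal": 80.0, "primary": 50.0, "metastasis": 2.0}
    )
    #: strength of the latent-position shift applied to infiltration means
    infiltration_coupling: float = 0.3
    #: per-patient mutation counts by class
    n_trunk: int = 30
    n_shared: int = 50
    n_private: int = 40
    #: probability a non-synonymous variant is a predicted neoantigen
    neoantigen_rate: float = 0.35
    #: gamma in [0,1]: 1 ties TCR sharing and shared-variant placement to a
    #: common latent divergence; 0 makes the two modalities independent
    coupling: float = 0.8
    #: bandwidth of the Gaussian kernel linking latent distance to clone
    #: inclusion (unit-square coordinates)
    kernel_tau: float = 0.45
    #: patient clone-pool size as a multiple of the largest required
    #: squared inclusion factor (headroom keeps inclusion rates << 1)
    pool_oversize: float = 6.0
    #: per-segment probability of an aberrant copy number, by class
    aberrant_cn_rate: Dict[str, float] = field(
        default_factory=lambda: {"normal": 0.02, "primary": 0.15, "metastasis": 0.30}
    )
    n_filler_genes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, j in self.category_jaccard.items():
            if not (0.0 <= j < 1.0):
                raise ValidationError(f"category Jaccard target {cat}={j} not in [0,1)")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValidationError("coupling must lie in [0, 1]")
        if not (0.0 <= self.neoantigen_rate <= 1.0):
            raise ValidationError("neoantigen_rate must lie in [0, 1]")
        for k, n in self.samples_per_class.items():
            if n < 0:
                raise ValidationError(f"negative sample count for class {k}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Cohort:
    """In-memory bundle of everything the generator produces."""

    sheet: SampleSheet
    repertoires: Dict[str, ClonotypeTable]
    infiltration: pd.DataFrame
    expression: pd.DataFrame
    mutations: MutationTable
    segments: SegmentTable
    truth: dict


# --------------------------------------------------------------------------
# repertoire primitives


def _random_keys(n: int, rng: np.random.Generator, v_weights=None, j_weights=None):
    """Random CDR3-like clonotype keys with valid TRBV/TRBJ names."""
    v_names, j_names = load_trb_genes()
    lengths = rng.integers(8, 17, size=n)
    vs = rng.choice(v_names, size=n, p=v_weights)
    js = rng.choice(j_names, size=n, p=j_weights)
    keys = []
    for i in range(n):
        mid = "".join(rng.choice(_AA, size=lengths[i] - 2))
        keys.append(ClonotypeKey("C" + mid + "F", vs[i], js[i]))
    return keys


def _zipf_weights(n: int, s: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-s)
    return w / w.sum()


def _observe(
    sample_id: str, keys: Sequence[ClonotypeKey], s: float, depth: int, rng
) -> ClonotypeTable:
    """Assign Zipf abundances to clone identities and observe reads.

    Zipf ranks are shuffled over the identity list, then reads are drawn
    multinomially at the given depth; clones with zero reads are unobserved.
    """
    n = len(keys)
    probs = _zipf_weights(n, s)[rng.permutation(n)]
    reads = rng.multinomial(depth, probs)
    counts = {k: int(c) for k, c in zip(keys, reads) if c > 0}
    return ClonotypeTable(sample_id=sample_id, counts=counts)


def simulate_repertoire(
    richness: int,
    zipf_s: float,
    depth: int,
    clone_pool: Sequence[ClonotypeKey],
    mix_weight: float,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> ClonotypeTable:
    """One repertoire drawing ``mix_weight`` of its clones from a shared pool.

    Identities: ``round(mix_weight * richness)`` clones sampled without
    replacement from ``clone_pool`` and the remainder freshly synthesized;
    abundances Zipf(``zipf_s``) with ranks assigned uniformly; reads
    multinomial at ``depth``.
    """
    if not (0.0 <= mix_weight <= 1.0):
        raise ValidationError("mix_weight must lie in [0, 1]")
    n_shared = int(round(mix_weight * richness))
    if n_shared > len(clone_pool):
        raise ValidationError(
            f"clone pool ({len(clone_pool)}) too small for {n_shared} shared clones"
        )
    if depth < richness:
        import warnings

        warnings.warn("depth < richness: some clones will go unobserved")
    shared_idx = rng.choice(len(clone_pool), size=n_shared, replace=False)
    keys = [clone_pool[i] for i in shared_idx] + _random_keys(richness - n_shared, rng)
    return _observe(sample_id, keys, zipf_s, depth, rng)


def calibrate_mix_weight(
    target_jaccard: float,
    richness: int,
    zipf_s: float,
    depth: int,
    pool_size: int,
    rng: np.random.Generator,
    n_pairs: int = 12,
    grid: Optional[Sequence[float]] = None,
) -> float:
    """Empirical inversion from a target observed Jaccard to a mix weight.

    Observed Jaccard depends on depth truncation, so the curve is built by
    simulation: for each mix weight on a grid, ``n_pairs`` repertoire pairs
    are drawn from a common pool and the mean observed Jaccard recorded;
    the target is then inverted by monotone interpolation.
    """
    from .repertoire import jaccard_shared

    if grid is None:
        grid = np.linspace(0.0, 1.0, 11)
    means = []
    for w in grid:
        vals = []
        for _ in range(n_pairs):
            pool = _random_keys(pool_size, rng)
            a = simulate_repertoire(richness, zipf_s, depth, pool, w, rng, "a")
            b = simulate_repertoire(richness, zipf_s, depth, pool, w, rng, "b")
            vals.append(jaccard_shared(a, b)[0])
        means.append(float(np.mean(vals)))
    means = np.maximum.accumulate(means)  # enforce monotone curve
    return float(np.interp(target_jaccard, means, grid))


def _detection_rate(richness: int, zipf_s: float, depth: int, rng, reps: int = 5):
    """Empirical probability that a clone of a (richness, s, depth)
    repertoire is observed at all, averaged over Zipf ranks."""
    seen = 0
    for _ in range(reps):
        probs = _zipf_weights(richness, zipf_s)
        reads = rng.multinomial(depth, probs)
        seen += int(np.count_nonzero(reads))
    return seen / (reps * richness)


# --------------------------------------------------------------------------
# other modality primitives

#: baseline bulk-tissue composition over the 22 cell types (sums to 1)
_BASE_MEAN = {
    "B cells naive": 0.04,
    "B cells memory": 0.03,
    "Plasma cells": 0.06,
    "T cells CD8": 0.12,
    "T cells CD4 naive": 0.03,
    "T cells CD4 memory resting": 0.12,
    "T cells CD4 memory activated": 0.04,
    "T cells follicular helper": 0.03,
    "T cells regulatory (Tregs)": 0.04,
    "T cells gamma delta": 0.02,
    "NK cells resting": 0.03,
    "NK cells activated": 0.02,
    "Monocytes": 0.05,
    "Macrophages M0": 0.08,
    "Macrophages M1": 0.05,
    "Macrophages M2": 0.09,
    "Dendritic cells resting": 0.02,
    "Dendritic cells activated": 0.02,
    "Mast cells resting": 0.04,
    "Mast cells activated": 0.02,
    "Eosinophils": 0.02,
    "Neutrophils": 0.03,
}

#: multiplicative class adjustments (metastases deplete effector T and
#: plasma cells, accumulate macrophages), renormalized afterwards
_CLASS_MEAN_FACTORS = {
    "normal": {},
    "primary": {},
    "metastasis": {
        "T cells CD8": 0.45,
        "T cells CD4 memory resting": 0.5,
        "Plasma cells": 0.5,
        "Macrophages M0": 1.6,
        "Macrophages M2": 1.5,
        "B cells naive": 1.4,
        "B cells memory": 1.4,
    },
}


def _class_mean(tissue_class: str) -> np.ndarray:
    base = np.array([_BASE_MEAN[c] for c in CELL_TYPES])
    for cell, f in _CLASS_MEAN_FACTORS.get(tissue_class, {}).items():
        base[CELL_TYPES.index(cell)] *= f
    return base / base.sum()


def simulate_infiltration(
    concentration: float,
    n: int,
    rng: np.random.Generator,
    mean: Optional[np.ndarray] = None,
) -> np.ndarray:
    """``n`` Dirichlet rows over the 22 cell types (each sums to 1)."""
    if mean is None:
        mean = _class_mean("primary")
    alpha = concentration * mean
    return rng.dirichlet(alpha, size=n)


def simulate_mutation_tree(
    tumour_samples: Sequence[str],
    n_trunk: int,
    n_shared: int,
    n_private: int,
    neoantigen_rate: float,
    latent: Optional[pd.DataFrame],
    rng: np.random.Generator,
    variant_offset: int = 0,
) -> MutationTable:
    """Constructive per-patient mutation table with exact class counts.

    Trunk variants go to all tumour samples, private to exactly one, and
    shared to a subset of 2..n-1 samples grown greedily around a random
    seed sample by proximity in the latent divergence matrix (random
    subsets when ``latent`` is None).  Neoantigen flags are Bernoulli on
    non-synonymous variants and False otherwise.
    """
    samples = list(tumour_samples)
    n = len(samples)
    if n_shared > 0 and n < 3:
        raise ValidationError(
            "shared (>=2 but not all) variants need >= 3 tumour samples"
        )
    classes = (
        ["Missense_Mutation"] * 60
        + ["Nonsense_Mutation"] * 8
        + ["Frame_Shift_Del"] * 4
        + ["Frame_Shift_Ins"] * 3
        + ["Splice_Site"] * 5
        + ["Silent"] * 20
    )
    bases = np.array(list("ACGT"))

    def new_key(i: int) -> VariantKey:
        chrom = f"chr{int(rng.integers(1, 23))}"
        pos = int((variant_offset + i) * 1500 + rng.integers(1, 1500))
        ref, alt = rng.choice(bases, size=2, replace=False)
        cls = classes[int(rng.integers(len(classes)))]
        return VariantKey(chrom, pos, str(ref), str(alt), f"GENE{variant_offset + i}", cls)

    records: List[MutationRecord] = []
    i = 0
    for _ in range(n_trunk):
        key = new_key(i)
        i += 1
        records.append(MutationRecord(key, set(samples), _neo_flag(key, neoantigen_rate, rng)))
    for _ in range(n_private):
        key = new_key(i)
        i += 1
        carrier = samples[int(rng.integers(n))]
        records.append(MutationRecord(key, {carrier}, _neo_flag(key, neoantigen_rate, rng)))
    for _ in range(n_shared):
        key = new_key(i)
        i += 1
        k = int(rng.integers(2, n))  # subset size in 2..n-1
        seed_sample = samples[int(rng.integers(n))]
        if latent is not None:
            order = latent.loc[seed_sample, samples].sort_values(kind="stable").index
            subset = set(list(order)[:k])  # seed itself is at distance 0
        else:
            others = [s for s in samples if s != seed_sample]
            subset = {seed_sample} | set(
                rng.choice(others, size=k - 1, replace=False).tolist()
            )
        records.append(MutationRecord(key, subset, _neo_flag(key, neoantigen_rate, rng)))
    return MutationTable(records)


def _neo_flag(key: VariantKey, rate: float, rng) -> bool:
    from .genomics import NONSYNONYMOUS_CLASSES

    if key.classification not in NONSYNONYMOUS_CLASSES:
        return False
    return bool(rng.random() < rate)


def simulate_expression(
    sample_ids: Sequence[str],
    classes: Dict[str, str],
    rng: np.random.Generator,
    n_filler: int = 30,
) -> pd.DataFrame:
    """Log-normal TPM matrix for the immune gene panel plus filler genes.

    Metastatic samples get an upward location shift for the
    immunomodulator panel (heavy immunomodulation) and a downward shift
    for T-cell effector genes (CD8A/CD8B/CD4/GZMA/PRF1), echoing depleted
    effector infiltration.
    """
    panel = load_immunomodulator_panel()["gene"].tolist()
    from .infiltration import BIOMARKER_GENES

    effector = ["CD8A", "CD8B", "CD4", "GZMA", "PRF1"]
    genes = list(
        dict.fromkeys(panel + BIOMARKER_GENES + effector + [f"FILLER{i}" for i in range(n_filler)])
    )
    mu = {g: rng.normal(1.5, 1.0) for g in genes}
    data = np.zeros((len(genes), len(sample_ids)))
    for j, s in enumerate(sample_ids):
        met = classes[s] == "metastasis"
        for i, g in enumerate(genes):
            shift = 0.0
            if met and g in panel:
                shift += 0.8
            if met and g in effector:
                shift -= 1.4
            data[i, j] = np.exp(mu[g] + shift + rng.normal(0.0, 0.6))
    return pd.DataFrame(data, index=genes, columns=list(sample_ids))


# --------------------------------------------------------------------------
# whole-cohort assembly

_CHROM_MB = {f"chr{c}": 250 - 9 * (c - 1) for c in range(1, 23)}


def _simulate_segments(sample_id: str, aberrant_rate: float, rng) -> List[dict]:
    rows = []
    for chrom, mb in _CHROM_MB.items():
        length = mb * 1_000_000
        n_seg = int(rng.integers(1, 4))
        while True:  # distinct interior breakpoints
            cuts = np.sort(rng.integers(1, length, size=n_seg - 1))
            if np.unique(cuts).size == cuts.size:
                break
        bounds = [0, *cuts.tolist(), length]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if rng.random() < aberrant_rate:
                cn = float(rng.uniform(0.3, 1.0)) if rng.random() < 0.5 else float(
                    rng.uniform(3.0, 5.0)
                )
            else:
                cn = float(np.clip(rng.normal(2.0, 0.15), 1.05, 2.95))
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": chrom,
                    "start": int(a),
                    "end": int(b),
                    "adjusted_cn": cn,
                }
            )
    return rows


#: spread of latent positions around the patient centroid, by class;
#: metastases are uniform over the unit square (maximal divergence)
_POSITION_SD = {"normal": 0.09, "primary": 0.07}


def _class_position(cls: str, centroid: np.ndarray, rng, n: int = 1) -> np.ndarray:
    """Latent positions: normals/primaries cluster near the patient
    centroid, metastases scatter over the whole unit square."""
    if cls == "metastasis":
        return rng.random((n, 2))
    sd = _POSITION_SD[cls]
    return np.clip(centroid + rng.normal(0.0, sd, size=(n, 2)), 0.0, 1.0)


def _blended_position(cls, centroid, rng, gamma: float, n: int = 1) -> np.ndarray:
    """gamma-blend of two independent class-conditional position draws
    (the marginal used by a modality's positions)."""
    return gamma * _class_position(cls, centroid, rng, n) + (1 - gamma) * _class_position(
        cls, centroid, rng, n
    )


def _draw_centroid(rng, n: int = 1) -> np.ndarray:
    return 0.25 + 0.5 * rng.random((n, 2))


def _kernel_constants(
    gamma: float, tau: float, rng: np.random.Generator, n: int = 40000
) -> Tuple[Dict[str, float], Dict[frozenset, float]]:
    """MC estimates of the kernel normalisers.

    Returns per-class ``k_mean[c] = E[k]`` and per-class-pair
    ``kk[{a,b}] = E[k_a k_b] / (k_mean[a] k_mean[b])`` under the
    class-conditional latent-position marginals (shared patient centroid,
    independent positions, uniform clone position).
    """
    classes = ("normal", "primary", "metastasis")
    c = _draw_centroid(rng, n)
    z = rng.random((n, 2))

    def kern(x):
        return np.exp(-((x - z) ** 2).sum(axis=1) / (2 * tau**2))

    k1 = {cls: kern(_blended_position(cls, c, rng, gamma, n)) for cls in classes}
    k2 = {cls: kern(_blended_position(cls, c, rng, gamma, n)) for cls in classes}
    k_mean = {
        cls: float(np.concatenate([k1[cls], k2[cls]]).mean()) for cls in classes
    }
    kk: Dict[frozenset, float] = {}
    for i, a in enumerate(classes):
        for b in classes[i:]:
            kk[frozenset((a, b))] = float((k1[a] * k2[b]).mean()) / (
                k_mean[a] * k_mean[b]
            )
    return k_mean, kk


def _latent_distance(points: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(points))
    m = d.max()
    if m > 0:
        d = d / m
    return pd.DataFrame(d, index=list(labels), columns=list(labels))


def simulate_cohort(config: CohortConfig, out_dir: Optional[Path] = None) -> Cohort:
    """Generate a full cohort; optionally write it as a ready-to-run
    directory (sample sheet, AIRR TSVs, matrices, MAF, SEG, truth JSON)."""
    rng_rep = substream(config.seed, "repertoire")
    rng_inf = substream(config.seed, "infiltration")
    rng_mut = substream(config.seed, "mutations")
    rng_expr = substream(config.seed, "expression")
    rng_seg = substream(config.seed, "segments")
    rng_lat = substream(config.seed, "latent")

    # per-class clone detection rate at the configured depth (empirical)
    q: Dict[str, float] = {
        cls: _detection_rate(config.richness[cls], config.zipf_s[cls], config.depth, rng_rep)
        for cls in ("normal", "primary", "metastasis", "blood")
    }

    # Monte-Carlo constants of the latent-position kernel: k_mean normalizes
    # inclusion rates per class; kk divides out the kernel-induced scaling
    # of expected pairwise intersections per class pair.
    k_mean, kk = _kernel_constants(
        config.coupling, config.kernel_tau, substream(config.seed, "kernel-mc")
    )

    v_names, _ = load_trb_genes()
    # primary tumours carry a planted enrichment of one V-J combination
    planted_vj = ("TRBV25-1", "TRBJ2-5")

    records: List[SampleRecord] = []
    repertoires: Dict[str, ClonotypeTable] = {}
    infiltration_rows: Dict[str, np.ndarray] = {}
    seg_rows: List[dict] = []
    mut_tables: List[MutationTable] = []
    truth_patients = {}
    variant_offset = 0

    site_labels = {
        "normal": ["adjacent gastric"],
        "primary": ["gastric tumour"],
        "metastasis": ["lymph node", "peritoneum", "liver", "uterine attachment"],
        "blood": ["peripheral blood"],
    }

    for p in range(1, config.n_patients + 1):
        pid = f"P{p}"
        sample_meta: List[Tuple[str, str]] = []  # (sample_id, class)
        for cls in ("normal", "primary", "metastasis", "blood"):
            for k in range(config.samples_per_class.get(cls, 0)):
                sid = f"{pid}_{cls[:3].upper()}{k + 1}"
                sample_meta.append((sid, cls))
        tissue_ids = [s for s, c in sample_meta if c != "blood"]
        tumour_ids = [s for s, c in sample_meta if c in ("primary", "metastasis")]
        blood_ids = [s for s, c in sample_meta if c == "blood"]
        cls_of = dict(sample_meta)

        # Latent geometry: every tissue sample gets a position (normals and
        # primaries cluster near a patient centroid; metastases scatter);
        # per-modality positions are gamma-blends of the common positions
        # with fresh class-conditional noise, so that gamma=1 makes TCR
        # sharing and neoantigen placement follow one divergence and
        # gamma=0 makes the two modalities independent.
        nt = len(tumour_ids)
        g = config.coupling
        centroid = _draw_centroid(rng_lat)[0]
        x_lat = {
            s: _class_position(cls_of[s], centroid, rng_lat)[0] for s in tissue_ids
        }
        pts_latent = np.array([x_lat[t] for t in tumour_ids])
        x_tcr = {
            s: g * x_lat[s] + (1 - g) * _class_position(cls_of[s], centroid, rng_lat)[0]
            for s in tissue_ids
        }
        # neoantigen noise positions are class-free: with no coupling,
        # mutational divergence carries no imprint of the tissue classes
        x_neo = g * np.array([x_lat[t] for t in tumour_ids]) + (1 - g) * rng_lat.random(
            (nt, 2)
        )
        Dneo = _latent_distance(x_neo, tumour_ids)

        # --- planted clonotype sharing -----------------------------------
        # For a category with Jaccard target J*, the required *identity*
        # intersection of a pair is I = J*(Ri qi + Rj qj) / (qi qj (1+J*)),
        # correcting for the clone detection rates q at the configured
        # depth.  Tissue-tissue sharing comes from one patient-wide clone
        # pool: a sample of class c includes each pool clone with a
        # class-specific rate u_c, modulated by a Gaussian kernel on the
        # latent distance between the sample's TCR position and the
        # clone's position (nearby samples share more clones, carrying
        # the coupling).  The u_c solve a log-least-squares system so
        # that expected pairwise intersections hit the category targets
        # (kernel inflation divided out via the MC constant kk_corr);
        # within-class shortfalls are topped up with small class pools.
        # Blood-tissue sharing uses dedicated blood-class pools.
        ids = [s for s, _ in sample_meta]
        identity: Dict[str, List[ClonotypeKey]] = {s: [] for s in ids}
        class_members = {
            cls: [s for s, c in sample_meta if c == cls]
            for cls in ("normal", "primary", "metastasis", "blood")
        }
        tissue_classes = [
            c for c in ("normal", "primary", "metastasis") if class_members[c]
        ]

        def intersect_target(ca: str, cb: str) -> float:
            cat = category_of(TissueClass(ca), TissueClass(cb))
            if cat is None:
                return 0.0
            jt = config.category_jaccard.get(cat, 0.0)
            if jt <= 0:
                return 0.0
            ra, rb = config.richness[ca], config.richness[cb]
            return jt * (ra * q[ca] + rb * q[cb]) / (q[ca] * q[cb] * (1 + jt))

        # solve g_c = u_c * sqrt(P) from E[I_ab] = g_a g_b kk_ab; cross-class
        # intersections are served only by the shared pool, so their
        # equations dominate; within-class pairs can be topped up afterwards
        eqs = []
        rhs = []
        for i, ca in enumerate(tissue_classes):
            for cb in tissue_classes[i:]:
                tgt = intersect_target(ca, cb)
                if tgt <= 0:
                    continue
                wgt = 1.0 if ca == cb else 10.0
                row = [0.0] * len(tissue_classes)
                row[tissue_classes.index(ca)] += wgt
                row[tissue_classes.index(cb)] += wgt
                eqs.append(row)
                rhs.append(wgt * np.log(tgt / kk[frozenset((ca, cb))]))
        if eqs:
            sol, *_ = np.linalg.lstsq(np.array(eqs), np.array(rhs), rcond=None)
            gf = {c: float(np.exp(v)) for c, v in zip(tissue_classes, sol)}
        else:
            gf = {c: 0.0 for c in tissue_classes}
        gmax = max(gf.values(), default=0.0)
        pool_size = int(np.ceil(config.pool_oversize * gmax**2)) if gmax > 0 else 0
        u = {c: gf[c] / np.sqrt(pool_size) if pool_size else 0.0 for c in gf}

        if pool_size > 0:
            pool_keys = _random_keys(pool_size, rng_rep)
            pool_pos = rng_lat.random((pool_size, 2))
            for s in tissue_ids:
                cls = cls_of[s]
                d2 = ((pool_pos - x_tcr[s]) ** 2).sum(axis=1)
                kern = np.exp(-d2 / (2 * config.kernel_tau**2))
                p_inc = np.minimum(u[cls] * kern / k_mean[cls], 0.999)
                mask = rng_rep.random(pool_size) < p_inc
                identity[s].extend(k for k, m in zip(pool_keys, mask) if m)

        # blood-tissue pools (one per tissue class)
        blood_pools: Dict[str, int] = {}
        if class_members["blood"]:
            for cls in tissue_classes:
                # immune-surveillance planting (top tissue clones carried by
                # blood) already contributes sharing; only the shortfall is
                # planted as a pool
                surv_expected = config.blood_top_rate.get(cls, 0.0) * config.blood_top_n
                tgt = int(round(max(0.0, intersect_target("blood", cls) - surv_expected)))
                blood_pools[cls] = tgt
                if tgt <= 0:
                    continue
                keys = _random_keys(tgt, rng_rep)
                for s in class_members[cls] + class_members["blood"]:
                    identity[s].extend(keys)

        # top up within-class intersections that the pool under-delivers
        for cls in tissue_classes:
            if len(class_members[cls]) < 2:
                continue
            expected = gf[cls] ** 2 * kk[frozenset((cls, cls))] + blood_pools.get(cls, 0)
            extra = int(round(intersect_target(cls, cls) - expected))
            if extra > 0:
                keys = _random_keys(extra, rng_rep)
                for s in class_members[cls]:
                    identity[s].extend(keys)

        # --- observe tissue repertoires ----------------------------------
        for s in tissue_ids:
            cls = cls_of[s]
            n_private = config.richness[cls] - len(identity[s])
            if n_private < 0:
                raise ValidationError(
                    f"sharing quota exceeds richness for sample {s}"
                )
            priv = _random_keys(n_private, rng_rep)
            if cls == "primary":
                # plant a differentially used V-J combination in primaries
                n_boost = int(0.03 * len(priv))
                priv = [
                    ClonotypeKey(k.junction_aa, planted_vj[0], planted_vj[1])
                    for k in priv[:n_boost]
                ] + priv[n_boost:]
            keys = identity[s] + priv
            repertoires[s] = _observe(s, keys, config.zipf_s[cls], config.depth, rng_rep)

        # --- blood: planted sharing + surveillance of top tissue clones ---
        for s in blood_ids:
            surv: List[ClonotypeKey] = []
            for t in tissue_ids:
                ranked = sorted(
                    repertoires[t].counts.items(), key=lambda kv: (-kv[1], kv[0])
                )
                top = [k for k_i, (k, _) in enumerate(ranked) if k_i < config.blood_top_n]
                rate = config.blood_top_rate[cls_of[t]]
                surv.extend(k for k in top if rng_rep.random() < rate)
            pool = list(dict.fromkeys(identity[s] + surv))
            n_private = max(0, config.richness["blood"] - len(pool))
            keys = pool + _random_keys(n_private, rng_rep)
            repertoires[s] = _observe(s, keys, config.zipf_s["blood"], config.depth, rng_rep)

        # --- infiltration -------------------------------------------------
        loadings = rng_inf.normal(0.0, 1.0, size=(len(CELL_TYPES), 2))
        # tumour samples reuse the latent positions behind D, so infiltration
        # co-evolves with the coupled modalities
        pos = {t: pts_latent[i] for i, t in enumerate(tumour_ids)}
        for s in tissue_ids:
            cls = cls_of[s]
            mean = _class_mean(cls)
            if s in pos and config.infiltration_coupling > 0:
                shift = np.exp(
                    config.infiltration_coupling * loadings @ (pos[s] - 0.5)
                )
                mean = mean * shift
                mean = mean / mean.sum()
            row = rng_inf.dirichlet(config.dirichlet_concentration[cls] * mean)
            infiltration_rows[s] = row

        # --- mutations ----------------------------------------------------
        muts = simulate_mutation_tree(
            tumour_ids,
            config.n_trunk,
            config.n_shared,
            config.n_private,
            config.neoantigen_rate,
            Dneo,
            rng_mut,
            variant_offset=variant_offset,
        )
        variant_offset += len(muts)
        mut_tables.append(muts)

        # --- segments -----------------------------------------------------
        for s in tissue_ids:
            seg_rows.extend(
                _simulate_segments(s, config.aberrant_cn_rate[cls_of[s]], rng_seg)
            )

        # --- sample records -----------------------------------------------
        for s, cls in sample_meta:
            if cls == "blood":
                frac = 0.5
            else:
                row = infiltration_rows[s]
                frac = float(
                    sum(row[CELL_TYPES.index(c)] for c in T_CELL_TYPES)
                )
            sites = site_labels[cls]
            stable_idx = sum(s.encode()) % len(sites)  # process-independent
            records.append(
                SampleRecord(
                    sample_id=s,
                    patient_id=pid,
                    tissue_class=TissueClass(cls),
                    site_label=sites[stable_idx] if cls == "metastasis" else sites[0],
                    t_cell_fraction=round(frac, 6),
                )
            )
        truth_patients[pid] = {
            "tumour_samples": tumour_ids,
            "latent_positions": {t: pts_latent[i].tolist() for i, t in enumerate(tumour_ids)},
            "mutation_classes": {
                "trunk": config.n_trunk,
                "shared": config.n_shared,
                "private": config.n_private,
            },
        }

    sheet = SampleSheet(records)
    all_records = []
    for t in mut_tables:
        all_records.extend(t.records.values())
    mutations = MutationTable(all_records)
    mutations.validate_against_sheet(sheet)

    infiltration = pd.DataFrame.from_dict(
        infiltration_rows, orient="index", columns=CELL_TYPES
    ).sort_index()

    tissue_all = [r.sample_id for r in sheet if r.tissue_class is not TissueClass.BLOOD]
    expression = simulate_expression(
        tissue_all,
        {r.sample_id: r.tissue_class.value for r in sheet},
        rng_expr,
        n_filler=config.n_filler_genes,
    )

    segments = SegmentTable(pd.DataFrame(seg_rows))

    truth = {
        "config": config.to_dict(),
        "detection_rate": q,
        "patients": truth_patients,
    }
    cohort = Cohort(sheet, repertoires, infiltration, expression, mutations, segments, truth)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: Path) -> None:
    """Write a cohort as the on-disk layout the pipeline consumes."""
    out_dir = Path(out_dir)
    (out_dir / "airr").mkdir(parents=True, exist_ok=True)
    write_sample_sheet(cohort.sheet, out_dir / "samples.tsv")
    for sid, table in cohort.repertoires.items():
        write_airr_tsv(table, out_dir / "airr" / f"{sid}.tsv")
    write_matrix(cohort.infiltration, out_dir / "infiltration.tsv")
    write_matrix(cohort.expression, out_dir / "expression.tsv")
    write_maf(cohort.mutations, out_dir / "mutations.maf")
    write_seg(cohort.segments, out_dir / "segments.seg")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
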