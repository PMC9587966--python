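"""Immune-cell infiltration divergence and expression-based immune summaries.

Infiltration divergence between two samples is the Euclidean distance
between their 22-dimensional immune-cell fraction vectors; on the simplex
the distance is bounded by sqrt(2).  Expression summaries cover the
immunomodulator panel (per-tissue-group medians, z-scored across the
three groups), cytolytic activity (geometric mean of GZMA and PRF1 TPM)
and a per-patient z-scored immunotherapy-biomarker panel.

All z-scores use the sample standard deviation (n-1 denominator);
zero-variance rows are reported as all-zero rather than NaN.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .io import SampleSheet, TissueClass, load_immunomodulator_panel
from .repertoire import PairwiseComparison, enumerate_pairs

__all__ = [
    "BIOMARKER_GENES",
    "euclidean_divergence",
    "divergence_pairs",
    "cytolytic_activity",
    "immunomodulator_summary",
    "biomarker_panel",
]

#: Immunotherapy biomarker genes (HGNC symbols).  CYT (cytolytic activity)
#: is computed from GZMA and PRF1 and prepended as its own row.
BIOMARKER_GENES = ["CD274", "PDCD1LG2", "PDCD1", "ENTPD1", "CD8A", "CD8B", "CD4"]

_TISSUE_GROUPS = (TissueClass.NORMAL, TissueClass.PRIMARY, TissueClass.METASTASIS)


def euclidean_divergence(f1: pd.Series, f2: pd.Series) -> float:
    """Euclidean distance between two immune-cell fraction vectors.

    The vectors must cover the same cell types; a mismatch is an error
    naming the differing labels.
    """
    if set(f1.index) != set(f2.index):
        only1 = sorted(set(f1.index) - set(f2.index))
        only2 = sorted(set(f2.index) - set(f1.index))
        raise ValidationError(
            f"cell-type sets differ: only in first {only1}, only in second {only2}"
        )
    diff = f1.to_numpy(dtype=float) - f2.reindex(f1.index).to_numpy(dtype=float)
    return float(np.sqrt((diff * diff).sum()))


def divergence_pairs(
    matrix: pd.DataFrame, sheet: SampleSheet
) -> tuple[List[PairwiseComparison], List[str]]:
    """Infiltration divergence for every within-patient pair.

    Reuses the same pair skeletons (and category labels) as TCR
    heterogeneity.  Pairs with a sample absent from the fraction matrix
    (e.g. blood, which is not deconvolved) are skipped and logged.
    """
    skeletons = enumerate_pairs(sheet.records)
    out: List[PairwiseComparison] = []
    skipped: List[str] = []
    for sk in skeletons:
        if sk.sample_a not in matrix.index or sk.sample_b not in matrix.index:
            skipped.append(f"{sk.sample_a} vs {sk.sample_b}: missing infiltration row")
            continue
        d = euclidean_divergence(matrix.loc[sk.sample_a], matrix.loc[sk.sample_b])
        out.append(sk.with_value("infiltration_divergence", d))
    return out, skipped


def cytolytic_activity(
    tpm_gzma: float, tpm_prf1: float, pseudocount: float = 0.0
) -> float:
    """Cytolytic activity: geometric mean of GZMA and PRF1 TPM.

    No pseudocount by default, so a zero in either gene propagates to a
    zero CYT; supply ``pseudocount`` (e.g. 0.01) to follow the convention
    of adding a small offset before the geometric mean.
    """
    if tpm_gzma < 0 or tpm_prf1 < 0:
        raise ValidationError("TPM values must be non-negative")
    return math.sqrt((tpm_gzma + pseudocount) * (tpm_prf1 + pseudocount))


def _zscore(values: np.ndarray) -> np.ndarray:
    """Sample-sd z-score; an (effectively) zero-variance vector maps to zeros."""
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd) or sd < 1e-12 * max(1.0, abs(values.mean())):
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def immunomodulator_summary(
    expr: pd.DataFrame,
    sheet: SampleSheet,
    gene_list: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene tissue-group medians and across-group z-scores.

    For each gene of the panel, the median TPM over the samples of each
    non-blood tissue group (normal, primary, metastasis) is computed and
    z-score-normalized across the three group medians.  Genes absent from
    the matrix are reported with ``missing = True``, not as zero.
    """
    if gene_list is None:
        gene_list = load_immunomodulator_panel()["gene"].tolist()
    group_samples: Dict[TissueClass, List[str]] = {}
    for tc in _TISSUE_GROUPS:
        ids = [
            r.sample_id
            for r in sheet
            if r.tissue_class is tc and r.sample_id in expr.columns
        ]
        if not ids:
            found = sorted(
                {r.tissue_class.value for r in sheet if r.sample_id in expr.columns}
            )
            raise ValidationError(
                f"no expression samples for tissue group {tc.value!r}; groups "
                f"with samples: {found}"
            )
        group_samples[tc] = ids
    rows = []
    for gene in gene_list:
        if gene not in expr.index:
            rows.append(
                {
                    "gene": gene,
                    "median_normal": np.nan,
                    "median_primary": np.nan,
                    "median_metastasis": np.nan,
                    "z_normal": np.nan,
                    "z_primary": np.nan,
                    "z_metastasis": np.nan,
                    "missing": True,
                }
            )
            continue
        medians = np.array(
            [float(expr.loc[gene, group_samples[tc]].median()) for tc in _TISSUE_GROUPS]
        )
        z = _zscore(medians)
        rows.append(
            {
                "gene": gene,
                "median_normal": medians[0],
                "median_primary": medians[1],
                "median_metastasis": medians[2],
                "z_normal": z[0],
                "z_primary": z[1],
                "z_metastasis": z[2],
                "missing": False,
            }
        )
    return pd.DataFrame(rows)


def biomarker_panel(
    expr: pd.DataFrame,
    sheet: SampleSheet,
    genes: Optional[Sequence[str]] = None,
    include_blood: bool = False,
    cyt_pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-patient z-scored immunotherapy biomarker matrix.

    Rows are CYT plus the biomarker genes; columns are samples.  CYT is
    computed per sample from GZMA and PRF1, then every row is z-scored
    *within each patient* across that patient's samples (independently
    per patient).  Patients with a single expressed sample get NaN
    (undefined) rather than numbers.  Blood samples are excluded by
    default: no tumour expression is expected there.
    """
    if genes is None:
        genes = BIOMARKER_GENES
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValidationError(f"biomarker genes absent from expression matrix: {missing}")
    for g in ("GZMA", "PRF1"):
        if g not in expr.index:
            raise ValidationError(f"CYT requires gene {g} in the expression matrix")
    sample_ids = [
        r.sample_id
        for r in sheet
        if r.sample_id in expr.columns
        and (include_blood or r.tissue_class is not TissueClass.BLOOD)
    ]
    raw = pd.DataFrame(index=["CYT"] + list(genes), columns=sample_ids, dtype=float)
    for s in sample_ids:
        raw.loc["CYT", s] = cytolytic_activity(
            float(expr.loc["GZMA", s]), float(expr.loc["PRF1", s]), cyt_pseudocount
        )
        for g in genes:
            raw.loc[g, s] = float(expr.loc[g, s])
    z = raw.copy()
    for patient in sheet.patients():
        cols = [s for s in sample_ids if sheet[s].patient_id == patient]
        if not cols:
            continue
        if len(cols) < 2:
            z.loc[:, cols] = np.nan  # undefined for single-sample patients
            continue
        block = raw.loc[:, cols].to_numpy(dtype=float)
        z.loc[:, cols] = np.apply_along_axis(_zscore, 1, block)
    return z
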