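"""End-to-end orchestration: read a cohort directory, run every analysis
stage, and emit tidy TSVs, Newick trees, a machine-readable JSON summary
and a run manifest.

All randomness flows from the single config seed through named substreams
per stage, so toggling one stage does not perturb another's results; two
runs with identical config and seed produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .coevolution import (
    complete_linkage,
    coevolution_test,
    euclidean_distance_matrix,
    jaccard_distance_matrix,
)
from .errors import TimecoError, UndefinedMetricError, ValidationError
from .genomics import cis_score, classify_mutations, neoantigen_sets, tmb
from .infiltration import biomarker_panel, divergence_pairs, immunomodulator_summary
from .io import (
    SampleSheet,
    TissueClass,
    read_airr_tsv,
    read_expression,
    read_infiltration,
    read_maf,
    read_sample_sheet,
    read_seg,
    write_newick,
)
from .repertoire import (
    diversity_profile,
    enumerate_pairs,
    jaccard_shared,
    top_n_overlap,
    differential_vj,
)
from .simulate import substream
from .stats import compare_categories, significance_stars

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Inputs, output directory, stage toggles and thresholds for a run."""

    cohort_dir: Path
    out_dir: Path
    seed: int = 0
    hec_threshold: float = 0.001
    top_n: int = 100
    rarefy_depth: Optional[int] = None  # default: min total reads in cohort
    cyt_pseudocount: float = 0.0
    n_perm: int = 10000
    two_sided: bool = False
    renormalize_infiltration: bool = False
    run_repertoire: bool = True
    run_vj: bool = True
    run_infiltration: bool = True
    run_genomics: bool = True
    run_coevolution: bool = True

    def __post_init__(self) -> None:
        self.cohort_dir = Path(self.cohort_dir)
        self.out_dir = Path(self.out_dir)
        if not self.cohort_dir.exists():
            raise ValidationError(f"cohort directory {self.cohort_dir} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _round(x: float) -> float:
    """Stable rounding for JSON output (12 significant digits)."""
    return float(f"{x:.12g}")


class _Stage:
    """Context wrapper that renames any stage failure for the run log."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise TimecoError(f"stage {self.name!r} failed: {exc}") from exc


def run_all(config: RunConfig) -> dict:
    """Execute repertoire -> infiltration -> genomics -> coevolution -> stats.

    Returns the JSON summary (also written to ``out_dir/summary.json``).
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)

    manifest_inputs = {}
    sheet = read_sample_sheet(config.cohort_dir / "samples.tsv")
    manifest_inputs["samples.tsv"] = _sha256(config.cohort_dir / "samples.tsv")

    summary: dict = {"seed": config.seed}
    pair_skeletons = enumerate_pairs(sheet.records)

    repertoires = {}
    if config.run_repertoire or config.run_coevolution:
        airr_dir = config.cohort_dir / "airr"
        for rec in sheet:
            path = airr_dir / f"{rec.sample_id}.tsv"
            if not path.exists():
                path = airr_dir / f"{rec.sample_id}.tsv.gz"
            repertoires[rec.sample_id] = read_airr_tsv(path, rec.sample_id)
            manifest_inputs[f"airr/{path.name}"] = _sha256(path)

    # ------------------------------------------------------------- repertoire
    tcr_pairs = []
    if config.run_repertoire:
        with _Stage("repertoire"):
            rng = substream(config.seed, "rarefaction")
            depth = config.rarefy_depth or min(
                t.total_reads for t in repertoires.values()
            )
            rows = []
            for rec in sheet:
                t = repertoires[rec.sample_id]
                d = diversity_profile(
                    t,
                    t_cell_fraction=rec.t_cell_fraction,
                    rarefy_depth=depth,
                    hec_threshold=config.hec_threshold,
                    rng=rng,
                )
                row = dataclasses.asdict(d)
                row["tissue_class"] = rec.tissue_class.value
                row["patient_id"] = rec.patient_id
                rows.append(row)
            diversity_df = pd.DataFrame(rows)
            diversity_df.to_csv(out / "diversity.tsv", sep="\t", index=False)

            for sk in pair_skeletons:
                jac, het = jaccard_shared(
                    repertoires[sk.sample_a], repertoires[sk.sample_b]
                )
                tcr_pairs.append(sk.with_value("tcr_heterogeneity", het))
            pairs_df = pd.DataFrame(
                {
                    "patient_id": [p.patient_id for p in tcr_pairs],
                    "sample_a": [p.sample_a for p in tcr_pairs],
                    "sample_b": [p.sample_b for p in tcr_pairs],
                    "category": [p.category for p in tcr_pairs],
                    "heterogeneity": [p.value for p in tcr_pairs],
                    "shared_pct": [100.0 * (1.0 - p.value) for p in tcr_pairs],
                }
            )
            pairs_df.to_csv(out / "tcr_pairs.tsv", sep="\t", index=False)

            overlap_rows = []
            for rec in sheet:
                if rec.tissue_class is TissueClass.BLOOD:
                    continue
                bloods = sheet.samples_of(rec.patient_id, (TissueClass.BLOOD,))
                for b in bloods:
                    overlap_rows.append(
                        {
                            "sample_id": rec.sample_id,
                            "tissue_class": rec.tissue_class.value,
                            "blood_sample": b.sample_id,
                            "top_n": config.top_n,
                            "pct_in_blood": top_n_overlap(
                                repertoires[rec.sample_id],
                                repertoires[b.sample_id],
                                n=config.top_n,
                            ),
                        }
                    )
            overlap_df = pd.DataFrame(overlap_rows)
            overlap_df.to_csv(out / "blood_overlap.tsv", sep="\t", index=False)

            summary["diversity_mean_richness_by_class"] = {
                cls: _round(v)
                for cls, v in diversity_df.groupby("tissue_class")["richness"]
                .mean()
                .items()
            }
            summary["tcr_heterogeneity_median_by_category"] = {
                cat: _round(v)
                for cat, v in pairs_df.groupby("category")["heterogeneity"]
                .median()
                .items()
            }
            summary["shared_pct_mean_by_category"] = {
                cat: _round(v)
                for cat, v in pairs_df.groupby("category")["shared_pct"].mean().items()
            }
            if not overlap_df.empty:
                summary["top_n_blood_overlap_mean_by_class"] = {
                    cls: _round(v)
                    for cls, v in overlap_df.groupby("tissue_class")["pct_in_blood"]
                    .mean()
                    .items()
                }
            summary["n_pairwise_comparisons"] = int(len(pairs_df))

    if config.run_repertoire and config.run_vj:
        with _Stage("vj_usage"):
            by_class: Dict[str, list] = {}
            for rec in sheet:
                by_class.setdefault(rec.tissue_class.value, []).append(
                    repertoires[rec.sample_id]
                )
            frames = []
            classes = [c for c, ts in sorted(by_class.items()) if len(ts) >= 2]
            for i, ca in enumerate(classes):
                for cb in classes[i + 1 :]:
                    frames.append(
                        differential_vj(by_class[ca], by_class[cb], ca, cb)
                    )
            if frames:
                vj_df = pd.concat(frames, ignore_index=True)
                vj_df.to_csv(out / "vj_differential.tsv", sep="\t", index=False)
                summary["vj_n_significant"] = int((vj_df["p_adjusted"] <= 0.05).sum())

    # ----------------------------------------------------------- infiltration
    infl = None
    infl_pairs = []
    if config.run_infiltration:
        with _Stage("infiltration"):
            infl = read_infiltration(
                config.cohort_dir / "infiltration.tsv",
                renormalize=config.renormalize_infiltration,
            )
            manifest_inputs["infiltration.tsv"] = _sha256(
                config.cohort_dir / "infiltration.tsv"
            )
            expr = read_expression(config.cohort_dir / "expression.tsv")
            manifest_inputs["expression.tsv"] = _sha256(
                config.cohort_dir / "expression.tsv"
            )
            infl_pairs, skipped = divergence_pairs(infl, sheet)
            div_df = pd.DataFrame(
                {
                    "patient_id": [p.patient_id for p in infl_pairs],
                    "sample_a": [p.sample_a for p in infl_pairs],
                    "sample_b": [p.sample_b for p in infl_pairs],
                    "category": [p.category for p in infl_pairs],
                    "divergence": [p.value for p in infl_pairs],
                }
            )
            div_df.to_csv(out / "infiltration_pairs.tsv", sep="\t", index=False)
            summary["infiltration_divergence_median_by_category"] = {
                cat: _round(v)
                for cat, v in div_df.groupby("category")["divergence"].median().items()
            }

            immu = immunomodulator_summary(expr, sheet)
            immu.to_csv(out / "immunomodulators.tsv", sep="\t", index=False)
            summary["immunomodulator_mean_z_metastasis"] = _round(
                float(immu.loc[~immu["missing"], "z_metastasis"].mean())
            )
            panel = biomarker_panel(
                expr, sheet, cyt_pseudocount=config.cyt_pseudocount
            )
            panel.to_csv(out / "biomarkers.tsv", sep="\t")

    # --------------------------------------------------------------- genomics
    muts = None
    if config.run_genomics:
        with _Stage("genomics"):
            muts = read_maf(config.cohort_dir / "mutations.maf")
            muts.validate_against_sheet(sheet)
            manifest_inputs["mutations.maf"] = _sha256(
                config.cohort_dir / "mutations.maf"
            )
            segs = read_seg(config.cohort_dir / "segments.seg")
            manifest_inputs["segments.seg"] = _sha256(
                config.cohort_dir / "segments.seg"
            )
            class_rows = []
            for pid in sheet.patients():
                tumour = [r.sample_id for r in sheet.tumour_samples_of(pid)]
                if not tumour:
                    continue
                counts, _ = classify_mutations(
                    muts.subset_for_samples(tumour), tumour, pid
                )
                class_rows.append(dataclasses.asdict(counts))
            class_df = pd.DataFrame(class_rows)
            class_df.to_csv(out / "mutation_classes.tsv", sep="\t", index=False)
            summary["mutation_classes_by_patient"] = {
                r["patient_id"]: {
                    "trunk": int(r["trunk"]),
                    "shared": int(r["shared"]),
                    "private": int(r["private"]),
                }
                for r in class_rows
            }

            tmb_rows = []
            for rec in sheet:
                if rec.tissue_class not in (TissueClass.PRIMARY, TissueClass.METASTASIS):
                    continue
                row = {"sample_id": rec.sample_id, "tmb": tmb(muts, rec.sample_id)}
                try:
                    row["cis"] = _round(cis_score(segs, rec.sample_id).cis)
                except UndefinedMetricError:
                    row["cis"] = float("nan")
                tmb_rows.append(row)
            tmb_df = pd.DataFrame(tmb_rows)
            tmb_df.to_csv(out / "tmb_cis.tsv", sep="\t", index=False)
            summary["tmb_mean"] = _round(float(tmb_df["tmb"].mean()))
            summary["cis_mean"] = _round(float(tmb_df["cis"].mean()))

    # ------------------------------------------------------------ coevolution
    if config.run_coevolution:
        with _Stage("coevolution"):
            if muts is None:
                muts = read_maf(config.cohort_dir / "mutations.maf")
            if infl is None:
                infl = read_infiltration(
                    config.cohort_dir / "infiltration.tsv",
                    renormalize=config.renormalize_infiltration,
                )
            rng = substream(config.seed, "coevolution")
            coev_rows = []
            skips = []
            for pid in sheet.patients():
                tumour = [r.sample_id for r in sheet.tumour_samples_of(pid)]
                if len(tumour) < 3:
                    skips.append(f"{pid}: fewer than 3 tumour samples")
                    continue
                neo = neoantigen_sets(muts.subset_for_samples(tumour))
                neo = {s: neo.get(s, set()) for s in tumour}
                if not any(neo.values()):
                    skips.append(f"{pid}: no predicted neoantigens")
                    continue
                dendros = {}
                dendros["neoantigen"] = complete_linkage(jaccard_distance_matrix(neo))
                tcr_sets = {s: repertoires[s].key_set for s in tumour}
                dendros["tcr"] = complete_linkage(jaccard_distance_matrix(tcr_sets))
                if all(s in infl.index for s in tumour):
                    dendros["infiltration"] = complete_linkage(
                        euclidean_distance_matrix(infl.loc[tumour])
                    )
                for name, dend in dendros.items():
                    write_newick(dend, out / "trees" / f"{pid}_{name}.nwk")
                seed_p = int(rng.integers(2**31))
                for res in coevolution_test(
                    pid,
                    dendros,
                    n_perm=config.n_perm,
                    seed=seed_p,
                    two_sided=config.two_sided,
                ):
                    coev_rows.append(dataclasses.asdict(res))
            coev_df = pd.DataFrame(coev_rows)
            coev_df.to_csv(out / "coevolution.tsv", sep="\t", index=False)
            summary["coevolution"] = [
                {
                    "patient_id": r["patient_id"],
                    "modalities": f"{r['modality_a']}~{r['modality_b']}",
                    "r": _round(r["r"]),
                    "p": _round(r["p"]),
                }
                for r in coev_rows
            ]
            if skips:
                summary["coevolution_skipped"] = skips

    # ------------------------------------------------------------------ stats
    with _Stage("stats"):
        test_rows = []
        for metric, pairs in (
            ("tcr_heterogeneity", tcr_pairs),
            ("infiltration_divergence", infl_pairs),
        ):
            if not pairs:
                continue
            results, skipped = compare_categories(pairs, metric)
            for r in results:
                row = dataclasses.asdict(r)
                row["stars"] = significance_stars(r.p_adjusted)
                test_rows.append(row)
        if test_rows:
            tests_df = pd.DataFrame(test_rows)
            tests_df.to_csv(out / "category_tests.tsv", sep="\t", index=False)
            summary["n_category_tests"] = int(len(tests_df))

    summary_text = json.dumps(summary, indent=2, sort_keys=True)
    (out / "summary.json").write_text(summary_text + "\n")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "inputs_sha256": manifest_inputs,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return summary
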