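"""Domain types and readers/writers for the cohort's external file formats.

The analysis consumes six kinds of input:

* per-sample TCR clonotype tables (AIRR rearrangement TSV),
* a sample sheet mapping samples to patients, tissue classes and sites,
* an immune-cell fraction matrix (22 cell types per sample),
* a gene-expression TPM matrix (genes x samples),
* a MAF-like somatic mutation table with an optional neoantigen flag,
* a SEG-like table of purity-adjusted segment copy numbers.

All readers accept plain or gzip-compressed text (``.gz`` suffix).
Coordinates in :class:`SegmentTable` are 0-based half-open internally;
SEG input is treated as 1-based inclusive and converted on read.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "TissueClass",
    "SampleRecord",
    "SampleSheet",
    "ClonotypeKey",
    "ClonotypeTable",
    "VariantKey",
    "MutationRecord",
    "MutationTable",
    "SegmentTable",
    "CELL_TYPES",
    "read_airr_tsv",
    "write_airr_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_infiltration",
    "write_matrix",
    "read_expression",
    "read_maf",
    "write_maf",
    "read_seg",
    "write_seg",
    "write_newick",
    "load_immunomodulator_panel",
    "load_trb_genes",
]


def _read_data_text(name: str) -> str:
    return importlib.resources.files("timeco.data").joinpath(name).read_text()


def load_cell_types() -> List[str]:
    """The canonical ordered list of the 22 deconvolved immune cell types."""
    return [ln for ln in _read_data_text("cell_types.txt").splitlines() if ln.strip()]


CELL_TYPES: List[str] = load_cell_types()

#: The 7 T-cell columns of the 22-type panel; their row sum is used as the
#: relative T-cell fraction of a sample when none is supplied explicitly.
T_CELL_TYPES = [c for c in CELL_TYPES if c.startswith("T cells")]


def load_immunomodulator_panel() -> pd.DataFrame:
    """Immunomodulator gene panel (gene, category, checkpoint_role).

    Category labels are annotation only; no computation depends on them.
    """
    import io as _io

    return pd.read_csv(_io.StringIO(_read_data_text("immunomodulators.tsv")), sep="\t")


def load_trb_genes() -> tuple[List[str], List[str]]:
    """Return (V gene names, J gene names) for labelling synthetic clonotypes."""
    names = [
        ln.strip()
        for ln in _read_data_text("trb_genes.txt").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    v = [n for n in names if n.startswith("TRBV")]
    j = [n for n in names if n.startswith("TRBJ")]
    return v, j


class TissueClass(str, Enum):
    """Tissue-of-origin class of a sample."""

    NORMAL = "normal"
    PRIMARY = "primary"
    METASTASIS = "metastasis"
    BLOOD = "blood"

    @classmethod
    def parse(cls, value: str) -> "TissueClass":
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            allowed = ", ".join(m.value for m in cls)
            raise FormatError(
                f"unknown tissue_class {value!r}; allowed values: {allowed}"
            ) from None


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample and its cohort metadata."""

    sample_id: str
    patient_id: str
    tissue_class: TissueClass
    site_label: str = ""
    t_cell_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.t_cell_fraction is not None and not (0.0 <= self.t_cell_fraction <= 1.0):
            raise ValidationError(
                f"t_cell_fraction for {self.sample_id} must lie in [0, 1], "
                f"got {self.t_cell_fraction}"
            )


class SampleSheet:
    """Cohort container mapping samples to patients and tissue classes.

    Drives every within-patient pairwise comparison downstream.
    """

    def __init__(self, records: Sequence[SampleRecord]):
        ids = [r.sample_id for r in records]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValidationError(f"duplicate sample_id(s): {sorted(dupes)}")
        self.records: List[SampleRecord] = list(records)
        self._by_id: Dict[str, SampleRecord] = {r.sample_id: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> List[str]:
        return [r.sample_id for r in self.records]

    def patients(self) -> List[str]:
        seen: Dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def samples_of(
        self,
        patient_id: str,
        classes: Optional[Iterable[TissueClass]] = None,
    ) -> List[SampleRecord]:
        wanted = set(classes) if classes is not None else None
        return [
            r
            for r in self.records
            if r.patient_id == patient_id
            and (wanted is None or r.tissue_class in wanted)
        ]

    def tumour_samples_of(self, patient_id: str) -> List[SampleRecord]:
        """Primary and metastatic samples of a patient (the mutation universe)."""
        return self.samples_of(
            patient_id, (TissueClass.PRIMARY, TissueClass.METASTASIS)
        )


class ClonotypeKey(NamedTuple):
    """Identity of a TCR clonotype: CDR3 amino-acid junction plus V and J calls.

    Equality is exact string equality on the triple.  D-segment calls are
    deliberately not part of the key (unreliable in short-amplicon data);
    a nucleotide-junction key can be used by passing a different junction
    column to :func:`read_airr_tsv`.
    """

    junction_aa: str
    v_call: str
    j_call: str


@dataclass
class ClonotypeTable:
    """One sample's TCR repertoire as a clonotype -> read-count map."""

    sample_id: str
    counts: Dict[ClonotypeKey, int] = field(default_factory=dict)
    n_dropped: int = 0  # input rows discarded for missing/empty junction

    def __post_init__(self) -> None:
        bad = [k for k, c in self.counts.items() if c < 1]
        if bad:
            raise ValidationError(
                f"clonotype counts must be >= 1; offending keys: {bad[:3]}"
            )

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)

    @property
    def key_set(self) -> Set[ClonotypeKey]:
        return set(self.counts)

    def count_vector(self) -> np.ndarray:
        return np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))


_AIRR_COLUMNS = ("junction_aa", "v_call", "j_call", "duplicate_count")


def read_airr_tsv(
    path,
    sample_id: Optional[str] = None,
    junction_column: str = "junction_aa",
) -> ClonotypeTable:
    """Read an AIRR rearrangement TSV into a :class:`ClonotypeTable`.

    Rows with an identical (junction, v_call, j_call) key are merged by
    summing duplicate_count; rows with a missing or empty junction are
    dropped and tallied in ``ClonotypeTable.n_dropped``.
    """
    from pathlib import Path

    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").removesuffix(".tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [junction_column, "v_call", "j_call", "duplicate_count"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory AIRR column {col!r}")
    counts: Dict[ClonotypeKey, int] = {}
    n_dropped = 0
    junctions = df[junction_column].to_numpy()
    vs = df["v_call"].to_numpy()
    js = df["j_call"].to_numpy()
    raw = df["duplicate_count"].to_numpy()
    for i in range(len(df)):
        junc = junctions[i].strip()
        if not junc:
            n_dropped += 1
            continue
        try:
            c = int(raw[i])
        except ValueError:
            raise FormatError(
                f"{path}: non-integer duplicate_count {raw[i]!r} at data row {i + 1}"
            ) from None
        if c < 1:
            raise FormatError(
                f"{path}: duplicate_count must be >= 1, got {c} at data row {i + 1}"
            )
        key = ClonotypeKey(junc, vs[i], js[i])
        counts[key] = counts.get(key, 0) + c
    return ClonotypeTable(sample_id=sample_id, counts=counts, n_dropped=n_dropped)


def write_airr_tsv(table: ClonotypeTable, path) -> None:
    """Write a clonotype table in AIRR rearrangement TSV form."""
    df = pd.DataFrame(
        {
            "junction_aa": [k.junction_aa for k in table.counts],
            "v_call": [k.v_call for k in table.counts],
            "j_call": [k.j_call for k in table.counts],
            "duplicate_count": list(table.counts.values()),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    """Read a CSV/TSV sample sheet (delimiter sniffed).

    Required columns: sample_id, patient_id, tissue_class, site_label.
    Optional: t_cell_fraction.  tissue_class is validated case-insensitively.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    for col in ("sample_id", "patient_id", "tissue_class", "site_label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing sample-sheet column {col!r}")
    records = []
    for _, row in df.iterrows():
        frac: Optional[float] = None
        if "t_cell_fraction" in df.columns and str(row["t_cell_fraction"]).strip():
            frac = float(row["t_cell_fraction"])
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                tissue_class=TissueClass.parse(row["tissue_class"]),
                site_label=row["site_label"],
                t_cell_fraction=frac,
            )
        )
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in sheet],
            "patient_id": [r.patient_id for r in sheet],
            "tissue_class": [r.tissue_class.value for r in sheet],
            "site_label": [r.site_label for r in sheet],
            "t_cell_fraction": [
                "" if r.t_cell_fraction is None else repr(r.t_cell_fraction)
                for r in sheet
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_infiltration(
    path, renormalize: bool = False, tol: float = 1e-6, renorm_tol: float = 1e-3
) -> pd.DataFrame:
    """Read a samples x 22-cell-type fraction matrix.

    Each row must sum to 1 within ``tol``.  Deviations up to ``renorm_tol``
    are repaired only when ``renormalize`` is set (deconvolution outputs sum
    to 1 by construction, so larger deviations signal corrupt input).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if set(df.columns) != set(CELL_TYPES):
        missing = sorted(set(CELL_TYPES) - set(df.columns))
        extra = sorted(set(df.columns) - set(CELL_TYPES))
        raise FormatError(
            f"{path}: infiltration matrix must have exactly the 22 canonical "
            f"cell-type columns; missing {missing}, unexpected {extra}"
        )
    df = df[CELL_TYPES]
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: infiltration fractions must be >= 0")
    sums = df.sum(axis=1)
    off = (sums - 1.0).abs()
    if (off > tol).any():
        if renormalize and (off <= renorm_tol).all():
            df = df.div(sums, axis=0)
        else:
            worst = off.idxmax()
            raise FormatError(
                f"{path}: row sums deviate from 1 by more than {tol} "
                f"(worst: {worst}, sum {sums[worst]:.6f}); pass renormalize=True "
                f"to repair deviations up to {renorm_tol}"
            )
    return df

def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a TSV matrix with an index column (shared by both matrix kinds)."""
    df.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TPM matrix; genes must be unique, values >= 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene symbols: {dupes[:5]}")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: TPM values must be >= 0")
    return df


class VariantKey(NamedTuple):
    """Somatic variant identity used to collapse MAF rows across samples."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    classification: str


@dataclass
class MutationRecord:
    key: VariantKey
    samples: Set[str]
    is_neoantigen: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValidationError(f"variant {self.key} carried by no sample")


class MutationTable:
    """Per-patient somatic variants with their carrying-sample sets."""

    def __init__(self, records: Iterable[MutationRecord]):
        self.records: Dict[VariantKey, MutationRecord] = {}
        for rec in records:
            if rec.key in self.records:
                raise ValidationError(f"duplicate variant record for {rec.key}")
            self.records[rec.key] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def samples(self) -> Set[str]:
        out: Set[str] = set()
        for rec in self.records.values():
            out |= rec.samples
        return out

    def present_in(self, sample_id: str) -> List[MutationRecord]:
        return [r for r in self.records.values() if sample_id in r.samples]

    def subset_for_samples(self, sample_ids: Iterable[str]) -> "MutationTable":
        wanted = set(sample_ids)
        return MutationTable(
            MutationRecord(r.key, set(r.samples), r.is_neoantigen)
            for r in self.records.values()
            if r.samples & wanted
        )

    def validate_against_sheet(self, sheet: SampleSheet) -> None:
        for rec in self.records.values():
            for s in rec.samples:
                if s not in sheet:
                    raise ValidationError(
                        f"variant {rec.key} carried by unknown sample {s!r}"
                    )
                if sheet[s].tissue_class is TissueClass.BLOOD:
                    raise ValidationError(
                        f"blood sample {s!r} must not carry somatic variants"
                    )


_MAF_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
)


def read_maf(path) -> MutationTable:
    """Read a MAF-essential TSV, collapsing rows with the same variant key.

    An optional ``is_neoantigen`` column (0/1/true/false) marks predicted
    neoantigens; rows of the same variant are OR-ed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for col in _MAF_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing MAF column {col!r}")
    has_flag = "is_neoantigen" in df.columns
    recs: Dict[VariantKey, MutationRecord] = {}
    for _, row in df.iterrows():
        key = VariantKey(
            chrom=row["Chromosome"],
            pos=int(row["Start_Position"]),
            ref=row["Reference_Allele"],
            alt=row["Tumor_Seq_Allele2"],
            gene=row["Hugo_Symbol"],
            classification=row["Variant_Classification"],
        )
        flag: Optional[bool] = None
        if has_flag:
            flag = str(row["is_neoantigen"]).strip().lower() in ("1", "true", "yes")
        rec = recs.get(key)
        if rec is None:
            recs[key] = MutationRecord(key, {row["Tumor_Sample_Barcode"]}, flag)
        else:
            rec.samples.add(row["Tumor_Sample_Barcode"])
            if flag is not None:
                rec.is_neoantigen = bool(rec.is_neoantigen) or flag
    return MutationTable(recs.values())


def write_maf(muts: MutationTable, path) -> None:
    rows = []
    for rec in muts.records.values():
        for s in sorted(rec.samples):
            rows.append(
                {
                    "Hugo_Symbol": rec.key.gene,
                    "Chromosome": rec.key.chrom,
                    "Start_Position": rec.key.pos,
                    "Reference_Allele": rec.key.ref,
                    "Tumor_Seq_Allele2": rec.key.alt,
                    "Variant_Classification": rec.key.classification,
                    "Tumor_Sample_Barcode": s,
                    "is_neoantigen": (
                        "" if rec.is_neoantigen is None else int(rec.is_neoantigen)
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class SegmentTable:
    """Purity-adjusted copy-number segments, 0-based half-open coordinates."""

    COLUMNS = ("sample_id", "chrom", "start", "end", "adjusted_cn")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"segment table missing columns {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["adjusted_cn"] = df["adjusted_cn"].astype(float)
        if (df["end"] <= df["start"]).any():
            raise ValidationError("segments must satisfy end > start")
        if (df["adjusted_cn"] < 0).any():
            raise ValidationError("adjusted_cn must be non-negative")
        for (sample, chrom), grp in df.groupby(["sample_id", "chrom"], sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValidationError(
                    f"overlapping segments for sample {sample!r} on {chrom!r}"
                )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample_id"] == sample_id]

    def samples(self) -> List[str]:
        return list(dict.fromkeys(self.df["sample_id"]))


def read_seg(path) -> SegmentTable:
    """Read a SEG-like TSV (sample, chrom, start, end, adjusted_cn).

    Input coordinates are 1-based inclusive; converted to 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    for col in df.columns:
        low = col.strip().lower()
        if low in ("sample", "id", "sample_id"):
            rename[col] = "sample_id"
        elif low in ("chrom", "chromosome"):
            rename[col] = "chrom"
        elif low in ("start", "loc.start"):
            rename[col] = "start"
        elif low in ("end", "loc.end"):
            rename[col] = "end"
        elif low in ("adjusted_cn", "seg.mean", "copy_number", "value"):
            rename[col] = "adjusted_cn"
    df = df.rename(columns=rename)
    missing = [c for c in SegmentTable.COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing SEG column(s) {missing}")
    df["start"] = df["start"].astype(np.int64) - 1  # 1-based incl -> 0-based half-open
    return SegmentTable(df)


def write_seg(segs: SegmentTable, path) -> None:
    out = segs.df.copy()
    out["start"] = out["start"] + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)


def write_newick(dendrogram, path) -> None:
    """Write a dendrogram as Newick with branch lengths equal to merge-height
    differences (leaves sit at height 0)."""
    with open(path, "w") as fh:
        fh.write(dendrogram.to_newick() + "\n")
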