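# timeco

Analysis toolkit for **t**umour **im**mune micro**e**nvironment heterogeneity and
**co**-evolution in multi-region cancer cohorts.

When several regions of a primary tumour, several metastatic sites, adjacent
normal tissue and blood are sampled from the same patient, the immune
compartment can be compared across all of them: how much of the T-cell
receptor (TCR) repertoire is shared between sites, how divergent the
immune-cell infiltrate is, and whether the tumour's neoantigen landscape and
the immune response evolved along the same path. `timeco` implements that
analysis as a tested, reusable pipeline, together with a seeded synthetic
cohort generator so every stage can be exercised and validated without any
external data.

## What it computes

**TCR repertoire** (per sample, from AIRR rearrangement TSVs keyed by CDR3
amino-acid junction + V/J calls):

- richness *S* (unique clonotypes), optionally rarefied to a common read
  depth and normalized by the sample's relative T-cell fraction;
- Shannon entropy *H* = −Σ pᵢ ln pᵢ (nats);
- Pielou evenness *J* = *H*/ln *S* and clonality *C* = 1 − *J*;
- highly expanded clones (HEC): clonotypes holding > 0.1% of a sample's reads;
- per V-J segment usage and differential usage between tissue groups
  (Wilcoxon rank-sum + Benjamini–Hochberg FDR).

**Heterogeneity** (within-patient sample pairs, labelled inter-normal /
intra-primary / inter-metastasis / inter-primary-normal /
inter-primary-metastasis / inter-normal-metastasis / blood-*):

- TCR heterogeneity = 1 − Jaccard similarity of clonotype sets;
- the percentage of a tissue sample's top-100 clonotypes found in blood;
- immune-cell infiltration divergence = Euclidean distance between
  22-dimensional deconvolved cell-fraction vectors.

**Expression summaries**: per-gene tissue-group medians of a 70-gene
immunomodulator panel, z-scored across the normal/primary/metastasis group
medians; cytolytic activity CYT = √(GZMA × PRF1) in TPM; an immunotherapy
biomarker panel (CYT, PD-L1, PD-L2, PD-1, CD39, CD8A, CD8B, CD4) z-scored
across samples within each patient.

**Genomic summaries**: trunk / shared / private classification of somatic
variants over each patient's tumour samples (present in all / ≥2-but-not-all /
exactly one), tumour mutational burden (count of non-synonymous variants per
sample), and the chromosome instability score CIS = fraction of the covered
genome with purity-adjusted copy number ≥ 3 or ≤ 1.

**Co-evolution**: per patient, complete-linkage dendrograms over the tumour
samples built from neoantigen sets (Jaccard distance), TCR clonotype sets
(Jaccard) and infiltration vectors (Euclidean); trees are compared by the
cophenetic correlation *r* (Pearson correlation of the two trees' merge
heights over all leaf pairs) with a leaf-label permutation p-value,
enumerated exhaustively for up to 7 leaves.

## Worked example

Generate a three-patient synthetic cohort (2 normal, 3 primary, 3 metastatic,
1 blood sample per patient) and run the full pipeline:

```bash
timeco simulate --out demo/cohort --seed 5 --n-patients 3
timeco run-all --cohort demo/cohort --outdir demo/run --seed 5
```

`demo/run/summary.json` then contains (excerpt):

```json
"shared_pct_mean_by_category": {
  "intra-primary": 9.53, "inter-metastasis": 4.65,
  "inter-primary-metastasis": 4.04, "inter-normal-metastasis": 4.13, ...
},
"diversity_mean_richness_by_class": {
  "metastasis": 1027.3, "normal": 504.5, "primary": 497.0, "blood": 390.0
},
"top_n_blood_overlap_mean_by_class": {
  "metastasis": 56.6, "primary": 40.6, "normal": 23.3
}
```

Read: samplings of the same primary tumour share ~9.5% of their clonotypes
while metastatic sites share only ~4.7% (metastases are the most
heterogeneous compartment); metastases carry the richest repertoires; and
56.6% of a metastasis' hundred most abundant clones are also found in the
patient's blood versus 23.3% for normal tissue — the circulating-surveillance
signature. Per-patient co-evolution rows report the cophenetic correlation
and permutation p for each modality pair, e.g.

```json
{"patient_id": "P3", "modalities": "neoantigen~tcr", "r": 0.755, "p": 0.044}
```

The run directory also holds tidy TSVs (diversity, pairwise comparisons,
VJ differential usage, biomarker/immunomodulator matrices, TMB/CIS,
mutation classes, category rank-sum tests with significance stars), Newick
trees per patient and modality, and a manifest with input hashes and the
seed. Identical config + seed reproduces every output byte-for-byte.

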