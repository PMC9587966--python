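# Methods

This note documents the statistical conventions of the analysis stages, the
model behind the synthetic cohort generator, and the limits of what the test
suite demonstrates.

## Repertoire metrics

A clonotype is identified by the exact triple (CDR3 amino-acid junction,
V call, J call). D-segment calls are excluded because they are unreliable in
short-amplicon data; a nucleotide junction can be used instead by pointing
`read_airr_tsv` at a different junction column. Reader rows with identical
keys are merged by summing counts, conserving total reads.

Diversity uses natural logarithms throughout. Clonality is 1 − Pielou
evenness; for a monoclonal sample (S = 1) Pielou's H/ln S is 0/0 and
clonality is defined as 1, the limit of a two-clone repertoire as the minor
clone vanishes. The HEC threshold is strict (> 0.1% of reads, not ≥): a
clone at exactly 0.1% is not counted. Both a clone-count proportion
(HEC/S) and a read-mass proportion are reported; the clone-count
proportion is the headline number.

Richness normalization rarefies each sample to a cohort-common depth
(default: the minimum total reads over samples) by seeded
without-replacement subsampling, repeated 10 times with the mean reported
to damp sampling noise, then divides by the sample's relative T-cell
fraction. The rarefaction mean matches the closed-form hypergeometric
expectation on small cases (tested).

Sharing between two repertoires is the Jaccard similarity of clonotype key
*sets* — abundance is deliberately ignored, so a clone present at 1 read
and at 10 000 reads contributes equally. Heterogeneity is 1 − Jaccard.
Top-n blood overlap ranks a tissue sample's clonotypes by count with ties
broken by descending count then lexicographic key, for determinism.

Pairwise comparisons are made strictly within patients. Blood samples pair
only with non-blood samples; the nine category labels follow the tissue
classes of the two samples. Unordered pairs are counted once (three
metastatic sites yield three inter-metastasis comparisons).

## Statistics

The two-sided Wilcoxon rank-sum test enumerates the exact permutation null
(a counting recursion over rank subsets) when the pooled sample size is at
most 12 and the data are tie-free; the exact two-sided p is
min(1, 2·min(P(W ≤ w), P(W ≥ w))) for the rank-sum W of the smaller group.
Otherwise the tie-corrected normal approximation with continuity correction
is used. Multiple testing uses Benjamini–Hochberg step-up, applied
separately per test family (category contrasts per metric; V-J usage).

Pairwise heterogeneity values within a patient share samples and are not
independent; pooled-pair rank-sum testing is nevertheless the field's
practice and is replicated as such. `compare_categories` offers an
optional per-patient median aggregation as a sensitivity analysis.

## Expression summaries

Immunomodulator summarization takes, per gene, the median TPM over each
non-blood tissue group and z-scores the three medians with the sample
standard deviation (n−1); zero-variance genes get all-zero z rather than
NaN, and genes absent from the matrix are flagged missing rather than
imputed as zero. The biomarker panel z-scores CYT plus seven genes within
each patient across that patient's samples; single-sample patients are
reported as undefined (NaN). Blood samples are excluded by default since no
tumour expression is measured there. CYT uses no pseudocount, so a zero in
GZMA or PRF1 propagates; a `cyt_pseudocount` option restores the
offset-before-geometric-mean convention.

## Genomic summaries

Trunk/shared/private classes are disjoint by construction: trunk requires
presence in *all* tumour samples, shared in ≥2 but not all, private in
exactly one; this makes the three counts partition the patient's variants
(the conservation invariant tested on 1 000 random presence matrices).
Normal-tissue and blood samples are excluded from the classification
universe. TMB counts variants (not variant-sample pairs) whose MAF
classification is in the canonical non-synonymous set; unknown
classification strings are an error unless strict mode is disabled. CIS
applies the aberrancy thresholds inclusively (CN ≥ 3 or ≤ 1) to the
purity-adjusted values as given, with the sample's total covered segment
length as denominator (exome coverage varies between samples); a fixed
genome size can be supplied instead. SEG input is 1-based inclusive and is
converted to 0-based half-open internally.

## Co-evolution

Per patient, dendrograms over the tumour samples (blood and normal
excluded) are built by complete-linkage agglomeration, with ties in the
minimum inter-cluster distance broken by the lexicographically smallest
member labels so results are label-deterministic. TCR trees use
presence/absence Jaccard distance on clonotype keys, mirroring the
heterogeneity metric; neoantigen trees use Jaccard on predicted-neoantigen
variant sets; infiltration trees use Euclidean distance on the 22-type
fraction vectors.

The cophenetic correlation is the Pearson correlation, over all unordered
leaf pairs matched by label, of the two trees' lowest-common-merge heights.
Significance comes from a leaf-label permutation null with the add-one
estimator, one-sided by default (only a large positive correlation counts
as co-evolution; a two-sided flag exists). For ≤ 7 leaves all n!
permutations are enumerated and the p-value is exact, with support
{k/n!}. The correlation is reported as undefined when either tree's
cophenetic vector is constant (Pearson is 0/0 there). Patients with fewer
than three tumour samples, or with no flagged neoantigens, are skipped
with the reason recorded.

## Synthetic cohort model

The generator emits every input the pipeline consumes, at a desk scale
chosen so the full acceptance analysis runs in seconds: by default
5 patients × (2 normal + 3 primary + 3 metastatic + 1 blood) samples,
repertoire richness 580/600/1200/400 for normal/primary/metastasis/blood
at 6 000 reads per sample. The class ordering (metastases richest, blood
poorest; metastases least clonal, Zipf exponent 0.85 vs ≈1.1 elsewhere)
mirrors the ordering reported for multi-region gastroesophageal cohorts at
roughly 1/75 of real-data richness.

**Abundances.** Clone abundances are Zipf(s) with ranks assigned uniformly
at random; reads are multinomial at the configured depth, so low-rank
clones can go unobserved (depth truncation). The clone detection rate q of
each class is measured empirically at build time and every sharing
calculation is corrected by it.

**Sharing.** Each comparison category has a target observed Jaccard
similarity (defaults: intra-primary and inter-normal 0.10, inter-metastasis
0.0467, inter-primary-metastasis 0.0426, inter-normal-metastasis 0.0399,
blood-tissue 0.01–0.02). The identity-level intersection a pair needs is
I = J*(Rᵢqᵢ + Rⱼqⱼ)/(qᵢqⱼ(1+J*)). Sharing is realized through one
patient-wide clone pool: every tissue sample includes each pool clone with
a class-specific rate, modulated by a Gaussian kernel (bandwidth 0.45) on
the distance between the sample's latent position and the clone's latent
position. The class rates solve a log-least-squares system so expected
pairwise intersections hit the category targets (cross-class equations
weighted 10×, since within-class pairs can be topped up by small
class-private pools afterwards); kernel-induced scaling is divided out
using Monte-Carlo constants computed under the actual position marginals.
A per-pair disjoint planting cannot work here: summed over a sample's
eight partners the required pairwise intersections exceed its richness,
which is exactly why real repertoire sharing is multi-way ("public"
clones). Measured recovery of the tissue-category targets is within
±0.003 at 10 patients.

**Latent geometry and coupling.** Normal and primary samples sit near a
patient centroid (s.d. 0.09/0.07 in the unit square); metastases are
uniform — the geometric counterpart of metastatic divergence. A coupling
parameter γ ∈ [0,1] blends each modality's positions between the common
latent positions and fresh noise: at γ=1 TCR sharing and shared-variant
placement follow one divergence, at γ=0 they are independent (neoantigen
noise positions are class-free, so the independent arm carries no shared
class imprint). Infiltration means are modulated along the same latent
axes, so TCR–infiltration co-evolution also emerges. Default γ=0.8.
Measured at 30 patients per arm: mean cophenetic r(TCR, neoantigen) ≈ 0.5
coupled vs ≈ 0 independent.

**Blood.** The blood sample carries each tissue sample's top-100 observed
clones with class-specific rates (0.19 normal, 0.38 primary, 0.565
metastasis — the circulating-surveillance pattern), plus pool sharing for
any shortfall. At desk scale this surveillance planting dominates: the
observed blood-tissue Jaccard (~0.05–0.08) overshoots the 0.01–0.02
targets, because a few hundred planted top clones are a large fraction of
a 400-clone blood repertoire where in real data they are a large fraction
of the *top* of a 30 000-clone repertoire. The top-100 overlap ordering is
reproduced; the blood Jaccard targets should be read as lower bounds at
this scale.

**Mutations, segments, expression.** Each patient gets exact configured
counts of trunk (all tumour samples), shared (subset of size 2..n−1 grown
around a random seed sample by latent proximity) and private variants;
neoantigen flags are Bernoulli(0.35) on non-synonymous variants only.
Segments partition a 22-chromosome genome with class-specific aberrancy
rates (normal 0.02, primary 0.15, metastasis 0.30), giving CIS its
expected class ordering. TPM is log-normal per gene with metastasis
location shifts: +0.8 for the immunomodulator panel (heavy
immunomodulation) and −1.4 for T-cell effector genes (depleted effector
infiltration). Primary-tumour repertoires carry one V-J combination
(TRBV25-1/TRBJ2-5) at ~3% of clones versus ~0.14% elsewhere, a planted
true positive for the differential-usage stage. The per-sample
t_cell_fraction in the sample sheet is the sum of the seven T-cell columns
of that sample's infiltration row (0.5 for blood).

All randomness descends from a single seed through named substreams
(SHA-256-derived spawn keys), so identical config + seed reproduces every
output file byte-for-byte and toggling one pipeline stage cannot perturb
another's draws.

## What the tests do and do not show

The synthetic cohort has the *statistical* structure the analysis assumes —
Zipf abundances, calibrated multi-way sharing, Dirichlet fractions,
constructive mutation trees, log-normal TPM — but none of the biological
texture of real data: no sequencing error or clonotype mis-assembly, no
batch effects, no covariance between infiltration and expression beyond
the planted shifts, pairwise-exchangeable (not phylogenetic) repertoire
sharing, and no deconvolution uncertainty (fractions are exact draws).
Passing tests therefore demonstrate correctness of the metrics and
pipeline plumbing and recoverability of planted effects at desk scale, not
robustness to real-data artefacts. The cophenetic permutation test
conditions on the inferred trees and ignores their estimation uncertainty,
and pooled-pair category tests inherit the non-independence caveat above.
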