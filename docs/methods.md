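# Methods

This note documents the statistical procedures implemented in `micoprog`,
the choices made where the underlying methods literature leaves room, and
what the synthetic-cohort experiments do and do not demonstrate.

## ICR scoring and immune subtyping

The Immunologic Constant of Rejection (ICR) is a fixed 20-gene signature of
Th1 polarization (*IFNG*, *IRF1*, *STAT1*, *IL12B*, *TBX21*), CD8 T cell
effectors and chemoattractants (*CD8A/B*, *CXCL9/10*, *CCL5*, granzymes,
*GNLY*, *PRF1*) and counter-regulatory checkpoints (*CD274*, *PDCD1*,
*CTLA4*, *FOXP3*, *IDO1*). The ICR score of a sample is the arithmetic mean
of its log2-normalized expression over these 20 genes; missing signature
genes are an error, never silently dropped.

Immune subtypes come from resampling consensus clustering restricted to the
signature genes: in each repetition a fraction of samples (default 0.8) is
drawn without replacement and clustered by Ward-linkage agglomerative
clustering (Euclidean distance on row-z-scored genes; gene z-scoring is
optional); the consensus matrix records, for every sample pair, the
co-clustering frequency among co-drawn repetitions. Final labels at each k
cut a complete-linkage dendrogram of `1 − consensus`; the number of
clusters (searched over 2–6) maximizes the Calinski–Harabasz criterion of
those labels on the signature data. The default repetition count is 5,000;
250 repetitions already give stable consensus matrices at the cohort sizes
used in the tests and CLI. The same subsample draws are reused across k so
criterion values are comparable. Clusters are mapped to Low/Medium/High by
ranking their mean ICR score; at k ≠ 3 only the extremes are labeled, with
a warning. Ties break deterministically (cluster size, then smallest
member id).

Single-sample enrichment uses the standard ssGSEA rank walk: genes are
ranked by expression, rank values n..1 raised to a weight exponent (default
0.25) weight the in-set cumulative distribution, and the score sums the
in-set minus out-of-set ECDF difference over all ranks. At exponent 0 the
walk reduces to an unweighted KS-like sum, which is what the brute-force
oracle test enumerates.

## TCR repertoire metrics

All metrics operate on productive (in-frame) clones only. Entropy is
Shannon entropy in bits over clone frequencies; Pielou evenness is
`J = H / log2(S)` with S the number of unique productive clones; clonality
is `1 − J`, requiring S ≥ 2. The identical formulas serve DNA-targeted and
RNA-derived clone tables — the log base cancels in J, so clonality is
base-independent.

A clone is *tumor-enriched* against its matched normal when its tumor
productive frequency strictly exceeds 0.1% and the tumor/normal frequency
ratio is at least 32. Clones undetected in the normal are treated as
satisfying the fold criterion (an undetected clone is maximally enriched);
a pseudo-count policy is available as an alternative. The enriched-clone
burden of a sample is the template-weighted fraction: enriched templates
over all productive templates.

## Somatic filtering, neoantigens, GIE and IES

Variants are retained when their class is nonsynonymous (frameshift and
in-frame indels, missense, nonsense, nonstop, splice site, translation
start site), allele fraction ≥ 5%, tumor depth > 3 reads, and population
allele frequency ≤ 1%. Nonsynonymous TMB divides the retained count by a
40 Mb capture; hypermutation is strictly > 12/Mb. MSI labeling is MSI-H
strictly above an instability score of 0.4, MSS at or below. A candidate
epitope is a neoantigen when its mutant median IC50 is strictly below
500 nM while its wild-type counterpart's is strictly above 500 nM.

The genetic immunoediting (GIE) value is O/E with E(x) = −2.38770 +
0.09171·x (x = nonsynonymous count). The line can be refit by OLS on a
reference set. E ≤ 0 (x below ≈ 26) makes a sample non-evaluable — no
ratio is fabricated. The binarization cutoff defaults to 1 (fewer
neoantigens than expected ⇒ edited). The IES composite maps (ICR Low, no
GIE) → IES1, (Low, GIE) → IES2, (High, no GIE) → IES3, (High, GIE) → IES4;
ICR-medium and non-evaluable samples stay unassigned.

## Microbiome profiling

Tables are samples × taxa. Counts are closed to relative abundances per
sample; genera are kept when present (abundance > 0) in at least 10% of
samples and reaching at least 1% relative abundance in at least one sample
(both bounds inclusive; the filter is idempotent). Alpha diversity reports
observed richness, bias-corrected Chao1 `S + F1(F1−1)/(2(F2+1))` (classic
form by flag; integer counts required), Shannon in natural log — the
ecology convention, deliberately distinct from the bits used for TCR
entropy — and inverse Simpson. Taxa harmonization merges many-to-one label
maps (e.g. *Ruminococcus 1*/*2* → *Ruminococcus*) by summation, conserving
per-sample mass exactly. Tumor-vs-normal differential abundance uses the
two-sided Wilcoxon signed-rank test on patient-paired differences with
Benjamini–Hochberg FDR across the union of taxa passing the filter in
either tissue; fold changes add a 1e-6 pseudo-abundance.

## The MBR risk signature

Training z-scores each genus with the training cohort's mean and sample
standard deviation (ddof = 1) and fits a relaxed elastic-net Cox model of
overall survival. A common λ path (50 values, down to 0.01·λ_max) is
computed on the full training matrix; for each fold of a 5-fold split the
penalized path is refit on the training fold and, per λ, the relaxation
blend `γ·β_penalized + (1−γ)·β_refit` (γ ∈ {0, 0.25, 0.5, 0.75, 1};
β_refit = unpenalized Cox on the active set) is scored on the held-out
fold by Harrell's C. The (γ, λ) maximizing the mean out-of-fold C wins
(exact ties prefer the stronger penalty, then the more penalized blend),
and the final model refits on all training data at that point. The mixing
parameter of the elastic net is fixed at 0.5 by default and exposed.
Unpenalized refits on active sets larger than 0.8× the event count are
skipped — such fits are unidentifiable — and the penalized solution is
used unchanged for those grid points.

Scoring a sample multiplies the z-scores of the classifier genera (nonzero
coefficients) present in the new table — always standardized with the
*training* parameters — by their coefficients and sums; absent classifier
genera contribute zero, each sample is scored independently, and genera
with zero training variance are excluded with a warning. Scores binarize
at 0: strictly negative is low risk; exactly 0 falls on the high side (the
low-risk definition is strict). Models serialize to a versioned plain-text
file with `%.17g` floats, which round-trips IEEE doubles exactly.

## Survival machinery

Kaplan–Meier, log-rank and Cox fitting are delegated to lifelines behind
the module surface (Efron ties by default; a Breslow flag routes through
statsmodels' proportional-hazards model), with Wald CIs on the log-hazard
scale. Pairwise hazard contrasts are guarded: both groups must hold at
least 10 patients unless overridden. Harrell's C is implemented here
directly: usable pairs are those where one member observably fails first,
score ties count 0.5. The density-matched subsampling experiment draws
subsets either uniformly or with weights proportional to a target cohort's
score density — a piecewise-linear interpolation of a 50-bin histogram
density evaluated at each case's matching score — fits a univariate Cox
model per subset, counts p < 0.05, and compares the two schemes'
significant counts by a chi-squared test. Horizon survival (e.g. 5-year)
is read from the step function with the drop at an event time included,
so S(t) = P(T > t).

The adjusted biomarker comparison fits, per candidate (ICR ordinal, GIE
binary, MBR binary), one multivariable Cox model with age continuous,
stage ordinal (I–IV), MSI binary (MSI-H vs MSS) and CMS categorical with
CMS4 as reference, on complete cases with the exclusion count reported.
The mICRoScore is high only for ICR-high ∧ MBR-low samples; any complete
other combination is low; a missing input leaves the sample unassigned.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
defaults chosen once to resemble a mid-sized colon-cancer profiling
cohort: 246 patients; 3 expression groups in equal proportions whose 20
signature genes shift by 3 log2 units per group level over unit Gaussian
noise; clone repertoires of richness 1,000 sampled as 20,000 templates
from a truncated-geometric clone law whose skew is calibrated by bisection
to per-group clonality targets (0.08/0.14/0.25) — the calibration
objective is the clonality realized by a fixed-seed multinomial reference
draw, since finite sampling of rare clones would otherwise bias realized
clonality below the ideal-law target; 5 tumor-spiked clones at 0.5% tumor
frequency and 64-fold enrichment with deterministic template counts, so
the 32×/0.1% rule is satisfied by construction; a 25% hypermutated
lognormal mutation mixture truncated above the expectation line's zero
crossing, with observed neoantigens E(x)·m + N(0,1) noise at editing
strength m = 0.5 for half the cohort; Dirichlet genus compositions
(concentration 50) where 3 risk and 2 protective taxa receive per-sample
standard-normal log-scale concentration perturbations; and exponential
proportional-hazards survival (baseline median 5 years, follow-up capped
at 15) whose log-hazard combines the ICR level (−0.5/level), the editing
flag (−0.5) and the designated taxa's z-scored realized abundances (±1),
with independent uniform censoring at rate 0.3. Driving the hazard by the
realized abundance z-scores makes a linear risk model over standardized
abundances the correctly specified target of the MBR trainer.

What the generator does *not* emulate: batch effects, count overdispersion
beyond the Dirichlet, phylogenetic correlation among taxa, sequence
content of clones, non-proportional hazards, informative censoring, or
assay-specific noise (e.g. PCR bias). Recovery results on these cohorts
therefore demonstrate the correctness and statistical calibration of the
pipeline's machinery under its own assumptions, not its performance on
real cohorts.

## Problem sizes and numerical choices

The test suite and acceptance checks run the recovery experiments at: 150
samples for consensus-clustering recovery (250 repetitions), 20 seeds of
full 246-sample cohorts for MBR sign recovery, 20 permutation replicates
for the null concordance calibration, 200 replicates (n = 500) for Cox CI
coverage, 1,000 null replicates (n = 60) for log-rank type-I error, and 20
meta-replicates of 25 subsets × 100 samples for the subsampling
experiment — sizes chosen to make Monte-Carlo error small relative to each
acceptance band. Numerical details: consensus matrices are symmetrized
and clipped to [0, 1] with unit diagonal; the relaxation Newton solver
uses a 1e-4 ridge and returns to the penalized solution on failure; BH
adjustment uses the standard step-up; all randomness flows from
`numpy.random.default_rng` seeds, making every experiment reproducible
bit-for-bit.
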