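# Methods

## Overview

`atacage` reimplements, as a tested library plus a sequence of analysis
scripts, the full path from per-sample ATAC-seq peak calls and fragment
files to an elastic-net aging clock: consensus open-chromatin-region (OCR)
construction, Tn5 cut-site quantification and QC, genome-wide
age-association statistics with multi-omic integration (expression,
CpG methylation), preranked GSEA, nested cross-validated clock training,
cell-composition/sex correction, and condition-effect testing on clock
output. Real cohorts are replaced by a synthetic generator whose planted
ground truth makes every stage testable.

## Consensus OCRs and annotation

Coordinates are 0-based half-open (BED) throughout; narrowPeak summit
columns are ignored. The consensus procedure is:

1. union of all per-sample peak sets (overlapping and book-ended intervals
   merged);
2. "reliable" regions = maximal sub-regions where at least `min_samples`
   samples called a peak simultaneously (default 50, matching a cohort of
   ~150; each sample contributes depth at most 1 per base);
3. union peaks are kept iff they overlap a reliable region by >= 1 bp;
4. peaks overlapping a blacklist by >= 1 bp are removed.

Both the union and the depth filter are exact sweep-line computations and
are tested against per-base brute-force oracles on randomized <= 10 kb
instances, and against `bedtools merge` on the union.

Annotation: an OCR is a promoter iff it intersects `[tss-w, tss+w]`
(closed on both ends, w = 1000 bp default) for any TSS; an enhancer iff it
overlaps any curated enhancer region by >= 1 bp; both criteria give the
dual class; otherwise unannotated. The four classes are mutually exclusive
and exhaustive. Gene linking offers nearest-TSS mode (distance from OCR
midpoint; ties broken by lexicographically smallest symbol so results are
deterministic) and a link-table mode (0..n genes per enhancer). Strand is
carried but unused for distances, because TSS positions are already
strand-resolved.

## Quantification, normalization and QC

Each fragment contributes two 1-bp Tn5 cut sites: its start and its last
covered base (end - 1). A site increments an OCR's count iff it lies
inside the OCR, so a fragment can contribute 0, 1 or 2 counts. Fragments
are assumed already shift-corrected; the reader can apply the standard
(+4, -5) transposase offset to raw coordinates.

Normalization: density_ij = count_ij / (length_i / 1000); then division by
per-sample reads-in-peaks in millions. The invariant
`sum_i normalized_ij * length_i(kbp) = 1e6` holds exactly per sample. The
log matrix is `ln(normalized + 1)`; the pseudocount is configurable.

QC: a sample is low-quality iff it has fewer than 11 million good
alignments or cut-site FRIP below 0.18; boundary values pass (failure is
phrased strictly below threshold). FRIP uses cut sites as units,
consistent with counting. Outliers are additionally flagged by a
minimum-covariance-determinant elliptic envelope on the first two
principal components of the feature-centered log-normalized matrix
(contamination default 0.10; the PCA is unscaled; degenerate covariance
flags nothing). The robust fit needs >= 10 samples and a seed.

## Age-association statistics

Per feature: Spearman correlation with age (average ranks for ties;
two-sided p from the t approximation), Benjamini–Hochberg q-values over
all features of the modality, and a class: opening/up if r > 0 and
q < 0.01, closing/down if r < 0 and q < 0.01, else stable. Constant
features get r = 0, p = 1, stable, with a flag.

Annotation enrichment among opening/closing OCRs uses Fisher's exact test
(two-sided, the safer default where sidedness is not dictated) on the 2x2 table
(in class vs rest) x (annotated vs not), with the dual class counting as
both promoter and enhancer.

Shift tests use the one-sided two-sample Kolmogorov–Smirnov statistic:
direction "greater" means the target sample is stochastically greater, and
D is the largest ECDF difference in that direction, with asymptotic
p = exp(-2 n_eff D^2), n_eff = n1 n2 / (n1 + n2). Exact pooled-grid
enumeration is the test oracle.

Cross-modality integration ("correlation of correlations"): Pearson r
between two per-feature age-correlation vectors over linked feature pairs,
restricted by region class. Each link is one observation (a gene linked to
several CpGs or OCRs contributes several points); CpGs are assigned to the
unique OCR containing them (half-open boundaries). Gene-body methylation
coupling reuses the same operation with CpG-in-gene-body links.

## GSEA

The ranked list comes from 1:1 OCR–gene links: OCRs without a linked gene
or whose gene is not in the expression matrix are dropped; when a gene has
several OCRs, the pair maximizing |Spearman(accessibility, expression)|
over the samples common to both assays is kept (or only promoter pairs, in
promoter-only mode); the gene's score is the Spearman correlation of the
kept OCR's accessibility with age.

Enrichment uses the weighted Kolmogorov–Smirnov running sum (hit steps
|score|^p / sum of hit weights with p = 1 by default, miss steps
1/(N - N_h); ES is the extremum of largest absolute value). The null is a
gene-label permutation: for each term size, `n_perm` (default 1000) random
same-size sets; NES = ES / mean |null ES| of matching sign; nominal
p = (1 + #{|null same-sign ES| >= |ES|}) / (1 + #same-sign); q = BH across
terms. Ties in scores keep stable input order, so callers should
pre-resolve exact ties deterministically. The implementation is checked
against a prefix-sum oracle and cross-checked against gseapy's preranked
ES/NES on a toy list; small numeric differences in NES are expected
because normalization constants are estimated from finite permutations.

## Clock

Model: elastic net on standardized features minimizing
`(1/2n)||y - Xb||^2 + lambda (alpha_l1 ||b||_1 + (1-alpha_l1)/2 ||b||_2^2)`
with an unpenalized intercept. Standardization parameters are always
estimated on the training split only and stored in the model;
zero-variance training features are dropped (coefficient 0). Fitting uses
scikit-learn coordinate descent; the pure-ridge case is solved in closed
form. The KKT stationarity conditions at the solution are an explicit
tested contract (violation < 1e-6 at tight tolerance).

Fold assignment sorts samples by age and deals consecutive blocks of k
round-robin into k groups (within-block order seeded), so every group's
ages span the cohort range; the trailing partial block is dealt to random
distinct groups. Default k = 11.

Nested CV: the outer loop leaves one group out; the inner loop, a
leave-one-group-out CV over the remaining groups, selects
(lambda, alpha_l1) by mean RMSE (ties prefer stronger penalty); the model
is refit on all non-held-out samples and predicts the held-out group once.
Metrics: RMSE, MEDIAN absolute error, Pearson r, reported per fold and as
mean +/- sd. Honesty is tested by perturbation: corrupting a held-out
group's ages cannot change its predictions. Default grids are 20
log-spaced lambdas in [1e-3, 100] and alpha in {0.1, 0.5, 0.9}; the
analyses and acceptance runs use 6–8 log-spaced lambdas in [0.1, ~30] and
alpha in {0.5, 0.9}, which select equivalent models on the synthetic
cohorts at a fraction of the cost.
The inner-loop solver runs at tolerance 1e-3 with warm starts along the
lambda path; final per-fold refits use 1e-5.

Multiomic clocks concatenate accessibility and expression matrices with
`atac:`/`rna:` prefixed feature ids; per-split standardization puts the
blocks on one scale.

## Correction

Composition correction fits, per feature, OLS of accessibility on
[1, age, cell fractions] and subtracts only the composition component with
fractions centered at training means, so the age effect is preserved and
the same coefficients can correct held-out samples. Within nested CV the
fit uses the outer-fold training samples only (leakage is perturbation-
tested). Fractions are used raw (not logit-transformed). Because the
measured panel is collinear by construction (T = CD4 + CD8, lymphocytes =
T + B + NK, leaves sum to ~1), the default design uses {monocytes, B, NK,
CD4 T, CD8 T}, leaving granulocytes as the implicit reference; rank
deficiency is detected and reported with the offending columns.

Generic covariate removal (sex, etc.) fits [1, age, covariates] and
subtracts the centered covariate component; with `preserve_age=False` the
age column is omitted so shared variance leaves with the covariates. The
inverse experiment — keep only what composition explains — returns
intercept + composition-fitted values (age and residual dropped), so a
clock trained on it can exploit composition signal only.

## Condition comparison

Given predicted and chronological ages with a two-level condition, the
delta = predicted - chronological is compared by a Welch t-test (unequal
variances by default; the degenerate all-constant case returns t = 0,
p = 1) and by OLS `delta ~ 1 + age + condition`,
whose condition coefficient is the effect in years. The reference level is
the lexicographically first label unless set. Non-overlapping age ranges
between conditions trigger a confounding warning.

Note an expected attenuation: a regularized clock compresses predictions
toward the cohort mean, so a shift planted as E years along the aging axis
is recovered as slightly less than E (about 0.8–0.95x at the scales used
here). The age term in the adjusted model absorbs the compression of the
age trend but not of the condition shift itself. The recovery test
therefore checks the planted value against the estimate's 95% CI rather
than expecting exact equality.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults are the study
conditions and all randomness flows from one seed through named substreams
(layers are independently reproducible; identical configs are
byte-identical).

* Donors: n = 150, ages uniform on [20, 74], 26% female, optional
  condition subgroup.
* Cell composition: logistic-normal over six leaf populations (monocytes,
  granulocytes, B, NK, CD4 T, CD8 T; baselines 0.20/0.03/0.12/0.10/
  0.35/0.20), latent sd 0.35, with per-year latent slopes for NK (+0.0070)
  and CD8 T (-0.0059) calibrated so the realized fraction–age Pearson
  correlations average ~+0.31 (NK), ~-0.25 (CD8 T) and ~-0.23 (total T) at
  n = 150 — the magnitudes reported for human blood. Aggregates T and
  lymphocytes are sums of leaves.
* OCR universe: 5000 OCRs on five synthetic chromosomes with exclusive
  class mix 19.1% promoter / 53.2% enhancer / 5.0% dual / 22.7%
  unannotated (the class mix typical of a PBMC consensus set), gene
  TSS tables and enhancer-link records laid out so that re-annotating the
  coordinates reproduces the stored classes exactly.
* Aging effects are planted at the gene level: 3.3% of genes opening and
  4.7% closing (genome-wide proportions of the scale seen in blood
  ATAC aging studies), half strong
  (target |Spearman| 0.5) and half weak (0.25), on top of a continuous
  background aging rate (sd 0.18). A gene's promoter OCR carries the
  gene's aging rate exactly; its enhancer OCRs carry a degraded copy; the
  gene's expression slope is coupled at rho = 0.32, which yields
  accessibility–expression age-effect correlations of ~0.32 at promoters
  and ~0.25 at enhancers by construction, the magnitudes reported for
  blood multi-omic aging data. CpG methylation slopes are anti-coupled to
  the host OCR at
  -0.20 (enhancers) / -0.045 (promoters), which induces a near-zero
  methylation–expression coupling, as observed.
* Counts: negative binomial (dispersion 0.05) around
  exp(baseline + composition mixing + sex offset + aging effect) times a
  per-sample lognormal library size (log-sd 0.3). The composition term is
  linear in the measured fractions, so it is exactly removable by the
  composition correction. Effect slopes are converted from target Spearman
  magnitudes using the model's known noise variance; the realized
  correlations are mildly attenuated by count noise (a strong 0.5 tier
  realizes at ~0.45–0.5).
* Expression and methylation are emitted directly as normalized matrices
  (Gaussian log-scale expression; betas as logistic transforms of a
  Gaussian latent); ~70% of CpGs fall inside OCRs.
* The condition subgroup is shifted along the planted aging axis by
  `condition_effect_years` (default 5), i.e. every OCR moves as if the
  donor were that much older.

A separate fragment-level generator emits per-sample fragment BEDs and
peak calls (true OCRs with Bernoulli dropout and jittered boundaries);
fragments land inside OCRs with probability `frip_target` and strictly
outside otherwise, so realized FRIP is binomial around the target.

What the generator does NOT emulate — and hence what passing tests do not
show about real data: sequence content and GC bias, fragment-length
periodicity, enrichment of enhancers among age-associated OCRs (planted
effects are uniform across annotation classes, so Fisher enrichment on
synthetic data is ~1 and the machinery is validated against exhaustive
oracles instead), batch and protocol effects between cohorts, and the
real effect-size spectrum (the synthetic clock reaches r ~ 0.99 because
planted effects are cleaner than biology; real-cohort clock accuracy is
lower). Real-cohort headline numbers are therefore not reproduced here;
the synthetic results mirror orderings and planted values, not
magnitudes.

## Problem sizes used

Tests and the acceptance script run at desk scale, chosen once: the
default cohort n = 150 x M = 5000 for age correlations and the main clock
CV; n = 120 x M = 1500 with boosted composition noise (loading sd 8.0 on
80% of OCRs) for the correction comparison; n = 200 (100 per condition
group) x M = 1000 for the condition effect; 20 samples x 40 OCRs x 8000
fragments for the fragment-level stages; 200 random sets x 1000
permutations for NES calibration.
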