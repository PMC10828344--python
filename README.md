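# atacage

Chromatin accessibility changes with age at specific regulatory elements,
and those changes can be used to predict a blood donor's age. `atacage` is
a tested reimplementation of that analysis for epigenomics researchers:
from per-sample ATAC-seq peak calls and fragment files to a consensus set
of open chromatin regions (OCRs), genome-wide aging statistics integrated
across accessibility, expression and CpG methylation, and an elastic-net
aging clock with cell-composition correction and condition-effect testing.

At its core is the penalized regression

    age ≈ X β + β0,   β = argmin (1/2n)‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²)

on standardized OCR accessibility features (cut-site densities per kbp per
million reads-in-peaks, log scale), evaluated by nested leave-one-group-out
cross-validation over k = 11 age-balanced groups and reported as RMSE,
median absolute error (MAE) and Pearson r. Around it sit the standard
stages: consensus peakset construction (union → regions called in ≥ 50
samples → blacklist), Tn5 cut-site counting (two 1-bp insertion sites per
fragment), FRIP/depth QC with elliptic-envelope outlier removal, per-feature
Spearman-with-age + Benjamini–Hochberg classification (opening / closing /
stable at FDR < 0.01), Fisher enrichment, one-sided KS shift tests,
preranked GSEA with a permutation NES, and OLS-based composition/sex
correction that preserves the age effect.

Real cohorts are replaced by a synthetic generator (`atacage.synthetic`)
that plants recoverable ground truth: age-drifting cell fractions (NK up,
CD8 T down), cell-intrinsic opening/closing effects in two strength tiers,
expression coherently coupled to promoter/enhancer accessibility,
methylation weakly anti-coupled to accessibility and nearly uncoupled from
expression, and an optional condition subgroup shifted along the aging
axis. See `docs/methods.md` for the model, parameters and limitations.

## Worked example

```sh
python analysis/01_simulate_cohort.py   # cohort with planted truth
python analysis/04_age_correlations.py  # genome-wide aging statistics
python analysis/06_clock.py             # nested-CV clock + multiomic comparison
```

which prints (seed 42):

```
accessibility: 649 opening, 666 closing of 5000 OCRs (FDR < 0.01)
  genes behind opening promoters: KS D=0.27 p=4e-09
  age-corr coupling acc_expr_promoter: r=0.301 (n=1205)
  age-corr coupling acc_expr_enhancer: r=0.220 (n=2910)
  age-corr coupling meth_acc_enhancer: r=-0.155 (n=1256)
  age-corr coupling meth_expr: r=-0.037 (n=1638)
...
nested 11-group leave-one-group-out CV, 5000 OCR features, 150 samples
  accessibility clock: RMSE 1.72 +/- 0.25, MAE 1.27 +/- 0.46, r 1.00 +/- 0.00, features 239
  expression clock: RMSE 3.22 +/- 0.68, MAE 2.18 +/- 0.87, r 0.98 +/- 0.01, features 240
  multiomic clock: RMSE 1.96 +/- 0.36, MAE 1.43 +/- 0.45, r 1.00 +/- 0.00, features 265
```

Reading this: opening/closing counts are the OCRs whose accessibility
rises/falls with age at FDR < 0.01; genes behind opening promoters shift
toward positive expression–age correlations (one-sided KS); the
accessibility↔expression age-effect coupling is stronger at promoters
(r ≈ 0.30) than enhancers (r ≈ 0.22) while methylation barely couples to
expression — the planted cross-modality structure. The clock recovers age
nearly perfectly here because synthetic effects are cleaner than biology;
the meaningful comparisons are the orderings (accessibility ≥ multiomic >
expression; see `analysis/07_composition_correction.py` for the
composition-corrected > uncorrected ≫ composition-only ordering, and
`analysis/08_condition_effect.py` for the +5-year condition shift
recovered from clock deltas by an age-adjusted linear model).

The remaining scripts cover the fragment-level stages (consensus peakset
from jittered peak calls with dropout, cut-site counting, FRIP/QC/outliers)
and preranked GSEA on the OCR→gene ranked list. All outputs land in
`results/`.

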