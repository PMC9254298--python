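# srnasig

Statistical workflow for discovering circulating small-RNA biomarkers of
diabetes subgroups from serum sRNA-seq count data: spike-in-calibrated
normalization, covariate-adjusted differential expression with
precision weights and moderated statistics, and nested cross-validated
sRNA signatures evaluated by ROC/AUC.

## Who this is for

Groups running case–control small-RNA sequencing studies (miRNAs,
isomiRs, tRNA fragments and other small non-coding RNAs) across several
clinical groups — here non-diabetic controls, adult-onset type 1
diabetes, type 2 diabetes and LADA (latent autoimmune diabetes in
adults) — who need the full chain from raw count matrices to validated
diagnostic signatures, with every statistical step testable against
synthetic data of known ground truth.

## The method

1. **Calibrator TMM normalization.** Ten synthetic spike-in RNAs are
   added in known amounts before library preparation, so their measured
   counts carry technical but not biological variation. Scaling factors
   are the trimmed mean of M-values (30 % trim on M, 5 % on A,
   precision-weighted) computed on the calibrator submatrix, with
   calibrator proportions taken relative to the biological library
   size; factors are rescaled to geometric mean 1. For sample *s* with
   calibrator counts *c<sub>ks</sub>* and biological library size
   *N<sub>s</sub>*, the M-values against the reference *r* are
   M<sub>k</sub> = log₂[(c<sub>ks</sub>/N<sub>s</sub>)/(c<sub>kr</sub>/N<sub>r</sub>)].

2. **Differential expression.** log₂-cpm with prior count 0.5, a lowess
   mean–variance trend of √(residual SD) against mean log₂ count,
   per-observation weights (trend⁻⁴), weighted least squares on a
   design with the compared groups plus age, sex and BMI, and
   empirical-Bayes variance moderation: s̃²₉ = (d₀s₀² + d₉s²₉)/(d₀ + d₉)
   with (d₀, s₀²) from closed-form moment matching of log s². Features
   pass a class-specific expression filter first (≥ 1 cpm in all
   samples for mature miRNAs, in ≥ 50 % of samples for isomiRs and
   other sRNAs). Discovery is controlled by Benjamini–Hochberg at
   q < 0.05. A fragment-length covariate (log₂ of total 30–33 nt read
   abundance) supports the tRNA sensitivity analysis.

3. **Signatures and validation.** A signature is the directed set of
   significant features for one contrast. Left-out samples are scored
   by the direction-aligned standardised mean of their signature
   features; leave-one-out cross-validation repeats feature selection
   inside every fold. The out-of-fold scores give the ROC curve, the
   Mann–Whitney AUC, a DeLong 95 % confidence interval and a one-sided
   Mann–Whitney p-value; signatures with cross-validated AUC > 0.7
   count as validated.

4. **Synthetic cohorts.** `srnasig.synthetic_data` generates
   negative-binomial counts (variance μ + φμ²) for four groups of 50
   samples with per-sample depth and technical-yield variation,
   calibrators that track input amount but not yield, isomiRs whose
   parent mature miRNA is their exact sum, sparse group effects of
   known log₂ fold change, and clinical covariates with realistic
   group-specific distributions — so FDR control, normalization
   recovery and selection-bias freedom are all verifiable.

## Worked example

```python
import srnasig as ss

# a synthetic cohort: 600 features x 200 samples, 5% of features truly
# differential in T2D with |log2 FC| = 1.5
cm, annotation, samples, truth = ss.make_fixture("medium")

de = ss.run_de(cm, annotation, samples, ("T2D", "LADA"))
print((de.table["q"] < 0.05).sum())        # 31 significant features

cv = ss.loocv(cm, annotation, samples, ("T2D", "LADA"))
print(round(cv.auc, 3), cv.p_value < 1e-10)  # 1.0 True
```

The differential-expression step recovers all 30 truly differential
features (31 calls, one extra at the FDR margin), and the nested
leave-one-out cross-validated signature separates the two groups
perfectly on this synthetic effect size. On a global-null cohort the
same pipeline returns a mean cross-validated AUC of ≈ 0.5 and no
systematic discoveries.

The same steps are available from the shell:

```sh
srnasig simulate --seed 7 --out data/
srnasig de --counts data/counts.tsv --annotation data/annotation.tsv \
    --samples data/samples.tsv --comparison T2D:LADA --out de.tsv
srnasig signature-cv --counts data/counts.tsv --annotation data/annotation.tsv \
    --samples data/samples.tsv --comparison T2D:LADA --seed 17 --out cv/
```

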