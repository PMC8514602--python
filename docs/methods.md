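# Methods

`swabomics` re-implements, as a tested library, the analysis chain used in
longitudinal on-swab profiling studies of the vaginal ecosystem in pregnancy:
direct ambient-ionization mass spectrometry of cervicovaginal swabs
(DESI-type), 16S-derived species count tables, immune-marker panels, and
term/preterm outcomes. This note records the models, the numerical choices,
and what the synthetic test bed does and does not establish.

## Synthetic cohorts

The generator (`swabomics.synthetic`) emulates a two-cohort pregnancy study:
subjects sampled at up to five visits inside gestational windows (defaults
8–16, 16–20, 20–26, 26–30, 30–37 weeks; ages uniform within a window, so
they increase strictly across visits). Default cohort size is 160 subjects,
matching the scale of the smaller study arm; the acceptance experiments use
smaller cohorts, stated per experiment below, purely as the package's own
choice of problem size.

* **Community state.** Each subject's community state type (CST, seven
  classes I–VII) follows a first-order Markov chain over visits
  (default self-persistence 0.85). CSTs I/II/III/V/VII are
  *Lactobacillus*-dominated (LDOM), IV/VI depleted (LDEPL).
* **Species counts** are Dirichlet-multinomial given the CST, with
  concentration mass 0.8 on the CST's dominant species and total
  concentration 50 (sharp, CST-like profiles) at library size 10 000.
* **Metabolome.** Log intensity per feature follows the same linear mixed
  model the inference stage fits: baseline + CST offsets + gestational
  slope + age/BMI/ethnicity effects + per-subject random intercept
  (sd 0.5) and random gestational-age slope (sd 0.02, uncorrelated) +
  Gaussian noise (sd 0.5). Defaults plant an LDEPL offset of 1.0 on half
  the features; all true coefficients are recorded as ground truth.
* **Immune markers** satisfy log(marker+1) = loadings · log-features +
  noise; concentrations are exponentiated and clipped at zero (assay
  floor).
* **Outcomes** are logistic in microbiome instability: base sPTB rate 0.18
  (the high-risk cohort rate), with the odds multiplied by a configurable
  factor (default 2.0, the order of the reported association) when the
  subject's trajectory crosses LDOM↔LDEPL. This is a deliberate
  simplification — the source studies report an association, not a
  generative outcome model — so outcome parameters are a modelling choice,
  not derived quantities.
* **Raw spectra** place one Gaussian per feature (width from resolving
  power R = 30 000) on a configurable m/z grid, apex height proportional
  to the feature intensity, with optional ppm jitter and additive baseline
  noise; 30 scans per sample by default.
* All randomness flows from one integer seed through spawned substreams
  (one per table), so adding a table never perturbs the others.

What the generator does **not** emulate: chromatography, isotope patterns,
matrix/ionization suppression, missing-not-at-random intensities, batch
effects beyond a smooth injection-order drift, or read-level 16S error.
Passing tests therefore demonstrate correctness of the algorithms under the
stated statistical model, not performance on real swab data.

## Spectral processing

The first 30 scans per sample are averaged (fewer scans: all available are
used). Noise is the scaled median absolute deviation (1.4826 × MAD),
constant per spectrum; peaks are strict local maxima within ±10 points at
SNR ≥ 3, ties breaking toward lower m/z for determinism. When the MAD is
exactly zero (noiseless synthetic spectra), positive intensities count as
infinite SNR; an all-zero spectrum yields no peaks.

Alignment warps each sample onto landmark peaks — strict bins present in
≥ 90 % of samples among peaks with SNR ≥ 2 — via locally weighted
regression of the matched displacements (linear fit below four matches;
identity warp with a warning below two). Binning is the strict recursive
scheme: a bin's member span must be ≤ 0.002 **relative** m/z and contain at
most one peak per sample, otherwise the group splits at its largest gap;
bins in < 1 % of samples are dropped, missing entries are zero (no
imputation), and the feature m/z is the mean of members. The 0.002
tolerance is interpreted as relative deviation (the convention of the
strict-binning algorithm being parameterized); an absolute-Da mode is
exposed in `PeakPickingParams` for users who prefer it. Half windows are in
points, not Da.

Drift correction fits a LOWESS trend of each feature's SR (pooled study
reference) intensity against injection index (span 2/3 of SR points, since
no span is prescribed), interpolates it to every sample and divides it out.
Rescaling is anchored either so the SR median is unchanged (default) or to
the trend value at the first injection (`anchor="run_start"`), which
restores the pre-drift intensity scale exactly when the run opens with an
SR injection — under a monotone drift the median-preserving anchor
necessarily leaves a global per-feature factor equal to the median drift
level, which is why both anchors exist. QC keeps features with SR
coefficient of variation ≤ 30 % and Pearson r ≥ 0.7 against the SR dilution
series; without a dilution series that filter is skipped with a warning.

## Community state typing

Samples are clustered by Ward linkage on pairwise Jensen–Shannon distances
(natural log; 0·log 0 := 0; no pseudocounts) between relative-abundance
profiles, after dropping species with fewer than 50 total counts. The
number of clusters maximizes the mean silhouette (computed on the same
distance matrix) over k = 2…15, smallest k on ties. Clusters take the CST
whose template taxon (I → *L. crispatus*, II → *L. gasseri*, III →
*L. iners*, IV → *G. vaginalis*, V → *L. jensenii*, VI → *B. breve*) has
the highest mean abundance among the cluster's top five taxa; a floor of
0.3 mean abundance (our choice — the merging of sub-clusters into CSTs was
originally manual) leaves a cluster "unassigned". Any sample whose most
abundant species is a *Lactobacillus* outside the four named ones becomes
CST VII regardless of its cluster.

## Biomarker discovery

Each feature is fitted by REML to

    log-intensity ~ GestationalAge + CST + MaternalAge + BMI + Ethnicity
                    + (GestationalAge || SubjectID)

with independent per-subject random intercepts and slopes. If the slope
variance collapses to the boundary or the fit fails to converge, the model
is refitted without the random slope and flagged — an expected, not
exceptional, outcome when the true slope variance is small.

Contrasts are estimated on a reference grid (maternal age 30 y, BMI 23,
gestational age 20 weeks, unweighted average over ethnicity levels):
LDOM vs LDEPL is the grand mean of CST I/II/III/V/VII predictions minus the
CST IV prediction; CST pair contrasts are direct differences; the
early-vs-late gestation contrast is the gestational slope scaled to a
20-week span (the week anchors are not prescribed anywhere, so the span is
a package default). Denominator degrees of freedom use the Satterthwaite
approximation, computed from the numerical curvature of the REML criterion
in the variance parameters, falling back to the residual df when a variance
sits on the boundary. (The Kenward–Roger adjustment would require
higher-order covariance corrections unavailable in this stack; at the
sample sizes involved the two agree closely and inference enters only
through signature-level FDR.)

Per contrast, p-values are pooled across all features of an assay and
Benjamini–Hochberg corrected as one signature at 5 % FDR; no correction is
applied across the five contrasts of a single feature. Cross-cohort
replication matches each feature to its nearest counterpart within 5 ppm
(|Δm/z|/m/z × 10⁶) and requires q < 0.05 on both sides.

Variance partition: per-feature semi-partial R² uses the Wald
standardized-effect form qF/(qF+ν) with ν the residual df; conditional R²
is the variance of fixed-plus-random predictions over the total response
variance. Matrix-level partitioning is a sequential (type-I) PERMANOVA on
Euclidean distances of log(x+1) — which reduces exactly to sequential
multivariate regression sums of squares, computed by incremental
orthogonalization — with terms in the order CST, gestational age,
ethnicity, BMI, age, subject; pseudo-F uses the full-model residual and
p = (#{F* ≥ F}+1)/(B+1) under free row permutation (B = 999 by default).
Subject enters last and absorbs repeated-measures variance; permutations
are unrestricted, mirroring the cited sequential procedure.

Immune–metabolite association fits log(marker+1) ~ feature per pair,
reports the slope t-ratio and F-test p, BH-corrects within each marker, and
exposes the R² > 0.1 selection rule.

## Prediction

Random forests (1000 trees by default) run inside repeated (15×) stratified
five-fold CV; all metrics use held-out predictions only, pooled per repeat
and averaged. mtry is p/3 for classification and √p for regression —
deliberately the printed protocol, though it reverses the common defaults —
and both rules are configurable. ROC/AUC uses held-out vote fractions;
sensitivity/specificity use majority-vote calls at 0.5 (the underlying CV
framework's convention; the original threshold is not stated). CV R² for
regression is the squared Pearson correlation between held-out predictions
and observed targets (headline), with 1−SSE/SST reported alongside.
16S matrices enter after centred-log-ratio transformation. For outcome
prediction the gestational axis splits into windows [0,14), [14,24),
[24,40] weeks — half-open so every age maps to exactly one window — with
one sample per subject per window (closest to the midpoint, earlier sample
on ties).

A caution encoded in the tests: under a true null, cross-validated AUC on a
*single* dataset is biased away from 0.5 by chance feature–outcome
correlations of order 1/√n that all folds share; null calibration is
therefore asserted on averages over independent cohort draws or label
permutations.

## Outcome statistics

A subject with ≥ 2 classified samples is unstable iff the ordered dominance
sequence contains both LDOM and LDEPL; single-sample subjects are excluded
with a warning. The instability–outcome association uses the two-sided
mid-p exact test: conditional on margins the table cell is hypergeometric,
the one-sided mid-p gives half weight to the observed table, and the
two-sided p doubles the smaller side (capped at 1) — the doubling rule is
our stated convention, as no two-sided rule is prescribed. The odds-ratio
point estimate is the sample cross-product ad/bc; the CI inverts the
two-sided mid-p over the odds parameter of Fisher's noncentral
hypergeometric distribution by bisection, bracketing from a coarse-grid
argmax since the mid-p is unimodal in log-odds. Fisher's exact test sums
hypergeometric probabilities ≤ that of the observed table (minimum-
likelihood rule; a doubling rule is available — note that mid-p ≤ Fisher
dominance holds only when both use the same sidedness rule, and a
counterexample exists against the minimum-likelihood rule). Pearson's
chi-squared supports the Yates correction on 2×2 tables; Welch's t uses the
Satterthwaite–Welch df. The "elevated marker" contingency builder uses
post > pre for paired data and > cohort median otherwise — a declared
convention, as the original threshold is not defined.

## Isolate screening

Replicate isolate intensities are compared to media background per feature
with the exact two-sided Wilcoxon–Mann–Whitney test (normal approximation
only when ties force it), BH-corrected within isolate (the original
correction, if any, is unstated); effect size is log₂(mean biomass / mean
background), undefined at zero background mean. Significant features are
matched to the in vivo signature by the same 5 ppm rule used for
cross-cohort replication — literally the same function.

## Numerical and degenerate-input conventions

Probability vectors must sum to 1 within 1e-12; all-zero spectra yield zero
noise and no peaks; constant responses short-circuit to zero contrasts with
p = 1; zero-margin 2×2 tables give p = 1 with the OR undefined and flagged;
constant features are skipped and flagged in pairwise regressions; a
degenerate (all-zero) distance matrix is an error. Ties: peak maxima break
to lower m/z, silhouette ties to smaller k, window-midpoint ties to the
earlier sample.

## Known limitations

Satterthwaite (not Kenward–Roger) denominator df; PERMANOVA permutations
unrestricted by subject (the subject term absorbs, but does not condition
on, repeated measures); the CST template floor and the outcome model's
logistic link are package conventions; binning tolerance semantics
(relative vs absolute Da) are exposed because the original parameterization
is ambiguous; no profile-mode resolution modelling or isotope
deconvolution; mzML files are read but not written — simulated spectra are
exported as two-column text scans; species count tables are exchanged as
TSV.
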