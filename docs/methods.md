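# Methods

This note documents the statistical procedures, the synthetic-data model
used to validate them, the numerical choices, and the limitations of both.

## Association testing

All association tests in the package share one inferential recipe: fit the
model with and without the term of interest by maximum likelihood and refer
−2 log(L₀/L₁) to χ² with one degree of freedom.

For the Gaussian linear model the error variance is profiled out, so the
statistic reduces to `n·log(RSS₀/RSS₁)`; both RSS values come from
least-squares solves (`numpy.linalg.lstsq`, with a QR-based
Frisch–Waugh decomposition in the vectorised genome-wide scan — the two
paths are algebraically identical and tested to agree to 1e-8). Designs
are checked for rank; a deficient design raises an error naming the
collinear columns rather than silently dropping one. Categorical
covariates (visit batch, plate) are one-hot encoded against the
lexicographically first level.

For the logistic model the statistic is the deviance drop, fitted by
damped Newton–Raphson. A vanishing deviance (no finite maximiser) is
surfaced as a distinct perfect-separation condition, never a silent
estimate; the incident-disease screen records such probes as untestable.
Odds ratios are reported per standard-deviation *decrement* of
methylation, `exp(−β)`, with Wald 95% intervals on the same scale (the
interval method is a package choice; the convention makes hypomethylation
risk read as OR > 1).

### Complete cases and transforms

Each marker is analysed on its own complete cases (markers differ in
missingness; antibody titres against oxLDL are the sparsest). Oxidised
LDL and its antibodies are ln-transformed before modelling; the other
eight markers enter raw. Responses are methylation beta values, not
M-values.

## Multiple testing

Per-trait FDR uses Storey q-values: π₀(λ) = #{p > λ}/(m(1−λ)) on the grid
λ = 0.05…0.95 (step 0.05), smoothed by a cubic polynomial (a df-3
smoother) evaluated at the grid maximum, clipped to (0, 1] with a floor of
1/m. Scans smaller than 100 tests carry too little tail information for
the smoother and fall back to π₀ = 1, which makes q-values coincide
exactly with Benjamini–Hochberg — an identity the tests assert. q-values
are monotone in p and invariant to input order.

The cis-meQTL scan does not use q-values: because only a candidate probe
set is scanned, the p-value distribution is not array-wide and the FDR is
estimated by permutation instead. Genotype sample labels are permuted
jointly across all SNPs — one permutation per replicate applied to the
whole dosage matrix — which preserves both LD and the methylation
correlation structure. Ten replicates record the minimum p per probe; the
threshold is the largest observed min-p `t` at which

    mean over replicates of #{probes with permuted min-p ≤ t}
    ---------------------------------------------------------  < 0.05.
              #{probes with observed min-p ≤ t}

0/0 counts as 0. An alternative reading (permuted-positive fraction of
probes < 5%) is available behind `estimator="perm_fraction"`. Probes at
or below the threshold are flagged significant (the threshold is itself an
observed value, so the comparison is inclusive). When no candidate
qualifies, the threshold is reported as undefined rather than forced.

Case/control and genotype permutation tests use the +1-smoothed
convention `(1 + #{stat ≥ observed})/(B + 1)`, valid under
exchangeability and bounded below by 1/(B+1). Covariates are refit under
every permuted label vector (a batched Newton solver fits thousands of
permuted logistic models simultaneously). In exhaustive mode all distinct
label arrangements are enumerated and p = #{stat ≥ observed}/N, the
observed arrangement included. Permuting the outcome breaks outcome–
covariate links; this is a known simplification of label-permutation
tests and is documented rather than corrected.

## Annotation conventions

Coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted on ingestion. Islands take precedence over
shores over shelves; shores are positions within 2,000 bp of an island
border (inclusive), shelves within 4,000 bp, distances measured to the
nearest border on the same chromosome. Gene features are strand-aware:
TSS200 spans 1–200 bp upstream of the transcription start, TSS1500 spans
201–1,500 bp; 5'UTR, first exon, 3'UTR are explicit intervals and the
body is the remaining transcript span. Labels accumulate over all
overlapping transcripts; for single-label summaries the precedence is
promoter (TSS1500/TSS200/5'UTR/first exon) > body > 3'UTR > intergenic.

Context enrichment uses an exact Fisher test implemented by direct
hypergeometric enumeration (two-sided p sums outcome probabilities no
larger than the observed one, with the conventional 1e-7 tie slack);
sidedness is a parameter with a two-sided default. The SNP filter for
meQTL analysis keeps MAF ≥ 5% and INFO strictly > 0.8 — the minor-allele
direction follows universal practice and the genotype-QC pipeline that
feeds this analysis. The cis window (±100 kb) is inclusive at the
boundary.

## Triad screen

A (SNP, CpG, marker) triad passes iff the SNP–marker nominal p < 0.001,
the SNP–CpG pair is meQTL-significant, and the CpG–marker q < 0.05.
These three gates are the screen's definition and are deliberately not
configurable. Triads are enumerated only over tested pairs. The
suggestive SNP–marker gate uses the nominal p; the permutation p is
reported alongside. The screen is an overlap criterion, not a formal
mediation model.

## Synthetic cohort

The generator emulates the data model of a population cohort of ~966
same-aged individuals with the ten-marker oxidative panel.

* **Methylation** is generated on the logit scale — probe baseline (a
  bimodal mixture, giving the characteristic U-shaped beta distribution)
  + cell-mixture loadings + batch/plate/conversion effects + planted
  effects + N(0, 0.4) noise — and mapped through the inverse logit, so
  betas stay strictly inside (0, 1). Probes carrying planted effects are
  anchored at baseline logit 0 (beta ≈ 0.5), where the logit slope `b`
  linearises to a beta-scale slope of `b/4`; the truth table stores that
  linearised slope per unit of transformed marker. The residual logistic
  curvature attenuates recovered slopes by a few percent, which the
  recovery tolerance absorbs.
* **Cell mixture**: six blood cell fractions from a Dirichlet with
  neutrophil-dominated concentration (≈0.55/0.15/0.10/0.05/0.05/0.10,
  concentration 60). Probes load on the centred fractions; markers are
  weakly coupled to a common cell-composition score, creating genuine
  cell-mixture confounding. The covariates carry *predicted* fractions
  (truth plus estimation noise, not renormalised), so adjustment is
  realistic rather than oracle-perfect.
* **Markers** reproduce the reported panel moments (e.g. homocysteine
  10.6 ± 3.98 µmol/l) and per-marker observation counts as missingness.
  oxLDL is drawn log-normal moment-matched on the raw scale; OLAB
  log-normal with the reported log-scale moments; the rest normal.
  Normal draws can produce occasional negative values for the
  glutathione ratio — a cosmetic artefact left in place to preserve the
  stated moments. All ten markers are drawn independently; the GSSG/GSH
  ratio is simulated as its own marker, not as an arithmetic ratio.
* **Genotypes**: Hardy–Weinberg genotypes at uniform MAF 0.01–0.5 with
  small imputation noise, quantised to 3 decimals like posterior-mean
  dosages; SNPs are independent (no LD) apart from planted placements.
  Planted meQTL SNPs are forced common (MAF ≥ 0.2) and well-imputed.
* **Planted effects**: a fraction of probes receive a marker coupling
  (logit slope per SD of transformed marker); a fraction receive a cis
  dosage effect whose slope is calibrated against the probe's realised
  non-genetic variance so the dosage explains the configured share of
  logit variance; triads add a direct SNP→marker effect (default 8% of
  marker variance). Incident T2D is drawn from a logistic model on the
  standardised betas of planted disease CpGs plus age/sex/BMI/smoking,
  with the intercept solved to hit the configured prevalence
  (default 71/966); cardiovascular sub-outcomes (MI, stroke, heart
  failure) are drawn null at their observed prevalences and unioned into
  the composite CVD flag.
* **Determinism**: one seed feeds a `SeedSequence` whose children drive
  each stage; a fixed seed yields byte-identical cohorts and fixture
  files.

What passing tests do *not* show about real data: the generator has no
LD, no probe-type chemistry differences beyond labels, no time-to-event
structure, no marker–marker correlation, and logit-linear effects only —
calibration and power results transfer to real cohorts only insofar as
those features do not dominate.

## Problem sizes and defaults

Validation runs use deliberately scaled problem sizes chosen to make the
Monte-Carlo error small relative to the tolerances: the null calibration
uses 500 samples × 5,000 probes; slope recovery 900 × 500 with 50 planted
effects; meQTL calibration 20 cohorts of 500 × 200 probes × 2,000 SNPs;
the disease-power check 20 planted CpGs across 10 cohorts with ~70 cases
each (2,000 permutations); the triad screen 20 cohorts of 400 × 300 ×
1,500. Default generator dimensions (966 × 5,000 × 5,000) are a
package choice standing in for an array-scale cohort.

## Known limitations

* Reference-based cell deconvolution is consumed as covariates, never
  estimated; bisulphite chemistry, genotype imputation and array QC
  upstream of the dosage/beta matrices are out of scope.
* The meQTL model is covariate-free by default (an optional covariate
  set residualises first); whether covariates belong in that model is a
  genuine modelling choice.
* Wald intervals can undercover at low case counts; the permutation p is
  the primary significance measure for disease models.
* The BMI-sensitivity gate is a screening heuristic (sex-adjusted
  marker~BMI at p < 0.01), not a confounding proof.
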