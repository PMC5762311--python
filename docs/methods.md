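# Methods

## Overview

`actsig` implements a driver-activation analysis for tumor cohorts with
paired copy-number and expression data. The canonical use case is a
Hippo-pathway effector such as YAP1 in head and neck squamous cell
carcinoma: amplification is one activation mechanism, but many tumors
activate the driver without amplification, so activation status must be
inferred from the downstream transcriptional program rather than from copy
number alone. The pipeline has four stages:

1. **Signature derivation** — a dual marginal Pearson screen over all
   genes against (a) the driver's thresholded GISTIC score and (b) the
   driver's mRNA; the signature is the intersection of the two passing
   lists.
2. **Classification** — a Bayesian compound covariate predictor (BCCP)
   trained on copy-number-defined classes, producing a posterior
   activation probability per tumor.
3. **Survival analysis** — Kaplan–Meier/log-rank and pooled Cox models
   comparing activated (YA) and inactivated (YI) subtypes.
4. **Association battery** — per-gene Fisher screens on copy-number and
   mutation events, differential miRNA filters including a staged screen
   for copy-number-independent activation, clinical cross-tabulations,
   and an interferon-γ composite immune score.

A synthetic multi-omics cohort generator with planted ground truth backs
all recovery tests.

## The dual correlation screen

For every gene *g* the screen computes Pearson *r* and a two-sided p-value
(t distribution on *n* − 2 df) of its log2 expression against the driver's
GISTIC score treated as numeric, and against the driver's mRNA. A gene
enters a list when *p* < 0.001 and |*r*| strictly exceeds 0.2; the
signature is the intersection of the copy-number-associated and
mRNA-associated lists, with the driver itself excluded (it passes both
screens trivially but is not a downstream target). Choices worth noting:

- The thresholded GISTIC integers (−2…2) are the copy-number covariate,
  not continuous segment means, because gene-level thresholded tables are
  the expected input.
- No multiple-testing correction is applied; the raw *p* < 0.001 rule is
  the screen's definition. Result tables carry Benjamini–Hochberg q-values
  for information only.
- Pearson *r* is invariant to per-gene standardization, so the screen runs
  on unstandardized log2 values (asserted in tests).
- An empty intersection is a warning-level outcome, not an error.

The screen assumes dosage-driven activity: a gene whose expression tracks
an activation state that is *decoupled* from copy number cannot correlate
with the GISTIC score, no matter how real the biology. This is a property
of the method, not a defect of the implementation, and it shapes the
validation design below.

## The Bayesian compound covariate predictor

Training classes come from the driver's copy number: *active* iff
GISTIC ≥ 2 (high-level amplification), *inactive* otherwise, with at least
three samples per class. The per-gene weight is the pooled-variance
two-sample t-statistic (active minus inactive) on per-cohort standardized
expression, and the compound score of sample *j* is
*s*ⱼ = Σ_g *w*_g *x*_gj. Scores in each class are modelled as Gaussians
with class means μ_A, μ_I and a single pooled SD σ (df = *n* − 2); with
equal priors the posterior is

  p_A(s) = φ(s; μ_A, σ) / [φ(s; μ_A, σ) + φ(s; μ_I, σ)]

computed in log space for stability. A tumor is called activated iff
p_A > 0.5 — strictly, so a posterior of exactly 0.5 is inactivated. With
equal priors and a shared σ this is equivalent to thresholding the score
at the class-mean midpoint (asserted as a property test).

- **Priors and variances.** Fixed 0.5/0.5 priors and the equal-variance
  Gaussian model match the classical compound covariate formulation; both
  are exposed as parameters.
- **Cross-platform application.** Expression is standardized within each
  cohort independently; no cross-cohort quantile mapping. When a test
  platform lacks some model genes (coverage checked against a floor,
  default 0.5), the remaining weights are kept and the score Gaussians are
  refit by re-scoring the stored training expression under the reduced
  gene set — compound scores scale with gene count, so the stored
  parameters would otherwise be on the wrong scale.
- **LOOCV.** Each fold refits the weights and score Gaussians on *n* − 1
  samples and predicts the held-out one; the gene list stays fixed because
  it is derived once on the full training cohort before classifier
  construction. Note the misclassification rate is measured against the
  copy-number classes, so cohorts with substantial copy-number-independent
  activation show a non-zero rate *by design*: those tumors carry the
  activated program but an "inactive" training label.
- **Multi-class extension.** K-class assignment (e.g. four expression
  subtypes) runs one-vs-rest: each class gets its own compound covariate
  axis and Gaussian pair, posteriors are computed independently per axis,
  and the label is the argmax with ties going to the earliest declared
  class.

## Survival analysis

Kaplan–Meier curves (simultaneous decrement at ties, Greenwood standard
errors) and the K-sample log-rank test come from lifelines, as do Cox
proportional-hazards fits with the Efron tie correction (the modern
default; differences from Breslow are negligible at these scales).
Five-year analyses administratively censor follow-up at 60 months.
Pooled multi-cohort models stratify the baseline hazard by cohort, since
cohorts differ in platform and follow-up; covariates are binary
indicators (male sex, age ≥ 60, oropharynx site, T4, node-positive,
stage III/IV, activated subtype). The radiation subgroup battery runs
log-rank tests for subtype within irradiated and non-irradiated patients
and for radiation within each subtype, plus a Cox model with subtype,
radiation and their product; the interaction hazard ratio is the ratio of
radiation effects between subtypes.

## Association battery

- **Fisher screens.** Copy-number events are tested per gene with the
  two-sided Fisher exact test (scipy backend; verified against full
  hypergeometric enumeration): amplification counts high-level events only
  (GISTIC ≥ 2), deletion counts all loss events (GISTIC ≤ −1). Mutation
  screens cross-tabulate mutated/wild-type per panel gene. The odds ratio
  is the cross-product ratio, reported as undefined (NaN) when its
  denominator is zero; a gene with no events at all gets *p* = 1.
- **Differential miRNA.** Pooled-variance t-test on log2 values (Welch
  optional); the fold change is 2^(mean difference) and the "fold change
  > 2" filter is two-sided (FC ≥ 2 or ≤ 0.5) because regulation runs in
  both directions.
- **CNI miRNA screen.** Activated tumors are partitioned by driver GISTIC
  into copy-number-dependent (≥ 2) and copy-number-independent (< 2).
  Stage 1 keeps miRNAs separating CNI from CND activation (fold ratio
  > 1.5 either way, *p* < 0.01); stage 2 keeps those also differing from
  normal tissue (*p* < 0.05); the final list keeps those whose CNI mean
  exceeds both the inactivated and the normal means. The three lists are
  nested by construction.
- **Cross-tabulations.** Two-level labels (e.g. HPV status) use Fisher;
  K > 2 levels use the chi-square test of independence.
- **IFNG composite score.** Mean of CXCL9, CXCL10, IDO1, IFNG, HLA-DRA
  and STAT1 on per-cohort standardized expression (the scale is not
  otherwise comparable across platforms), computed when at least five of
  the six genes are measured; compared between subtypes by t-test and
  correlated (Pearson) with the BCCP posterior.

## Synthetic cohort generator

One seed drives everything; per-layer substreams are spawned
deterministically so identical configs reproduce byte-identical cohorts.
The generative model:

- Driver GISTIC: amplified (score 2) with probability `amp_fraction`
  (default 0.086); otherwise drawn from a background over {−2…1}
  concentrated at 0 (75%) with a 20% single-copy gain.
- Latent activation: amplified ⇒ activated; non-amplified tumors are
  activated with probability `cni_fraction` (default 0.30, reconciling
  ~36% activated overall with ~9% amplified).
- Driver mRNA = dosage_effect·GISTIC + activation_shift·activation +
  Gaussian noise (defaults 1.0, 1.5, SD 0.5), giving a driver mRNA-vs-CN
  correlation near 0.74 by moment calculation.
- Program genes (default 200, alternating sign) load on the **binary
  activation state**, with the loading calibrated so each gene's marginal
  Pearson correlation with activation equals `program_corr` (default
  0.5): c = ρ·σ_noise / (σ_act·√(1 − ρ²)). Null genes are i.i.d.
  Gaussian.
- Survival is exponential with hazard λ₀·HR^activation (defaults
  0.015/month, HR 2.0) under independent exponential censoring
  (0.010/month) — closed-form Kaplan–Meier targets.
- HPV positivity: baseline probability 0.01 in activated tumors, odds
  multiplied by `hpv_odds` (default 26, the odds ratio implied by a
  1/105-vs-35/174 split) under inactivation.
- Mutations are Bernoulli with per-gene subtype-specific rates (defaults
  mirror reported head-and-neck rates, e.g. TP53 82.6% vs 64.4%);
  copy-number events for named genes likewise (e.g. EGFR amplification
  enriched under activation, PIK3CA under inactivation).
- The miRNA layer plants 12 fold changes ≥ 2 in magnitude (8 up, 4 down)
  between subtypes, plus two miRNAs elevated (1.5 log2 units) only in
  CNI-activated tumors, and carries normal-tissue columns.
- The six interferon-γ genes are depressed by `ifng_shift` (default 1.0)
  in activated tumors.

What the generator does **not** emulate: RNA-seq count distributions
(expression is Gaussian on the log scale), batch and platform effects,
gene–gene correlation beyond the shared activation factor, genomic
linkage between copy-number events, and informative censoring. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to real-data artifacts.

## Validation design

Two deliberately different study conditions isolate the two inferential
stages:

- **Screen recovery** runs on cohorts whose activation is entirely
  copy-number-driven (`cni_fraction = 0`, immune shift off, only the
  program planted): 500 tumors, a 200-gene program at ρ = 0.4 against
  5,000 null genes. This is the regime the dual screen assumes — under
  copy-number-independent activation the CN arm is structurally blind
  (corr(gene, GISTIC) ≈ ρ·corr(activation, GISTIC) ≈ 0.11 < 0.2 at the
  defaults), so testing the screen there would measure the biology of the
  simulation, not the code. Median sensitivity ≥ 0.90 and median FDR
  ≤ 0.05 over 20 seeds.
- **Classification recovery** runs on the default config (30% CNI
  activation) with the classifier fitted on the planted signature,
  measuring median agreement with the latent activation state over 100
  seeds (≥ 0.95; in practice ≈ 1.0 — with 200 genes at ρ = 0.5 the
  aggregate score separates the states by many noise SDs).

Further calibration checks: LOOCV is zero under 10σ class separation and
at chance level (binomial 99% envelope around 0.5, 50 seeds × 200
samples) under permuted labels — the permutation check uses 200 samples
because leave-one-out error of mean-difference classifiers is biased
above 0.5 at small *n*; Cox 95% intervals cover a planted hazard ratio of
2.0 in ≥ 90% of 200 replicates; log-rank type-I error at α = 0.05 sits in
the binomial 99% envelope over 1,000 null replicates; the product-limit
estimate of S(60) under censoring-free exponential survival lands within
3 Monte-Carlo SEs of e^(−60λ) at n = 2,000; and all screens show nominal
false-positive rates under fully null configurations.

## Numerical choices and degenerate inputs

- Standardization uses SD with denominator *n* − 1; constant genes map to
  all-zero rows (keeping matrix shapes stable) rather than being dropped;
  single-sample cohorts are rejected.
- Duplicate gene rows in input files are collapsed by averaging
  (symmetric, order-independent); gene symbols are matched by exact
  uppercase string equality, with no alias resolution (documented
  limitation).
- Missing expression values are rejected at read time; the correlation
  screen and the compound score assume complete rows.
- Sample IDs match exactly after an optional prefix truncation
  (barcode-style IDs need truncation to the patient level); the default is
  no truncation.
- Posterior computation clips the log-density difference at ±700 before
  exponentiation; correlation p-values use the t transform with the
  denominator floored at the smallest positive double.
- Fisher's two-sided p sums hypergeometric point probabilities not
  exceeding the observed one with a 1e-7 relative tie tolerance.

## Known limitations

- The screen's raw thresholds are kept for fidelity; at genome scale the
  expected number of null genes passing *p* < 0.001 in a *single* arm is
  non-trivial, and the |r| > 0.2 requirement is what keeps the
  intersection clean at n ≈ 500.
- The one-vs-rest multi-class mechanism is one explicit interpretation of
  compound covariate multi-class assignment; alternatives (single
  multinomial axis, pairwise coupling) are not implemented.
- LOOCV does not re-derive the gene list per fold, so its error estimate
  is optimistic with respect to selection bias in the screen.
- No proportional-hazards diagnostics, time-varying covariates or
  competing risks; no probe-level platform harmonization; no miRNA target
  prediction.
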