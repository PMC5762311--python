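# actsig — driver-activation gene signatures for tumor cohorts

Tumor drivers such as YAP1, the Hippo-pathway transcriptional effector,
are often activated by gene amplification — but not only: in head and
neck squamous cell carcinoma many tumors express a fully activated
downstream program without carrying the amplification. Classifying tumors
by the *program* rather than by copy number alone is what makes the
activation state clinically useful: activated tumors have worse survival,
are almost always HPV-negative, carry distinct copy-number and mutation
profiles, and show depressed interferon-γ immune activity.

`actsig` is a Python library (with a thin CLI) for exactly this analysis:

- **Dual correlation screen** — for every gene, Pearson correlation of its
  expression with the driver's thresholded GISTIC copy-number score and
  with the driver's mRNA; genes with *p* < 0.001 and |r| > 0.2 in *both*
  screens form the activation signature.
- **Bayesian compound covariate predictor (BCCP)** — per-gene weights
  w_g are two-sample t-statistics between copy-number-defined training
  classes (GISTIC ≥ 2 vs < 2); the compound score s_j = Σ_g w_g·x_gj is
  modelled with equal-variance class Gaussians, giving a posterior
  activation probability P(active | s); tumors with p > 0.5 are called
  activated (YA), the rest inactivated (YI). Includes leave-one-out
  cross-validation, cross-platform application with missing-gene refits,
  and a one-vs-rest multi-class extension.
- **Survival machinery** — Kaplan–Meier, log-rank, pooled uni-/multivariate
  Cox (Efron ties, cohort-stratified baseline), radiation subgroup
  analyses with an interaction test.
- **Association battery** — per-gene Fisher screens on copy-number events
  (amplification = GISTIC ≥ 2 only, deletion = all loss events) and
  mutations; differential miRNA filter (fold change ≥ 2, *p* < 0.001,
  two-sided); a staged screen for miRNAs specific to
  copy-number-independent activation; HPV/molecular-subtype
  cross-tabulations; the six-gene interferon-γ composite score.
- **Synthetic cohort generator** — multi-omics cohorts with planted
  ground truth (activation states, signature, hazard ratio, mutation
  rates, miRNA fold changes) for recovery testing.

See `docs/methods.md` for the full model description and the validation
design.

## Worked example

Each script in `examples/` exercises one capability. Classification
(`examples/03_classify_subtypes.py`) on a default synthetic cohort —
500 tumors, 8.6% driver-amplified, 30% of the rest activated without
amplification — prints:

```
training classes from copy number: 38 amplified, 462 non-amplified
leave-one-out misclassification vs copy-number classes: 0.260 (500 folds)
(non-zero by design: CNI-activated tumors score active despite their
non-amplified training label)

posterior stratification: 168 activated of 500 (33.6%)
agreement with latent activation truth: 1.000
  CND-YA : 100.0% called activated
  CNI-YA : 100.0% called activated
  YI     :   0.0% called activated
```

The classifier is trained only on amplification labels, yet it calls
every copy-number-independently activated tumor (CNI-YA) activated — the
expression program, not the copy number, drives the posterior. The 26%
"misclassification" against the copy-number labels is precisely those
tumors. Survival (`examples/04_survival_analysis.py`) on two pooled
cohorts with a planted hazard ratio of 2 prints:

```
YA: n=125, 5-year survival S(60) = 0.109 (+/- 0.038 Greenwood SE)
YI: n=625, 5-year survival S(60) = 0.414 (+/- 0.023 Greenwood SE)

log-rank: chi2 = 45.0, p = 1.99e-11 (activated tumors die faster)

pooled Cox models (baseline stratified by cohort):
  univariate    HR = 2.24 (1.76-2.86), p = 5.02e-11
  multivariate  HR = 2.19 (1.72-2.79), p = 2.99e-10
```

The 95% interval covers the planted hazard ratio.

## Command-line pipeline

```sh
actsig full --config config.yaml --outdir run/ --seed 1
```

Subcommands `simulate`, `derive-signature`, `fit`, `classify`,
`survival`, `associate`, `ifng` and `full` operate on a YAML config (see
`tests/test_cli.py` for a complete example); every run writes its
resolved config next to its outputs, and identical config + seed produces
byte-identical tables.

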