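"""Survival separation between activation subtypes.

Kaplan-Meier five-year survival, the log-rank test, and pooled
univariate/multivariate Cox models (cohort-stratified baseline) on two
synthetic cohorts with a planted hazard ratio of 2 for activated tumors.
"""

from actsig import SimulationConfig, simulate_multi_cohort
from actsig.pipeline import pooled_survival_frame, run_full
from actsig.survival import censor_at, km_estimate

cfgs = [SimulationConfig(seed=10, name="train", cni_fraction=0.1),
        SimulationConfig(seed=11, name="validation", n_tumors=250,
                         cni_fraction=0.1)]
cohorts = [b for b, _ in simulate_multi_cohort(cfgs)]
result = run_full(cohorts, "YAP1", run_loocv=False)

surv = result.survival_table  # already censored at 60 months
for grp in ("YA", "YI"):
    sub = surv[surv["group"] == grp]
    curve = km_estimate(sub["time"], sub["event"])
    print(f"{grp}: n={len(sub)}, 5-year survival "
          f"S(60) = {curve.survival_at(60):.3f} "
          f"(+/- {curve.se_at(60):.3f} Greenwood SE)")

chi2, p = result.logrank
print(f"\nlog-rank: chi2 = {chi2:.1f}, p = {p:.2e} "
      "(activated tumors die faster)")

print("\npooled Cox models (baseline stratified by cohort):")
for r in result.cox_results:
    if r.covariate == "activated":
        print(f"  {r.model_type:13s} HR = {r.hazard_ratio:.2f} "
              f"({r.ci_low:.2f}-{r.ci_high:.2f}), p = {r.p_value:.2e}")
print("the planted hazard ratio is 2.0; the multivariate model adjusts "
      "for sex, age, site and stage covariates.")
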