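"""Genomic and clinical associations of the activated subtype.

Per-gene copy-number and mutation Fisher screens, the differential miRNA
filter (fold change > 2, P < 0.001), the staged screen for miRNAs specific
to copy-number-independent activation, the HPV cross-tabulation, and the
interferon-gamma composite immune score.
"""

from actsig import SimulationConfig, simulate_cohort, standardize_genes
from actsig.associations import (
    cni_mirna_screen,
    compare_mutations,
    crosstab_subtype,
    differential_mirna,
    ifng_association,
    ifng_score,
)
from actsig.bccp import ClassProbability

bundle, truth = simulate_cohort(SimulationConfig(seed=4))
# classify from the planted truth to isolate the screens themselves
calls = [ClassProbability(s, 0.0, 0.95 if a else 0.05, "YA" if a else "YI")
         for s, a in truth.true_activation.items()]

print("mutation screen (activated vs inactivated rates, Fisher p):")
for r in compare_mutations(bundle, calls, ["TP53", "CDKN2A", "NFE2L2"]):
    print(f"  {r.feature_id:7s} {100 * r.rate_a:5.1f}% vs "
          f"{100 * r.rate_b:5.1f}%  p = {r.p_value:.2e}")

de = [r for r in differential_mirna(bundle, calls) if r.passes]
print(f"\nmiRNAs passing the FC>2 / P<0.001 filter: {len(de)}")
print("  " + ", ".join(r.feature_id for r in de))

cni = cni_mirna_screen(bundle, calls, "YAP1")
print(f"\nCNI miRNA screen: stage 1 n={len(cni.stage1)}, "
      f"stage 2 n={len(cni.stage2)}, final = {cni.final}")
print("the final list contains miRNAs elevated only in tumors activated "
      "without driver amplification — candidate activating miRNAs.")

hpv = bundle.clinical.table["hpv_status"]
ct = crosstab_subtype(calls, hpv[hpv.isin(["positive", "negative"])])
print(f"\nHPV-positive tumors by subtype "
      f"(p = {ct.p_value:.2e}, {ct.method}):")
print(ct.counts.to_string())

scores = ifng_score(standardize_genes(bundle.expression))
res = ifng_association(scores, calls)
print(f"\ninterferon-gamma composite score: activated mean "
      f"{res.mean_activated:.2f} vs inactivated {res.mean_inactivated:.2f} "
      f"(t-test p = {res.t_p_value:.2e})")
print(f"correlation of score with activation posterior: "
      f"r = {res.pearson_r:.3f} — activated tumors show depressed immune "
      "activity.")
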