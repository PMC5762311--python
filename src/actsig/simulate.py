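"""Synthetic multi-omics tumor cohort generator with planted ground truth.

The generator emulates the statistical structure the activation-signature
pipeline assumes in real cohorts:

* a driver gene whose thresholded copy number (GISTIC) and mRNA correlate
  through a dosage effect;
* a latent binary activation state — every amplified tumor is activated,
  and a configurable fraction of non-amplified tumors is activated through
  a copy-number-independent mechanism (CNI);
* a planted downstream transcriptional program whose genes correlate with
  the activation state at a target marginal Pearson correlation;
* exponential survival with a subtype hazard ratio and independent
  exponential censoring (closed-form Kaplan-Meier targets);
* HPV positivity anti-associated with activation via an odds multiplier;
* per-gene mutation rates that differ by subtype;
* a miRNA layer with planted activated-vs-inactivated fold changes plus a
  pair of miRNAs elevated only in CNI-activated tumors (the planted
  miRNA-mediated activation mechanism), and normal-tissue columns;
* six interferon-gamma response genes depressed in activated tumors.

All randomness flows from one seed; per-layer substreams are derived
deterministically so layers are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ClinicalTable,
    CohortBundle,
    CopyNumberMatrix,
    GeneExpressionMatrix,
    GeneSet,
    MiRNAMatrix,
    MutationMatrix,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "simulate_multi_cohort"]

IFNG_GENES = ("CXCL9", "CXCL10", "IDO1", "IFNG", "HLA-DRA", "STAT1")

# Per-gene (rate_active, rate_inactive) non-silent mutation probabilities.
# Defaults mirror reported subtype-specific rates in head-and-neck tumors.
DEFAULT_MUTATION_RATES: dict[str, tuple[float, float]] = {
    "TP53": (0.826, 0.644),
    "CDKN2A": (0.283, 0.191),
    "NFE2L2": (0.011, 0.078),
    "PTEN": (0.005, 0.042),
    "SYNE1": (0.141, 0.223),
    "NSD1": (0.082, 0.149),
    "AJUBA": (0.071, 0.058),
}

# Per-gene planted copy-number event rates by subtype:
# gene -> (p_amp_active, p_amp_inactive, p_del_active, p_del_inactive)
DEFAULT_CN_GENE_RATES: dict[str, tuple[float, float, float, float]] = {
    "EGFR": (0.30, 0.05, 0.0, 0.0),
    "SNAI2": (0.20, 0.05, 0.0, 0.0),
    "CDKN2A": (0.0, 0.0, 0.50, 0.20),
    "NOTCH1": (0.0, 0.0, 0.30, 0.12),
    "PIK3CA": (0.05, 0.30, 0.0, 0.0),
    "SOX2": (0.05, 0.25, 0.0, 0.0),
    "TP63": (0.05, 0.25, 0.0, 0.0),
}

# Planted fold changes (linear scale, activated vs inactivated) for the
# differential miRNA screen: 12 miRNAs, both directions.
DEFAULT_MIRNA_FC: dict[str, float] = {
    "MIR-1-2": 3.0, "MIR-133A": 2.8, "MIR-133B": 2.6, "MIR-206": 3.5,
    "MIR-101": 2.3, "MIR-378": 2.2, "MIR-145": 2.4, "MIR-100": 2.1,
    "MIR-21": 0.40, "MIR-155": 0.35, "MIR-142": 0.30, "MIR-203": 0.45,
}

# miRNAs elevated only in CNI-activated tumors (the planted
# copy-number-independent activation mechanism), with their log2 shift.
DEFAULT_CNI_MIRNA: dict[str, float] = {"MIR-187": 1.5, "MIR-675": 1.5}

_GISTIC_BACKGROUND = {-2: 0.01, -1: 0.09, 0: 0.80, 1: 0.09, 2: 0.01}
_DRIVER_NONAMP = {-2: 0.005, -1: 0.045, 0: 0.75, 1: 0.20}  # given not amplified


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Defaults describe a strong-effect head-and-neck-like cohort of 500
    tumors: 8.6% driver amplification, 30% copy-number-independent
    activation among non-amplified tumors, a 200-gene downstream program
    at marginal correlation 0.5, a subtype hazard ratio of 2, and an HPV
    odds multiplier of 26 favouring the inactivated subtype.
    """

    seed: int
    n_tumors: int = 500
    n_normals: int = 40
    n_genes: int = 2000
    n_signature_genes: int = 200
    driver_name: str = "YAP1"
    amp_fraction: float = 0.086
    cni_fraction: float = 0.30
    dosage_effect: float = 1.0          # expression units per GISTIC level
    activation_shift: float = 1.5       # driver mRNA shift under activation
    program_corr: float = 0.5           # target marginal Pearson r with activation
    noise_sd: float = 0.5               # log2-scale residual SD
    hazard_ratio: float = 2.0           # activated vs inactivated
    baseline_hazard: float = 0.015      # events / month for inactivated
    censor_rate: float = 0.010          # exponential censoring rate / month
    radiation_prob: float = 0.5
    radiation_hr_active: float = 1.0    # hazard multiplier of radiation, activated
    radiation_hr_inactive: float = 1.0  # and inactivated
    hpv_base_prob: float = 0.01         # P(HPV+) in activated tumors
    hpv_odds: float = 26.0              # odds multiplier for HPV+ under inactivation
    mutation_rates: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MUTATION_RATES))
    cn_gene_rates: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CN_GENE_RATES))
    n_mirna: int = 150
    mirna_fc: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIRNA_FC))
    cni_mirna: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CNI_MIRNA))
    ifng_shift: float = 1.0             # mean depression of IFNG genes when activated
    missing_gene_fraction: float = 0.0  # signature genes absent from this platform
    name: str = "synthetic"

    def __post_init__(self) -> None:
        for f in ("amp_fraction", "cni_fraction", "censor_rate", "radiation_prob",
                  "hpv_base_prob", "missing_gene_fraction"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0.0 <= self.program_corr < 1.0:
            raise ValueError("program_corr must be in [0, 1)")
        n_special = 1 + len(IFNG_GENES) + self.n_signature_genes
        if n_special >= self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for driver + "
                f"{len(IFNG_GENES)} immune genes + "
                f"{self.n_signature_genes} signature genes"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Planted simulation truth for recovery tests."""

    true_activation: pd.Series            # 0/1 per tumor
    true_signature: GeneSet               # planted downstream program
    cni_labels: pd.Series                 # CND-YA / CNI-YA / YI per tumor
    hazard_ratio: float
    config: SimulationConfig

    def __post_init__(self) -> None:
        lab, act = self.cni_labels, self.true_activation
        if not ((lab.isin(["CND-YA", "CNI-YA"]) == (act == 1)).all()):
            raise ValueError("cni_labels inconsistent with true_activation")


def _categorical(rng: np.random.Generator, probs: dict[int, float], size) -> np.ndarray:
    levels = np.array(list(probs), dtype=int)
    p = np.array(list(probs.values()), dtype=float)
    p = p / p.sum()
    return rng.choice(levels, size=size, p=p)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_cohort(cfg: SimulationConfig) -> tuple[CohortBundle, GroundTruth]:
    """Draw one cohort and its ground truth.

    The expression matrix contains the driver row, the six
    interferon-gamma genes, ``n_signature_genes`` planted program genes
    (``SIG0001``...) and i.i.d. noise genes (``G0001``...) filling out
    ``n_genes`` rows.  See the module docstring for the layer models.
    """
    (rng_cn, rng_act, rng_expr, rng_surv, rng_clin,
     rng_mut, rng_mirna, rng_panel) = _substreams(cfg.seed, 8)

    n = cfg.n_tumors
    samples = [f"{cfg.name}-T{i + 1:04d}" for i in range(n)]

    # --- driver copy number and latent activation -------------------------
    amplified = rng_cn.random(n) < cfg.amp_fraction
    driver_gistic = np.where(
        amplified, 2, _categorical(rng_cn, _DRIVER_NONAMP, n)
    ).astype(int)
    activation = np.where(
        amplified, 1, (rng_act.random(n) < cfg.cni_fraction).astype(int)
    ).astype(int)
    cni_labels = np.select(
        [amplified & (activation == 1), ~amplified & (activation == 1)],
        ["CND-YA", "CNI-YA"], default="YI",
    )

    # --- expression -------------------------------------------------------
    sig_genes = [f"SIG{i + 1:04d}" for i in range(cfg.n_signature_genes)]
    n_null = cfg.n_genes - 1 - len(IFNG_GENES) - cfg.n_signature_genes
    null_genes = [f"G{i + 1:04d}" for i in range(n_null)]
    gene_order = [cfg.driver_name, *IFNG_GENES, *sig_genes, *null_genes]

    a = activation.astype(float)
    p_act = cfg.amp_fraction + (1 - cfg.amp_fraction) * cfg.cni_fraction
    sd_a = np.sqrt(p_act * (1 - p_act))
    # loading c such that corr(c*a + noise, a) == program_corr marginally
    rho = cfg.program_corr
    loading = rho * cfg.noise_sd / (sd_a * np.sqrt(1.0 - rho ** 2)) if rho > 0 else 0.0

    base_means = rng_expr.normal(8.0, 1.0, size=cfg.n_genes)
    x = np.empty((cfg.n_genes, n))
    x[0] = (base_means[0] + cfg.dosage_effect * driver_gistic
            + cfg.activation_shift * a + rng_expr.normal(0, cfg.noise_sd, n))
    for k in range(len(IFNG_GENES)):
        x[1 + k] = (base_means[1 + k] - cfg.ifng_shift * a
                    + rng_expr.normal(0, cfg.noise_sd, n))
    # program genes: half positively, half negatively correlated
    signs = np.where(np.arange(cfg.n_signature_genes) % 2 == 0, 1.0, -1.0)
    off = 1 + len(IFNG_GENES)
    for k in range(cfg.n_signature_genes):
        x[off + k] = (base_means[off + k] + signs[k] * loading * a
                      + rng_expr.normal(0, cfg.noise_sd, n))
    off += cfg.n_signature_genes
    x[off:] = (base_means[off:, None]
               + rng_expr.normal(0, cfg.noise_sd, (n_null, n)))

    expr_df = pd.DataFrame(x, index=gene_order, columns=samples)
    if cfg.missing_gene_fraction > 0:
        n_drop = int(round(cfg.missing_gene_fraction * cfg.n_signature_genes))
        drop = rng_panel.choice(sig_genes, size=n_drop, replace=False)
        expr_df = expr_df.drop(index=list(drop))
    expression = GeneExpressionMatrix(expr_df, standardized=False)

    # --- copy number ------------------------------------------------------
    cn_extra = [g for g in cfg.cn_gene_rates if g not in set(gene_order)]
    cn_genes = gene_order + cn_extra
    cn = _categorical(rng_cn, _GISTIC_BACKGROUND, (len(cn_genes), n))
    cn[0] = driver_gistic
    act_mask = activation == 1
    for gene, (amp_a, amp_i, del_a, del_i) in cfg.cn_gene_rates.items():
        row = cn_genes.index(gene)
        p_amp = np.where(act_mask, amp_a, amp_i)
        p_del = np.where(act_mask, del_a, del_i)
        u = rng_cn.random(n)
        vals = _categorical(rng_cn, _GISTIC_BACKGROUND, n)
        vals = np.where(u < p_amp, 2, vals)
        # deletions drawn as a mix of hemizygous and deep loss
        deep = rng_cn.random(n) < 0.3
        vals = np.where((u >= p_amp) & (u < p_amp + p_del),
                        np.where(deep, -2, -1), vals)
        cn[row] = vals
    cn_layer = CopyNumberMatrix(pd.DataFrame(cn, index=cn_genes, columns=samples))

    # --- mutations --------------------------------------------------------
    mut_genes = list(cfg.mutation_rates)
    mut = np.zeros((len(mut_genes), n), dtype=int)
    for j, gene in enumerate(mut_genes):
        r_a, r_i = cfg.mutation_rates[gene]
        p = np.where(act_mask, r_a, r_i)
        mut[j] = (rng_mut.random(n) < p).astype(int)
    mutations = MutationMatrix(pd.DataFrame(mut, index=mut_genes, columns=samples))

    # --- survival and clinical -------------------------------------------
    rad = rng_clin.random(n) < cfg.radiation_prob
    rad_hr = np.where(act_mask, cfg.radiation_hr_active, cfg.radiation_hr_inactive)
    hazard = cfg.baseline_hazard * cfg.hazard_ratio ** a * np.where(rad, rad_hr, 1.0)
    event_time = rng_surv.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        censor_time = rng_surv.exponential(1.0 / cfg.censor_rate, n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    base_odds = cfg.hpv_base_prob / (1 - cfg.hpv_base_prob)
    odds = np.where(act_mask, base_odds, base_odds * cfg.hpv_odds)
    p_hpv = odds / (1 + odds)
    hpv = np.where(rng_clin.random(n) < p_hpv, "positive", "negative")

    sites = rng_clin.choice(
        ["oral_cavity", "oropharynx", "larynx", "hypopharynx"],
        size=n, p=[0.60, 0.16, 0.22, 0.02])
    t_stage = rng_clin.choice(["T1", "T2", "T3", "T4"], size=n,
                              p=[0.07, 0.30, 0.27, 0.36])
    n_stage = rng_clin.choice(["N0", "N1", "N2", "N3"], size=n,
                              p=[0.50, 0.16, 0.32, 0.02])
    stage = rng_clin.choice(["I", "II", "III", "IV"], size=n,
                            p=[0.04, 0.20, 0.21, 0.55])
    clinical = ClinicalTable(pd.DataFrame({
        "os_time": os_time,
        "os_event": os_event,
        "dfs_time": os_time,
        "dfs_event": os_event,
        "hpv_status": hpv,
        "sex": rng_clin.choice(["male", "female"], size=n, p=[0.74, 0.26]),
        "age": np.round(rng_clin.normal(61.0, 12.0, n), 1),
        "anatomic_site": sites,
        "t_stage": t_stage,
        "n_stage": n_stage,
        "overall_stage": stage,
        "radiation": np.where(rad, "yes", "no"),
        "cohort_name": cfg.name,
    }, index=samples))

    # --- miRNA ------------------------------------------------------------
    planted = list(cfg.mirna_fc) + [m for m in cfg.cni_mirna if m not in cfg.mirna_fc]
    n_fill = max(cfg.n_mirna - len(planted), 0)
    mirna_ids = planted + [f"MIR-N{i + 1:03d}" for i in range(n_fill)]
    normals = [f"{cfg.name}-N{i + 1:03d}" for i in range(cfg.n_normals)]
    cols = samples + normals
    mir_base = rng_mirna.normal(6.0, 1.0, size=len(mirna_ids))
    m = (mir_base[:, None]
         + rng_mirna.normal(0, cfg.noise_sd, (len(mirna_ids), len(cols))))
    for i, mid in enumerate(mirna_ids):
        if mid in cfg.mirna_fc:
            m[i, :n] += np.log2(cfg.mirna_fc[mid]) * a
        if mid in cfg.cni_mirna:
            m[i, :n] += cfg.cni_mirna[mid] * (cni_labels == "CNI-YA")
    mirna = MiRNAMatrix(
        pd.DataFrame(m, index=mirna_ids, columns=cols),
        pd.Series(["tumor"] * n + ["normal"] * cfg.n_normals, index=cols),
    )

    bundle = CohortBundle(
        name=cfg.name, expression=expression, clinical=clinical,
        cn=cn_layer, mutations=mutations, mirna=mirna,
    )
    truth = GroundTruth(
        true_activation=pd.Series(activation, index=samples, name="true_activation"),
        true_signature=GeneSet("planted_program", tuple(sig_genes)),
        cni_labels=pd.Series(cni_labels, index=samples, name="cni_label"),
        hazard_ratio=cfg.hazard_ratio,
        config=cfg,
    )
    return bundle, truth


def simulate_multi_cohort(
    cfgs: Sequence[SimulationConfig],
) -> list[tuple[CohortBundle, GroundTruth]]:
    """Draw independent cohorts (training + test sets).

    Cohort names must be distinct; gene panels may differ across configs
    (via ``missing_gene_fraction``) to exercise signature-coverage
    handling downstream.
    """
    if len(cfgs) < 2:
        raise ValueError("simulate_multi_cohort needs at least 2 configs")
    names = [c.name for c in cfgs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate cohort names: {names}")
    return [simulate_cohort(c) for c in cfgs]
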