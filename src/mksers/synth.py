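"""Synthetic multi-omic cohort generator.

Emulates the joint structure the stratification pipeline assumes: two
correlated latent axes (proliferation m, ER signalling e) drive the MKS and
ERS member genes and the biomarker panel (immune signatures wired negatively
to e); subgroup membership — the sign pattern of (m, e) — drives pathological
response, post-endocrine Ki67, distant-event hazards, driver-gene mutation
frequencies and tumour mutational burden. Default outcome parameters are the
subgroup rates the pipeline is expected to recover (pathR 22% vs 8%; pCR
20.9/41.7/9.8/12.5% by ERS stratum and arm; TP53 34/16/12/6%; PIK3CA 52 vs
32-33%; TMB medians 43 vs 27 mutations; 4-year distant event-free survival
70% vs 94%).

Two deterministic fixtures reconstruct printed trial tables: the two-arm
pCR contingency tables (ERS strata) and the post-AI Ki67 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import FOUR_GROUP_LABELS
from .matrix import ExpressionMatrix
from .signatures import load_default_panel, load_mks_ers
from .stats import ContingencyTable2x2

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "make_ispy2_fixture",
    "make_poetic_fixture",
]

HI_LO, HI_HI, LO_LO, LO_HI = "MKShi_ERSlo", "MKShi_ERShi", "MKSlo_ERSlo", "MKSlo_ERShi"


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _default_pcr_logit() -> dict[tuple[str, str], float]:
    # chemo-alone and chemo+pembrolizumab pCR rates by ERS stratum; MKSlo
    # tumours respond rarely to chemotherapy
    return {
        (HI_LO, "chemo"): _logit(0.209), (HI_LO, "chemo_pembro"): _logit(0.417),
        (HI_HI, "chemo"): _logit(0.098), (HI_HI, "chemo_pembro"): _logit(0.125),
        (LO_LO, "chemo"): _logit(0.05), (LO_LO, "chemo_pembro"): _logit(0.06),
        (LO_HI, "chemo"): _logit(0.05), (LO_HI, "chemo_pembro"): _logit(0.06),
    }


def _default_pathr_prob() -> dict[str, float]:
    return {HI_LO: 0.22, HI_HI: 0.08, LO_LO: 0.08, LO_HI: 0.08}


def _default_hazard() -> dict[str, float]:
    # events/year chosen so exponential 4-year distant-event-free survival is
    # 70% (MKShi/ERSlo), 94% (MKShi/ERShi) and ~95% in MKSlo tumours
    return {
        HI_LO: -math.log(0.70) / 4.0,
        HI_HI: -math.log(0.94) / 4.0,
        LO_LO: -math.log(0.95) / 4.0,
        LO_HI: -math.log(0.95) / 4.0,
    }


def _default_mut_freq() -> dict[tuple[str, str], float]:
    return {
        ("TP53", HI_LO): 0.34, ("TP53", HI_HI): 0.16,
        ("TP53", LO_LO): 0.12, ("TP53", LO_HI): 0.06,
        ("PIK3CA", HI_LO): 0.33, ("PIK3CA", HI_HI): 0.32,
        ("PIK3CA", LO_LO): 0.33, ("PIK3CA", LO_HI): 0.52,
        ("CDH1", HI_LO): 0.05, ("CDH1", HI_HI): 0.10,
        ("CDH1", LO_LO): 0.15, ("CDH1", LO_HI): 0.28,
        ("MAP3K1", HI_LO): 0.03, ("MAP3K1", HI_HI): 0.07,
        ("MAP3K1", LO_LO): 0.08, ("MAP3K1", LO_HI): 0.14,
        ("PTEN", HI_LO): 0.10, ("PTEN", HI_HI): 0.04,
        ("PTEN", LO_LO): 0.04, ("PTEN", LO_HI): 0.04,
        ("TTN", HI_LO): 0.18, ("TTN", HI_HI): 0.14,
        ("TTN", LO_LO): 0.12, ("TTN", LO_HI): 0.10,
        ("MUC16", HI_LO): 0.12, ("MUC16", HI_HI): 0.09,
        ("MUC16", LO_LO): 0.08, ("MUC16", LO_HI): 0.07,
    }


def _default_tmb_median() -> dict[str, float]:
    # whole-exome coding mutation counts (medians of the real subgroups)
    return {HI_LO: 43.0, HI_HI: 27.0, LO_LO: 25.0, LO_HI: 22.0}


def _nb_mean_for_median(target: float, size: float) -> float:
    """Negative-binomial mean whose distribution median equals `target`.

    The NB is right-skewed (median < mean), so planting a published median
    requires inverting median(NB(size, mean)) = target; bisection on the mean.
    """
    from scipy.stats import nbinom

    lo, hi = target * 0.5, target * 2.0 + 5.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if nbinom.ppf(0.5, size, size / (size + mid)) < target:
            lo = mid
        else:
            hi = mid
    return hi


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort; defaults define the study conditions."""

    n_samples: int = 400
    n_noise_genes: int = 100
    latent_corr: float = -0.3  # proliferation vs ER signalling
    loading_mean: float = 1.0
    loading_sd: float = 0.1
    noise_sd: float = 0.5
    baseline_mean: float = 7.0  # log2 units
    baseline_sd: float = 1.0
    arms: dict[str, float] = field(default_factory=lambda: {"chemo": 1.0})
    pcr_logit: dict[tuple[str, str], float] = field(default_factory=_default_pcr_logit)
    pathr_prob: dict[str, float] = field(default_factory=_default_pathr_prob)
    hazard: dict[str, float] = field(default_factory=_default_hazard)
    censor_rate: float = 0.05  # events/year, independent exponential
    admin_horizon_years: float = 5.0
    mut_freq: dict[tuple[str, str], float] = field(default_factory=_default_mut_freq)
    tmb_median: dict[str, float] = field(default_factory=_default_tmb_median)
    tmb_dispersion: float = 8.0  # negative-binomial size parameter
    ki67_intercept: float = 3.6
    ki67_slope: float = 8.0  # on the proliferation latent
    ki67_ers_suppression: float = -6.0  # additional suppression when ERS-high
    ki67_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not -1.0 < self.latent_corr < 1.0:
            raise ValueError("latent_corr must be in (-1, 1)")
        for k, lam in self.hazard.items():
            if k not in FOUR_GROUP_LABELS or lam <= 0:
                raise ValueError(f"bad hazard entry {k!r}: {lam}")
        for (g, sg), p in self.mut_freq.items():
            if sg not in FOUR_GROUP_LABELS or not 0.0 <= p <= 1.0:
                raise ValueError(f"bad mut_freq entry {(g, sg)!r}")
        for (sg, arm), _ in self.pcr_logit.items():
            if sg not in FOUR_GROUP_LABELS or arm not in self.arms and arm not in {
                "chemo", "chemo_pembro"}:
                raise ValueError(f"bad pcr_logit key {(sg, arm)!r}")
        if abs(sum(self.arms.values()) - 1.0) > 1e-9:
            raise ValueError("arm probabilities must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside outputs; never consumed by the pipeline."""

    m: np.ndarray
    e: np.ndarray
    subgroup: np.ndarray
    config: CohortConfig


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    truth: SyntheticTruth


# gene -> (latent, loading sign/scale): how the panel is wired to the latents
_PANEL_WIRING = {
    "RBsig": ("m", 1.0),
    "IRPS": ("m", 0.5),
    "CCNE1": ("m", 1.0),
    "TILs_metagene": ("e", -0.8),
    "Tcell_inflamed_GEP": ("e", -0.8),
}

_CODING_CLASS_PROBS = {
    "Missense_Mutation": 0.60, "Silent": 0.20, "Nonsense_Mutation": 0.08,
    "Frame_Shift_Del": 0.06, "Splice_Site": 0.04, "In_Frame_Ins": 0.02,
}


def simulate_cohort(cfg: CohortConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort (expression, clinical, mutations, truth)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]

    cov = np.array([[1.0, cfg.latent_corr], [cfg.latent_corr, 1.0]])
    latents = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    m, e = latents[:, 0], latents[:, 1]
    subgroup = np.where(
        m > 0,
        np.where(e > 0, HI_HI, HI_LO),
        np.where(e > 0, LO_HI, LO_LO),
    )

    expression = _simulate_expression(cfg, rng, m, e, sample_ids)
    clinical = _simulate_clinical(cfg, rng, m, e, subgroup, sample_ids)
    mutations = _simulate_mutations(cfg, rng, subgroup, sample_ids)
    truth = SyntheticTruth(m=m, e=e, subgroup=subgroup, config=cfg)
    return SimulatedCohort(expression, clinical, mutations, truth)


def _simulate_expression(cfg, rng, m, e, sample_ids) -> ExpressionMatrix:
    sigs = load_mks_ers()
    panel = load_default_panel()
    rows, names = [], []

    def gene_row(latent_vec, scale):
        loading = scale * rng.normal(cfg.loading_mean, cfg.loading_sd)
        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
        return baseline + loading * latent_vec + rng.normal(0.0, cfg.noise_sd, size=len(latent_vec))

    for member in sigs["MKS"].members:
        names.append(member.symbol)
        rows.append(gene_row(m, 1.0))
    for member in sigs["ERS"].members:
        names.append(member.symbol)
        rows.append(gene_row(e, 1.0))
    seen = set(names)
    for sig in panel:
        latent_name, scale = _PANEL_WIRING[sig.name]
        latent_vec = m if latent_name == "m" else e
        for member in sig.members:
            if member.symbol in seen:
                continue
            seen.add(member.symbol)
            names.append(member.symbol)
            rows.append(gene_row(latent_vec, scale))
    for i in range(cfg.n_noise_genes):
        names.append(f"NOISE{i:04d}")
        rows.append(rng.normal(cfg.baseline_mean, cfg.baseline_sd)
                    + rng.normal(0.0, 1.0, size=len(m)))
    values = pd.DataFrame(np.vstack(rows), index=names, columns=sample_ids)
    return ExpressionMatrix(values, platform="synthetic_log2")


def _simulate_clinical(cfg, rng, m, e, subgroup, sample_ids) -> pd.DataFrame:
    n = len(sample_ids)
    arm_names = list(cfg.arms)
    arm = rng.choice(arm_names, size=n, p=[cfg.arms[a] for a in arm_names])

    # RCB class: pCR prob from the (subgroup, arm) logit; RCB I tops pathR up
    # to the configured subgroup pathR probability; the rest is RCB II/III
    rcb = np.empty(n, dtype=object)
    u = rng.random(n)
    v = rng.random(n)
    for i in range(n):
        p_pcr = 1.0 / (1.0 + math.exp(-cfg.pcr_logit.get((subgroup[i], arm[i]),
                                                         _logit(0.05))))
        p_rcb1 = max(cfg.pathr_prob.get(subgroup[i], 0.08) - p_pcr, 0.0)
        if u[i] < p_pcr:
            rcb[i] = "0"
        elif u[i] < p_pcr + p_rcb1:
            rcb[i] = "I"
        else:
            rcb[i] = "II" if v[i] < 0.7 else "III"

    lam = np.array([cfg.hazard[s] for s in subgroup])
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.exponential(1.0 / cfg.censor_rate, size=n)
    t_obs = np.minimum.reduce([t_event, t_censor, np.full(n, cfg.admin_horizon_years)])
    event = t_event <= np.minimum(t_censor, cfg.admin_horizon_years)

    ki67 = (cfg.ki67_intercept + cfg.ki67_slope * m
            + np.where(e > 0, cfg.ki67_ers_suppression, 0.0)
            + rng.normal(0.0, cfg.ki67_noise_sd, size=n))
    ki67 = np.clip(ki67, 0.0, 100.0)

    esr1 = 3.0 + e + rng.normal(0.0, 0.3, size=n)
    erbb2 = rng.normal(5.0, 0.5, size=n)

    return pd.DataFrame({
        "sample_id": sample_ids,
        "rcb_class": rcb,
        "ki67_post_pct": np.round(ki67, 2),
        "time_years": np.round(t_obs, 6),
        "event": event,
        "arm": arm,
        "er_ihc": "pos",
        "her2_ihc": "neg",
        "esr1_log2fpkm": np.round(esr1, 4),
        "erbb2_log2fpkm": np.round(erbb2, 4),
    })


def _simulate_mutations(cfg, rng, subgroup, sample_ids) -> pd.DataFrame:
    driver_genes = sorted({g for g, _ in cfg.mut_freq})
    classes = list(_CODING_CLASS_PROBS)
    class_p = np.array(list(_CODING_CLASS_PROBS.values()))
    nb_mean = {sg: _nb_mean_for_median(med, cfg.tmb_dispersion)
               for sg, med in cfg.tmb_median.items()}
    records = []
    for sid, sg in zip(sample_ids, subgroup):
        mean = nb_mean[sg]
        size = cfg.tmb_dispersion
        tmb = int(rng.negative_binomial(size, size / (size + mean)))
        hits = [g for g in driver_genes if rng.random() < cfg.mut_freq.get((g, sg), 0.0)]
        n_passenger = max(tmb - len(hits), 0)
        passengers = [f"PSG{j:05d}" for j in rng.integers(0, 20000, size=n_passenger)]
        for gene in hits + passengers:
            records.append((sid, gene, rng.choice(classes, p=class_p)))
        # a few non-coding records that TMB must ignore
        for _ in range(rng.poisson(2.0)):
            records.append((sid, f"PSG{rng.integers(0, 20000):05d}",
                            rng.choice(["Intron", "3'UTR", "5'Flank"])))
    return pd.DataFrame(records, columns=["sample_id", "gene", "variant_classification"])


# ---------------------------------------------------------------------------
# Deterministic fixtures reconstructed from printed trial tables


def _assert_rate(count: int, n: int, printed_pct: float) -> None:
    # reconstruction must reproduce the printed rate to one decimal
    assert round(100.0 * count / n, 1) == printed_pct, (count, n, printed_pct)


def make_ispy2_fixture() -> tuple[ContingencyTable2x2, ContingencyTable2x2, pd.DataFrame]:
    """Two-arm neoadjuvant pCR fixture by ERS stratum (134 patients).

    Counts are reconstructed by rounding printed rate x printed arm size:
    ERS-low 9/43 (chemo, 20.9%) vs 10/24 (chemo+pembrolizumab, 41.7%);
    ERS-high 5/51 (9.8%) vs 2/16 (12.5%). Returns (ERS-low table, ERS-high
    table, per-patient clinical frame).
    """
    _assert_rate(9, 43, 20.9)
    _assert_rate(10, 24, 41.7)
    _assert_rate(5, 51, 9.8)
    _assert_rate(2, 16, 12.5)
    lo = ContingencyTable2x2(a=10, b=14, c=9, d=34)
    hi = ContingencyTable2x2(a=2, b=14, c=5, d=46)
    rows = []
    idx = 0
    for ers, arm, n, n_pcr in [
        ("ERSlo", "chemo_pembro", 24, 10), ("ERSlo", "chemo", 43, 9),
        ("ERShi", "chemo_pembro", 16, 2), ("ERShi", "chemo", 51, 5),
    ]:
        for j in range(n):
            rows.append({
                "sample_id": f"ISPY2_{idx:03d}",
                "ers_stratum": ers,
                "arm": arm,
                "rcb_class": "0" if j < n_pcr else "II",
            })
            idx += 1
    return lo, hi, pd.DataFrame(rows)


def make_poetic_fixture() -> pd.DataFrame:
    """Post-AI Ki67 fixture: 42 MKShi/ERSlo (21 with Ki67 > 10%) and 41
    MKShi/ERShi tumours (10 with Ki67 > 10%); deterministic values."""
    _assert_rate(21, 42, 50.0)
    _assert_rate(10, 41, 24.4)
    rows = []

    def block(subgroup, n, n_high, prefix):
        for j in range(n):
            if j < n_high:
                ki67 = 12.0 + 2.0 * j  # strictly above 10%
            else:
                ki67 = 1.0 + (8.0 * (j - n_high)) / max(n - n_high - 1, 1)  # in [1, 9]
            rows.append({"sample_id": f"{prefix}{j:03d}", "subgroup": subgroup,
                         "ki67_post_pct": round(ki67, 2)})

    block(HI_LO, 42, 21, "POETIC_LO_")
    block(HI_HI, 41, 10, "POETIC_HI_")
    df = pd.DataFrame(rows)
    assert df["ki67_post_pct"].between(0, 100).all()
    return df
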