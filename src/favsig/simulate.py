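"""Synthetic cohorts and cell-line panels with known planted structure.

Every downstream stage of the pipeline (survival screen, confounder filter,
favorability scoring, stratification, IC-50 screen, phenotype correlates) is
exercised against data generated here, where the ground truth is recorded in
a :class:`SimTruth` object:

* :func:`simulate_tumor_cohort` — per-gene log-scale Gaussian expression;
  survival times from an exponential (optionally Weibull) proportional-
  hazards model whose per-sample log-hazard is ``effect_log_hazard`` times
  the standardized combined score (sum of unfavorable-gene minus sum of
  favorable-gene latent expression; for independent genes this equals the
  raw difference divided by sqrt(n_planted)), with independent exponential
  right-censoring. Planted genes of each direction share a latent
  "program" factor (loading ``sqrt(program_r2)``), so the signature
  behaves like a co-regulated expression program whose member genes are
  individually visible to a univariate screen; the program means are
  separated by ``subgroup_separation`` SD between two planted sample
  classes (favorable- vs unfavorable-signature), the discrete subgroup
  structure the clustering stage is meant to recover. Confounded genes are
  mean-shifted between levels of a designated binary covariate (TP53
  status by default) and carry no hazard effect, so the confounder
  filter's behaviour is testable as pure recall/rejection.
* :func:`simulate_cellline_panel` — signal genes are monotone (Gaussian
  copula) transforms of log IC-50. For bivariate normal ranks the Kendall
  tau is ``(2/pi) * arcsin(r)``, so the latent correlation is set to
  ``r = sin(pi * target_tau / 2)`` — a closed-form calibration, checked by
  simulation in the tests.
* :func:`simulate_phenotype_panel` — cell volume ``V0`` and proliferation
  rate ``kp`` are log-normal with a planted negative rank correlation; drug
  sensitivity ``-log10(IC-50)`` loads on ``(log kp - log V0)``, which is by
  construction uncorrelated with ``log kg = log V0 + log kp`` (equal latent
  variances), reproducing the proliferation-vs-growth-rate contrast as a
  property of the generator. Drugs come in families sharing a latent factor
  (family encoded in the drug id) for the similarity-clustering analyses,
  and CORE metabolite exchange rates include one planted association with a
  drug family.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import DoseResponsePanel, ExpressionMatrix

__all__ = [
    "TumorSimConfig",
    "SimTruth",
    "simulate_tumor_cohort",
    "simulate_cellline_panel",
    "simulate_phenotype_panel",
    "simulate_raw_counts",
]

DEFAULT_COVARIATES: tuple[tuple[str, str], ...] = (
    ("tp53_mutant", "binary"),
    ("stage", "ordinal"),
    ("age", "continuous"),
    ("grade", "ordinal"),
    ("nodal_status", "ordinal"),
)


@dataclass
class TumorSimConfig:
    """Configuration for :func:`simulate_tumor_cohort`.

    Units: ``baseline_hazard`` and ``censoring_rate`` are events per day;
    ``effect_log_hazard`` is the log-hazard per SD of the combined planted
    risk score. ``program_r2`` is the fraction of each planted gene's
    variance explained by its direction's shared program factor.
    """

    n_samples: int = 200
    n_genes: int = 1000
    n_favorable: int = 25
    n_unfavorable: int = 25
    n_confounded: int = 25
    effect_log_hazard: float = 0.5
    baseline_hazard: float = 1.0 / 500.0
    censoring_rate: float = 1.0 / 1000.0
    confounder_shift: float = 1.0
    program_r2: float = 0.5
    subgroup_separation: float = 2.0
    event_time_law: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5
    covariate_spec: Sequence[tuple[str, str]] = DEFAULT_COVARIATES
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_samples, self.n_genes, self.n_favorable,
                  self.n_unfavorable, self.n_confounded)
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_favorable + self.n_unfavorable + self.n_confounded > self.n_genes:
            raise ValueError("planted + confounded gene count exceeds n_genes")
        if not np.isfinite(self.effect_log_hazard):
            raise ValueError("effect_log_hazard must be finite")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("baseline_hazard and censoring_rate must be > 0")
        if not 0.0 <= self.program_r2 < 1.0:
            raise ValueError("program_r2 must be in [0, 1)")
        if self.event_time_law not in ("exponential", "weibull"):
            raise ValueError("event_time_law must be 'exponential' or 'weibull'")


@dataclass
class SimTruth:
    """Ground-truth record of a simulated data set."""

    favorable_genes: list[str] = field(default_factory=list)
    unfavorable_genes: list[str] = field(default_factory=list)
    confounded_genes: list[str] = field(default_factory=list)
    per_sample_risk: Optional[pd.Series] = None
    planted_subgroup: Optional[pd.Series] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [set(self.favorable_genes), set(self.unfavorable_genes),
                set(self.confounded_genes)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("planted gene sets must be pairwise disjoint")

    @property
    def signal_genes(self) -> set[str]:
        return set(self.favorable_genes) | set(self.unfavorable_genes)

    def to_json(self, path) -> None:
        obj = {
            "favorable_genes": list(self.favorable_genes),
            "unfavorable_genes": list(self.unfavorable_genes),
            "confounded_genes": list(self.confounded_genes),
            "per_sample_risk": None if self.per_sample_risk is None
            else self.per_sample_risk.to_dict(),
            "planted_subgroup": None if self.planted_subgroup is None
            else self.planted_subgroup.to_dict(),
            "extra": self.extra,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def _covariate_table(spec, n, rng) -> pd.DataFrame:
    cols = {}
    for name, kind in spec:
        if kind == "binary":
            cols[name] = rng.binomial(1, 0.4, n)
        elif kind == "ordinal":
            cols[name] = rng.integers(1, 5, n)
        elif kind == "continuous":
            cols[name] = np.round(rng.normal(65.0, 10.0, n), 1)
        else:
            raise ValueError(f"unknown covariate type {kind!r} for {name!r}")
    return pd.DataFrame(cols)


def simulate_tumor_cohort(
    config: TumorSimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Simulate a tumor cohort with planted survival-associated genes.

    Returns ``(expression, survival, truth)`` where expression is on the
    log2 scale (genes x samples), survival is a DataFrame indexed by sample
    id with ``time`` (days), ``event`` and the configured covariates, and
    truth records planted assignments, the per-sample log-hazard score and a
    two-level planted risk subgroup (median split of the risk score).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    nf, nu, nc = config.n_favorable, config.n_unfavorable, config.n_confounded

    sample_ids = [f"S{j:04d}" for j in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(g)]
    fav = gene_ids[:nf]
    unfav = gene_ids[nf:nf + nu]
    conf = gene_ids[nf + nu:nf + nu + nc]

    covariates = _covariate_table(config.covariate_spec, n, rng)
    covariates.index = sample_ids

    # latent expression; planted genes share a per-direction program factor
    # whose mean differs between the two planted subgroups, so the cohort
    # contains genuinely distinct favorable- and unfavorable-signature
    # classes (the structure the clustering stage is meant to recover)
    z = rng.standard_normal((g, n))
    load = np.sqrt(config.program_r2)
    resid = np.sqrt(1.0 - config.program_r2)
    subgrp = rng.binomial(1, 0.5, n)  # 1 = unfavorable-signature class
    shift = 0.5 * config.subgroup_separation * np.where(subgrp == 1, 1.0, -1.0)
    if nf > 0:
        f_fav = rng.standard_normal(n) - shift
        z[:nf] = load * f_fav + resid * z[:nf]
    if nu > 0:
        f_unfav = rng.standard_normal(n) + shift
        z[nf:nf + nu] = load * f_unfav + resid * z[nf:nf + nu]

    # confounded genes: mean shift between levels of the first binary
    # covariate, no hazard effect
    binary_names = [nm for nm, kind in config.covariate_spec if kind == "binary"]
    if nc > 0:
        if not binary_names:
            raise ValueError("confounded genes require a binary covariate")
        lev = covariates[binary_names[0]].to_numpy()
        z[nf + nu:nf + nu + nc] += config.confounder_shift * lev[None, :]

    # combined risk score: unfavorable-program minus favorable-program
    # expression, standardized to unit SD so effect_log_hazard is the
    # per-SD log-hazard of the combined score (for independent planted
    # genes this equals the raw sum divided by sqrt(n_planted))
    n_planted = nf + nu
    if n_planted > 0:
        score = z[nf:nf + nu].sum(axis=0) - z[:nf].sum(axis=0)
        risk = config.effect_log_hazard * (score - score.mean()) / score.std()
    else:
        risk = np.zeros(n)

    rate = config.baseline_hazard * np.exp(risk)
    u = rng.uniform(size=n)
    if config.event_time_law == "exponential":
        t_event = -np.log(u) / rate
    else:
        t_event = (-np.log(u) / rate) ** (1.0 / config.weibull_shape)
    t_cens = rng.exponential(1.0 / config.censoring_rate, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    # dress the standardized values up as log2 expression
    mu = rng.uniform(2.0, 12.0, g)
    sd = rng.uniform(0.5, 2.0, g)
    values = pd.DataFrame(mu[:, None] + sd[:, None] * z,
                          index=gene_ids, columns=sample_ids)
    expr = ExpressionMatrix(values, scale="log2")

    surv = pd.DataFrame({"time": time, "event": event}, index=sample_ids)
    surv = pd.concat([surv, covariates], axis=1)

    risk_s = pd.Series(risk, index=sample_ids, name="log_hazard")
    subgroup = pd.Series(
        np.where(subgrp == 1, "poor", "good"),
        index=sample_ids, name="planted_subgroup",
    )
    if subgroup.nunique() < 2:  # degenerate draw: force two levels
        half = n // 2
        subgroup.iloc[:half] = "good"
        subgroup.iloc[half:] = "poor"
    truth = SimTruth(
        favorable_genes=list(fav),
        unfavorable_genes=list(unfav),
        confounded_genes=list(conf),
        per_sample_risk=risk_s,
        planted_subgroup=subgroup,
        extra={"binary_confounder": binary_names[0] if binary_names else None},
    )
    return expr, surv, truth


def simulate_cellline_panel(
    n_lines: int,
    n_genes: int,
    n_signal: int,
    target_tau: float,
    seed: int = 0,
    drug: str = "drugA",
) -> tuple[ExpressionMatrix, DoseResponsePanel, SimTruth]:
    """Simulate a cell-line panel with genes rank-correlated with IC-50.

    Signal genes alternate sign: even-indexed signal genes are resistance
    markers (positive Kendall tau with IC-50, unfavorable) and odd-indexed
    ones sensitivity markers (negative tau, favorable). The latent Gaussian
    correlation ``sin(pi * target_tau / 2)`` yields an expected Kendall tau
    of ``target_tau`` in magnitude.
    """
    if n_lines < 5:
        raise ValueError("n_lines must be >= 5 (screen undefined below)")
    if abs(target_tau) >= 1:
        raise ValueError("|target_tau| must be < 1")
    if n_signal > n_genes:
        raise ValueError("n_signal must be <= n_genes")
    rng = np.random.default_rng(seed)
    line_ids = [f"CL{j:03d}" for j in range(n_lines)]
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]

    log_ic50 = rng.normal(2.0, 1.0, n_lines)  # natural log, micromolar-ish
    z_ic = (log_ic50 - log_ic50.mean()) / log_ic50.std(ddof=1)

    r = np.sin(np.pi * target_tau / 2.0)
    z = rng.standard_normal((n_genes, n_lines))
    signs = np.ones(n_signal)
    signs[1::2] = -1.0
    if target_tau != 0 and n_signal > 0:
        z[:n_signal] = signs[:, None] * (
            r * z_ic[None, :] + np.sqrt(1 - r ** 2) * z[:n_signal]
        )
    else:
        n_signal, signs = 0, signs[:0]

    mu = rng.uniform(4.0, 10.0, n_genes)
    sd = rng.uniform(0.8, 1.6, n_genes)
    values = pd.DataFrame(mu[:, None] + sd[:, None] * z,
                          index=gene_ids, columns=line_ids)
    expr = ExpressionMatrix(values, scale="log2")

    panel = DoseResponsePanel(
        pd.DataFrame({drug: np.exp(log_ic50)}, index=line_ids)
    )
    unfav = [gene_ids[i] for i in range(n_signal) if signs[i] > 0]
    fav = [gene_ids[i] for i in range(n_signal) if signs[i] < 0]
    truth = SimTruth(
        favorable_genes=fav, unfavorable_genes=unfav,
        extra={"target_tau": target_tau, "drug": drug},
    )
    return expr, panel, truth


def simulate_phenotype_panel(
    n_lines: int = 60,
    n_drugs: int = 17,
    seed: int = 0,
    n_families: int = 3,
    volume_kp_corr: float = -0.5,
) -> DoseResponsePanel:
    """Simulate an NCI-60-like panel of IC-50s, volumes, kp and CORE values.

    Planted structure (recoverable from the returned panel):

    * ``volume`` and ``kp`` log-normal with rank correlation
      ``volume_kp_corr`` (< 0, as in real panels: big cells divide slowly);
    * ``-log10(IC-50)`` positively rank-correlated with ``kp`` and, by
      construction, uncorrelated with the growth rate
      ``kg = V0 * kp / ln 2``;
    * drugs split into ``n_families`` families sharing a latent factor; the
      family is encoded in the drug id (``drugNN_famK``) so similarity-
      clustering analyses can be scored against it;
    * ``CORE_phosphocholine`` release negatively correlated with sensitivity
      to family-0 drugs; ``CORE_deoxycytidine`` correlated with a single
      drug; ``CORE_alanine`` null.
    """
    if n_lines < 10:
        raise ValueError("n_lines must be >= 10")
    if n_drugs < n_families:
        raise ValueError("need at least one drug per family")
    rng = np.random.default_rng(seed)
    line_ids = [f"CL{j:03d}" for j in range(n_lines)]

    rho = float(volume_kp_corr)
    u = rng.standard_normal(n_lines)                      # latent log-volume
    w = rho * u + np.sqrt(1 - rho ** 2) * rng.standard_normal(n_lines)
    volume = np.exp(np.log(2000.0) + 0.4 * u)             # fL
    kp = np.exp(np.log(0.5) + 0.4 * w)                    # 1/day

    # common sensitivity axis: uncorrelated with u + w (= log growth rate)
    s = (w - u) / np.sqrt(2.0 - 2.0 * rho)

    fam_of = np.arange(n_drugs) % n_families
    fam_factor = rng.standard_normal((n_families, n_lines))
    drug_noise = rng.standard_normal((n_drugs, n_lines))
    sens = 0.8 * s[None, :] + 1.0 * fam_factor[fam_of] + 0.5 * drug_noise
    offset = rng.uniform(-1.0, 1.0, n_drugs)
    ic50 = 10.0 ** (-(0.5 * sens + offset[:, None]))      # micromolar

    drug_ids = [f"drug{i:02d}_fam{fam_of[i]}" for i in range(n_drugs)]
    ic50_df = pd.DataFrame(ic50.T, index=line_ids, columns=drug_ids)

    core_pc = -0.7 * fam_factor[0] + 0.7 * rng.standard_normal(n_lines)
    core_dc = 0.8 * drug_noise[min(2, n_drugs - 1)] + 0.6 * rng.standard_normal(n_lines)
    core_ala = rng.standard_normal(n_lines)
    phen = pd.DataFrame(
        {
            "volume": volume,
            "kp": kp,
            "CORE_phosphocholine": 5.0 * core_pc,
            "CORE_deoxycytidine": -2.0 + core_dc,
            "CORE_alanine": 3.0 * core_ala,
        },
        index=line_ids,
    )
    return DoseResponsePanel(ic50_df, phen)


def simulate_raw_counts(
    n_genes: int = 200,
    n_samples: int = 20,
    n_low: int = 50,
    seed: int = 0,
) -> ExpressionMatrix:
    """Raw-count matrix with a block of low-count genes.

    Exists solely to exercise the low-count filter and the log2 transform;
    the first ``n_low`` genes have Poisson(0.2) counts (nearly all <= 2),
    the rest Poisson rates log-uniform in [5, 500).
    """
    if n_low > n_genes:
        raise ValueError("n_low must be <= n_genes")
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.uniform(np.log(5.0), np.log(500.0), n_genes))
    lam[:n_low] = 0.2
    counts = rng.poisson(lam[:, None], size=(n_genes, n_samples))
    values = pd.DataFrame(
        counts,
        index=[f"G{i:05d}" for i in range(n_genes)],
        columns=[f"S{j:04d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(values.astype(float), scale="raw_count")
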