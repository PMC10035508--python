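"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes can be generated here at desk scale, with
known effects planted so that recovery can be scored exactly:

* :func:`gen_multitissue_panel` — a GTEx-like multi-tissue panel: per-tissue
  RBP expression (lognormal tissue means), a target gene expressed highly in
  a subset of tissues, and two competing splice junctions whose inclusion
  fraction is tied to one planted regulator through a logistic link.
  Junction totals are negative-binomial (RNA-seq overdispersion is the
  realistic stress for usage estimates), split binomially between the
  inclusion and exclusion junctions.
* :func:`gen_cohort` — a tumor cohort: PSI from a two-component beta
  mixture, exponential survival with a proportional hazard between the
  PSI-defined groups, uniform censoring calibrated to a target rate, and an
  expression matrix with planted fold-change genes and prognosis-marker
  labels.
* :func:`gen_titration` — binding titrations on the single-site isotherm
  with Gaussian noise, for Kd-recovery experiments.

All generators are pure functions of their config (seed mandatory):
identical inputs give identical outputs, and every generated object passes
the io-layer validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import (ExpressionMatrix, JunctionCountMatrix, SampleAttributes,
                 ClinicalTable, TitrationCurve)
from .kinetics import isotherm

__all__ = ["PanelConfig", "CohortConfig", "gen_multitissue_panel",
           "gen_cohort", "gen_titration", "TARGET_GENE",
           "INCLUSION_JUNCTION", "EXCLUSION_JUNCTION"]

TARGET_GENE = "TP63"
# two junctions sharing one donor site: gamma-exon inclusion vs skip to the
# downstream exon (the J11-12 / J11-13 competition)
INCLUSION_JUNCTION = "chr3:189000-190000"
EXCLUSION_JUNCTION = "chr3:189000-195000"


@dataclass
class PanelConfig:
    """Multi-tissue panel layout and planted regulator effect.

    Defaults emulate the GTEx-style screen at desk scale: 54 tissues of
    which 10 express the target gene, 30 samples per tissue, one planted
    repressor with logistic slope -1.5 among 50 RBPs, negative-binomial
    junction totals (mean 200, dispersion 0.3).
    """

    n_tissues: int = 54
    samples_per_tissue: int = 30
    n_rbps: int = 50
    regulator_index: int = 0
    regulator_slope: float = -1.5  # logistic slope b; negative = repressor
    usage_intercept: float = 0.0  # logistic intercept a
    junction_total_mean: float = 200.0
    dispersion: float = 0.3  # NB: var = mu + disp * mu^2
    expressing_tissue_count: int = 10
    target_expr_high: float = 50.0
    target_expr_low: float = 0.5
    design_threshold: float = 5.0  # selection threshold separating the two
    tissue_mean_sigma: float = 0.5  # spread of lognormal tissue means
    within_tissue_sigma: float = 0.3
    depth_sigma: float = 0.2  # per-sample library-depth lognormal spread
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_tissues, self.samples_per_tissue, self.n_rbps) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.regulator_index < self.n_rbps:
            raise ValueError("regulator_index out of range")
        if not 0 < self.expressing_tissue_count <= self.n_tissues:
            raise ValueError("expressing_tissue_count out of range")
        if abs(self.regulator_slope) > 10:
            raise ValueError("|slope| implausibly large")
        if self.dispersion < 0 or self.junction_total_mean <= 0:
            raise ValueError("invalid NB parameters")


@dataclass
class CohortConfig:
    """Tumor-cohort layout: PSI mixture, survival model, planted DEGs.

    PSI (percent) is a two-component beta mixture for low/high gamma-exon
    inclusion; the true group is defined by psi >= threshold_true.  Survival
    is exponential with hazard h0 * HR^[group == high]; censoring is uniform
    and calibrated to the target rate.  ``n_planted_deg`` genes are shifted
    by ``deg_log2fc`` (multiplicative) in the high group; planted up-genes
    are labelled unfavorable prognosis markers, an equal number of null
    genes favorable.
    """

    n_patients: int = 200
    high_frac: float = 0.35
    psi_low_a: float = 2.0
    psi_low_b: float = 98.0
    psi_high_a: float = 8.0
    psi_high_b: float = 92.0
    threshold_true: float = 4.07  # percent
    hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 1500.0  # per day
    censoring_rate: float = 0.3
    n_genes: int = 1000
    n_planted_deg: int = 100
    deg_log2fc: float = 1.0
    expr_sigma: float = 0.5  # lognormal within-group noise
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients too small")
        if not 0 < self.high_frac < 1:
            raise ValueError("high_frac must be in (0,1)")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0,1)")
        if self.n_planted_deg > self.n_genes:
            raise ValueError("more planted DEGs than genes")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float,
             size: int) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def gen_multitissue_panel(config: PanelConfig):
    """Generate (JunctionCountMatrix, ExpressionMatrix, SampleAttributes, truth).

    The expression matrix holds the target gene plus all RBPs on a raw
    counts-like scale, with per-sample depth variation so that the depth
    normalization stage has real work to do.  The truth record stores the
    planted regulator, its slope, the per-sample true inclusion fraction and
    the designed expressing tissues.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t, n_s = config.n_tissues, config.samples_per_tissue
    n_samples = n_t * n_s

    tissues = [f"tissue_{i+1:02d}" for i in range(n_t)]
    sample_ids = [f"{t}_s{j+1:03d}" for t in tissues for j in range(n_s)]
    tissue_of = np.repeat(np.arange(n_t), n_s)
    expressing = set(tissues[: config.expressing_tissue_count])
    is_expr = np.array([tissues[ti] in expressing for ti in tissue_of])

    rbp_names = [f"RBP{i:03d}" for i in range(config.n_rbps)]
    regulator = rbp_names[config.regulator_index]

    # RBP expression: lognormal tissue means, lognormal within-tissue spread
    base = 20.0
    tissue_means = rng.lognormal(np.log(base), config.tissue_mean_sigma,
                                 size=(config.n_rbps, n_t))
    expr = rng.lognormal(np.log(tissue_means[:, tissue_of]),
                         config.within_tissue_sigma)

    # target gene: high in expressing tissues, low elsewhere
    target_mean = np.where(is_expr, config.target_expr_high, config.target_expr_low)
    target = rng.lognormal(np.log(target_mean), config.within_tissue_sigma)

    # inclusion via logistic link to standardized regulator expression,
    # standardized over the samples where the target gene is expressed
    reg = expr[config.regulator_index]
    mu, sd = reg[is_expr].mean(), reg[is_expr].std()
    z = (reg - mu) / sd
    inclusion = expit(config.usage_intercept + config.regulator_slope * z)

    # junction totals: NB in expressing tissues, trace elsewhere
    totals = np.where(
        is_expr,
        _nb_draw(rng, config.junction_total_mean, config.dispersion, n_samples),
        _nb_draw(rng, 2.0, config.dispersion, n_samples),
    )
    inc_counts = rng.binomial(totals, inclusion)
    exc_counts = totals - inc_counts

    # per-sample sequencing depth multiplies everything
    depth = rng.lognormal(0.0, config.depth_sigma, size=n_samples)
    expr_obs = expr * depth[np.newaxis, :]
    target_obs = target * depth
    inc_obs = rng.poisson(inc_counts * depth)
    exc_obs = rng.poisson(exc_counts * depth)

    junctions = JunctionCountMatrix(
        junction_ids=[INCLUSION_JUNCTION, EXCLUSION_JUNCTION],
        gene_of_junction={INCLUSION_JUNCTION: TARGET_GENE,
                          EXCLUSION_JUNCTION: TARGET_GENE},
        sample_ids=sample_ids,
        counts=np.vstack([inc_obs, exc_obs]).astype(np.int64),
    )
    expression = ExpressionMatrix(
        gene_ids=[TARGET_GENE] + rbp_names,
        sample_ids=sample_ids,
        values=np.vstack([target_obs, expr_obs]),
        normalized=False,
    )
    attrs = SampleAttributes(pd.DataFrame(
        {"tissue": [tissues[ti] for ti in tissue_of], "condition": "NA"},
        index=pd.Index(sample_ids, name="sample_id"),
    ))
    truth = {
        "regulator": regulator,
        "slope": config.regulator_slope,
        "rbp_names": rbp_names,
        "expressing_tissues": sorted(expressing),
        "design_threshold": config.design_threshold,
        "true_inclusion": dict(zip(sample_ids, inclusion.tolist())),
        "config": asdict(config),
    }
    return junctions, expression, attrs, truth


def _uniform_censor_max(rates: np.ndarray, target: float) -> float:
    """Upper bound u of U(0, u) censoring giving the target censoring rate.

    For T ~ Exp(r) and C ~ U(0, u), P(T > C) = (1 - exp(-r u)) / (r u);
    solve the cohort average for u by bisection.
    """

    def censored_frac(u):
        x = rates * u
        return float(np.mean((1.0 - np.exp(-x)) / x)) - target

    lo, hi = 1e-9, 1e9
    return brentq(censored_frac, lo, hi, xtol=1e-9)


def gen_cohort(config: CohortConfig):
    """Generate (ClinicalTable, psi Series, ExpressionMatrix, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"P{i+1:04d}" for i in range(n)]

    comp_high = rng.random(n) < config.high_frac
    psi = np.where(
        comp_high,
        rng.beta(config.psi_high_a, config.psi_high_b, size=n),
        rng.beta(config.psi_low_a, config.psi_low_b, size=n),
    ) * 100.0
    group_high = psi >= config.threshold_true
    if group_high.all() or not group_high.any():
        raise ValueError("degenerate PSI mixture: all patients in one group")

    rates = config.baseline_hazard * np.where(group_high, config.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rates)
    if config.censoring_rate > 0:
        u = _uniform_censor_max(rates, config.censoring_rate)
        t_cens = rng.uniform(0.0, u, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    time = np.maximum(time, 0.5)  # keep times positive after rounding

    clinical = ClinicalTable(pd.DataFrame({
        "patient_id": patients,
        "time_days": np.round(time, 1),
        "event": event,
    }))
    psi_series = pd.Series(psi, index=patients, name="exon12_inclusion")

    genes = [f"G{i+1:04d}" for i in range(config.n_genes)]
    baseline = rng.lognormal(np.log(100.0), 1.0, size=config.n_genes)
    log_expr = np.log(baseline)[:, np.newaxis] + rng.normal(
        0.0, config.expr_sigma, size=(config.n_genes, n))
    deg_idx = rng.choice(config.n_genes, size=config.n_planted_deg, replace=False)
    shift = config.deg_log2fc * np.log(2.0)
    log_expr[np.ix_(deg_idx, np.nonzero(group_high)[0])] += shift
    expr = ExpressionMatrix(gene_ids=genes, sample_ids=patients,
                            values=np.exp(log_expr), normalized=True)

    deg_genes = [genes[i] for i in sorted(deg_idx)]
    null_idx = [i for i in range(config.n_genes) if i not in set(deg_idx)]
    fav_idx = rng.choice(len(null_idx), size=min(config.n_planted_deg,
                                                 len(null_idx)), replace=False)
    markers = {g: "unfavorable" for g in deg_genes}
    markers.update({genes[null_idx[i]]: "favorable" for i in sorted(fav_idx)})

    truth = {
        "group_high": dict(zip(patients, group_high.tolist())),
        "threshold_true": config.threshold_true,
        "hazard_ratio": config.hazard_ratio,
        "deg_genes": deg_genes,
        "markers": markers,
        "config": asdict(config),
    }
    return clinical, psi_series, expr, truth


DEFAULT_LADDER = tuple(12.5 * 2 ** k for k in range(8))  # 12.5 .. 1600 nmol/L


def gen_titration(
    kd: float,
    concs=DEFAULT_LADDER,
    noise_sd: float = 0.05,
    n_replicates: int = 4,
    seed: int = 0,
    probe_name: str = "probe",
) -> list[TitrationCurve]:
    """Titration replicates on the isotherm with Gaussian noise, clipped."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    conc = np.asarray(list(concs), dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration ladder")
    rng = np.random.default_rng(seed)
    truth = isotherm(kd, conc)
    curves = []
    for r in range(n_replicates):
        noisy = truth + rng.normal(0.0, noise_sd, size=conc.size) \
            if noise_sd > 0 else truth.copy()
        curves.append(TitrationCurve(
            probe_name=probe_name,
            conc=conc.copy(),
            bound_frac=np.clip(noisy, 0.0, 1.0),
            replicate_id=f"rep{r+1}",
        ))
    return curves
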