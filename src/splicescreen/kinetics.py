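"""Equilibrium binding isotherm fitting for EMSA titrations.

A single-site, 1:1 protein–RNA equilibrium at protein excess gives the
bound fraction as a function of free protein concentration [P]:

    f([P]) = 1 / (1 + Kd / [P])  =  [P] / ([P] + Kd)

with Kd the dissociation constant in nmol/L — the concentration at which
half the RNA is bound.  f(0) = 0 by continuity and f -> 1 as [P] -> inf;
the amplitude is fixed at 1 (fully bindable RNA) by default, with an
optional free-plateau variant for partially active probe preparations.

The fit minimises squared residuals over log(Kd) — positivity by
construction and much better conditioning across the nmol/L–µmol/L range.
Uncertainty is the SD across per-replicate fits when >=3 replicates exist,
otherwise a seeded nonparametric bootstrap over points (200 resamples).
Probes whose bound fraction never rises are not forced through the
optimiser: they are declared *unbound* with Kd censored at > max tested
concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io import TitrationCurve

logger = logging.getLogger(__name__)

__all__ = ["isotherm", "BindingModel", "KdFit", "fit_kd", "compare_kd",
           "KdComparison"]

UNBOUND_MAX_FRAC = 0.2  # max observed bound fraction below which no fit is attempted
N_BOOTSTRAP = 200


def isotherm(kd: float, conc) -> np.ndarray | float:
    """Bound fraction 1 / (1 + kd/conc) with f(0) = 0 by continuity."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    conc_arr = np.asarray(conc, dtype=float)
    if np.any(conc_arr < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        f = np.where(conc_arr > 0, conc_arr / (conc_arr + kd), 0.0)
    return float(f) if np.isscalar(conc) else f


@dataclass
class KdFit:
    """Fitted dissociation constant and its uncertainty."""

    probe_name: str
    kd_hat: float  # nmol/L; NaN when censored
    sd: float  # nmol/L
    n_points: int
    residual_sse: float
    converged: bool
    censored: bool = False  # True => kd > censor_limit, no point estimate
    censor_limit: float = float("nan")  # max tested concentration
    sd_method: str = "bootstrap"
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.censored and not (self.kd_hat > 0):
            raise ValueError("kd_hat must be positive for a converged fit")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def summary(self) -> str:
        if self.censored:
            return (f"{self.probe_name}: unbound "
                    f"(Kd > {self.censor_limit:g} nmol/L, {self.n_points} points)")
        return (f"{self.probe_name}: Kd = {self.kd_hat:.1f} "
                f"+/- {self.sd:.1f} nmol/L "
                f"({self.sd_method} SD, {self.n_points} points, "
                f"SSE {self.residual_sse:.4g})")


def _fit_single(conc: np.ndarray, frac: np.ndarray,
                free_amplitude: bool) -> tuple[float, float, float, bool]:
    """Least-squares over log-kd; returns (kd, amplitude, sse, converged)."""
    pos = conc > 0
    # initial kd: concentration whose bound fraction is nearest half-saturation
    init_kd = conc[pos][np.argmin(np.abs(frac[pos] - 0.5))]
    init_kd = max(init_kd, 1e-6)

    if free_amplitude:
        def resid(theta):
            kd, amp = np.exp(theta[0]), theta[1]
            return amp * np.where(conc > 0, conc / (conc + kd), 0.0) - frac
        x0 = [np.log(init_kd), max(frac.max(), 0.1)]
    else:
        def resid(theta):
            kd = np.exp(theta[0])
            return np.where(conc > 0, conc / (conc + kd), 0.0) - frac
        x0 = [np.log(init_kd)]

    sol = optimize.least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    kd = float(np.exp(sol.x[0]))
    amp = float(sol.x[1]) if free_amplitude else 1.0
    sse = float(np.sum(sol.fun ** 2))
    return kd, amp, sse, bool(sol.success)


class BindingModel:
    """Model: one probe's titration replicates; ``fit()`` -> :class:`KdFit`.

    Parameters
    ----------
    curves : list of TitrationCurve
        Replicate titrations of one probe (probe names must agree).
    free_amplitude : bool
        Fit a plateau parameter instead of fixing the amplitude at 1.
    """

    def __init__(self, curves: list[TitrationCurve] | TitrationCurve,
                 free_amplitude: bool = False):
        if isinstance(curves, TitrationCurve):
            curves = [curves]
        if not curves:
            raise ValueError("need at least one titration curve")
        probes = {c.probe_name for c in curves}
        if len(probes) > 1:
            raise ValueError(f"curves from multiple probes: {sorted(probes)}")
        self.curves = curves
        self.probe_name = curves[0].probe_name
        self.free_amplitude = free_amplitude
        self.conc = np.concatenate([c.conc for c in curves])
        self.frac = np.concatenate([c.bound_frac for c in curves])
        if len(np.unique(self.conc[self.conc > 0])) < 3:
            raise ValueError("need >=3 distinct positive concentrations")

    def fit(self, seed: int | None = 0) -> KdFit:
        conc, frac = self.conc, self.frac
        max_conc = float(conc.max())
        if frac.max() < UNBOUND_MAX_FRAC:
            logger.info("%s: no binding observed; censoring Kd at > %g",
                        self.probe_name, max_conc)
            return KdFit(self.probe_name, float("nan"), 0.0, conc.size,
                         float(np.sum(frac ** 2)), converged=False,
                         censored=True, censor_limit=max_conc,
                         sd_method="none")

        kd, amp, sse, ok = _fit_single(conc, frac, self.free_amplitude)
        if kd > 10 * max_conc:
            # saturation never approached within the ladder: report a bound
            return KdFit(self.probe_name, float("nan"), 0.0, conc.size, sse,
                         converged=ok, censored=True, censor_limit=max_conc,
                         sd_method="none")

        if len(self.curves) >= 3:
            reps = []
            for c in self.curves:
                try:
                    k_r, _, _, ok_r = _fit_single(c.conc, c.bound_frac,
                                                  self.free_amplitude)
                    if ok_r and k_r <= 10 * max_conc:
                        reps.append(k_r)
                except Exception:  # degenerate replicate: skip from SD
                    continue
            if len(reps) >= 3:
                return KdFit(self.probe_name, kd, float(np.std(reps, ddof=1)),
                             conc.size, sse, ok, sd_method="replicate",
                             amplitude=amp)

        rng = np.random.default_rng(seed)
        boot = []
        n = conc.size
        for _ in range(N_BOOTSTRAP):
            idx = rng.integers(0, n, size=n)
            c_b, f_b = conc[idx], frac[idx]
            if len(np.unique(c_b[c_b > 0])) < 3:
                continue
            try:
                k_b, _, _, ok_b = _fit_single(c_b, f_b, self.free_amplitude)
            except Exception:
                continue
            if ok_b and k_b <= 10 * max_conc:
                boot.append(k_b)
        sd = float(np.std(boot, ddof=1)) if len(boot) >= 2 else float("nan")
        return KdFit(self.probe_name, kd, 0.0 if np.isnan(sd) else sd,
                     conc.size, sse, ok, sd_method="bootstrap", amplitude=amp)


def fit_kd(curves: list[TitrationCurve] | TitrationCurve,
           free_amplitude: bool = False, seed: int | None = 0) -> KdFit:
    """Convenience wrapper: build a :class:`BindingModel` and fit it."""
    return BindingModel(curves, free_amplitude=free_amplitude).fit(seed=seed)


@dataclass
class KdComparison:
    """Fold change Kd_b / Kd_a with a delta-method interval on log scale."""

    fold: float
    ci_low: float
    ci_high: float
    censored: bool = False  # True => fold is a lower bound (>=)

    def __str__(self) -> str:
        if self.censored:
            return f">= {self.fold:.1f}-fold"
        return f"{self.fold:.2f}-fold (95% CI {self.ci_low:.2f}-{self.ci_high:.2f})"


def compare_kd(fit_a: KdFit, fit_b: KdFit, z: float = 1.959963984540054) -> KdComparison:
    """Affinity fold change between two probes (b relative to a).

    If fit_b is censored the fold is reported as a lower bound computed from
    the censoring limit; a censored reference fit is an error.
    """
    if fit_a.censored:
        raise ValueError("reference fit is censored; fold change undefined")
    if fit_b.censored:
        return KdComparison(fold=fit_b.censor_limit / fit_a.kd_hat,
                            ci_low=float("nan"), ci_high=float("nan"),
                            censored=True)
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    fold = fit_b.kd_hat / fit_a.kd_hat
    # delta method on log fold: var = (sd_a/kd_a)^2 + (sd_b/kd_b)^2
    se_log = np.sqrt((fit_a.sd / fit_a.kd_hat) ** 2 +
                     (fit_b.sd / fit_b.kd_hat) ** 2)
    return KdComparison(fold=float(fold),
                        ci_low=float(fold * np.exp(-z * se_log)),
                        ci_high=float(fold * np.exp(z * se_log)))
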