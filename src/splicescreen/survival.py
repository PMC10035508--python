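"""PSI-threshold survival stratification: Kaplan–Meier and log-rank.

Patients are split into high/low strata by an exon-inclusion (PSI) cutoff —
the boundary value itself goes to "high" (the split is psi >= threshold) —
and their survival compared.  The product-limit estimator and the two-group
log-rank test are implemented from first principles:

* Kaplan–Meier: S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event
  times t_i with d_i deaths among n_i at risk; tied deaths are aggregated at
  their common time.  The median is the smallest event time with
  S(t) <= 0.5, undefined (NaN) if S never reaches 0.5.
* Log-rank: at each distinct event time, expected events per stratum from
  the at-risk proportions, with the exact hypergeometric variance
  V = d (n1/n) (1 - n1/n) (n - d)/(n - 1) handling ties; the statistic
  (O1 - E1)^2 / V is chi-square with 1 df.

`scan_cutpoints` makes the threshold choice explicit and reproducible: it
scans a quantile grid, keeps cutoffs leaving a minimum fraction of patients
in each stratum, and reports the p-minimising threshold together with the
full scan table and a multiple-testing caveat flag — a p-value minimised
over a grid is optimistically biased and must not be read at face value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable

logger = logging.getLogger(__name__)

__all__ = ["KMCurve", "LogRankResult", "StratifiedCohort", "CutpointScan",
           "stratify_by_psi", "km_estimate", "logrank_test", "scan_cutpoints",
           "SurvivalStratification", "SurvivalResults"]


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S(0) = 1 and the
    function is a non-increasing right-continuous step function.
    """

    event_times: np.ndarray  # distinct times with >=1 death, ascending
    survival: np.ndarray  # S after each event time
    at_risk: np.ndarray  # n_i at each event time
    n_events: np.ndarray  # d_i at each event time
    median_survival: float  # NaN when S never reaches 0.5
    n_subjects: int

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """S(t) via the step function (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def plot(self, ax=None, label: str | None = None, **kwargs):
        """Step plot of the curve (lazy matplotlib import)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.event_times])
        s = np.concatenate([[1.0], self.survival])
        ax.step(t, s, where="post", label=label, **kwargs)
        ax.set_xlabel("time (days)")
        ax.set_ylabel("S(t)")
        ax.set_ylim(0, 1.02)
        return ax


@dataclass
class LogRankResult:
    """Two-group log-rank outcome (1 df)."""

    chi_square: float
    p: float
    observed: dict[str, float]
    expected: dict[str, float]


@dataclass
class StratifiedCohort:
    """Patients labelled high/low by a PSI threshold."""

    table: pd.DataFrame  # patient_id, time_days, event, psi_value, stratum
    threshold: float
    n_excluded_missing_psi: int = 0

    def arm(self, stratum: str) -> pd.DataFrame:
        return self.table[self.table["stratum"] == stratum]


@dataclass
class CutpointScan:
    best_threshold: float
    scan_table: pd.DataFrame  # threshold, chi_square, p, n_high, n_low
    multiple_testing_caveat: bool = True


def stratify_by_psi(
    clinical: ClinicalTable,
    psi: pd.Series,
    threshold: float,
    direction: str = "ge_is_high",
) -> StratifiedCohort:
    """Assign stratum 'high' iff psi >= threshold (boundary goes to high).

    Patients with missing PSI are excluded and counted; an empty stratum is
    an error (no two-group comparison is possible).
    """
    if direction != "ge_is_high":
        raise ValueError("only direction='ge_is_high' is supported")
    df = clinical.table.copy()
    df["psi_value"] = df["patient_id"].map(psi)
    n_missing = int(df["psi_value"].isna().sum())
    if n_missing:
        logger.warning("excluding %d patients with missing PSI", n_missing)
        df = df.dropna(subset=["psi_value"])
    df["stratum"] = np.where(df["psi_value"] >= threshold, "high", "low")
    counts = df["stratum"].value_counts()
    for arm in ("high", "low"):
        if counts.get(arm, 0) == 0:
            raise ValueError(
                f"empty stratum: {arm} (high={counts.get('high', 0)}, "
                f"low={counts.get('low', 0)}) at threshold {threshold}"
            )
    cols = ["patient_id", "time_days", "event", "psi_value", "stratum"]
    return StratifiedCohort(df[cols].reset_index(drop=True), float(threshold),
                            n_missing)


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate from times and 0/1 event flags."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")

    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    n = times.size

    uniq, first_idx = np.unique(t_sorted, return_index=True)
    event_times, surv, at_risk, n_ev = [], [], [], []
    s = 1.0
    for t, i0 in zip(uniq, first_idx):
        mask = t_sorted == t
        d = int(e_sorted[mask].sum())
        if d == 0:
            continue
        n_i = n - i0  # subjects with time >= t
        s *= 1.0 - d / n_i
        event_times.append(t)
        surv.append(s)
        at_risk.append(n_i)
        n_ev.append(d)

    surv_arr = np.asarray(surv)
    below = np.nonzero(surv_arr <= 0.5)[0] if surv_arr.size else np.array([], int)
    median = float(event_times[below[0]]) if below.size else float("nan")
    return KMCurve(
        event_times=np.asarray(event_times),
        survival=surv_arr,
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(n_ev, dtype=int),
        median_survival=median,
        n_subjects=n,
    )


def logrank_test(cohort: StratifiedCohort) -> LogRankResult:
    """Two-group log-rank test between the high and low strata."""
    hi = cohort.arm("high")
    lo = cohort.arm("low")
    if hi.empty or lo.empty:
        raise ValueError("both strata must be non-empty")
    return _logrank(
        hi["time_days"].to_numpy(float), hi["event"].to_numpy(int),
        lo["time_days"].to_numpy(float), lo["event"].to_numpy(int),
    )


def _logrank(t1, e1, t2, e2) -> LogRankResult:
    all_t = np.concatenate([t1, t2])
    all_e = np.concatenate([e1, e2])
    grp1 = np.concatenate([np.ones_like(t1, bool), np.zeros_like(t2, bool)])

    event_times = np.unique(all_t[all_e == 1])
    if event_times.size == 0:
        warnings.warn("no events in either stratum; log-rank undefined",
                      stacklevel=2)
        return LogRankResult(0.0, 1.0, {"high": 0.0, "low": 0.0},
                             {"high": 0.0, "low": 0.0})

    O1 = E1 = V = 0.0
    D1 = D2 = 0.0
    for t in event_times:
        at_risk = all_t >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & grp1).sum())
        dying = (all_t == t) & (all_e == 1)
        d = int(dying.sum())
        d1 = int((dying & grp1).sum())
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        D1 += d1
        D2 += d - d1
    if V == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (O1 - E1) ** 2 / V
        p = float(stats.chi2.sf(chi2, df=1))
    total_d = D1 + D2
    return LogRankResult(
        chi_square=float(chi2),
        p=p,
        observed={"high": float(D1), "low": float(D2)},
        expected={"high": float(E1), "low": float(total_d - E1)},
    )


def scan_cutpoints(
    psi: pd.Series,
    clinical: ClinicalTable,
    grid: np.ndarray | int = 20,
    min_group_frac: float = 0.1,
) -> CutpointScan:
    """Scan PSI thresholds and return the log-rank p-minimising cutoff.

    ``grid`` is either explicit thresholds or a number of quantile points of
    the observed PSI distribution.  Each admissible cutoff must leave at
    least ``min_group_frac`` of patients in both strata.  The result carries
    a multiple-testing caveat flag: the minimised p-value is biased.
    """
    values = psi.dropna().to_numpy(dtype=float)
    if values.size == 0:
        raise ValueError("no PSI values")
    if isinstance(grid, int):
        qs = np.linspace(0.0, 1.0, grid + 2)[1:-1]
        thresholds = np.unique(np.quantile(values, qs))
    else:
        thresholds = np.unique(np.asarray(grid, dtype=float))
        lo_v, hi_v = values.min(), values.max()
        if ((thresholds < lo_v) | (thresholds > hi_v)).any():
            raise ValueError("grid extends outside the observed PSI range")

    rows = []
    n_total = len(clinical.table)
    for thr in thresholds:
        try:
            cohort = stratify_by_psi(clinical, psi, float(thr))
        except ValueError:
            continue
        n_hi = len(cohort.arm("high"))
        n_lo = len(cohort.arm("low"))
        if min(n_hi, n_lo) < min_group_frac * n_total:
            continue
        res = logrank_test(cohort)
        rows.append((float(thr), res.chi_square, res.p, n_hi, n_lo))
    if not rows:
        raise ValueError("no admissible threshold in grid")
    scan = pd.DataFrame(rows, columns=["threshold", "chi_square", "p",
                                       "n_high", "n_low"])
    best = scan.loc[scan["p"].idxmin(), "threshold"]
    return CutpointScan(best_threshold=float(best), scan_table=scan)


# ---------------------------------------------------------------------------
# model / results wrapper
# ---------------------------------------------------------------------------


class SurvivalStratification:
    """Model: a cohort with per-patient PSI, stratified at a threshold.

    ``fit()`` returns :class:`SurvivalResults` holding both KM curves, the
    per-arm medians and the log-rank comparison.
    """

    def __init__(self, clinical: ClinicalTable, psi: pd.Series, threshold: float):
        self.clinical = clinical
        self.psi = psi
        self.threshold = float(threshold)

    def fit(self) -> "SurvivalResults":
        cohort = stratify_by_psi(self.clinical, self.psi, self.threshold)
        curves = {}
        for arm in ("high", "low"):
            sub = cohort.arm(arm)
            curves[arm] = km_estimate(sub["time_days"].to_numpy(),
                                      sub["event"].to_numpy())
        lr = logrank_test(cohort)
        return SurvivalResults(cohort=cohort, curves=curves, logrank=lr)


@dataclass
class SurvivalResults:
    cohort: StratifiedCohort
    curves: dict[str, KMCurve]
    logrank: LogRankResult

    @property
    def median_survival(self) -> dict[str, float]:
        return {arm: c.median_survival for arm, c in self.curves.items()}

    def plot(self, ax=None):
        for arm, color in (("high", "C3"), ("low", "C0")):
            ax = self.curves[arm].plot(
                ax=ax, label=f"{arm} PSI (n={self.curves[arm].n_subjects})",
                color=color)
        ax.legend()
        return ax

    def summary(self) -> str:
        med = self.median_survival
        lines = [
            "PSI-threshold survival stratification",
            f"  threshold (PSI %)    : {self.cohort.threshold:g}",
            f"  n high / low         : {len(self.cohort.arm('high'))} / "
            f"{len(self.cohort.arm('low'))}",
            f"  median survival high : {med['high']:.1f} days"
            if np.isfinite(med["high"]) else "  median survival high : NA",
            f"  median survival low  : {med['low']:.1f} days"
            if np.isfinite(med["low"]) else "  median survival low  : NA",
            f"  log-rank chi-square  : {self.logrank.chi_square:.4f}",
            f"  log-rank p           : {self.logrank.p:.4g}",
        ]
        return "\n".join(lines)
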