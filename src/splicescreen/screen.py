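"""Correlation screen for trans-acting splicing regulators.

The screen asks: which RNA-binding proteins have expression that tracks the
usage of a target junction across many samples?  For each RBP the Pearson
correlation coefficient between its normalized expression and the junction
usage is computed over pairwise-complete samples, with the usual t-based
two-sided p-value (t = r * sqrt((n-2)/(1-r^2)) on n-2 df).  Candidates are
ranked by |r| — both strong enhancers (positive r) and strong repressors
(negative r) are of interest — with ties broken by smaller p, then by
symbol, so the ranking is deterministic.

A cross-cohort concordance filter then confronts each candidate with tumor
data: samples are split into high/low PSI groups and the candidate's
expression compared by a two-sided Wilcoxon rank-sum test.  A negatively
correlated candidate (putative repressor) is concordant only if its tumor
expression is significantly *lower* in the high-PSI group, and a positively
correlated candidate only if *higher* — a candidate whose tumor behaviour
contradicts its cross-tissue correlation sign is rejected as implausible.

Organised statsmodels-style: build a :class:`RegulatorScreen` from the data,
``fit()`` returns :class:`ScreenResults` with the ranked table, a
``summary()`` and the concordance filter method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["RegulatorScreen", "ScreenResults", "ConcordanceVerdict", "concordance_filter"]


@dataclass
class ConcordanceVerdict:
    """Tumor-concordance call for one screen candidate."""

    rbp: str
    correlation_sign: str  # '+' or '-'
    tumor_de_sign: str  # higher_in_highPSI / lower_in_highPSI / ns
    tumor_p: float
    concordant: bool


class RegulatorScreen:
    """Pearson screen of RBP expression against one junction's usage.

    Parameters
    ----------
    rbp_expr : ExpressionMatrix
        Normalized expression restricted to the RBP candidates.
    usage : pd.Series
        Per-sample usage of the target junction (index = sample ids); missing
        values allowed and handled pairwise-complete.
    log1p : bool
        Apply log1p to expression before correlating (off by default: the
        screen correlates normalized expression as-is).
    """

    MIN_PAIRS = 3

    def __init__(self, rbp_expr: ExpressionMatrix, usage: pd.Series, log1p: bool = False):
        self.rbp_expr = rbp_expr
        common = [s for s in rbp_expr.sample_ids if s in usage.index]
        if len(common) < len(rbp_expr.sample_ids):
            logger.warning("%d expression samples lack usage values",
                           len(rbp_expr.sample_ids) - len(common))
        if not common:
            raise ValueError("no samples shared between expression and usage")
        self.sample_ids = common
        cols = [rbp_expr.sample_ids.index(s) for s in common]
        X = rbp_expr.values[:, cols].astype(float)
        self.exog = np.log1p(X) if log1p else X
        self.usage = usage[common].to_numpy(dtype=float)
        self.log1p = log1p

    def fit(self) -> "ScreenResults":
        y = self.usage
        rows, untestable = [], []
        for gi, gene in enumerate(self.rbp_expr.gene_ids):
            x = self.exog[gi]
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < self.MIN_PAIRS:
                untestable.append((gene, "fewer than 3 complete pairs"))
                continue
            xs, ys = x[ok], y[ok]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                untestable.append((gene, "zero variance"))
                continue
            r, p = stats.pearsonr(xs, ys)
            rows.append((gene, float(r), float(p), n, "+" if r >= 0 else "-"))
        table = pd.DataFrame(rows, columns=["rbp", "r", "p", "n", "sign"])
        # deterministic rank: |r| desc, then p asc, then symbol
        order = sorted(range(len(table)),
                       key=lambda i: (-abs(table["r"].iat[i]), table["p"].iat[i],
                                      table["rbp"].iat[i]))
        table = table.iloc[order].reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        return ScreenResults(table=table, untestable=untestable, model=self)


@dataclass
class ScreenResults:
    """Ranked correlation table plus the untestable RBPs and filters."""

    table: pd.DataFrame  # rbp, r, p, n, sign, rank
    untestable: list[tuple[str, str]]
    model: RegulatorScreen | None = field(default=None, repr=False)

    def top(self, k: int) -> pd.DataFrame:
        """Top-k candidates by |r| (deterministic tie rule baked into rank)."""
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > len(self.table):
            logger.warning("k=%d exceeds %d tested RBPs; returning all",
                           k, len(self.table))
        return self.table.head(k).copy()

    def rank_of(self, rbp: str) -> int:
        sub = self.table[self.table["rbp"] == rbp]
        if sub.empty:
            raise KeyError(f"{rbp!r} not among tested RBPs")
        return int(sub["rank"].iloc[0])

    def concordance_filter(
        self,
        tumor_expr: ExpressionMatrix,
        groups: pd.Series,
        alpha: float = 0.05,
        k: int | None = None,
    ) -> list[ConcordanceVerdict]:
        """Apply the tumor sign-concordance filter to the top-k candidates."""
        cand = self.top(k) if k is not None else self.table
        return concordance_filter(cand, tumor_expr, groups, alpha=alpha)

    def summary(self) -> str:
        lines = [
            "Regulator correlation screen",
            f"  samples used : {len(self.model.sample_ids) if self.model else 'NA'}",
            f"  RBPs tested  : {len(self.table)}",
            f"  untestable   : {len(self.untestable)}",
            "",
            self.table.head(10).to_string(index=False,
                                          float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def concordance_filter(
    candidates: pd.DataFrame,
    tumor_expr: ExpressionMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
) -> list[ConcordanceVerdict]:
    """Two-sided Wilcoxon rank-sum of each candidate between PSI groups.

    ``groups`` maps tumor sample id -> 'high' / 'low'.  A candidate passes
    iff its tumor shift is significant at ``alpha`` AND its direction matches
    the correlation sign (repressors lower, enhancers higher in high-PSI).
    """
    labels = set(groups.unique())
    if not labels <= {"high", "low"}:
        raise ValueError(f"groups must be 'high'/'low', got {sorted(labels)}")
    hi = [s for s in tumor_expr.sample_ids if groups.get(s) == "high"]
    lo = [s for s in tumor_expr.sample_ids if groups.get(s) == "low"]
    if len(hi) < 2 or len(lo) < 2:
        raise ValueError(f"need >=2 samples per group, got high={len(hi)}, low={len(lo)}")
    hi_idx = [tumor_expr.sample_ids.index(s) for s in hi]
    lo_idx = [tumor_expr.sample_ids.index(s) for s in lo]

    verdicts = []
    for _, row in candidates.iterrows():
        rbp, sign = row["rbp"], row["sign"]
        if rbp not in tumor_expr.gene_ids:
            verdicts.append(ConcordanceVerdict(rbp, sign, "ns", float("nan"), False))
            continue
        gi = tumor_expr.gene_ids.index(rbp)
        x_hi = tumor_expr.values[gi, hi_idx]
        x_lo = tumor_expr.values[gi, lo_idx]
        stat, p = stats.ranksums(x_hi, x_lo)
        if p < alpha:
            de_sign = "higher_in_highPSI" if np.median(x_hi) > np.median(x_lo) \
                else "lower_in_highPSI"
        else:
            de_sign = "ns"
        concordant = (
            (sign == "-" and de_sign == "lower_in_highPSI")
            or (sign == "+" and de_sign == "higher_in_highPSI")
        )
        verdicts.append(ConcordanceVerdict(rbp, sign, de_sign, float(p), concordant))
    return verdicts
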