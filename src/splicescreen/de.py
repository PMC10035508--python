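"""Group-wise differential expression with FDR control and enrichment.

Gene-wise two-sided Wilcoxon rank-sum between the high- and low-PSI tumor
groups, Benjamini–Hochberg adjustment across the testable genes, a pseudo-
count log2 fold change for the volcano plot, an optional prognostic-marker
overlay, and a classic hypergeometric gene-set over-representation test
(observed/expected fold enrichment with an upper-tail p, BH across sets).

The rank-sum p-value uses exact enumeration for small groups and the
normal approximation with tie correction for larger ones; genes that are
constant across all samples are untestable and excluded from the BH family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["DifferentialExpression", "DEResults", "EnrichmentResult",
           "bh_adjust", "fisher_enrichment", "annotate_prognostic"]

EXACT_MAX_N = 25  # per-group size up to which the exact null is enumerated
LOG2FC_PSEUDOCOUNT = 1.0


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sort ascending, scale p_(i) by m/i, enforce monotonicity from the
    largest rank downwards, cap at 1, restore the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum: exact for small tie-free groups, else normal
    approximation with tie correction.  Returns (U statistic, p)."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(nx, ny) <= EXACT_MAX_N and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


class DifferentialExpression:
    """Model: expression matrix plus a high/low group labelling.

    ``fit()`` performs the gene-wise rank-sum comparison and BH adjustment
    and returns :class:`DEResults`.
    """

    def __init__(self, expr: ExpressionMatrix, groups: pd.Series):
        missing = [s for s in expr.sample_ids if s not in groups.index
                   or pd.isna(groups.get(s))]
        if missing:
            raise ValueError(f"group label missing for sample(s): {missing}")
        labels = set(groups[expr.sample_ids])
        if not labels <= {"high", "low"}:
            raise ValueError(f"group labels must be 'high'/'low', got {sorted(labels)}")
        self.expr = expr
        self.hi_idx = [i for i, s in enumerate(expr.sample_ids) if groups[s] == "high"]
        self.lo_idx = [i for i, s in enumerate(expr.sample_ids) if groups[s] == "low"]
        if len(self.hi_idx) < 2 or len(self.lo_idx) < 2:
            raise ValueError("need >=2 samples per group")

    def fit(self) -> "DEResults":
        X = self.expr.values
        rows, untestable = [], []
        eps = LOG2FC_PSEUDOCOUNT
        for gi, gene in enumerate(self.expr.gene_ids):
            x_hi, x_lo = X[gi, self.hi_idx], X[gi, self.lo_idx]
            log2fc = float(np.log2((x_hi.mean() + eps) / (x_lo.mean() + eps)))
            if np.ptp(np.concatenate([x_hi, x_lo])) == 0:
                untestable.append(gene)
                rows.append((gene, np.nan, np.nan, np.nan, log2fc))
                continue
            u, p = _ranksum_p(x_hi, x_lo)
            rows.append((gene, u, p, np.nan, log2fc))
        table = pd.DataFrame(rows, columns=["gene", "stat", "p", "p_adj", "log2fc"])
        testable = table["p"].notna()
        if testable.any():
            table.loc[testable, "p_adj"] = bh_adjust(table.loc[testable, "p"])
        table["prognosis"] = "none"
        return DEResults(table=table, untestable=untestable,
                         n_high=len(self.hi_idx), n_low=len(self.lo_idx))


@dataclass
class DEResults:
    """Gene-wise rank-sum table with BH adjustment and marker overlay."""

    table: pd.DataFrame  # gene, stat, p, p_adj, log2fc, prognosis
    untestable: list[str]
    n_high: int
    n_low: int
    method: str = "wilcoxon_ranksum+BH"

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha]

    def annotate_prognostic(self, markers: dict[str, str]) -> "DEResults":
        """Overlay favorable/unfavorable prognosis labels (in place)."""
        self.table["prognosis"] = [
            markers.get(g, "none") for g in self.table["gene"]
        ]
        bad = set(self.table["prognosis"]) - {"favorable", "unfavorable", "none"}
        if bad:
            raise ValueError(f"invalid prognosis labels: {sorted(bad)}")
        return self

    def enrichment(self, sets: GeneSetCollection, universe: set[str] | None = None,
                   alpha: float = 0.05) -> "EnrichmentResult":
        """Hypergeometric over-representation of the DE genes."""
        universe = universe if universe is not None else set(self.table["gene"])
        de_genes = set(self.significant(alpha)["gene"])
        return fisher_enrichment(de_genes, sets, universe)

    def volcano_frame(self) -> pd.DataFrame:
        df = self.table.copy()
        df["neg_log10_p_adj"] = -np.log10(df["p_adj"])
        return df[["gene", "log2fc", "neg_log10_p_adj", "prognosis"]]

    def summary(self, alpha: float = 0.05) -> str:
        sig = self.significant(alpha)
        lines = [
            "Differential expression (Wilcoxon rank-sum, BH adjusted)",
            f"  n high / low samples : {self.n_high} / {self.n_low}",
            f"  genes tested         : {int(self.table['p'].notna().sum())}",
            f"  untestable (constant): {len(self.untestable)}",
            f"  significant at BH {alpha:g}: {len(sig)} "
            f"({int((sig['log2fc'] > 0).sum())} up, "
            f"{int((sig['log2fc'] < 0).sum())} down in high group)",
        ]
        return "\n".join(lines)


def annotate_prognostic(de: DEResults, markers: dict[str, str]) -> DEResults:
    """Functional alias for :meth:`DEResults.annotate_prognostic`."""
    return de.annotate_prognostic(markers)


@dataclass
class EnrichmentResult:
    """Per-set hypergeometric over-representation (classic, BH-adjusted)."""

    table: pd.DataFrame  # set_name, k, K, n, N, fold_enrichment, p, p_adj
    method: str = "hypergeometric_classic"

    def summary(self) -> str:
        return self.table.sort_values("p").head(10).to_string(
            index=False, float_format=lambda v: f"{v:.4g}")


def fisher_enrichment(
    de_genes: set[str],
    sets: GeneSetCollection,
    universe: set[str],
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of each set against the DE genes.

    With N universe genes, K set members, n DE genes and k the overlap,
    p = P(X >= k) for X ~ Hypergeom(N, K, n), and the fold enrichment is
    the observed/expected ratio (k/n) / (K/N).
    """
    if not universe:
        raise ValueError("empty universe")
    extra = de_genes - universe
    if extra:
        raise ValueError(f"DE genes outside universe: {sorted(extra)[:5]}")
    N, n = len(universe), len(de_genes)
    rows = []
    for name in sorted(sets.sets):
        members = sets.sets[name] & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & de_genes)
        fold = (k / n) / (K / N) if n > 0 else 0.0
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n > 0 else 1.0
        rows.append((name, k, K, n, N, fold, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N",
                                        "fold_enrichment", "p"])
    table["p_adj"] = bh_adjust(table["p"]) if len(table) else []
    return EnrichmentResult(table=table)
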