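"""Sequencing-depth normalization and expressing-tissue selection.

For every sample *s* the total read count ``Ts`` is the column sum of the
count matrix.  The median read depth ``Mrd`` is the median of the retained
``Ts`` values, and each sample receives the dimensionless depth factor

    Ns = Mrd / Ts

so that multiplying a sample's counts by ``Ns`` equalises library depth:
normalized column totals all equal ``Mrd``.  Normalized expression is

    Egs = Rgs * Ns

for raw value ``Rgs`` of gene *g* in sample *s*.  Samples with a zero total
are excluded from the median and reported, never silently kept.

Tissue selection: a tissue counts as expressing a gene when the median (or
mean) of the gene's normalized expression over the tissue's samples reaches
a threshold.  The median is the default statistic because a single
high-expression outlier sample should not qualify a whole tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, JunctionCountMatrix, SampleAttributes

logger = logging.getLogger(__name__)

__all__ = ["DepthFactors", "TissueSelection", "compute_depth_factors",
           "normalize_expression", "select_expressing"]


@dataclass
class DepthFactors:
    """Per-sample depth totals and normalization factors.

    Invariants: ``ts[s] > 0`` for retained samples, ``mrd`` is the median of
    the retained totals, ``ns[s] = mrd / ts[s] > 0`` (so a sample at exactly
    median depth has factor 1).
    """

    ts: dict[str, float]
    mrd: float
    ns: dict[str, float]
    excluded_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.ts.values()):
            raise ValueError("retained sample with non-positive total")
        if any(n <= 0 for n in self.ns.values()):
            raise ValueError("non-positive normalization factor")


@dataclass
class TissueSelection:
    """Result of the expressing-tissue test for one gene."""

    gene: str
    expressing_tissues: set[str]
    expressing_samples: set[str]
    threshold_used: float
    statistic: str
    tissue_stat: dict[str, float] = field(default_factory=dict)


def compute_depth_factors(counts: JunctionCountMatrix | ExpressionMatrix) -> DepthFactors:
    """Column totals Ts, their median Mrd, and factors Ns = Mrd / Ts.

    Samples with a zero total are excluded (and listed in
    ``excluded_samples``); an all-zero matrix is an error.
    """
    if isinstance(counts, JunctionCountMatrix):
        mat, samples = counts.counts, counts.sample_ids
    else:
        mat, samples = counts.values, counts.sample_ids
    totals = np.asarray(mat, dtype=float).sum(axis=0)
    keep = totals > 0
    if not keep.any():
        raise ValueError("no usable samples: all column totals are zero")
    excluded = [s for s, k in zip(samples, keep) if not k]
    if excluded:
        logger.warning("excluding %d zero-total samples: %s", len(excluded), excluded)
    ts = {s: float(t) for s, t, k in zip(samples, totals, keep) if k}
    mrd = float(np.median(list(ts.values())))
    ns = {s: mrd / t for s, t in ts.items()}
    return DepthFactors(ts=ts, mrd=mrd, ns=ns, excluded_samples=excluded)


def normalize_expression(raw: ExpressionMatrix, factors: DepthFactors) -> ExpressionMatrix:
    """Scale each sample column by its depth factor: Egs = Rgs * Ns.

    When ``factors`` derive from the same matrix, every normalized column
    sums to Mrd (depth conservation).
    """
    missing = [s for s in raw.sample_ids if s not in factors.ns]
    if missing:
        raise ValueError(f"no depth factor for sample(s): {missing}")
    scale = np.array([factors.ns[s] for s in raw.sample_ids])
    return ExpressionMatrix(
        gene_ids=list(raw.gene_ids),
        sample_ids=list(raw.sample_ids),
        values=raw.values * scale[np.newaxis, :],
        normalized=True,
        unit=raw.unit,
    )


def select_expressing(
    expr: ExpressionMatrix,
    attrs: SampleAttributes,
    gene: str,
    threshold: float,
    statistic: str = "median",
) -> TissueSelection:
    """Select tissues (and their samples) whose per-tissue summary of the
    gene's expression reaches ``threshold``.

    An empty selection is a warning, not an error: a threshold above the
    global maximum simply selects nothing.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    vec = expr.gene_vector(gene)  # raises KeyError if absent
    common = [s for s in expr.sample_ids if s in attrs.table.index]
    dropped = len(expr.sample_ids) - len(common)
    if dropped:
        logger.warning("%d samples lack attributes and are ignored", dropped)
    if not common:
        raise ValueError("no samples shared between expression matrix and attributes")

    agg = np.median if statistic == "median" else np.mean
    tissues: set[str] = set()
    samples: set[str] = set()
    tissue_stat: dict[str, float] = {}
    for tissue in sorted(set(attrs.table.loc[common, "tissue"])):
        t_samples = [s for s in common if attrs.tissue_of(s) == tissue]
        stat = float(agg(vec[t_samples].to_numpy()))
        tissue_stat[tissue] = stat
        if stat >= threshold:
            tissues.add(tissue)
            samples.update(t_samples)
    if not tissues:
        logger.warning("no tissue reaches %s(%s) >= %g", statistic, gene, threshold)
    return TissueSelection(
        gene=gene,
        expressing_tissues=tissues,
        expressing_samples=samples,
        threshold_used=float(threshold),
        statistic=statistic,
        tissue_stat=tissue_stat,
    )
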