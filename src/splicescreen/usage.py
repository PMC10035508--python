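"""Competing-junction sets, junction usage, and event-level PSI.

Alternative terminal-exon choice is a competition between splice junctions
sharing an anchor coordinate: for the TP63 γ exon, the junctions to exon 12
and to exon 13 share one 5' splice site, and the fraction of normalized
split reads each receives among its competitors is its *usage*.  The default
competing-set mode is therefore ``shared_donor``; ``shared_acceptor``,
``either_end`` and ``whole_gene`` are provided for sensitivity analysis.

Usage of junction j in sample s:

    usage(j, s) = N_js / sum_{k in set(j)} N_ks

with N the depth-normalized read count.  When the denominator falls below
``min_coverage`` (default 8 normalized reads) the usage is *missing*, not
zero — a 0/0 event carries no information about splice choice.

PSI for an inclusion/exclusion event is reported on the 0–100 percent scale:
psi = 100 * inclusion / (inclusion + exclusion), missing below coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import JunctionCountMatrix, parse_junction_id
from .normalization import DepthFactors

logger = logging.getLogger(__name__)

__all__ = ["CompetingSets", "UsageTable", "build_competing_sets",
           "compute_junction_usage", "compute_psi", "DEFAULT_MIN_COVERAGE"]

DEFAULT_MIN_COVERAGE = 8.0

_MODES = ("shared_donor", "shared_acceptor", "either_end", "whole_gene")


@dataclass
class CompetingSets:
    """Partition of junctions into competing groups under a sharing mode."""

    mode: str
    sets: dict[str, frozenset[str]]  # junction -> its competing set (incl. itself)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        for j, grp in self.sets.items():
            if j not in grp:
                raise ValueError(f"junction {j!r} missing from its own set")

    def groups(self) -> list[frozenset[str]]:
        return sorted(set(self.sets.values()), key=lambda g: sorted(g))


@dataclass
class UsageTable:
    """Long-form per-(junction, sample) usage fractions.

    ``usage`` is NaN exactly when the competing-set denominator is below the
    coverage floor; within every covered set the usages sum to one.
    """

    table: pd.DataFrame  # columns junction_id, sample_id, usage, denominator_reads
    min_coverage: float = DEFAULT_MIN_COVERAGE
    mode: str = "shared_donor"

    def usage_vector(self, junction_id: str) -> pd.Series:
        sub = self.table[self.table["junction_id"] == junction_id]
        if sub.empty:
            raise KeyError(f"junction {junction_id!r} not in usage table")
        return pd.Series(sub["usage"].to_numpy(), index=list(sub["sample_id"]),
                         name=junction_id)

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _merge_either_end(keys: dict[str, tuple]) -> dict[str, frozenset[str]]:
    # union-find over junctions of one gene linked by a shared start or end
    parent = {j: j for j in keys}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_coord: dict[tuple, str] = {}
    for j, (chrom, start, end) in keys.items():
        for anchor in ((chrom, "s", start), (chrom, "e", end)):
            if anchor in by_coord:
                parent[find(j)] = find(by_coord[anchor])
            else:
                by_coord[anchor] = j
    groups: dict[str, set[str]] = {}
    for j in keys:
        groups.setdefault(find(j), set()).add(j)
    return {j: frozenset(grp) for grp in groups.values() for j in grp}


def build_competing_sets(junctions: JunctionCountMatrix, mode: str = "shared_donor") -> CompetingSets:
    """Group junctions that compete for the same splice site.

    Junctions compete only within one gene; a junction without a gene
    assignment becomes its own singleton set (with a warning).  Constitutive
    junctions naturally form singletons.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {_MODES}")
    coords = {j: parse_junction_id(j) for j in junctions.junction_ids}
    sets: dict[str, frozenset[str]] = {}
    by_gene: dict[str, list[str]] = {}
    for j in junctions.junction_ids:
        gene = junctions.gene_of_junction.get(j, "")
        if not gene or gene == "NA":
            logger.warning("junction %s has no gene; treated as singleton", j)
            sets[j] = frozenset({j})
        else:
            by_gene.setdefault(gene, []).append(j)

    for gene, js in by_gene.items():
        if mode == "whole_gene":
            grp = frozenset(js)
            sets.update({j: grp for j in js})
        elif mode == "either_end":
            sets.update(_merge_either_end({j: coords[j] for j in js}))
        else:
            anchor_idx = 1 if mode == "shared_donor" else 2
            by_anchor: dict[tuple, set[str]] = {}
            for j in js:
                chrom, start, end = coords[j]
                key = (chrom, (start, end)[anchor_idx - 1])
                by_anchor.setdefault(key, set()).add(j)
            for grp in by_anchor.values():
                fz = frozenset(grp)
                sets.update({j: fz for j in grp})
    return CompetingSets(mode=mode, sets=sets)


def compute_junction_usage(
    counts: JunctionCountMatrix,
    factors: DepthFactors,
    sets: CompetingSets,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> UsageTable:
    """Per-sample fraction of normalized reads within each competing set.

    Samples excluded at the depth stage (zero totals, hence no factor) get
    missing usage everywhere rather than failing the whole table.
    """
    missing = [s for s in counts.sample_ids if s not in factors.ns]
    if missing:
        logger.warning("%d samples lack depth factors (zero totals); "
                       "usage set to missing: %s", len(missing), missing[:5])
    scale = np.array([factors.ns.get(s, np.nan) for s in counts.sample_ids])
    normed = counts.counts.astype(float) * scale[np.newaxis, :]
    jindex = {j: i for i, j in enumerate(counts.junction_ids)}

    denom_of = np.zeros_like(normed)
    for grp in sets.groups():
        rows = [jindex[j] for j in grp if j in jindex]
        total = normed[rows, :].sum(axis=0)
        for r in rows:
            denom_of[r, :] = total

    with np.errstate(invalid="ignore", divide="ignore"):
        usage = np.where(denom_of >= min_coverage, normed / denom_of, np.nan)

    n_j, n_s = normed.shape
    table = pd.DataFrame({
        "junction_id": np.repeat(counts.junction_ids, n_s),
        "sample_id": np.tile(counts.sample_ids, n_j),
        "usage": usage.ravel(),
        "denominator_reads": denom_of.ravel(),
    })
    return UsageTable(table=table, min_coverage=min_coverage, mode=sets.mode)


def compute_psi(
    inclusion_reads: float,
    exclusion_reads: float,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> float:
    """Percent spliced in: 100 * inclusion / (inclusion + exclusion).

    Returns NaN (missing) when total coverage is below ``min_coverage`` —
    including the 0/0 case.  Negative read counts are an error.
    """
    if inclusion_reads < 0 or exclusion_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = inclusion_reads + exclusion_reads
    if total < min_coverage:
        return float("nan")
    return 100.0 * inclusion_reads / total
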