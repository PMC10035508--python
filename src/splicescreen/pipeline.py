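"""End-to-end conveniences chaining the pipeline stages in memory."""

from __future__ import annotations

import pandas as pd

from .io import ExpressionMatrix, JunctionCountMatrix
from .normalization import compute_depth_factors, normalize_expression
from .screen import RegulatorScreen, ScreenResults
from .usage import (DEFAULT_MIN_COVERAGE, build_competing_sets,
                    compute_junction_usage)

__all__ = ["screen_junction_regulators"]


def screen_junction_regulators(
    junctions: JunctionCountMatrix,
    expression: ExpressionMatrix,
    junction_id: str,
    exclude_genes: tuple[str, ...] = (),
    mode: str = "shared_donor",
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    log1p: bool = False,
) -> ScreenResults:
    """Junction counts + expression -> ranked regulator screen.

    Runs depth normalization on both matrices, computes competing-set usage
    for ``junction_id``, and correlates every gene in ``expression`` (minus
    ``exclude_genes``, typically the target gene itself) with that usage.
    """
    jfactors = compute_depth_factors(junctions)
    sets = build_competing_sets(junctions, mode)
    usage = compute_junction_usage(junctions, jfactors, sets, min_coverage)
    uvec = usage.usage_vector(junction_id)

    efactors = compute_depth_factors(expression)
    normed = normalize_expression(expression, efactors)
    if exclude_genes:
        keep = [i for i, g in enumerate(normed.gene_ids)
                if g not in set(exclude_genes)]
        normed = ExpressionMatrix(
            [normed.gene_ids[i] for i in keep], normed.sample_ids,
            normed.values[keep], normalized=True)
    return RegulatorScreen(normed, uvec, log1p=log1p).fit()
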