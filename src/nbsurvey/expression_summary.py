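"""Expression profiling of family members: low vs expressed calls.

Abundances (TPM or equivalent) arrive precomputed.  A gene is called
``low`` when its arithmetic mean across samples falls below a threshold
(default 1.0 TPM); everything else is ``expressed``.  A log2(x+1)
transformed matrix is returned alongside for heatmap-style plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionCall", "ExpressionSummary", "classify_expression"]


@dataclass(frozen=True)
class ExpressionCall:
    gene_id: str
    mean_abundance: float
    level: str  # low | expressed


@dataclass
class ExpressionSummary:
    calls: list[ExpressionCall]
    fraction_low: float
    missing: list[str]
    log_matrix: pd.DataFrame


def classify_expression(
    matrix: pd.DataFrame,
    nbs_ids: set[str],
    low_threshold: float = 1.0,
) -> ExpressionSummary:
    """Classify family members as low/expressed by mean abundance.

    Ids absent from the matrix are listed in ``missing`` and excluded from
    ``fraction_low``'s denominator.  Raising the threshold can only move
    genes from expressed to low (fraction_low is monotone non-decreasing).
    """
    present = sorted(nbs_ids & set(matrix.index))
    missing = sorted(nbs_ids - set(matrix.index))
    sub = matrix.loc[present]
    means = sub.mean(axis=1)
    calls = [
        ExpressionCall(
            gene_id=g,
            mean_abundance=float(means[g]),
            level="low" if means[g] < low_threshold else "expressed",
        )
        for g in present
    ]
    n_low = sum(1 for c in calls if c.level == "low")
    fraction_low = n_low / len(calls) if calls else float("nan")
    log_matrix = np.log2(sub + 1.0)
    return ExpressionSummary(
        calls=calls, fraction_low=fraction_low, missing=missing, log_matrix=log_matrix
    )
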