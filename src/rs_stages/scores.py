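"""Gene-level scores: two-sample t-statistics and their rank transform.

The pathway statistic downstream consumes *ranks* of per-gene t-statistics,
oriented tumor minus normal: the most tumor-downregulated gene gets rank 1,
the most upregulated gets rank G.  Ties receive average ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import ExpressionMatrix, PhenotypeLabels


@dataclass
class GeneScoreVector:
    """Per-gene t-statistic and its rank, aligned to the source matrix."""

    gene_ids: list[str]
    t: np.ndarray
    rank: np.ndarray | None = None


def group_stats(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-gene mean and unbiased variance over the samples selected by mask."""
    n = int(mask.sum())
    m = values[:, mask].mean(axis=1)
    v = values[:, mask].var(axis=1, ddof=1)
    return m, v, n


def t_statistics(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    *,
    equal_var: bool = True,
) -> GeneScoreVector:
    """Classical two-sample t per gene, numerator mean(tumor) - mean(normal).

    Pooled-variance (Student) t by default; ``equal_var=False`` switches to
    Welch.  A gene whose pooled variance is zero scores t = 0 when the group
    means agree, and +/-inf otherwise (with a warning); the infinities are
    harmless downstream because only ranks are consumed, where they take the
    extreme position in the direction of the mean difference.
    """
    labels.validate_against(expr)
    t = t_statistics_values(expr.values, labels.labels == 1, equal_var=equal_var)
    n_degenerate = int(np.isinf(t).sum())
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} gene(s) with zero within-group variance but nonzero "
            "mean difference; assigned extreme ranks",
            stacklevel=2,
        )
    return GeneScoreVector(list(expr.gene_ids), t)


def t_statistics_values(
    values: np.ndarray, tumor_mask: np.ndarray, *, equal_var: bool = True
) -> np.ndarray:
    """Vectorised t over a genes x samples array given a boolean tumor mask.

    This is the permutation-loop workhorse: no container validation, no
    warnings, suitable for thousands of calls.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    m1, v1, n1 = _mv(values, tumor_mask)
    m0, v0, n0 = _mv(values, ~tumor_mask)
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        else:
            se = np.sqrt(v1 / n1 + v0 / n0)
        t = diff / se
    # zero variance, zero difference -> 0; zero variance, nonzero diff -> +/-inf
    t = np.where((se == 0) & (diff == 0), 0.0, t)
    signed_inf = np.where(diff > 0, np.inf, -np.inf)
    t = np.where((se == 0) & (diff != 0), signed_inf, t)
    return t


def _mv(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n = int(mask.sum())
    sub = values[:, mask]
    m = sub.mean(axis=1)
    v = sub.var(axis=1, ddof=1)
    return m, v, n


def rank_scores(scores: GeneScoreVector) -> GeneScoreVector:
    """Ascending average-tie ranks of t: downregulated -> 1, upregulated -> G."""
    scores.rank = rankdata(scores.t, method="average")
    return scores


def rank_values(t: np.ndarray) -> np.ndarray:
    """Bare rank transform used inside permutation loops."""
    return rankdata(t, method="average")
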