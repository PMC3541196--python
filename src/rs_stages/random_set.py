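"""The random-set (RS) enrichment statistic.

A pathway's score is the mean gene-level score (here: rank of the two-sample
t-statistic) over its n members present on the array.  Under the null that
the pathway is indistinguishable from n genes drawn at random from the array
without replacement, the mean has exact closed-form moments:

    mu0      = mean of the G gene-level scores,
    sigma0^2 = (population variance of the scores) * (G - n) / ((G - 1) * n).

For untied ranks 1..G these reduce to mu0 = (G+1)/2 and
sigma0^2 = (G+1)(G-n)/(12 n).  The standardised statistic
z = (xbar - mu0) / sigma0 is approximately Gaussian; its sign carries the
direction (positive = tumor-upregulated set, negative = downregulated).

Moments are always computed from the realised score vector, so average-tie
ranks are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .scores import GeneScoreVector


@dataclass
class RSScore:
    set_name: str
    effective_n: int
    xbar: float
    mu0: float
    sigma0: float
    z: float


def rs_null_moments(gene_scores: np.ndarray, n: int) -> tuple[float, float]:
    """Exact null mean and SD of the mean of n scores drawn without replacement.

    Raises for n = 0 and for n = G (zero-variance degenerate null).
    """
    scores = np.asarray(gene_scores, dtype=float)
    G = scores.size
    if n < 1:
        raise ValueError("set size n must be >= 1")
    if n >= G:
        raise ValueError(f"degenerate null: zero variance (n={n}, G={G})")
    mu0 = scores.mean()
    pop_var = scores.var(ddof=0)
    sigma0_sq = pop_var * (G - n) / ((G - 1) * n)
    return float(mu0), float(np.sqrt(sigma0_sq))


def rs_score(scores: GeneScoreVector, members: list[str], set_name: str = "") -> RSScore | None:
    """RS z-score of one gene set against ranked gene-level scores.

    Members absent from the array are dropped first; n in the null moments is
    the effective (intersected) size.  Returns None (with no score) for an
    empty intersection — the caller logs and skips.
    """
    if scores.rank is None:
        raise ValueError("scores must be ranked first (rank_scores)")
    idx_map = {g: i for i, g in enumerate(scores.gene_ids)}
    idx = [idx_map[m] for m in dict.fromkeys(members) if m in idx_map]
    if not idx:
        return None
    n = len(idx)
    xbar = float(scores.rank[idx].mean())
    mu0, sigma0 = rs_null_moments(scores.rank, n)
    return RSScore(set_name, n, xbar, mu0, sigma0, (xbar - mu0) / sigma0)


def rs_z_values(rank: np.ndarray, membership, sizes: np.ndarray) -> np.ndarray:
    """Vectorised z for all sets at once.

    ``membership`` is a (sets x genes) sparse indicator over the array;
    ``sizes`` its row sums (effective n).  Used by the permutation engine,
    where this runs once per label permutation.
    """
    G = rank.size
    mu0 = rank.mean()
    pop_var = rank.var(ddof=0)
    xbar = np.asarray(membership @ rank).ravel() / sizes
    sigma0 = np.sqrt(pop_var * (G - sizes) / ((G - 1.0) * sizes))
    return (xbar - mu0) / sigma0


def rs_gaussian_pvalue(z: float) -> float:
    """One-sided standard-normal tail p in the direction of z.

    Auxiliary diagnostic only — the headline p comes from phenotype-label
    permutation.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(norm.sf(z) if z > 0 else norm.cdf(z) if z < 0 else 0.5)
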