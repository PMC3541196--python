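"""GSEA-style cross-check and cross-list concordance statistics.

An independent enrichment arm: the weighted Kolmogorov-Smirnov running-sum
enrichment score (ES) with phenotype-label permutation p-values, used to
corroborate the RS calls.  Alongside it live the concordance statistics for
comparing enriched-pathway lists: Fisher-exact overlap of two lists over a
set universe, and the one-tailed comparison of mean set sizes between the
up- and down-regulated tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection, PhenotypeLabels
from .scores import t_statistics_values


@dataclass
class GSEAResult:
    set_name: str
    effective_n: int
    ES: float
    p: float
    direction: str


@dataclass
class OverlapStat:
    universe: int
    size_a: int
    size_b: int
    overlap: int
    fraction: float  # overlap relative to list A
    p: float  # one-sided hypergeometric upper tail


def gsea_enrichment_score(
    metric: np.ndarray, hit: np.ndarray, q: float = 1.0
) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``metric`` is the gene-level score vector (any order; genes are walked
    in decreasing metric order), ``hit`` a boolean membership vector aligned
    to it.  Hits increment by |metric|^q normalised to sum 1 over the hits;
    misses decrement by 1/(G - n).  At q = 0 this is the classic two-sample
    KS statistic between hit and miss positions.
    """
    metric = np.asarray(metric, dtype=float)
    hit = np.asarray(hit, dtype=bool)
    G = metric.size
    n = int(hit.sum())
    if n == 0:
        raise ValueError("set has no members in the ranked list")
    if n == G:
        raise ValueError("set covers the whole list; miss decrement undefined")
    order = np.argsort(-metric, kind="stable")
    hit_sorted = hit[order]
    w = np.abs(metric[order]) ** q
    w = np.where(hit_sorted, w, 0.0)
    total = w.sum()
    if total == 0:  # all hit weights zero (q>0, zero metrics): fall back to equal
        w = hit_sorted.astype(float)
        total = w.sum()
    running = np.cumsum(np.where(hit_sorted, w / total, -1.0 / (G - n)))
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _es_all_sets(
    metric: np.ndarray, membership_lists: list[np.ndarray], q: float
) -> np.ndarray:
    """ES for many sets sharing one ranked list (one argsort, then O(n) each)."""
    G = metric.size
    order = np.argsort(-metric, kind="stable")
    pos_of_gene = np.empty(G, dtype=int)
    pos_of_gene[order] = np.arange(G)
    w_sorted = np.abs(metric[order]) ** q
    out = np.empty(len(membership_lists))
    for k, gene_idx in enumerate(membership_lists):
        n = gene_idx.size
        pos = np.sort(pos_of_gene[gene_idx])
        w = w_sorted[pos]
        total = w.sum()
        if total == 0:
            w = np.ones(n)
            total = float(n)
        cum_hit = np.cumsum(w) / total
        miss = 1.0 / (G - n)
        # candidate extremes: just after each hit, and just before each hit
        after = cum_hit - (pos + 1 - np.arange(1, n + 1)) * miss
        before = np.r_[0.0, cum_hit[:-1]] - (pos - np.arange(n)) * miss
        cand = np.r_[after, before]
        out[k] = cand[np.argmax(np.abs(cand))]
    return out


def signal_to_noise(values: np.ndarray, tumor_mask: np.ndarray) -> np.ndarray:
    """Per-gene (mean_tumor - mean_normal) / (sd_tumor + sd_normal)."""
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    m1 = values[:, tumor_mask].mean(axis=1)
    m0 = values[:, ~tumor_mask].mean(axis=1)
    s1 = values[:, tumor_mask].std(axis=1, ddof=1)
    s0 = values[:, ~tumor_mask].std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2n = (m1 - m0) / (s1 + s0)
    return np.where(np.isfinite(s2n), s2n, 0.0)


def gsea_pvalues(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    sets: GeneSetCollection,
    B: int = 1000,
    seed: int = 0,
    *,
    q: float = 1.0,
    alpha: float = 0.05,
    metric: str = "s2n",
) -> list[GSEAResult]:
    """ES plus label-permutation p per set.

    The permutation p follows the standard sign-matched convention: a
    positive observed ES is compared with the positive permuted ES only
    (and mirrored for negative), which keeps the null p uniform on (0, 1).
    ``metric`` is "s2n" (signal-to-noise, the usual default) or "t"
    (pooled two-sample t, for symmetry with the RS arm).
    """
    labels.validate_against(expr)
    if metric not in ("s2n", "t"):
        raise ValueError("metric must be 's2n' or 't'")

    def gene_metric(tumor_mask: np.ndarray) -> np.ndarray:
        if metric == "s2n":
            return signal_to_noise(expr.values, tumor_mask)
        t = t_statistics_values(expr.values, tumor_mask)
        return np.where(np.isfinite(t), t, np.sign(t) * 1e12)

    gene_idx = expr.gene_index()
    names, member_lists = [], []
    for name, members in sets:
        idx = np.array([gene_idx[m] for m in members if m in gene_idx], dtype=int)
        if idx.size == 0 or idx.size == expr.n_genes:
            continue
        names.append(name)
        member_lists.append(idx)
    if not names:
        return []

    tumor = labels.labels == 1
    es_obs = _es_all_sets(gene_metric(tumor), member_lists, q)

    rng = np.random.default_rng(seed)
    n_samples = expr.n_samples
    n_tumor = int(tumor.sum())
    hits = np.zeros(len(names))
    same_sign = np.zeros(len(names))
    for _ in range(B):
        perm = np.zeros(n_samples, dtype=bool)
        perm[rng.permutation(n_samples)[:n_tumor]] = True
        es_b = _es_all_sets(gene_metric(perm), member_lists, q)
        pos = es_b > 0
        match = np.where(es_obs > 0, pos, ~pos)
        same_sign += match
        hits += match & (np.abs(es_b) >= np.abs(es_obs))
    with np.errstate(invalid="ignore"):
        p = np.where(same_sign > 0, hits / np.maximum(same_sign, 1), 1.0)

    out = []
    for k, name in enumerate(names):
        direction = "up" if (es_obs[k] > 0 and p[k] < alpha) else (
            "down" if (es_obs[k] < 0 and p[k] < alpha) else "none"
        )
        out.append(
            GSEAResult(name, member_lists[k].size, float(es_obs[k]), float(p[k]), direction)
        )
    return out


def overlap_fisher(
    list_a: list[str], list_b: list[str], universe_size: int
) -> OverlapStat:
    """One-sided Fisher-exact (hypergeometric upper tail) overlap of two lists.

    The fraction is the overlap relative to list A.  ``universe_size`` is
    the number of sets tested in both analyses (880 for within-study
    comparisons over the canonical-pathway collection).
    """
    a, b = set(list_a), set(list_b)
    if universe_size < len(a | b):
        raise ValueError("universe smaller than the union of the two lists")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return OverlapStat(universe_size, len(a), len(b), k, k / len(a) if a else 0.0, p)


def overlap_fisher_counts(
    universe_size: int, size_a: int, size_b: int, overlap: int
) -> OverlapStat:
    """Overlap statistic straight from the 2x2 margins (for published counts)."""
    if overlap > min(size_a, size_b):
        raise ValueError("overlap exceeds a list size")
    if universe_size < size_a + size_b - overlap:
        raise ValueError("universe smaller than the union of the two lists")
    p = float(stats.hypergeom.sf(overlap - 1, universe_size, size_a, size_b))
    return OverlapStat(universe_size, size_a, size_b, overlap,
                       overlap / size_a if size_a else 0.0, p)


def setsize_comparison(
    sizes_up: np.ndarray, sizes_down: np.ndarray
) -> tuple[float, float, float]:
    """(mean_up, mean_down, one-tailed p) for 'downregulated sets are larger'.

    Pooled two-sample t with alternative mean_down > mean_up.
    """
    up = np.asarray(sizes_up, dtype=float)
    down = np.asarray(sizes_down, dtype=float)
    if up.size == 0 or down.size == 0:
        raise ValueError("both size vectors must be non-empty")
    res = stats.ttest_ind(down, up, equal_var=True, alternative="greater")
    return float(up.mean()), float(down.mean()), float(res.pvalue)
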