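"""GSEA running-sum cross-check and list-concordance statistics."""

import math

import numpy as np
import pytest

from rs_stages import (
    PermutationConfig,
    gsea_enrichment_score,
    gsea_pvalues,
    overlap_fisher,
    overlap_fisher_counts,
    permutation_pvalues,
    reference_tables,
    setsize_comparison,
)


def brute_force_es(metric, hit, q):
    """Direct O(G) walk of the running sum (the oracle)."""
    order = np.argsort(-np.asarray(metric), kind="stable")
    hit = np.asarray(hit, dtype=bool)[order]
    w = np.abs(np.asarray(metric, dtype=float)[order]) ** q
    nr = w[hit].sum()
    G, n = hit.size, int(hit.sum())
    running, best = 0.0, 0.0
    for i in range(G):
        running += w[i] / nr if hit[i] else -1.0 / (G - n)
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def test_top_two_of_four_unweighted(self):
        es = gsea_enrichment_score(
            np.array([4.0, 3, 2, 1]), np.array([True, True, False, False]), q=0)
        assert es == 1.0

    def test_whole_list_set_rejected(self):
        with pytest.raises(ValueError, match="whole list"):
            gsea_enrichment_score(np.arange(4.0), np.ones(4, bool))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            gsea_enrichment_score(np.arange(4.0), np.zeros(4, bool))

    def test_interleaved_set_bound(self):
        # evenly interleaved hits with equal weights: |ES| <= 1/n + 1/(G-n)
        G = 20
        hit = np.zeros(G, bool)
        hit[::2] = True
        es = gsea_enrichment_score(np.arange(G, 0, -1, dtype=float), hit, q=0)
        n = hit.sum()
        assert abs(es) <= 1 / n + 1 / (G - n) + 1e-12

    @pytest.mark.parametrize("q", [0.0, 1.0, 2.0])
    def test_matches_brute_force_walk(self, q):
        rng = np.random.default_rng(17)
        for _ in range(20):
            G = rng.integers(5, 40)
            metric = rng.normal(size=G)
            hit = np.zeros(G, bool)
            hit[rng.choice(G, size=rng.integers(1, G), replace=False)] = True
            es = gsea_enrichment_score(metric, hit, q=q)
            assert es == pytest.approx(brute_force_es(metric, hit, q), abs=1e-12)

    def test_q0_reduces_to_two_sample_ks(self):
        # at q=0 with untied metrics the ES is the signed KS distance between
        # hit-position and miss-position empirical CDFs
        rng = np.random.default_rng(23)
        for _ in range(10):
            G = int(rng.integers(8, 30))
            metric = rng.permutation(G).astype(float)
            hit = np.zeros(G, bool)
            hit[rng.choice(G, size=int(rng.integers(2, G - 1)), replace=False)] = True
            es = gsea_enrichment_score(metric, hit, q=0)
            order = np.argsort(-metric)
            pos_hit = np.where(hit[order])[0]
            pos_miss = np.where(~hit[order])[0]
            # KS distance between the two position samples
            grid = np.arange(G)
            F_hit = np.searchsorted(pos_hit, grid, side="right") / pos_hit.size
            F_miss = np.searchsorted(pos_miss, grid, side="right") / pos_miss.size
            ks = np.max(np.abs(F_hit - F_miss))
            assert abs(es) == pytest.approx(ks, abs=1e-12)


class TestGseaPvalues:
    def test_planted_set_recovered(self, planted_dataset):
        expr, labels, sets, _ = planted_dataset
        res = {r.set_name: r for r in gsea_pvalues(expr, labels, sets,
                                                   B=100, seed=3)}
        assert res["set000"].ES > 0 and res["set000"].p < 0.05
        assert res["set001"].ES < 0 and res["set001"].p < 0.05

    def test_fixed_seed_deterministic(self, planted_dataset):
        expr, labels, sets, _ = planted_dataset
        a = gsea_pvalues(expr, labels, sets, B=50, seed=9)
        b = gsea_pvalues(expr, labels, sets, B=50, seed=9)
        assert [(r.set_name, r.ES, r.p) for r in a] == \
               [(r.set_name, r.ES, r.p) for r in b]

    def test_es_bounded(self, planted_dataset):
        expr, labels, sets, _ = planted_dataset
        for r in gsea_pvalues(expr, labels, sets, B=20, seed=1):
            assert -1 <= r.ES <= 1

    def test_direction_agrees_with_rs_on_planted_sets(self, planted_dataset):
        expr, labels, sets, _ = planted_dataset
        rs = {r.set_name: r for r in permutation_pvalues(
            expr, labels, sets, PermutationConfig(B=100, seed=4))}
        gs = {r.set_name: r for r in gsea_pvalues(expr, labels, sets,
                                                  B=100, seed=4)}
        for name in ("set000", "set001"):
            assert np.sign(rs[name].z) == np.sign(gs[name].ES)


def log_factorial_hypergeom_tail(N, K, n, k):
    """Independent upper-tail oracle via lgamma sums."""

    def lchoose(a, b):
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.exp(lchoose(K, i) + lchoose(N - K, n - i) - lchoose(N, n))
    return total


class TestOverlap:
    def test_identical_lists(self):
        a = [f"p{i}" for i in range(10)]
        stat = overlap_fisher(a, a, universe_size=100)
        assert stat.fraction == 1.0
        assert stat.p == pytest.approx(
            log_factorial_hypergeom_tail(100, 10, 10, 10), rel=1e-9)

    def test_disjoint_lists_near_one(self):
        a = [f"a{i}" for i in range(5)]
        b = [f"b{i}" for i in range(5)]
        assert overlap_fisher(a, b, universe_size=1000).p == pytest.approx(1.0, abs=1e-6)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_fisher([f"a{i}" for i in range(5)],
                           [f"b{i}" for i in range(5)], universe_size=8)

    def test_published_margins_agree_with_log_factorial_oracle(self):
        # 33 upregulated pathways vs 107 in an independent CRC dataset,
        # 24 shared over a universe of 880 canonical pathways
        stat = overlap_fisher_counts(880, 33, 107, 24)
        assert round(100 * stat.fraction) == 73
        oracle = log_factorial_hypergeom_tail(880, 33, 107, 24)
        assert stat.p == pytest.approx(oracle, rel=1e-10)

    def test_counts_and_list_interfaces_agree(self):
        universe = [f"p{i}" for i in range(50)]
        a, b = universe[:12], universe[6:26]
        stat_l = overlap_fisher(a, b, 50)
        stat_c = overlap_fisher_counts(50, 12, 20, 6)
        assert stat_l.p == pytest.approx(stat_c.p, rel=1e-12)


class TestSetSizeComparison:
    def test_reference_tables_reproduce_published_means(self):
        up, down = reference_tables()
        mean_up, mean_down, p = setsize_comparison(
            up.table["n"].to_numpy(), down.table["n"].to_numpy())
        assert mean_up == pytest.approx(27.9, abs=0.05)
        assert mean_down == pytest.approx(69.0, abs=0.05)
        assert p == pytest.approx(2.4e-4, rel=0.05)

    def test_identical_vectors_give_half(self):
        x = np.array([10.0, 20, 30, 40])
        _, _, p = setsize_comparison(x, x.copy())
        assert p == pytest.approx(0.5)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            setsize_comparison(np.array([]), np.array([1.0]))
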