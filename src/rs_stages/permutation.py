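"""Phenotype-label permutation null and nominal p-values for RS scores.

Significance is decided by shuffling the sample class labels B times
(default 1000) and recomputing the entire statistic — t, ranks and the
per-set z — inside every permutation.  Shuffling labels rather than genes
preserves inter-gene correlation, which is why these p-values stay valid
when set members are co-expressed (where the analytic Gaussian null would
not be).  One shared stream of label permutations scores every set, so the
run is seed-stable and single-pass.

The default p-value is the two-sided permutation tail on |z|
(#{b : |z_b| >= |z_obs|} / B), with the direction of the call taken from
sign(z_obs).  Under an exchangeable null this p is uniform on (0, 1), so a
0.05 gate spends 0.05 of type-I error in total across the up and down
tables.  The one-sided tail in the observed direction (same numerator
restricted to the observed sign, still / B) is available via
``sided="directional"``; note its null distribution is uniform on (0, 0.5),
so gating it at alpha doubles the false-call rate.  The plug-in estimator
b/B (which can be exactly 0) is the default; ``estimator="smoothed"`` gives
(b+1)/(B+1), which can never be 0 and is the better choice when p-values
feed downstream multiplicity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, GeneSetCollection, PhenotypeLabels
from .random_set import rs_gaussian_pvalue, rs_z_values
from .scores import rank_values, t_statistics_values


@dataclass
class PermutationConfig:
    """Knobs of the permutation test.

    B: number of label permutations (study default 1000).
    alpha: nominal significance gate (study default 0.05).
    estimator: "plugin" (b/B) or "smoothed" ((b+1)/(B+1)).
    sided: "two" (default; tail on |z|) or "directional" (tail in the
        direction of the observed z).
    equal_var: pooled (True) vs Welch (False) gene-level t.
    """

    B: int = 1000
    seed: int = 0
    alpha: float = 0.05
    estimator: str = "plugin"
    sided: str = "two"
    equal_var: bool = True

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.estimator not in ("plugin", "smoothed"):
            raise ValueError("estimator must be 'plugin' or 'smoothed'")
        if self.sided not in ("two", "directional"):
            raise ValueError("sided must be 'two' or 'directional'")
        if self.B < 100:
            import warnings

            warnings.warn(
                f"B={self.B} permutations cannot resolve p-values near "
                f"alpha={self.alpha}; use B >= 100",
                stacklevel=2,
            )


@dataclass
class EnrichmentResult:
    """Per-set outcome of one stage contrast."""

    set_name: str
    effective_n: int
    z: float
    p: float
    direction: str  # up / down / none
    p_gaussian: float = field(default=float("nan"))


def enrichment_call(z: float, p: float, alpha: float = 0.05) -> str:
    """up if z > 0 and p < alpha, down if z < 0 and p < alpha, else none."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < alpha and z > 0:
        return "up"
    if p < alpha and z < 0:
        return "down"
    return "none"


def permutation_pvalues(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    sets: GeneSetCollection,
    config: PermutationConfig | None = None,
) -> list[EnrichmentResult]:
    """Nominal permutation p-value and direction call for every gene set.

    Deterministic given ``config.seed``.  Sets with empty intersection with
    the array are skipped (warning logged by the collection).
    """
    config = config or PermutationConfig()
    labels.validate_against(expr)
    names, membership = sets.membership_matrix(expr)
    if not names:
        return []
    sizes = np.asarray(membership.sum(axis=1)).ravel()
    values = expr.values
    tumor = labels.labels == 1

    z_obs = rs_z_values(
        rank_values(t_statistics_values(values, tumor, equal_var=config.equal_var)),
        membership,
        sizes,
    )

    rng = np.random.default_rng(config.seed)
    n_samples = values.shape[1]
    exceed_two = np.zeros(len(names))
    exceed_dir = np.zeros(len(names))
    for _ in range(config.B):
        perm_tumor = np.zeros(n_samples, dtype=bool)
        perm_tumor[rng.permutation(n_samples)[: tumor.sum()]] = True
        t_b = t_statistics_values(values, perm_tumor, equal_var=config.equal_var)
        z_b = rs_z_values(rank_values(t_b), membership, sizes)
        exceed_two += np.abs(z_b) >= np.abs(z_obs)
        exceed_dir += np.where(z_obs >= 0, z_b >= z_obs, z_b <= z_obs)

    exceed = exceed_two if config.sided == "two" else exceed_dir
    if config.estimator == "plugin":
        p = exceed / config.B
    else:
        p = (exceed + 1.0) / (config.B + 1.0)

    return [
        EnrichmentResult(
            set_name=name,
            effective_n=int(sizes[i]),
            z=float(z_obs[i]),
            p=float(p[i]),
            direction=enrichment_call(z_obs[i], p[i], config.alpha),
            p_gaussian=rs_gaussian_pvalue(float(z_obs[i])),
        )
        for i, name in enumerate(names)
    ]


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values, reported alongside but never gating the calls."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
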