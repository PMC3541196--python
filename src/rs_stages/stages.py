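"""Stage orchestration: three contrasts, trajectories, Venn partition,
and the clustering/PCA diagnostics.

Each tumor stage (SPL, LPL, CRC) is compared against the shared normal
samples with the full RS + permutation machinery; the per-stage direction
calls are then assembled into a per-pathway trajectory and partitioned into
the seven non-empty Venn cells per direction.  Sample-level diagnostics for
a single pathway — two-cluster Ward agglomeration and a 2-D PCA projection
— quantify how well that pathway's genes alone separate tumor from normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .io import (
    STAGES,
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeLabels,
    ResultTable,
    results_from_calls,
)
from .permutation import EnrichmentResult, PermutationConfig, permutation_pvalues

VENN_CELLS = (
    "SPL only",
    "LPL only",
    "CRC only",
    "SPL+LPL",
    "SPL+CRC",
    "LPL+CRC",
    "SPL+LPL+CRC",
)


def run_stage_contrast(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    sets: GeneSetCollection,
    config: PermutationConfig | None = None,
) -> list[EnrichmentResult]:
    """One normal-vs-stage enrichment pass (the permutation-engine contract)."""
    return permutation_pvalues(expr, labels, sets, config)


def trajectory_table(
    per_stage: dict[str, list[EnrichmentResult]],
) -> ResultTable:
    """Combine three stage contrasts into one per-pathway trajectory table."""
    names: list[str] = []
    effective_n: dict[str, int] = {}
    calls: dict[str, dict[str, tuple[float, str]]] = {s: {} for s in STAGES}
    for stage, results in per_stage.items():
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        for r in results:
            if r.set_name not in effective_n:
                names.append(r.set_name)
                effective_n[r.set_name] = r.effective_n
            calls[stage][r.set_name] = (r.p, r.direction)
    return results_from_calls(names, effective_n, calls)


def venn_cell(directions: tuple[str, str, str], direction: str) -> str | None:
    """Venn cell of one pathway for one direction, or None if never called."""
    present = [s for s, d in zip(STAGES, directions) if d == direction]
    if not present:
        return None
    return "+".join(present) if len(present) > 1 else f"{present[0]} only"


def venn_counts(trajectories: ResultTable) -> pd.DataFrame:
    """2 x 7 table of pathway counts per direction and Venn cell.

    Marginals per stage equal the per-stage significant counts by
    construction (each significant pathway lands in exactly one cell).
    """
    counts = pd.DataFrame(0, index=["up", "down"], columns=list(VENN_CELLS))
    for _, row in trajectories.table.iterrows():
        dirs = tuple(row[f"dir_{s}"] for s in STAGES)
        for direction in ("up", "down"):
            cell = venn_cell(dirs, direction)
            if cell is not None:
                counts.loc[direction, cell] += 1
    return counts


def venn_stage_marginals(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-stage significant counts implied by the Venn partition."""
    out = pd.DataFrame(0, index=counts.index, columns=list(STAGES))
    for stage in STAGES:
        cells = [c for c in VENN_CELLS if stage in c]
        out[stage] = counts[cells].sum(axis=1)
    return out


@dataclass
class ClusterDiagnostic:
    """Two-cluster Ward split of samples on one pathway's genes."""

    assignment: np.ndarray  # per-sample cluster in {0, 1}
    misclassified: int  # min mismatch vs labels over the two relabelings


def cluster_diagnostic(
    expr: ExpressionMatrix, labels: PhenotypeLabels
) -> ClusterDiagnostic:
    """Agglomerate samples (Euclidean, Ward's inner-squared-distance linkage),
    cut into two clusters, and count label mismatches minimised over the two
    cluster-to-label assignments.

    ``expr`` should already be restricted to the pathway's genes (>= 2).
    The agglomeration is deterministic; distance ties resolve by the
    ordering of the condensed distance matrix (lowest pair index first).
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples to cluster")
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes")
    X = expr.values.T  # samples x genes
    Z = linkage(pdist(X, metric="euclidean"), method="ward")
    assignment = fcluster(Z, t=2, criterion="maxclust") - 1
    y = labels.labels
    mis = min(int((assignment != y).sum()), int((1 - assignment != y).sum()))
    return ClusterDiagnostic(assignment, mis)


@dataclass
class PCAProjection:
    coordinates: np.ndarray  # samples x 2
    explained: tuple[float, float]  # variance fractions of PC1, PC2


def pca_projection(expr: ExpressionMatrix) -> PCAProjection:
    """Project samples onto the first two principal components.

    Genes are the features and are mean-centered (so the projection is
    invariant to per-gene location shifts); explained fractions are relative
    to the total variance of the centered data.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes")
    X = expr.values.T
    if np.allclose(X, X[0]):
        raise ValueError("constant matrix: PCA undefined")
    pca = PCA(n_components=2)
    coords = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    return PCAProjection(coords, (float(frac[0]), float(frac[1])))
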