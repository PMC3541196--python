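"""Synthetic two-group expression data with planted pathway enrichment.

The generator emulates the structure the analysis assumes downstream of
array preprocessing: a genes x samples matrix of log2-scale intensities with
Gaussian noise around per-gene baselines, a normal and a tumor group, and a
collection of gene sets of heterogeneous sizes.  Selected sets are
"planted": a fraction f of their members has the tumor-group mean shifted by
delta noise-SDs up or down, giving known ground truth against which the
whole pipeline (scores, RS z, permutation p, direction calls, trajectories)
can be validated.

Per-gene baselines are drawn Uniform(4, 12) on the log2 scale to mimic
typical array intensity ranges; the choice is cosmetic — every downstream
statistic is location-invariant per gene.

Genes are independent by default.  ``correlation`` > 0 adds an
equicorrelated within-set component (one shared latent factor per set),
under which the analytic Gaussian null for the mean rank is too narrow but
the phenotype-permutation null remains valid — the reason permutation
p-values are the headline numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    PhenotypeLabels,
    write_cls,
    write_expression,
    write_gmt,
)


@dataclass
class PlantedSet:
    """One gene set carrying a planted signal."""

    set_index: int
    direction: str  # "up" or "down"
    delta: float  # effect size in units of noise SD
    fraction: float = 1.0  # fraction of members shifted

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class SimulationConfig:
    """Study-shaped defaults: G=2000 genes, 30 normal + 30 tumor samples,
    50 sets with sizes spanning the heterogeneous 8-400 range of curated
    pathway collections, unit noise SD."""

    G: int = 2000
    n_normal: int = 30
    n_tumor: int = 30
    n_sets: int = 50
    set_size_range: tuple[int, int] = (8, 400)
    planted: list[PlantedSet] = field(default_factory=list)
    noise_sd: float = 1.0
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must lie in [0, 1)")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi <= self.G:
            raise ValueError("set sizes must satisfy 1 <= lo <= hi <= G")
        for p in self.planted:
            if not 0 <= p.set_index < self.n_sets:
                raise ValueError(f"planted set index {p.set_index} out of range")


@dataclass
class GroundTruth:
    """What was planted: per-set direction and per-gene true mean shift."""

    set_direction: dict[str, str]  # set name -> up / down / none
    gene_shift: np.ndarray  # per gene, tumor-mean shift in log2 units


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, PhenotypeLabels, GeneSetCollection, GroundTruth]:
    """Simulate one dataset; fully reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    G, S = config.G, config.n_normal + config.n_tumor
    gene_ids = [f"g{i:05d}" for i in range(G)]
    sample_ids = [f"N{i:03d}" for i in range(config.n_normal)] + [
        f"T{i:03d}" for i in range(config.n_tumor)
    ]
    labels = np.r_[np.zeros(config.n_normal, int), np.ones(config.n_tumor, int)]

    # membership sampled without replacement within each set
    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_sets)
    member_idx = [rng.choice(G, size=sz, replace=False) for sz in sizes]
    sets = GeneSetCollection(
        {
            f"set{k:03d}": [gene_ids[i] for i in idx]
            for k, idx in enumerate(member_idx)
        }
    )

    shift = np.zeros(G)
    set_direction = {name: "none" for name in sets.names()}
    for p in config.planted:
        idx = member_idx[p.set_index]
        n_shift = int(np.ceil(p.fraction * idx.size))
        chosen = rng.choice(idx, size=n_shift, replace=False)
        sign = 1.0 if p.direction == "up" else -1.0
        shift[chosen] += sign * p.delta * config.noise_sd
        name = f"set{p.set_index:03d}"
        if p.delta > 0:
            set_direction[name] = p.direction

    baseline = rng.uniform(4.0, 12.0, size=G)
    noise = rng.normal(0.0, 1.0, size=(G, S))
    if config.correlation > 0:
        # one latent factor per set, shared by its members (equicorrelation)
        factors = rng.normal(0.0, 1.0, size=(config.n_sets, S))
        w = np.sqrt(config.correlation)
        for k, idx in enumerate(member_idx):
            noise[idx] = w * factors[k] + np.sqrt(1 - config.correlation) * noise[idx]
    values = baseline[:, None] + config.noise_sd * noise
    values[:, labels == 1] += shift[:, None]

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    pheno = PhenotypeLabels(sample_ids, labels)
    return expr, pheno, sets, GroundTruth(set_direction, shift)


@dataclass
class StageDataset:
    """One shared gene universe measured across N + SPL + LPL + CRC samples.

    ``contrast(stage)`` returns the (matrix, labels) pair for one normal-vs-
    stage comparison, sharing the normal samples across the three contrasts
    the way the study design does.
    """

    expr: ExpressionMatrix
    stage_samples: dict[str, list[str]]
    normal_samples: list[str]
    sets: GeneSetCollection
    truth: dict[str, GroundTruth]

    def contrast(self, stage: str) -> tuple[ExpressionMatrix, PhenotypeLabels]:
        cols = self.normal_samples + self.stage_samples[stage]
        col_idx = [self.expr.sample_ids.index(s) for s in cols]
        sub = ExpressionMatrix(self.expr.gene_ids, cols, self.expr.values[:, col_idx])
        labels = np.r_[
            np.zeros(len(self.normal_samples), int),
            np.ones(len(self.stage_samples[stage]), int),
        ]
        return sub, PhenotypeLabels(cols, labels, stage=stage)


def generate_stage_dataset(
    config: SimulationConfig,
    planted_by_stage: dict[str, list[PlantedSet]],
    n_per_stage: int | None = None,
) -> StageDataset:
    """Three-stage design: shared normals, per-stage tumor groups and signals.

    Stage keys are SPL/LPL/CRC; ``planted_by_stage[stage]`` lists the sets
    planted in that stage's tumor samples only, so trajectories like
    (none, none, up) have a knowable truth.
    """
    stages = ("SPL", "LPL", "CRC")
    rng = np.random.default_rng(config.seed)
    n_t = n_per_stage or config.n_tumor
    G = config.G
    gene_ids = [f"g{i:05d}" for i in range(G)]
    normal = [f"N{i:03d}" for i in range(config.n_normal)]
    stage_samples = {st: [f"{st}{i:03d}" for i in range(n_t)] for st in stages}
    sample_ids = normal + [s for st in stages for s in stage_samples[st]]

    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_sets)
    member_idx = [rng.choice(G, size=sz, replace=False) for sz in sizes]
    sets = GeneSetCollection(
        {f"set{k:03d}": [gene_ids[i] for i in idx] for k, idx in enumerate(member_idx)}
    )

    baseline = rng.uniform(4.0, 12.0, size=G)
    values = baseline[:, None] + config.noise_sd * rng.normal(
        0.0, 1.0, size=(G, len(sample_ids))
    )

    truth: dict[str, GroundTruth] = {}
    offset = len(normal)
    for st in stages:
        shift = np.zeros(G)
        set_direction = {name: "none" for name in sets.names()}
        for p in planted_by_stage.get(st, []):
            if not 0 <= p.set_index < config.n_sets:
                raise ValueError(f"planted set index {p.set_index} out of range")
            idx = member_idx[p.set_index]
            n_shift = int(np.ceil(p.fraction * idx.size))
            chosen = rng.choice(idx, size=n_shift, replace=False)
            sign = 1.0 if p.direction == "up" else -1.0
            shift[chosen] += sign * p.delta * config.noise_sd
            if p.delta > 0:
                set_direction[f"set{p.set_index:03d}"] = p.direction
        values[:, offset : offset + n_t] += shift[:, None]
        truth[st] = GroundTruth(set_direction, shift)
        offset += n_t

    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    return StageDataset(expr, stage_samples, normal, sets, truth)


def export_dataset(
    expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    sets: GeneSetCollection,
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write GCT + CLS + GMT plus a ground-truth TSV into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(expr, out / "expression.gct")
    write_cls(labels, out / "phenotype.cls")
    write_gmt(sets, out / "sets.gmt")
    pd.DataFrame(
        {"gene_id": expr.gene_ids, "true_shift": truth.gene_shift}
    ).to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.set_direction.items()), columns=["set", "direction"]
    ).to_csv(out / "truth_sets.tsv", sep="\t", index=False)
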