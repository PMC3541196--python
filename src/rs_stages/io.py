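"""Data containers and readers/writers for the standard expression-analysis formats.

The pipeline speaks the Broad text dialects that pathway-analysis tools have
standardised on: GCT 1.2 (log-scale expression matrices), CLS (binary sample
phenotypes), GMT (named gene sets, one per line) — plus plain TSV for both
expression and result tables.  Membership between gene sets and the array is
resolved by exact string match on identifiers; no symbol-mapping layer exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("SPL", "LPL", "CRC")
DIRECTIONS = ("up", "down", "none")


class FormatError(ValueError):
    """A file violated the expected dialect or failed validation."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of finite log-scale intensities.

    ``values[i, j]`` is the log intensity of ``gene_ids[i]`` in
    ``sample_ids[j]``.  Identifiers must be unique and every cell finite;
    upstream RMA-style summarisation leaves no missing values, so none are
    tolerated here.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise FormatError(f"duplicate gene identifiers: {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample identifiers")
        if self.n_genes < 2:
            raise FormatError("need at least 2 genes")
        if self.n_samples < 4:
            raise FormatError("need at least 4 samples")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PhenotypeLabels:
    """Binary class per sample (0 = normal mucosa, 1 = tumor) plus a stage tag."""

    sample_ids: list[str]
    labels: np.ndarray
    stage: str = "CRC"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise FormatError("one label per sample required")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise FormatError("labels must be 0 (normal) or 1 (tumor)")
        if (self.labels == 0).sum() < 2 or (self.labels == 1).sum() < 2:
            raise FormatError("each class needs at least 2 samples")
        if self.stage not in STAGES:
            raise FormatError(f"stage must be one of {STAGES}, got {self.stage!r}")

    @property
    def n_normal(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def n_tumor(self) -> int:
        return int((self.labels == 1).sum())

    def validate_against(self, expr: ExpressionMatrix) -> None:
        """Require exact, ordered agreement with the matrix's samples."""
        if self.sample_ids != expr.sample_ids:
            raise FormatError(
                "phenotype sample order does not match the expression matrix"
            )


@dataclass
class GeneSetCollection:
    """Named gene sets; members are de-duplicated identifier lists."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))
            dropped = len(members) - len(uniq)
            if dropped:
                logger.warning("set %s: dropped %d duplicate member(s)", name, dropped)
            if not uniq:
                logger.warning("set %s has no members; skipped", name)
                continue
            cleaned[name] = uniq
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def names(self) -> list[str]:
        return list(self.sets)

    def effective_sizes(self, expr: ExpressionMatrix) -> dict[str, int]:
        """Distinct members present on the array — the n of every null formula."""
        on_array = set(expr.gene_ids)
        return {name: len(on_array.intersection(m)) for name, m in self.sets.items()}

    def membership_matrix(self, expr: ExpressionMatrix):
        """Sparse CSR (sets x genes) indicator over the array, plus row order.

        Sets with empty intersection are dropped (with a warning) so every
        retained row has effective size >= 1.
        """
        from scipy import sparse

        gene_idx = expr.gene_index()
        rows, cols = [], []
        names = []
        for name, members in self.sets.items():
            hit = [gene_idx[m] for m in members if m in gene_idx]
            if not hit:
                logger.warning("set %s has empty intersection with array; skipped", name)
                continue
            r = len(names)
            names.append(name)
            rows.extend([r] * len(hit))
            cols.extend(hit)
        mat = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(names), expr.n_genes),
        )
        return names, mat


# ---------------------------------------------------------------------------
# result tables

RESULT_COLUMNS = ["pathway", "n", "p_SPL", "p_LPL", "p_CRC",
                  "dir_SPL", "dir_LPL", "dir_CRC"]


@dataclass
class ResultTable:
    """Per-pathway per-stage nominal p-values and direction calls.

    ``table`` has columns ``pathway, n, p_SPL, p_LPL, p_CRC, dir_SPL,
    dir_LPL, dir_CRC``; a missing p (NaN) means "not significant at that
    stage" and is rendered as "-" on disk.  A reported p implies a non-none
    direction at that stage.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in RESULT_COLUMNS:
            if col not in df.columns:
                if col.startswith("dir_"):
                    stage = col[4:]
                    df[col] = np.where(df[f"p_{stage}"].notna(), "up", "none")
                else:
                    raise FormatError(f"result table missing column {col!r}")
        df = df[RESULT_COLUMNS].reset_index(drop=True)
        for stage in STAGES:
            p = df[f"p_{stage}"]
            if ((p < 0) | (p > 1)).any():
                raise FormatError("p-values must lie in [0, 1]")
            bad_dir = ~df[f"dir_{stage}"].isin(DIRECTIONS)
            if bad_dir.any():
                raise FormatError(f"bad direction values: {df.loc[bad_dir, f'dir_{stage}'].tolist()}")
            if (p.notna() & (df[f"dir_{stage}"] == "none")).any():
                raise FormatError("a reported p-value implies a non-none direction")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    def stage_counts(self) -> dict[str, int]:
        """Significant pathways per stage (p present)."""
        return {s: int(self.table[f"p_{s}"].notna().sum()) for s in STAGES}

    def sorted(self) -> "ResultTable":
        """Stable sort by (first significant stage, p-value at that stage)."""
        df = self.table.copy()
        pcols = [f"p_{s}" for s in STAGES]
        first = df[pcols].notna().to_numpy().argmax(axis=1)
        first[~df[pcols].notna().any(axis=1).to_numpy()] = len(STAGES)
        firstp = np.array(
            [df.iloc[i][pcols[j]] if j < len(STAGES) else np.inf
             for i, j in enumerate(first)]
        )
        order = np.lexsort((firstp, first))
        return ResultTable(df.iloc[order].reset_index(drop=True))


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        (dup if x in seen else seen).add(x)
    return dup


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read a GCT 1.2 or plain TSV expression matrix.

    The format is inferred from the extension unless given explicitly.
    TSV layout: first column gene identifiers, remaining columns samples.
    """
    path = Path(path)
    if format is None:
        format = "GCT" if path.suffix.lower() == ".gct" else "TSV"
    format = format.upper()
    if format == "GCT":
        return _read_gct(path)
    if format == "TSV":
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return _frame_to_matrix(df, path)
    raise FormatError(f"unknown expression format {format!r}")


def _read_gct(path: Path) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise FormatError(f"{path}: malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if list(df.columns[:2]) != ["Name", "Description"]:
        raise FormatError(f"{path}: GCT header must start with Name\\tDescription")
    if len(df) != n_genes or df.shape[1] - 2 != n_samples:
        raise FormatError(
            f"{path}: dimensions line says {n_genes}x{n_samples}, "
            f"found {len(df)}x{df.shape[1] - 2}"
        )
    df = df.drop(columns="Description").set_index("Name")
    return _frame_to_matrix(df, path)


def _frame_to_matrix(df: pd.DataFrame, path: Path) -> ExpressionMatrix:
    dupes = _duplicates(df.index.astype(str))
    if dupes:
        raise FormatError(f"{path}: duplicate gene identifiers: {sorted(dupes)}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna()
    if bad.to_numpy().any() or numeric.isna().to_numpy().any():
        isna = numeric.isna().to_numpy()
        i, j = np.argwhere(isna)[0]
        raise FormatError(
            f"{path}: non-numeric or missing value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=numeric.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     format: str | None = None) -> None:
    """Write GCT 1.2 or TSV; inverse of :func:`read_expression`."""
    path = Path(path)
    if format is None:
        format = "GCT" if path.suffix.lower() == ".gct" else "TSV"
    format = format.upper()
    df = expr.to_frame()
    if format == "GCT":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.n_genes}\t{expr.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", float_format="%.17g")
    elif format == "TSV":
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.17g")
    else:
        raise FormatError(f"unknown expression format {format!r}")


_NORMAL_NAMES = {"n", "normal", "norm", "0", "control", "ctrl"}


def read_cls(path: str | Path, sample_ids: Sequence[str] | None = None,
             stage: str = "CRC") -> PhenotypeLabels:
    """Read a two-class CLS file, mapping the normal-mucosa class to 0.

    CLS layout: ``<S> <classes> 1`` header, ``# name0 name1`` class-name
    line, then one label per sample (class names or 0/1 indices).  The class
    whose name looks like normal mucosa (N/NORMAL/CONTROL, case-insensitive)
    becomes 0 regardless of its position on the name line.
    """
    path = Path(path)
    lines = [ln.strip() for ln in open(path) if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs header, class-name line, label line")
    header = lines[0].split()
    n_samples, n_classes = int(header[0]), int(header[1])
    if n_classes != 2:
        raise FormatError(f"{path}: expected 2 classes, header says {n_classes}")
    if not lines[1].startswith("#"):
        raise FormatError(f"{path}: second line must be '# name0 name1'")
    class_names = lines[1][1:].split()
    if len(class_names) != 2:
        raise FormatError(f"{path}: expected 2 class names, got {class_names}")
    tokens = " ".join(lines[2:]).split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}: header says {n_samples} samples, label line has {len(tokens)}"
        )
    if set(tokens) <= {"0", "1"}:
        labels = np.array([int(t) for t in tokens])
    else:
        by_name = {name: i for i, name in enumerate(class_names)}
        try:
            labels = np.array([by_name[t] for t in tokens])
        except KeyError as exc:
            raise FormatError(f"{path}: label {exc} not among class names") from exc
    # orient: normal-mucosa-looking class -> 0
    if class_names[1].lower() in _NORMAL_NAMES and class_names[0].lower() not in _NORMAL_NAMES:
        labels = 1 - labels
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: {len(sample_ids)} sample ids supplied for {n_samples} labels"
        )
    return PhenotypeLabels(list(sample_ids), labels, stage=stage)


def read_cls_classes(path: str | Path,
                     sample_ids: Sequence[str] | None = None) -> dict[str, str]:
    """Read a CLS with any number of classes; returns sample -> class name.

    Used for multi-stage designs where one CLS carries N/SPL/LPL/CRC classes
    and each contrast subsets to normal + one stage.
    """
    path = Path(path)
    lines = [ln.strip() for ln in open(path) if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS needs header, class-name line, label line")
    header = lines[0].split()
    n_samples, n_classes = int(header[0]), int(header[1])
    if not lines[1].startswith("#"):
        raise FormatError(f"{path}: second line must name the classes")
    class_names = lines[1][1:].split()
    if len(class_names) != n_classes:
        raise FormatError(
            f"{path}: header says {n_classes} classes, names line has "
            f"{len(class_names)}"
        )
    tokens = " ".join(lines[2:]).split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}: header says {n_samples} samples, label line has {len(tokens)}"
        )
    if set(tokens) <= {str(i) for i in range(n_classes)} and not (
        set(tokens) & set(class_names)
    ):
        classes = [class_names[int(t)] for t in tokens]
    else:
        unknown = set(tokens) - set(class_names)
        if unknown:
            raise FormatError(f"{path}: labels {sorted(unknown)} not among class names")
        classes = tokens
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: {len(sample_ids)} sample ids supplied for {n_samples} labels"
        )
    return dict(zip(sample_ids, classes))


def write_cls(labels: PhenotypeLabels, path: str | Path,
              class_names: tuple[str, str] = ("N", "T")) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(labels.sample_ids)} 2 1\n")
        fh.write(f"# {class_names[0]} {class_names[1]}\n")
        fh.write(" ".join(class_names[v] for v in labels.labels) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT collection: per line, name, description (ignored), members."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(open(path), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: GMT line needs name and description")
        name, members = fields[0], [m for m in fields[2:] if m]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        if not members:
            logger.warning("%s:%d: set %s has no members; skipped", path, lineno, name)
            continue
        sets[name] = members
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            fh.write("\t".join([name, "na", *members]) + "\n")


def write_result_table(results: ResultTable, path: str | Path) -> None:
    """Write the per-pathway stage table, '-' for non-significant cells.

    Rows are stable-sorted by (first significant stage, p-value), the layout
    of the study's printed up/down tables.
    """
    df = results.sorted().table.copy()
    for s in STAGES:
        df[f"p_{s}"] = df[f"p_{s}"].map(lambda p: "-" if pd.isna(p) else _fmt_p(p))
    df.to_csv(path, sep="\t", index=False)


def _fmt_p(p: float) -> str:
    return repr(float(p))  # shortest exact round-trip decimal


def read_result_table(path: str | Path) -> ResultTable:
    df = pd.read_csv(path, sep="\t", na_values="-", float_precision="round_trip",
                     dtype={f"dir_{s}": str for s in STAGES})
    return ResultTable(df)


def results_from_calls(
    names: Sequence[str],
    effective_n: Mapping[str, int],
    per_stage: Mapping[str, Mapping[str, tuple[float, str]]],
) -> ResultTable:
    """Assemble a ResultTable from per-stage {name: (p, direction)} calls.

    A p-value is reported (kept non-NaN) only where the direction call is
    significant, mirroring the printed tables.
    """
    rows = []
    for name in names:
        row: dict[str, object] = {"pathway": name, "n": effective_n[name]}
        for stage in STAGES:
            p, direction = per_stage.get(stage, {}).get(name, (np.nan, "none"))
            row[f"dir_{stage}"] = direction
            row[f"p_{stage}"] = p if direction != "none" else np.nan
        rows.append(row)
    return ResultTable(pd.DataFrame(rows))
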