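"""Packaged reference result tables from the colorectal progression study.

Two tables of pathway-level outcomes are shipped with the package: the
canonical pathways called tumor-upregulated and tumor-downregulated at one
or more of the three stage contrasts (normal vs SPL, LPL, CRC), each with
its RefSeq count n and the nominal permutation p-value per stage ("-" where
the pathway was not significant at that stage).  They serve as ground truth
for the reporting layer (per-stage counts, Venn trajectories, set-size
comparison) and as realistic fixtures for the I/O round-trip tests.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .io import ResultTable

_DATA = resources.files("rs_stages") / "data"


def _load(name: str, direction: str) -> ResultTable:
    with (_DATA / name).open() as fh:
        df = pd.read_csv(fh, sep="\t", na_values="-")
    for stage in ("SPL", "LPL", "CRC"):
        df[f"dir_{stage}"] = np.where(df[f"p_{stage}"].notna(), direction, "none")
    return ResultTable(df)


def reference_tables() -> tuple[ResultTable, ResultTable]:
    """(upregulated, downregulated) reference pathway tables.

    The upregulated table has 49 pathways, the downregulated 63; per-stage
    significant counts are 23/21/33 (up) and 41/29/25 (down) for SPL/LPL/CRC.
    """
    return (
        _load("upregulated_pathways.tsv", "up"),
        _load("downregulated_pathways.tsv", "down"),
    )
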