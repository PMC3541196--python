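"""Summarise the packaged reference tables of stage-wise pathway calls.

The two tables list the canonical pathways found tumor-upregulated and
-downregulated at the SPL/LPL/CRC stages of colorectal tumorigenesis.  This
script recomputes the headline summaries: per-stage counts, the Venn
marginals, and the comparison of gene-set sizes between the two directions
(downregulated pathways are markedly larger).
"""

import pandas as pd

import rs_stages as rs

up, down = rs.reference_tables()
print(f"{len(up)} upregulated and {len(down)} downregulated pathways "
      f"({len(up) + len(down)} total)")
print("per-stage counts (SPL/LPL/CRC):")
print(f"  up:   {list(up.stage_counts().values())}")
print(f"  down: {list(down.stage_counts().values())}")

merged = rs.ResultTable(pd.concat([up.table, down.table], ignore_index=True))
venn = rs.venn_counts(merged)
print("\nVenn partition of the calls:")
print(venn.to_string())

mean_up, mean_down, p = rs.setsize_comparison(
    up.table["n"].to_numpy(), down.table["n"].to_numpy())
print(f"\nmean set size: up {mean_up:.1f} vs down {mean_down:.1f} RefSeqs")
print(f"one-tailed pooled t-test (down > up): p = {p:.2e}")
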