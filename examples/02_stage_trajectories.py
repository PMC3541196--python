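"""Run all three tumor-stage contrasts and report cross-stage trajectories.

Builds a shared gene universe measured in normal mucosa plus three tumor
groups (SPL, LPL, CRC), plants one set upregulated only at the invasive
stage and one downregulated throughout, and reports each pathway's
direction call per stage plus the Venn partition of the calls.
"""

import rs_stages as rs

config = rs.SimulationConfig(G=1000, n_normal=20, n_tumor=20, n_sets=10,
                             set_size_range=(15, 60), seed=7)
dataset = rs.generate_stage_dataset(config, {
    "CRC": [rs.PlantedSet(0, "up", 2.0, 1.0),
            rs.PlantedSet(1, "down", 2.0, 1.0)],
    "LPL": [rs.PlantedSet(1, "down", 2.0, 1.0)],
    "SPL": [rs.PlantedSet(1, "down", 2.0, 1.0)],
})

per_stage = {}
for stage in ("SPL", "LPL", "CRC"):
    expr, labels = dataset.contrast(stage)
    per_stage[stage] = rs.run_stage_contrast(
        expr, labels, dataset.sets,
        rs.PermutationConfig(B=500, seed=7, alpha=0.01))

trajectories = rs.trajectory_table(per_stage)
called = trajectories.table[
    (trajectories.table[["dir_SPL", "dir_LPL", "dir_CRC"]] != "none").any(axis=1)]
print("pathways with at least one significant stage (alpha=0.01):")
print(called[["pathway", "n", "dir_SPL", "dir_LPL", "dir_CRC"]].to_string(index=False))

venn = rs.venn_counts(trajectories)
print("\nVenn cells with pathways:")
print(venn.loc[:, (venn != 0).any()].to_string())
print("\nset000 was planted up only in CRC; set001 down at every stage.")
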