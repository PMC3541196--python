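"""Sample-level diagnostics for a single enriched pathway: Ward clustering
and PCA of the samples using only that pathway's genes.

A pathway that truly separates tumor from normal should yield a two-cluster
split that matches the class labels, and a 2-D principal-component map in
which the classes occupy distinct regions.
"""

import numpy as np

import rs_stages as rs

config = rs.SimulationConfig(
    G=1000, n_normal=25, n_tumor=25, n_sets=5, set_size_range=(22, 22),
    planted=[rs.PlantedSet(0, "up", 2.0, 1.0)], seed=12)
expr, labels, sets, _ = rs.generate_dataset(config)

for name in ("set000", "set001"):  # planted vs null pathway
    idx = [expr.gene_index()[g] for g in sets.sets[name]]
    sub = rs.ExpressionMatrix(
        [expr.gene_ids[i] for i in idx], expr.sample_ids, expr.values[idx])
    diag = rs.cluster_diagnostic(sub, labels)
    proj = rs.pca_projection(sub)
    sep = np.mean(proj.coordinates[labels.labels == 1, 0]) - \
        np.mean(proj.coordinates[labels.labels == 0, 0])
    print(f"{name}: {diag.misclassified}/{expr.n_samples} samples misclassified "
          f"by the 2-cluster Ward split; PC1+PC2 explain "
          f"{100 * sum(proj.explained):.0f}% of variance; "
          f"tumor-normal separation along PC1 = {abs(sep):.1f}")
print("\nset000 carries a planted 2-SD signal; set001 is null.")
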