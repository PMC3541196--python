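"""Simulate a two-group expression dataset with planted pathway signals and
run the random-set enrichment test on it.

Plants one upregulated and one downregulated gene set (effect 2 noise-SDs in
every member) among 20 sets, then scores all sets: the RS z measures how far
each set's mean t-statistic rank sits from its random-set expectation, and
the permutation p decides significance.  Expect the two planted sets at
p = 0 with the correct sign and everything else mostly non-significant.
"""

import rs_stages as rs

config = rs.SimulationConfig(
    G=2000, n_normal=30, n_tumor=30, n_sets=20, set_size_range=(10, 100),
    planted=[rs.PlantedSet(0, "up", 2.0, 1.0),
             rs.PlantedSet(1, "down", 2.0, 1.0)],
    seed=42,
)
expr, labels, sets, truth = rs.generate_dataset(config)
results = rs.permutation_pvalues(
    expr, labels, sets, rs.PermutationConfig(B=1000, seed=42))

print(f"{'set':<8} {'n':>4} {'z':>7} {'p':>7}  call   planted")
for r in sorted(results, key=lambda r: r.p)[:6]:
    planted = truth.set_direction[r.set_name]
    print(f"{r.set_name:<8} {r.effective_n:>4} {r.z:>7.2f} {r.p:>7.3f}  "
          f"{r.direction:<6} {planted}")

n_sig = sum(r.direction != "none" for r in results)
print(f"\n{n_sig} of {len(results)} sets significant at alpha=0.05 "
      f"(2 planted; null sets false-positive at ~5%)")
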