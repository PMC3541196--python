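# Methods

## Model and procedure

The pipeline tests, for each gene set C in a collection, whether C is
enriched for genes differentially expressed between two sample classes
(normal mucosa vs tumor), and does so independently for each of three
tumor-progression stages (SPL, LPL, CRC) against a shared pool of normal
samples.

Gene-level evidence is the classical two-sample t-statistic per gene,
oriented tumor minus normal, computed with pooled variance. The t values
are rank-transformed (ascending, average ties), and the pathway statistic
is the mean rank of the set's members present on the array. The null model
is *random set membership*: C is compared with hypothetical sets of the
same effective size n drawn uniformly without replacement from the G array
genes. The mean of n draws without replacement from a finite population has
exact moments μ₀ = mean of the scores and
σ₀² = Var(scores) · (G − n)/((G − 1)n); the standardized
z = (x̄ − μ₀)/σ₀ is approximately Gaussian by a finite-population CLT.
Moments are always computed from the realized score vector rather than the
closed-form untied-rank expressions, so average-tie ranks are handled
exactly; the two agree when no ties exist (verified by enumeration in the
test suite).

Two nulls coexist deliberately. The analytic standardization (the z)
encodes the random-set comparison; statistical significance is decided by a
second, phenotype-label permutation null: labels are shuffled B times
(default 1000) and t, ranks and z are recomputed inside every permutation.
Label permutation preserves the inter-gene correlation structure, under
which the analytic Gaussian null for the mean rank is too narrow (set
members are co-expressed in real data); the simulator's block-correlation
option exists precisely to let tests demonstrate this. One shared stream of
label permutations scores all sets in a contrast, which makes results
seed-stable and keeps the run single-pass.

## The p-value convention

The reported nominal p is the permutation tail on the *magnitude*:
p = #{b : |z_b| ≥ |z_obs|}/B, with the direction of the call taken from
sign(z_obs) and a gate of p < α (default 0.05): up if z_obs > 0, down if
z_obs < 0. Under an exchangeable null this p is uniform on (0, 1), so the
α gate spends α of type-I error in total across the up and down calls —
the calibration the acceptance suite verifies (measured null false-call
rate 0.051 at α = 0.05 with 2000 sets).

The alternative convention — the one-sided tail in the observed direction
with the same denominator, #{b : z_b ≥ z_obs}/B for z_obs > 0 — is
available via `PermutationConfig(sided="directional")`. It is *not* the
default because its null distribution is uniform on (0, 0.5): gating it at
α doubles the realized false-call rate to ≈ 2α. The two conventions agree
on strong signals (both hit the plug-in floor p = 0).

The plug-in estimator b/B is the default so that complete separation is
reported as p = 0, matching how such results are conventionally printed;
the smoothed (b + 1)/(B + 1) estimator (never zero, slightly conservative)
is available and is the right choice when p-values feed multiplicity
corrections. A Benjamini–Hochberg helper is provided but never gates the
calls; the headline analysis uses nominal p at 0.05.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| B | 1000 | label permutations; resolution of p is 1/B, so B ≥ 100 is enforced by warning |
| α | 0.05 | nominal per-stage gate for up/down calls |
| equal_var | True | pooled (Student) vs Welch gene-level t |
| sided | "two" | permutation tail convention (see above) |
| estimator | "plugin" | b/B vs smoothed (b+1)/(B+1) |
| min/max set size | none | no size filter is applied by default — the reference tables include sets from n = 8 up to n = 400, and the implementation reproduces that inclusion behavior |

Pooled variance is the default t flavor because it is the textbook
two-sample default (and the default of the numerical environment the
original analysis used); Welch is a switch because the choice is
config-sensitive and neither is canonical for rank-based downstream use.
Degenerate genes (zero within-group variance) score t = 0 when the means
agree and ±∞ otherwise; the infinities are deliberate — only ranks enter
the pathway statistic, and ±∞ takes the extreme rank in the direction of
the mean difference, with a warning.

Effective set size n is always the size of the intersection between the
set's members and the array's identifiers (exact string match; no symbol
mapping is built, since identifier mapping tables are external data).
Sets with empty intersection are skipped with a warning. Missing expression
values are rejected rather than imputed: upstream array summarization
produces complete matrices, so a missing cell indicates a broken file.

## The GSEA cross-check

The validation arm implements the weighted Kolmogorov–Smirnov running-sum
score: genes are walked in decreasing order of a gene-level metric
(signal-to-noise by default; pooled t available for symmetry with the RS
arm), set members increment the sum by |metric|^q normalized over the hits
(q = 1 default), non-members decrement by 1/(G − n); the enrichment score
ES is the signed maximum deviation. At q = 0 with untied metrics ES reduces
exactly to the two-sample KS statistic between hit and miss positions
(property-tested against a brute-force walk). Significance again comes from
label permutations, with the standard sign-matched convention (a positive
observed ES is compared against the positive permuted ES only), which keeps
the null p uniform on (0, 1). FDR q-values, gene-tag permutation and
leading-edge analysis are out of scope.

List concordance between methods or datasets is quantified by the one-sided
Fisher exact test: the hypergeometric upper tail of the observed overlap
given the two list sizes and a universe of tested sets (880 for
within-study comparisons; configurable, since the appropriate universe for
cross-platform comparisons is genuinely ambiguous). The set-size comparison
between up- and down-regulated tables is a pooled two-sample t with the
one-tailed alternative "downregulated sets are larger".

## Stage reports and diagnostics

Each stage contrast is an independent run of the permutation engine against
the shared normals. Per-pathway direction calls across the three stages
form a trajectory; for each direction the trajectory maps to one of the 7
non-empty Venn cells (stage singletons, pairs, and the triple), and cell
counts conserve the per-stage significant counts by construction.

Sample-level diagnostics restrict the matrix to one pathway's genes:
(1) agglomerative clustering of samples (Euclidean distance, Ward's
minimum-variance linkage — the "inner squared distance" criterion), cut at
two clusters, scored by the label mismatch minimized over the two
cluster-to-class assignments; (2) PCA of the samples with genes as
(mean-centered) features, reporting the first two component coordinates and
their explained-variance fractions. The agglomeration is deterministic;
equal-cost merges resolve by the ordering of the condensed distance matrix.

## The synthetic-data generator

`generate_dataset` emulates what the analysis assumes about its input:
log2-scale intensities, Gaussian noise (SD 1 by default) around per-gene
baselines drawn Uniform(4, 12), two classes of 30 samples each, 50 sets
with sizes drawn from 8–400 (the size heterogeneity of curated canonical-
pathway collections), membership sampled without replacement. Planting
shifts the tumor-class mean of a chosen fraction f of a set's members by
±δ noise-SDs. `generate_stage_dataset` extends this to the three-stage
design with shared normals and per-stage planted signals, so trajectory
recovery has a knowable truth.

What the simulator does **not** emulate: probe-level structure, batch and
array effects, heavy-tailed or intensity-dependent noise, correlated
baselines between overlapping sets, and histology covariates. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under its stated model, not that any biological conclusion transfers to a
particular real dataset.

## Problem sizes used in the checks

The calibration check uses G = 2000 genes, 30 + 30 samples, 2000 random
sets and B = 200 permutations; power checks use G = 1000, a planted set of
n = 20 at δ = 2, f = 1 with 50 replicates at B = 100, plus three 3-point
monotonicity sweeps (δ ∈ {0.2, 0.6, 1.8}, f ∈ {0.2, 0.5, 1.0},
n ∈ {5, 20, 80}) at 50 replicates each. These sizes give binomial standard
errors small enough for 3-SE acceptance bands while keeping the full suite
fast on a single core.

## Known limitations

- Exact string matching of identifiers means collections and matrices must
  share an identifier space; no annotation layer is provided.
- The plug-in p = 0 understates uncertainty (its one-sided 95% bound at
  B = 1000 is ≈ 0.003); use the smoothed estimator when that matters.
- Permutations are sampled uniformly and independently (no uniqueness
  enforcement, identity permutation not deliberately included) — standard
  Monte-Carlo practice; with the sample sizes involved, collisions are
  immaterial.
- The Gaussian tail p (`rs_gaussian_pvalue`) is a diagnostic; under
  correlated expression it is anticonservative and should not gate calls.
- Cross-platform overlap p-values depend on the chosen universe; 880 is the
  right universe only when both analyses tested the same 880 sets.
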