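# Methods

## The analysis model

The package treats a microbial survey as a pair of tables: an OTU × sample
abundance matrix (counts or relative abundances, samples as columns) and a
per-sample environment table. All inference happens between *distance
matrices* derived from these tables, so the assumptions are those of the
distance-based toolkit: community structure is summarized by Bray–Curtis
dissimilarity of (filtered, relative-abundance) OTU profiles; environmental
structure by Euclidean distance over unit-norm-scaled variable blocks; and
association between matrices by permutation tests that assume
exchangeability of samples under the null.

Co-occurrence edges are Spearman correlations between OTU profiles computed
on Hellinger-transformed abundances. With only ~11 samples these
correlations are noisy, which is exactly why the conventional double gate is
used — an edge needs both a large effect (|ρ| > 0.7, strict) and
significance (p < 0.01, strict). At n = 11 the t approximation makes the
effective threshold |ρ| ≳ 0.735, i.e. the significance gate is slightly
stricter than the strength gate.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `abundance_threshold` | 1e-4 | keep OTUs with mean relative abundance strictly above 0.01% |
| `filter_mode` | `mean_across_samples` | aggregation for the filter (`overall` pools all samples) |
| `rho_threshold` | 0.7 | strength gate on \|ρ\| (strict >) |
| `p_threshold` | 0.01 | significance gate (strict <) |
| `pvalue_method` | `t_approx` | ρ·√((n−2)/(1−ρ²)) with n−2 df, two-sided; `exact_perm` enumerates all n! rank permutations for n ≤ 8, samples otherwise |
| `modular_structure_q` | 0.4 | Q above which a network is called modular |
| `major_module_min_nodes` | 16 | "more than 15 nodes" |
| `n_permutations` | 999 | Mantel / PERMANOVA permutations; p = (1 + #extreme)/(1 + n_perm), so p ≥ 1/1000 |
| `env_normalize_margin` | `per_sample` | unit-Euclidean-norm scaling margin for the 13 environment variables |
| `rng_seed` | 0 | single run seed; every stage derives its own substream |

The preprocessing order is fixed: relative abundance → filter → Hellinger.
Filtering and transforming do not commute once totals change, so the
Hellinger step always uses the totals of the table it receives, and module
sub-tables are never renormalized.

## Design choices

- **Module detection** uses seeded Louvain modularity maximization on a
  canonically ordered copy of the graph (deterministic given the seed,
  invariant to node input order). Greedy CNM-style agglomeration was
  evaluated first and found path-dependent on dense signed networks: it
  locks in early cross-module merges and returns partitions with *lower* Q
  than the planted grouping, while Louvain's local-moving phase recovers
  partitions with higher Q and much better planted-truth agreement. Q is
  always reported from the package's own per-community formula
  (unsigned, unweighted; negative edges count as connections), and module
  membership from any modularity heuristic is configuration-dependent — on
  real data, different tools will produce different rosters.
- **P-values for edges** default to the t approximation; at n = 11 it
  tracks the permutation null closely near the 0.01 gate (verified against
  10⁵-draw permutation p-values), and a permutation option remains for
  sensitivity analysis. No multiple-testing correction is applied to the
  OTU-pair p-values by default, matching common practice for descriptive
  co-occurrence networks; a Benjamini–Hochberg flag exists and is off.
- **Characteristic path length** is the median over nodes of each node's
  mean unweighted shortest-path length *within its component*; disconnected
  pairs are excluded (and logged). Degree-deficient nodes contribute 0 to
  the mean clustering coefficient (configurable), matching the common
  network-analyzer convention.
- **Mantel tests** are one-sided (greater), the convention of the vegan
  lineage these analyses come from. Partial Mantel permutes the second
  matrix while holding the first and the covariate fixed, recomputing the
  two affected correlations per permutation.
- **PERMANOVA between modules** needs an observation unit; comparing
  modules *within one community* leaves only one consistent construction —
  observations are OTUs, each represented by its across-sample abundance
  profile, with Bray–Curtis distances between profiles and module
  membership as the grouping.
- **Geographic distance** uses the haversine great-circle formula with the
  mean Earth radius (6371.0088 km); at the ~10-km scale of a stream survey
  the difference from full ellipsoidal geodesics is far below the noise.
- **Sample alignment**: whenever a community is missing samples (the
  fungal preset drops one, mirroring a failed library), every cross-matrix
  test first intersects sample ids (keeping the first argument's order)
  and logs what was dropped.

## The synthetic-data generator

The generator emulates the *processed* layer of a glacier-fed stream
survey; there is no sequencing-error or phylogenetic realism.

- A latent gradient g (11 evenly spaced samples + jitter) drives the
  environment table: GD, NDVI, pH, Cond, DOC increase with g; GA, GS,
  elevation decrease; the five nutrient variables are independent noise;
  coordinates lie on a line so geographic distance tracks sample order.
- Every OTU belongs to one planted module. Module m has a shared latent
  profile f_m = (effect · mult_m · dir_m) · g̃ + idio · w_m, where g̃ is the
  standardized gradient and w_m a module-specific standardized random walk
  **shuffled across samples**. The shuffle makes w_m exchangeable with
  respect to g — a raw walk over gradient-ordered samples would correlate
  with the gradient by drift and break the null for non-responsive
  modules. Responsive modules differ in sensitivity (multipliers 1.2, 1.0,
  0.8, 0.9) and alternate direction, which keeps between-module
  correlations below the edge threshold while the community aggregate
  still tracks g. OTU i adds a lognormal baseline (a_i, sd 1.2) and
  per-OTU noise (sd 0.75); counts are multinomial at fixed depth 20,000.
- Presets: `bacteria_like` (400 OTUs, 5 modules, 4 responsive, effect 1.25,
  module-idiosyncratic weights 1.3/1.5) yields a dense, connected,
  environment-driven network; `fungi_like` (150 OTUs, 6 modules, exactly
  one responsive with a strong gradient share — effect 1.6, idiosyncratic
  0.55 — noise modules at 2.1, one sample dropped) yields a sparser, more
  clustered network whose community-level dissimilarity does *not* track
  the gradient while the responsive module's does. The variance budget was
  chosen so the planted claims hold with margin at n = 11: within-module
  latent correlations ≈ 0.85–0.9, between-module ≲ 0.45, community-level
  Mantel power ≈ 0.95 (bacteria) and responsive-module power ≈ 0.85
  (fungi) at 999 permutations.

What passing tests on these data do **not** show: robustness to
compositional artifacts (no zero-replacement or log-ratio handling),
uneven sequencing depth (a flag exists but defaults off), phylogenetic
correlation among OTUs, or the behavior of module detection under the
specific clustering tool another study may have used.

## Numerical conventions

- Permutation counts use the +1 numerator/denominator correction;
  comparisons use a 1e-12 tie tolerance in favor of the null.
- Spearman is Pearson on midranks; constant profiles give NaN correlations,
  which can never become edges (and are warned about).
- PERMANOVA with zero within-group sum of squares returns F = ∞, R² = 1.
- Bray–Curtis between two all-zero profiles is undefined; it is set to 0
  with a warning.
- All randomized stages draw from `numpy` Generators seeded from the single
  run seed via named SeedSequence substreams; identical config + seed gives
  byte-identical outputs.

## Problem sizes used by the test suite and acceptance script

Oracle equivalence uses 200 random graphs of ≤ 12 nodes and exhaustive
permutation enumeration at 4–6 observations. Calibration uses 1,000 null
replicates at n = 11 with 999 permutations for both Mantel and PERMANOVA,
judged against the exact binomial 99% interval around 0.05. Planted-truth
recovery uses the presets at their default sizes: module ARI over 10 seeds
per preset and Mantel power/level over 50 seeds. These sizes give stable
Monte-Carlo estimates while keeping a full run under a minute.

## Known limitations

- Correlation-based co-occurrence on relative abundances is subject to
  compositional bias; SparCC-style estimators are out of scope by design.
- Module membership from modularity maximization is not unique near
  degenerate optima; only planted-truth recovery, not exact rosters, is
  guaranteed.
- The exact-permutation p-value option is exponential in n and only
  practical for the tiny-sample regimes it is meant to check.
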