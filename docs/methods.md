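# Methods

## The question being modeled

Prevalence filtering ("keep ASVs present in ≥ t of samples") is the standard
way to define a core microbiome, but the threshold t is arbitrary. The
package quantifies how each of eight diversity measures responds to t, on
data whose macroecological structure is controlled. Everything below
documents the generative model, the metric conventions, the statistical
procedures, and — importantly — what the synthetic results do and do not
say about real data.

## Diversity measures: one kernel, eight measures

Let x_ij be the count of taxon j in sample i, N_i = Σ_j x_ij, and
p_j = x_ij/N_i the within-sample relative abundance. For a rooted tree with
branch lengths l_e, the *edge mass* p_e of a sample is the summed relative
abundance of the leaves below edge e; it is computed for all edges in one
post-order accumulation, vectorized across samples (a matrix of shape
nodes × samples), which is what makes a 10-threshold × 8-metric sweep over
~500 samples take under a minute.

Conventions that matter and are easy to get wrong:

- **Faith's PD** uses the rooted convention: every edge with p_e > 0 counts,
  including the path from the subtree of present taxa up to the root. A
  single-taxon sample therefore scores its root-to-leaf path, not zero.
  The input tree's root is taken as authoritative; no re-rooting is done.
- **BWPD_θ** = Σ_e l_e (2 min(p_e, 1−p_e))^θ with θ ∈ [0,1], default 0.5.
  The convention 0^0 := 0 keeps edges with p_e ∈ {0, 1} (everything or
  nothing below them) from contributing at any θ. Numerically, a balance
  below 1e-12 is snapped to zero before the power is applied: for θ < 1 a
  rounding-level residual ε would otherwise contribute ε^θ ≫ ε.
- **Weighted UniFrac** defaults to the normalized form (divide by
  Σ l_e (p_e^x + p_e^y)), which is bounded in [0,1]; the raw form is a flag.
- **Morisita** (not Morisita–Horn) is used: λ_x = Σ x(x−1)/(X(X−1)) requires
  integer counts, so integrality is enforced at the file-reading boundary,
  and sample totals must be ≥ 2. The similarity C can exceed 1 for
  near-identical low-count samples; the dissimilarity 1 − C is clamped at 0
  by default (unclamped available for cross-checking).
- **Shannon** uses the natural log, no base option.
- Empty samples raise errors in the scalar API rather than returning 0, so
  upstream filtering mistakes surface; inside the sweep, samples emptied by
  a filter get *missing* scores instead (see below).

## Macroecology

Expected richness under rarefaction to depth m is the hypergeometric form
E[S_m] = Σ_j [1 − C(N−x_j, m)/C(N, m)]; taxon accumulation over k samples is
the analogous incidence form with m_j = number of samples containing j. Both
are evaluated with log-gamma binomial coefficients so depths of 10^5 do not
overflow. Permutation versions (seeded) accompany both; their means agree
with the closed forms within Monte-Carlo error, which the tests assert at
3 SE. The pool extrapolator is the first-order jackknife
S_jack1 = S_obs + f₁ (n−1)/n (the estimate is reported assuming a closed
system; no open-system correction is attempted). Occupancy–abundance uses
mean relative abundance over *all* samples (zeros included) by default —
the convention that produces the classic triangular cloud — with
occupied-only means behind a flag. Occupancy-class distributions are binned
1, 2, …, 8+ by default (configurable).

## The sweep

Per dataset: samples under the rarefaction depth are dropped (logged), the
rest are subsampled without replacement to exactly 10,000 reads (default;
`multivariate_hypergeometric`, one RNG stream per dataset spawned from the
config seed). Prevalence is computed **on the rarefied table**, and each
threshold filters that same table independently — thresholds are not
applied cumulatively, though the retained taxon sets are nested anyway
because occupancy does not change between thresholds. The boundary is
inclusive (occupancy ≥ t), exercised by a boundary test at t = 0.5.

Filtering never drops samples; a sample whose taxa are all filtered away
gets missing scores (not zeros) for every metric at that threshold, and all
downstream correlations use pairwise deletion. Beta scores per sample are
the mean dissimilarity to all other scoreable samples at that threshold.

Standardization: z = (score − mean)/sd within each (dataset, metric) group,
pooling **all thresholds jointly** (sd with n−1). This is the only grouping
under which "how far does the mean z move with t" measures
filtering-sensitivity on a scale comparable across metrics and hosts.
Zero-variance groups yield missing z with a warning.

Statistics are implemented from their formulas (scipy used only for
distribution tails) and cross-checked against scipy in the tests:
Bartlett's K² with the small-sample correction C and a χ²_{k−1} tail;
Spearman's rho as the Pearson correlation of midranks with the
t-approximation p-value on n−2 df (adequate at n ≥ 50; exact permutation
p-values are out of scope). A rank correlation within 1e-12 of ±1 is
snapped to ±1. No multiple-testing correction is applied — raw rho and p
are reported. `variance_profile` (Bartlett across threshold groups, pooled
over datasets by default, per-dataset by flag) excludes threshold groups
with fewer than two finite scores or zero variance, with a warning; calling
`bartlett_test` directly on a degenerate group still raises.

## The synthetic-data generator

Each dataset is drawn from:

1. **Metacommunity**: relative abundances p_j from a lognormal with spread
   σ, renormalized. Two modes: `iid` draws (default), and a `quantile`
   lattice (p_j ∝ exp(σ Φ^{-1}((j−½)/n))) that pins the rank-abundance
   shape exactly — the presets use the lattice so their calibration is a
   property of the parameters, not of the seed.
2. **Counts**: x_ij ~ NegativeBinomial(mean = depth_i · p_j, shape k),
   independent across cells. This yields the closed-form occupancy
   occ_j = 1 − (k/(k + depth·p_j))^k (Poisson limit 1 − e^{−depth·p_j}),
   which is the generator's analytic acceptance surface: empirical
   occupancy is tested against it at 500 samples. Smaller k means patchier
   presence at fixed mean abundance.
3. **Individualization**: a fraction u of each sample's taxa should be
   unique to that sample. After the shared draw, m_i = ⌈u/(1−u) · S_i⌉
   sample-private taxa (S_i = the sample's shared richness) are injected at
   1–2 reads each from a reserved label pool, so the injected taxa are a
   fraction u of the sample's final richness. Pool exhaustion is an error,
   never silent. Uniqueness is structural (private labels), not a
   dispersion effect, because that is what "taxa unique to each sample"
   means ecologically.
4. **Tree**: a Yule topology grown by random leaf splitting over the
   observed taxa, iid Exponential(birth rate) branch lengths, root edge 0.
   Tree and abundances are independent — there is no phylogenetic signal in
   who is abundant.

Everything is deterministic given the seed (independent child streams for
metacommunity, counts, injection, tree).

**The eight-dataset preset** mirrors a published multi-host gut survey
design: six cohesive hosts (u ≈ 0.08) and two individualized ones (a bat at
u = 0.39 and a migratory shorebird at u = 0.26); sample sizes are the
surveys' 98–552 scaled down 4× (25–138) for desk runtime; depth 20,000
(keeping every sample above the 10,000-read rarefaction floor); σ, n_taxa
and k tuned once so the top taxon sits at 4–10% expected mean relative
abundance and 50–90% expected occupancy. `check_calibration` verifies those
bands *analytically* (on the quantile metacommunity and the occupancy
closed form) and raises if a preset is detuned — a mis-calibrated preset
can never pass silently. Realized tables land close: at seed 1 the top
taxon averages 4.9% abundance and 83% occupancy, ~70% of taxa occur in one
sample, per-sample uniqueness is 8.1% / 39.1% / 26.2% for
cohesive / bat / shorebird, and the jackknife pool captures 53–66% of
predicted richness.

## What the generator does and does not emulate

It reproduces the *within-dataset marginal* structure of host gut surveys:
lognormal-like rank-abundance, occupancy rising with abundance, a dominant
singleton class, tunable per-sample uniqueness, realistic depths. It does
**not** contain between-sample structure: samples are exchangeable draws
from one metacommunity, with no community types, gradients, batch effects,
or phylogenetic clustering of abundance. Three observable consequences,
which passing tests therefore do and do not establish:

- Pair-level concordance between Bray–Curtis and Jaccard (near-perfect in
  field data) requires a compositional gradient for both to track. On
  exchangeable tables the two metrics rank pairs almost independently; the
  association test therefore runs on a two-metacommunity mixture, where it
  is strong, and asserts rho > 0.6.
- Shannon and Morisita are *flatter* under filtering here than in field
  data. Both are dominated by abundant taxa, whose across-sample
  variability under NB dispersion k ≈ 0.2 (needed for realistic top-taxon
  occupancy of 50–90%) is enormous relative to the systematic shift
  filtering induces. In real hosts these measures shift more, so the
  synthetic rank of BWPD (2nd least sensitive alpha, behind Shannon) and
  weighted UniFrac (2nd least sensitive beta, behind Morisita)
  *understates* their real-data advantage; the presence-weighted measures
  are robustly the most sensitive in both worlds, and the pooled Bartlett
  ordering of the beta measures (unweighted UniFrac > Jaccard > weighted
  UniFrac > Morisita) matches the field ordering.
- The decline of filtered-vs-unfiltered correlation with threshold, and
  the steeper accumulation of individualized datasets (compared at equal
  sample size), are driven by the rare-taxon structure the generator does
  control, and reproduce cleanly.

## Numerical and interface choices

- Counts are strict non-negative integers at the I/O boundary; non-integer
  cells are an error with coordinates, never rounded.
- BIOM support is the TSV export dialect only (leading `#` comments, with a
  `#OTU ID` header line recognized); HDF5 BIOM is out of scope.
- Newick: every non-root edge must carry a length; the root edge defaults
  to 0; internal labels are read and ignored. Pruning collapses degree-2
  nodes by summing adjacent lengths, preserving all pairwise leaf paths.
- Tidy outputs: TSV, floats at 10 significant digits, NaN as `NA`,
  deterministic row order, and a header comment with tool version, config
  hash and seed.
- Problem sizes: the shipped study uses 493 samples across eight datasets,
  ~3,000–27,000 observed taxa per dataset (shared + private), depth 20,000
  rarefied to 10,000. The full generate + sweep cycle runs in about a
  minute on one CPU; the test suite, including Monte-Carlo calibration, in
  about one more.

## Known limitations

- No between-sample covariance structure (see above); parameter-recovery
  beyond occupancy (e.g. σ from observed tables) is not attempted.
- The Spearman p-value t-approximation is inaccurate below ~10 pairs;
  within the pipeline the smallest preset has 25 samples.
- Jackknife-1 assumes a closed taxon pool and is known to underestimate
  open communities; it is reported as "percent of *predicted* pool", not
  of the true pool.
- The unnormalized (no-rarefaction) sweep variant is available
  (`rarefy: false`) but the defaults follow common core-microbiome
  practice of rarefying first.
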