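# Methods

This note documents the models and procedures implemented in `trophonet`,
the parameter choices that matter, what the synthetic generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Trophic State Index

Sites are scored with a modified Carlson TSI whose four components are
affine in the natural logarithm of the measurement, `10·(a + b·ln x)`,
with (a, b) = (2.5, 1.086) for chlorophyll-a (μg/L), (5.453, 1.694) for
total nitrogen (mg/L), (9.436, 1.624) for total phosphorus (mg/L) and
(5.118, −1.94) for Secchi depth (m). The composite is the weighted sum
with weights (0.326, 0.219, 0.230, 0.225) in the order (Chl-a, TN, TP,
SD); the weights sum to 1, so equal components pass through unchanged.
Natural logarithms are intentional: the printed component constants are
only mutually consistent on the ln scale (base-10 would shift every
intercept).

Decisions:

- **Units are enforced, never converted.** A units row under the header is
  validated when present; mixing mg/L and μg/L silently would corrupt
  every score by ~7 TSI units per decade.
- **Non-positive measurements are rejected, not clamped.** There is no
  defensible detection-limit substitution that does not move the score;
  the caller must decide.
- **Missing components are a hard error by default.** An opt-in flag
  renormalizes the remaining weights (`assess_record(allow_missing=True)`);
  it is an extension, not the default, because the composite is defined on
  all four components.
- **Class boundaries** follow the printed intervals exactly (closed at 30
  and 50 for mesotrophic, left-open elsewhere); the eutrophic predicate is
  strictly TSI > 50, so the three eutrophic classes partition it.
- One input row is one classified unit; replicate aggregation (e.g.
  multiple containers per site) is left to the caller.

## Community metrics

Shannon diversity uses the natural log (H in nats, H ≤ ln S); this is the
dominant convention in ecology and the one under which the invariant
H ≤ ln S used throughout the tests holds. Rarefaction draws without
replacement (multivariate hypergeometric) to exactly the target depth,
seeded; samples below depth are **dropped with a warning** rather than
resampled with replacement, which would fabricate reads. Rarefaction is
applied to bacterial read tables only — phytoplankton microscopy cell
densities are not count-limited in the same sense and are never rarefied.
Bray–Curtis is computed on rarefied counts for bacteria and on relative
abundances for phytoplankton (cell densities are instrument-scaled); the
choice is recorded in the output's metadata.

## Association statistics

- **Spearman** is the Pearson correlation of average ranks (ties get
  average ranks). Constant vectors make the statistic undefined; NaN is
  returned and such pairs are excluded from the FDR family.
- **p-values**: the t-distribution approximation for n ≥ 10; below that
  the exact two-sided permutation null (all n! orderings, identity
  included, so p > 0).
- **BH-FDR** is applied across the full pair family of each correlation
  matrix, not per taxon — one gate, one family.
- **Mantel tests** use Spearman on the upper-triangle distances by default
  (a Pearson flag exists), permute the second matrix's labels jointly,
  and report the one-tailed ("greater") add-one p-value
  p = (1 + #{r_perm ≥ r_obs})/(1 + B), resolution 1/(B+1), default
  B = 999. For n ≤ 8 an exact mode enumerates all n! permutations. The
  partial variant residualizes the (rank-transformed) triangles of both
  matrices on the control by least squares and correlates the residuals.
- **Environment–community correlation** standardizes one variable, forms
  its Euclidean distance matrix, and runs a Mantel test against the
  community distances. This is a distance-based approximation of
  envfit-style Monte Carlo vector fitting: it shares the permutation
  logic and sign but does not reproduce fitted vector coefficients.

## Co-occurrence networks

Edges require |ρ| ≥ 0.6 **and** BH q < 0.05 simultaneously. Correlation is
computed on **per-kingdom relative abundances**: Spearman's rank
invariance is what makes cells/L and read counts commensurable, which is
why Spearman is the only supported edge statistic. The node set is the
taxa passing the 0.01% overall-relative-abundance filter (strictly above,
per kingdom, on the pooled table), applied identically to every group so
the groups share one node set; taxa without edges stay as isolated nodes.

Topology follows the Gephi reporting conventions: metrics on the unsigned
simple graph; diameter and average path length on the largest connected
component (component count logged); clustering is the mean local
clustering with degree-<2 nodes contributing 0. Modularity is maximized
by Louvain (resolution 1.0, 10 seeded restarts, best Q kept) — except on
graphs with ≤ 8 nodes, where the package enumerates all set partitions
and returns the exact optimum. The exact branch exists because the greedy
single-node-move heuristic can be permanently trapped below the optimum
on tiny graphs regardless of restart seed, while exhaustive search there
costs microseconds (Bell(8) = 4140 partitions); production networks are
far larger and always take the Louvain path.

Signed percentages are reported over retained edges (positive + negative
= 100%). Cross-kingdom composition classifies each edge BB/PP/BP and
reports counts and fractions both over all edges and within each sign
class; no attempt is made to reproduce summary rows whose denominator is
not well-defined from counts of retained edges.

## Synthetic gradient generator

The generator emulates the statistical structure the analysis assumes and
emits the planted truth so recovery can be scored exactly.

**Chemistry.** Each site draws a target composite TSI uniformly in its
group band (L: [30, 50], M: (50, 60], H: (60, 70]); all four components
are back-solved at that same target (`x = exp((TSI/10 − a)/b)`), so at
zero noise the forward computation reproduces the target to 1e−9, and
each value is then jittered by multiplicative lognormal noise (default
sd = 0.05, giving ≥ 95% class accuracy; boundary-adjacent sites can
legitimately cross).

**Composition.** Phytoplankton phylum weights follow a logistic turnover
in TSI (midpoint 55, slope 0.25 per TSI unit): diatoms (Bacillariophyta)
dominate low-TSI sites, cyanobacteria (Cyanophyta) high-TSI sites, with
minor phyla at fixed weights. Bacterial profiles are Proteobacteria-
dominated (base fraction 0.60) with within-phylum proportions drawn once
per scenario (Dirichlet(2)) and tilted by a power β(TSI) = 1 + 0.02·(TSI −
45), which monotonically concentrates the composition and drives the
Shannon decline with trophic state. Mixing weights are evaluated at each
**group's midpoint TSI**, not each site's: per-site evaluation would
inject a shared within-group trend, i.e. real pairwise correlations that
are not part of the planted truth, making false-positive accounting
ill-defined. The compositional shift across the gradient is preserved;
within-group correlation is entirely under the copula's control.

**Correlation structure.** Counts are drawn through a Gaussian copula
with negative-binomial marginals (dispersion k = 5), so the rank
correlations Spearman sees are controlled while counts stay
overdispersed; the latent→rank attenuation is measured by the recovery
tests, not assumed. The copula correlation is a one-factor-per-block
model: five blocks (two bacterial, two phytoplankton, one mixed) whose
members load ±√0.9 on their block factor. Blocks are deliberately placed
in **mid-abundance phyla** (Bacteroidota, Actinobacteriota, Chlorophyta,
Pyrrophyta, plus the mixed block in the two cyanobacterial groups):
planting them in dominant phyla makes compositional closure of the
relative-abundance transform convert a block's coherent swings into
strong unplanted negative correlations across the rest of the kingdom.

Module fusion along the gradient is hierarchical: at L all factors are
independent; at M the within-kingdom boundaries collapse (bacterial
factors share one parent, phytoplankton + mixed another); at H a single
parent couples all five (coupled factors correlate at 0.8). This is
always a valid correlation matrix and gives a structurally robust
intermediate state, unlike a flat coupling that either produces no
cross-block edges or sits on the edge-threshold knife edge. In the mixed
block, 0/3/5 phytoplankton members (L/M/H) flip to negative loadings, so
the negative-edge share rises along the gradient. These block parameters
are free parameters chosen for clear recoverability of the qualitative
pattern (module collapse, rising negativity); they are not estimates of
any field system.

Bacterial columns are rescaled to exactly the library size (default
33,000 reads, above the 27,000 rarefaction depth) by largest-remainder
rounding, which is rank-preserving within a sample.

**Truth scoring.** `score_recovery` treats pairs with latent |r| ≥ 0.8
(within-block pairs) as planted edges and pairs with latent |r| < 0.3 as
null; pairs whose correlation arises only from factor coupling
(|r| ≈ 0.72) sit in a gray zone excluded from both recall and
false-positive denominators, because their sample Spearman straddles the
0.6 edge threshold by construction and neither detection nor
non-detection is an error.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: taxon identities and realistic phylogenetic
structure; spatial/temporal autocorrelation between sites; compositional
dependence beyond the closure induced by the relative-abundance
transform; sequencing artifacts (chimeras, contamination, variable read
quality); detection limits and zero-inflation beyond what the
negative-binomial marginals produce; any absolute topology values of a
real survey (only the qualitative L→M→H directions are designed in).

## Problem sizes and determinism

Default study conditions: 30 sites per group, 30 phytoplankton and 70
bacterial taxa. All randomness flows from a single scenario/run seed
through stage-keyed substreams (`SeedSequence(seed, spawn_key=(stage,))`),
so adding a stage never perturbs earlier stages' draws and identical
(inputs, config, seed) give byte-identical outputs. Recovery benchmarks
in the test suite use 50 generator seeds; permutation tests default to
999 permutations in the analysis scripts and use 49–99 in tests where
only calibration, not resolution, is at stake.

## Known limitations

- Spearman co-occurrence on relative abundances is not a
  compositionality-aware estimator (no SparCC/SPIEC-EASI); closure can
  induce real but biologically spurious negative associations, which is
  visible in the generator's L group (~1–3% negative edges with none
  planted).
- The exact Spearman permutation p (n < 10) enumerates n! orderings and
  is intended for small fixtures, not large matrices at tiny n.
- The environment–community test approximates, but does not reproduce,
  envfit-style fitted coefficients.
- No ordination fitting (NMDS/RDA/VPA): distance matrices are exported
  for external tools.
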