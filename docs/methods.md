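# Methods

## The model

A structural connectome is an undirected, positively weighted graph
G = (V, E): nodes are atlas-parcellated gray-matter regions (the default
emulated layout is 83 regions — 41 per hemisphere plus the brainstem), and
the weight w_xy of an edge is the normalized volume of tractography
streamlines joining regions x and y. Weights are dimensionless after
division by whole-brain white-matter volume, which makes them comparable
across subjects and timepoints.

### Graph metric

d(x, y) is the shortest-path distance. By default it is the **hop count**
(every positive-weight edge has length 1); a weighted variant with edge
length 1/w_xy is available, since any intrinsic metric is admissible — strong
connections are then short. All distances are computed once per network with
Dijkstra on the full graph (`scipy.sparse.csgraph`). Pairs in different
components are flagged unreachable rather than failing the whole
computation.

### Random-walk measures

The weighted degree at x is d_x = Σ_z w_xz over neighbors z, and the
one-step random-walk measure is

    μ_x(y) = w_xy / d_x.

The walk is **non-lazy**: μ_x puts no mass on x itself. Much published
curvature software defaults to a lazy walk with idleness α = 0.5; the two
conventions give different numbers, so this package's choice is stated here
once and used everywhere. Isolated nodes have no measure and are excluded
with an explicit error.

### Ollivier–Ricci edge curvature and scalar node curvature

    k(x, y) = 1 − W1(μ_x, μ_y) / d(x, y),

where W1 is the Wasserstein-1 (earth mover's) distance between the endpoint
measures under the ground metric d. Positive curvature means the two
neighborhoods are closer together than the nodes themselves — many
triangles, redundant feedback paths, a robust connection. The node-level
scalar curvature is the contraction

    S(x) = Σ_y μ_x(y) · k(x, y),

a convex combination of incident edge curvatures, so S(x) always lies
between the smallest and largest incident k.

W1 is solved exactly as a minimum-cost transportation linear program over
the two neighbor supports (ground distances come from the full graph), with
scipy's HiGHS backend. Supports are small (node degree), so each LP has at
most degree² variables; only the optimal cost is contractually unique —
degenerate problems admit multiple optimal plans, and no consumer of this
API should depend on the plan itself. Solver feasibility tolerance is 1e-9.

Useful limits, used as test fixtures: complete graph K_n with unit weights
has k = (n−2)/(n−1) on every edge; interior edges of a long unit-weight
path have k = 0; a single isolated edge has k = 0; under the hop metric
k ≤ 1 always and k ≥ −2 for adjacent nodes (both supports lie within
distance 1 of the endpoints). Hop-metric curvature is invariant to global
weight rescaling because the measures are.

## Preprocessing

* **Normalization** divides all weights by whole-brain white-matter volume;
  optional, because inputs may arrive pre-normalized.
* **Cross-hemisphere removal** zeroes every left–right edge (low
  angular-resolution DTI resolves interhemispheric streamlines poorly).
  Edges touching the brainstem (hemisphere label `none`) are kept by
  default; a flag removes them, since conventions differ and the choice is
  not forced by the model.
* **Self-loops** (diagonal entries) are dropped at load with a warning: the
  walk measure is defined over neighbors only.
* Matrices must be symmetric; asymmetry up to 1e-8 (relative to the largest
  weight) is averaged away, anything larger is rejected as corrupted input.

## Longitudinal analysis

Change per unit (edge or node) is the **ratio** of follow-up curvature to
baseline curvature — curvature is unitless, so a ratio is interpretable
where a difference is not. Ratios are undefined, and the subject is
excluded for that unit, when the unit is absent at either timepoint or
|baseline k| < ε (default 1e-12). Curvature may legitimately be negative,
so negative ratios are kept, not clipped.

Each retained unit (by default one with a defined ratio in every subject;
`min_valid` relaxes this) is Spearman-correlated against the three
behavioral change scores. VABS-SS and EOW changes are follow-up minus
baseline; CGI-I is the follow-up improvement rating used directly, and
**lower CGI-I means more improvement** — a robustness gain that tracks
improvement therefore shows positive r on VABS-SS/EOW and negative r on
CGI-I. The p-value uses the two-sided t approximation with average ranks
for ties (adequate at ~19 subjects); an exact permutation p is available
for fewer than ten subjects. Constant ratio vectors make the correlation
undefined: such units get NaN r/p, never count as significant, and do not
enter the FDR family.

A unit is **selected** when p < 0.05 on at least two of the three measures
(both thresholds configurable). Benjamini–Hochberg q-values are computed
afterwards, one family per unit-type × measure (all edge units for VABS-SS
form one family, separately from node units and from the other measures);
the family layout is a documented implementation choice, configurable in
spirit by calling `benjamini_hochberg` directly on any slice. A unit
`survives_fdr` when q < α on at least the same number of measures.

## Synthetic cohorts

No subject-level imaging or clinical data ship with this package, so the
generator produces cohorts with the same statistical shape, plus ground
truth:

* One edge **support** (topology) per cohort, shared by all subjects —
  connectomes from a fixed parcellation overlap heavily in topology, and a
  shared support keeps longitudinal ratios defined across the cohort.
  Intra-hemisphere pairs connect with probability `edge_density` (default
  0.3, in the range of parcellated DTI connectomes after cross-hemisphere
  removal); a small cross-hemisphere density (default 0.05) gives the
  preprocessing filter something to remove; each hemisphere is required to
  be connected (resampled up to 100 times).
* A cohort-level weight **template** is drawn log-normal(μ = −4, σ = 1) —
  heavy-tailed and strictly positive like normalized streamline volumes.
  Each subject's baseline deviates from the template by multiplicative
  log-normal noise (`subject_weight_sd`, default 0.3). The template matters:
  if baselines were independent across subjects, the *sign* of a unit's
  baseline curvature would vary by subject and the follow-up/baseline ratio
  would not respond monotonically to a common effect even without noise.
* A latent improvement factor L ~ N(0,1) per subject drives both sides:
  behavioral scores are noisy linear functions of L scaled to the
  instruments (ΔVABS-SS 3.37 ± 6.71, ΔEOW 4.95 ± 6.34, CGI-I 2.79 ± 1.82;
  CGI-I enters with a negative loading), with `noise_sd` in units of the
  latent SD; and each planted intra-hemisphere edge changes weight by
  exp(effect_size · L) between timepoints **together with its triangle
  support** — the edges joining its endpoints to their common neighbors.
  The triangle co-scaling is deliberate: feedback triangles are the
  geometry behind the curvature–robustness link, and strengthening a
  pathway with its triangles raises its curvature, whereas inflating one
  edge in isolation concentrates each endpoint's walk measure on the other
  endpoint and *lowers* curvature. Planted edges are required to have at
  least one common neighbor and, when possible, pairwise-distinct
  endpoints. All follow-up edges also carry multiplicative log-normal
  noise (`weight_noise_sd`, default 0.1).
* The whole cohort is a pure function of the config (including its seed).

Because the perturbation moves the walk measure of every *affected node*
(planted endpoints and their common neighbors), edges incident to affected
nodes genuinely change curvature. The recovery report therefore
distinguishes planted units, selected affected-adjacent units, and false
positives proper (selected edges touching no affected node). At zero noise
the non-affected units have ratio exactly 1, their correlation is
undefined, and the false-positive count is structurally zero — which is
what the noiseless recovery check verifies end to end.

What the generator does **not** emulate: spatial embedding and
distance-dependent connection probability, hub structure and rich-club
organization, measurement artifacts correlated across edges (motion,
registration), ordinal granularity of the CGI-I (generated continuous to
avoid heavy ties), and any treatment-assignment structure. Passing
recovery tests show the pipeline transduces weight-level effects into
detectable curvature–behavior correlations under these idealized
conditions; they do not certify sensitivity on real DTI data.

## Problem sizes and calibration checks

The package's verification suite runs at sizes chosen to keep the full
cycle quick while leaving the statistical conclusions meaningful:

* Transport-oracle equivalence: 50 random connected graphs of ≤ 8 nodes,
  integer weights (so an exact rational min-cost-flow oracle applies),
  every edge compared at 1e-9.
* Null calibration: 19 subjects, 200 units, 500 replicates; the per-test
  type-I rate at p < 0.05 must land in [0.03, 0.07]; the two-of-three
  selection null rate is reported alongside (~2%, reflecting the latent
  coupling among the three measures).
* Recovery: 24-region networks (12 per hemisphere, density 0.4), 19
  subjects, 3 planted edges. The noiseless strong-effect regime
  (effect 1.0, all noise parameters 0) must reach sensitivity 1.0 with
  zero false positives; the moderate regime (effect 0.5, behavioral noise
  0.5, default weight noise) is repeated over 50 seeds and its mean
  sensitivity compared against the null selection rate, with the
  sign-pattern tallies of selected planted units reported per measure.
  The reduced region count keeps 50 simulate→analyze cycles to a few
  minutes; the full 83-region default is exercised once per run elsewhere.

## Numerical choices

* LP solver: HiGHS via `scipy.optimize.linprog`; redundant marginal
  constraint rows are left in place (HiGHS handles them).
* Unordered edge keys are stored lower-index-first and iterated in sorted
  order; all output tables are written with `%.17g`, so float64 values
  round-trip exactly and repeated runs are byte-identical.
* ε = 1e-12 for near-zero baseline curvature in ratios; 1e-12 for measure
  normalization checks; 1e-8 relative tolerance for input asymmetry.
* Degenerate inputs: empty networks yield empty results (not errors);
  isolated nodes and zero-weight pairs raise typed errors naming the node
  or edge.

## Known limitations

* Curvature ratios are unstable when baseline curvature is near zero; such
  units are excluded rather than winsorized, which can drop genuinely
  interesting sign-crossing units.
* The two-of-three selection rule is reported alongside BH q-values but is
  itself uncorrected; at 19 subjects almost nothing survives FDR, and the
  selection list should be read as hypothesis-generating.
* The hop-metric default treats all present edges as equally long; the
  1/w alternative is provided but the two metrics are not comparable
  numerically.
* With `min_valid` at its default (all subjects), units missing in any
  subject are silently absent from the results table (the run log records
  the counts).
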