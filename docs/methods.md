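# Methods

## The detection problem

A defoliated soybean plant scanned by a terrestrial laser scanner is a 3D
point cloud: a roughly vertical main stem (radius ~0.25 cm) with woody
branches (radius ~0.2 cm) leaving it at angles between ~20° and ~90°,
sampled at roughly 2 mm spacing. The quantities of agronomic interest are
the **node points** (stem–branch junctions) and the **branch angle** at each
node — the angle between the direction up the stem and the direction up the
branch. Small angles mean compact plants that tolerate dense planting.

## The detector

`scag.core.run_scag` implements a stratified–clustered–growing pipeline:

1. **Stratify.** The cloud is cut into horizontal layers of height `H`
   (default 1 cm, about twice the branch diameter). Layers are half-open
   `[z_lo, z_hi)` with the topmost closed; empty layers are kept but skipped
   in comparisons (each clustered layer is compared with the nearest
   clustered layer below it).

2. **Cluster.** Each layer is clustered with DBSCAN (`eps` = 0.5 cm ≈ 2.5×
   the point spacing, `min_samples` = 5). Every cluster is summarised by a
   robust center.

3. **Detect branch layers.** Adjacent layer pairs are compared by cluster
   count. Count increase ⇒ a new branch appeared. At equal or decreasing
   counts the nearest-center distances `D_CNL` from each lower cluster to
   the upper layer decide: equal counts fire when `max(D_CNL) >
   2·min(D_CNL)`; decreasing counts fire when the number of entries below
   `2·min(D_CNL)` is smaller than the upper count (some upper cluster has
   no source below). The multiplier 2 is exposed as
   `ScagParams.ratio_multiplier`; a floor of 1e-9 on the minimum prevents
   coincident centers from firing the ratio rules spuriously.

4. **Seed pairing.** In a retained layer the new cluster must be paired
   with the structure it split from. Upper clusters claim their nearest
   lower cluster greedily in ascending distance order; an upper cluster
   whose lower is already claimed is the new branch, and the claimant of
   that lower is its source. (The simpler closest-pair rule is kept as
   `select_branch_pair` and used as a fallback; it picks wrong pairs when
   two branches run close together.)

5. **Locate the node (downward growth).** The two cluster centers seed an
   iterative search. Each iteration removes all points above the current
   seeds, replaces each seed by the robust center of its `N` nearest
   remaining neighbours (`N` = 60; ties at the k-th distance are all
   included so the set is reproducible under rigid motion), and stops when
   the two neighbour sets share at least `overlap_fraction·N` points
   (default 0.5, cap 100 iterations). The node is the robust center of the
   shared points. Re-applying the removal every iteration is what drives
   the seeds downhill; without it the medians stall half a neighbourhood
   below the initial crop.

6. **Refine the node.** The overlap test stops where the two neighbourhoods
   merge. For steep branches that is the junction; for shallow branches the
   two cylinders lie within one neighbourhood radius of each other long
   before they meet, so the raw node lands up to ~3 cm above the junction
   (measured on Y fixtures at 20°) — the same shallow-angle overestimation
   reported for this class of detector. The refinement follows the new
   cluster and each other cluster of its layer upward as per-layer cluster
   chains, fits a principal axis to each chain, and moves the node to the
   closest-approach midpoint between the branch axis and the partner axis
   with the smallest line-to-line gap: the source structure's axis passes
   through the junction; an unrelated branch's axis passes at a distance.
   Two safeguards keep the fits honest: a chain stops when the next
   cluster's size jumps >1.6× the chain median (it has absorbed another
   branch emerging just above), and each axis fit trims points beyond
   1.75× the median tube distance and refits, so a bulge from a merging
   structure cannot tilt the axis. The refinement is skipped (preliminary
   node kept) when chains are too short, axes nearly parallel, the gap too
   wide (> 0.5 cm), or the intersection lands implausibly far from the
   preliminary estimate. `ScagParams.refine = False` disables it.

7. **De-duplicate.** The ratio rules legitimately re-fire along a steep
   branch; all those candidates converge to the same junction. Nodes closer
   than `merge_radius` (1 cm, the evaluation radius) are merged, keeping
   the lower layer's.

8. **Optimize branch points and compute the angle.** A slice
   `[node_z + D, node_z + D + 1 cm)` (`D` = 2.5 cm, in the 2–3 cm range
   where angle agreement is best) is restricted to the eps-connected
   component of the junction — a branch crossing the slice whose own
   junction lies below the node is not chained to this component and cannot
   be mistaken for this junction's branch — then split with DBSCAN. The
   stem group is laterally nearest the node; the branch group is the one
   whose own axis points back at the node (candidates misaligned by >30°
   are rejected). The two robust centers are the branch points; the angle
   is `atan2(|a×b|, a·b)` of the two node-to-point vectors. If the slice
   will not split, `eps` is halved and then `D` shrunk by 25% before giving
   up. The chain axes from step 6 arbitrate the result (disagreement >15°
   means the slice grabbed a wrong group) and stand in when optimization
   fails — typical for near-horizontal branches whose tops never reach the
   slice; such records are flagged `degraded`.

### Robust centers

All cluster/node centers are geometric medians (Weiszfeld iteration, warm
started at the componentwise median, relative tolerance 1e-10). Like the
per-axis median the geometric median ignores stray points, but it is also
exactly equivariant under rigid motions — rotating or translating a cloud
moves every detected node consistently and changes angles by <1e-6°, which
the per-axis median cannot guarantee (its error under rotation is of the
order of the point spacing). Layer binning adds a 1e-9 relative nudge so
points sitting exactly on a layer boundary bin identically after a
translation.

### Parameters that matter

| name | default (cm) | role | sensitivity |
|---|---|---|---|
| `H` | 1.0 | slice height | the one influential parameter; best F between 0.5 and 1.5 (≈2× branch diameter). Too large ⇒ two junctions per slice (recall drops); too small ⇒ slices thinner than the point spacing become DBSCAN noise (precision drops) |
| `N` | 60 | growth neighbourhood | detection F flat over 20–140 at operating `H` |
| `D` | 2.5 | slice depth for branch points | angle agreement flat over 1.5–4 |
| `eps` | 0.5 | DBSCAN reach | must bridge the sampling gap (~2.5× spacing) without bridging stem–branch gaps |
| `min_samples` | 5 | DBSCAN density | below this a slice fragment is noise |
| `merge_radius` | 1.0 | node de-duplication | matches the evaluation radius |
| `overlap_fraction` | 0.5 | growth stop | reconciliation of an over-determined stopping rule; the refinement step removes its residual bias |

All lengths are interpreted in the cloud's declared unit (`mm`/`cm`/`m`);
`ScagParams.for_unit` rescales the cm defaults.

## The density baseline

`scag.baseline` keeps points above the 95th percentile of the
neighbour-count field (radius 1 cm), clusters them (DBSCAN, eps = radius),
and returns one robust center per cluster as a candidate node; candidates
share the branch-point optimization and angle computation with the main
detector. The original comparison method's density statistic and threshold
are not specified anywhere reproducible; radius counts and the 95th
percentile are this repository's defaults, stated as such.

## The synthetic generator and what it does (not) emulate

`scag.synthetic` builds plants from a parametric skeleton: a vertical stem
with mild sinusoidal drift (amplitude 0.5 cm over the plant height),
straight branches attached ≥3 cm apart in the middle 60% of the stem,
azimuths uniform on the circle, angles uniform in a group-specific range,
lengths 8–15 cm, radii 0.25/0.2 cm (stem/branch), heights 40–80 cm. Points
are laid on the cylinder surfaces on an isotropic ~2 mm grid (the scanner's
nominal resolution); optional Gaussian jitter, per-branch dropout and
box-uniform outliers emulate measurement noise. The stored truth angle is
the angle between the branch direction and the local stem tangent at the
attachment — exactly the quantity the detector's vector construction
estimates.

Complexity groups are repository conventions emulating a
simple/medium/complex split: simple = 1–2 branches at 20–50°, medium = 3–5
at 20–70°, complex = 6–9 at 20–90° with 10% per-branch dropout. Fixture
suites are fully determined by `(group, n, seed)`.

What the generator does **not** emulate: occlusion shadows from discrete
scanner positions, registration error between stations, leaves/petioles/
pods, curved or broken branches, and soil/pot returns. Perfect scores on
clean fixtures therefore demonstrate algorithmic correctness, not field
performance; field-data scores for this family of detectors (F ≈ 0.77)
sit well below the clean-fixture scores here (F ≈ 0.9–1.0), and the gap is
exactly those unmodelled effects.

## Evaluation

A predicted node is a true positive if at least one labelled node lies
strictly within 1 cm (about the diameter of a soybean node region);
otherwise a false positive; a labelled node with no prediction within 1 cm
is a false negative. Many-to-one matches are allowed on both sides, per the
per-prediction/per-label counting rule taken literally. R, P, F follow the
usual formulas with NaN for undefined ratios. Angle agreement (Pearson r,
RMSE) is computed over matched pairs only, pairing each true-positive
prediction with its nearest label. Suite-level metrics pool TP/FP/FN and
angle pairs over plants before computing ratios (micro-averaging; with
per-plant macro-averaging the clean-fixture numbers are indistinguishable).

The sensitivity sweep evaluates the full H×N×D product (H ∈ {0.5…3.0} cm,
N ∈ {20…140}, D ∈ {1.5…4.0} cm by default), locating nodes once per (H, N)
and re-using them across D, which only affects the angle stage. On the
packaged clean suite F is flat across N for H ≤ 1.5 and the best-F H is
0.5–1.0 cm; at H ≥ 2 adjacent junctions share slices and F both drops and
becomes N-dependent.

## Trait and screening layer

Basic traits per plant: height (z extent), canopy width (max pairwise xy
distance — rotation-invariant and posture-robust; the quantity is otherwise
underspecified), stem length (polyline through per-layer stem-cluster
centers chained from the base, closed with vertical extensions at both
ends; ±2% on straight stems), average angle and angle count from the
detector, and mean nearest-point distance as a sampling-density diagnostic.

Ten composite indices (CHR, CLR, LHR, CAR, AHR, ALR, ANR, ACHR, ACLR,
ANRCHR) are ratios/products of those traits; smaller = more compact.

Replicate filtering drops varieties missing any (year, replicate) cell and
varieties whose within-year stem-length relative error |a−b|/mean(a,b)
exceeds 30% (symmetric-denominator definition; the threshold is exposed).

Cross-year repeatability uses classic DTW (absolute-difference cost,
unconstrained window, no path-length normalization) on min–max-normalized
trait profiles over a fixed common variety order; a rank-based mode is
exposed as well, since both conventions are used in practice.
DTW values change under reordering, but the ranking of traits by DTW is
stable under a common permutation of both years, which is what makes the
comparison meaningful.

Broad-sense heritability is estimated from a one-way random-effects
decomposition with variety as the group: σ²_e = MS_within, σ²_g =
(MS_between − MS_within)/n₀ truncated at zero, and H² = σ²_g/(σ²_g +
σ²_e/n̄) on an entry-mean basis (n₀ the unbalanced-design effective
replicate count, n̄ the mean replicate count). Several H² conventions exist;
the entry-mean basis is this package's documented choice, and a simulation
with σ²_g = σ²_e and two replicates recovers the closed-form value 2/3
within ±0.05 at 500 varieties.

## Numerical choices and degenerate inputs

- Ties in kNN sets are included wholesale (relative tolerance 1e-9) so
  regularly sampled clouds give identical neighbour sets after rotation.
- `min(D_CNL)` is floored at 1e-9 before the ratio tests.
- Cluster order, pair tie-breaks (lowest indices) and the merge order
  (bottom-up, keep lower) are all deterministic; the pipeline contains no
  randomness.
- A cropped cloud smaller than `N` aborts that branch with a warning; a
  slice that never splits falls back to fitted axes, then to the seed
  centers, and flags the record.
- Angles of exactly 0° or 180° (degenerate optimizations) are dropped with
  a warning rather than reported.
- Constant series are rejected by min–max normalization; heritability
  requires ≥2 varieties and at least one replicated variety.

## Problem sizes used by the packaged checks

The packaged test suite and the acceptance script run on generated data
sized for a laptop-class single core: 20 fixtures per complexity group for
recovery scoring, 5 fixtures for the sensitivity sweep, 500 simulated
varieties × 2 replicates for heritability. All sizes are constants at the
top of `scripts/acceptance.py` and scale up trivially.

## Known limitations

- Near-horizontal branches (≳80°) violate the upward-growth premise: their
  tops never reach the optimization slice, detection relies on the ratio
  rules re-firing, and angles come from the fallback estimators; recall in
  the complex group is correspondingly lower (~0.85 on clean fixtures).
- Two branches emerging within one slice yield one detection per layer
  pair; the second is found only if a later layer pair fires for it.
- Petioles are not distinguished from branches; plants are assumed
  defoliated.
- The stem-length chain assumes the stem is the cluster continuing from
  the base; a plant lying on its side would need re-orientation first
  (readers never reorient).
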