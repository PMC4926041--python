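# Methods

## Model and procedure

`harmonyseg` treats grayscale segmentation as 1-D clustering of pixel
intensities rescaled to [0, 1]. Spatial context is deliberately ignored:
each pixel is represented by its intensity alone, so the method assumes
classes that are separable by gray level (the situation in which
intensity-based MRI tissue clustering is meaningful). Internally the
distance code is dimension-generic, but the shipped pipeline encodes a
candidate solution as the concatenated `c` scalar centers.

The pipeline has three stages.

**1. Rough-set construction of the harmony memory.** Initial centers are
placed at the evenly spaced data quantiles `(2i+1)/(2k)` (midpoint
interpolation) — deterministic and spread over the intensity range. Each
round assigns every pixel either to the lower approximation of its
nearest center (certain member) or, when the second-nearest center is
within `boundary_threshold` of the nearest in distance, to the boundary
region shared by the qualifying clusters' upper approximations. Centers
then move to `w_low · mean(lower) + (1 − w_low) · mean(boundary)`; a
cluster with no boundary members takes its plain lower mean (so with
`boundary_threshold = 0` the iteration is exactly Lloyd's k-means), one
with an empty lower set takes its upper mean, and a fully empty cluster
keeps its center. Rounds stop when the maximum center shift reaches
`stop_threshold` or after `max_rounds`. The boundary region of the
converged partition is resolved once by an unweighted K-nearest-neighbor
majority vote over the lower-set pixels (ties broken by summed inverse
neighbor distance, then lowest cluster index), and the crisp class means
form row 1 of the harmony memory. Running the KNN vote inside every
round would let its crisp means override the weighted update and make
`w_low` inert, so it is applied once at the end. The remaining
`hms − 1` rows are seeded Gaussian perturbations of row 1 with sigma
equal to 2% of each variable's range, clipped to bounds and sorted —
population diversity around a good start.

**2. Adaptive harmony search.** Each iteration improvises one candidate:
per component, with probability `hmcr` copy from a uniformly chosen
memory row, then with probability `PAR(t)` perturb by `± rand · BW`;
otherwise redraw uniformly in the bounds. Candidates are clipped to the
box (clipping rather than reflection: deterministic and simple), and a
candidate strictly better than the worst row replaces it — ties keep the
incumbent, so the best row can never be evicted and the best-fitness
trace is exactly non-increasing. `PAR` ramps linearly from `par_min` to
`par_max` over the run. `BW` follows a two-regime schedule driven by the
feedback statistic `T = Σ|x_best − x_worst| / Σ(x_best − x_worst)²`
computed from the current memory: while `T < t_max/2` the bandwidth
grows as `bw_min + (bw_max − bw_min) · T·t/t_max` (clamped to its
configured range); once `T` reaches `t_max/2` it is held at `bw_max`.
Comparing a distance-ratio statistic against an iteration count is
dimensionally odd but is implemented as printed in the source
derivation; the clamp keeps the schedule well-behaved regardless. The
numerator uses absolute differences so the statistic is a non-negative
magnitude (a bare sum could go negative and break the branch test); it
scales as `1/s` when the memory is scaled by `s`, and it is defined as 0
when best and worst rows coincide. The run terminates at
`max_iterations` or as soon as `T ≤ stop_threshold` — with the default
threshold this fires exactly when the memory has fully collapsed
(best = worst), the natural end of useful search. One field serves both
this level and the rough-iteration convergence test, since both play the
role of "the threshold" in the derivation.

A consequence worth knowing: on very easy objectives the collapse
termination can stop the improved optimizer early while a plain run
keeps polishing the optimum to machine precision. The improved
variant's advantage is the quality of its starting memory, so
comparisons against plain harmony search are most meaningful at modest
budgets or on the actual clustering objective; the tests are written
accordingly.

**3. Fuzzy c-means.** Standard alternating closed-form updates with
fuzzifier `m` (one parameter, default 2 — the universal FCM default),
stopping when the maximum center shift drops below `epsilon`. A pixel
coinciding with a center gets crisp membership (split equally among
coincident centers). The returned memberships are recomputed from the
final centers so the stored (U, V) pair is self-consistent. Validity:
`Vpc = (1/n) Σ u²` and `Vpe = −(1/n) Σ u ln u` with natural logarithm,
so `Vpe`'s upper bound is `ln c` (the entropy identity) and `0·ln 0 = 0`.

**Cluster-count selection** runs the full improved pipeline for each
candidate `c` and keeps the maximizer of `Vpc` (ties to the smaller
`c`). `Vpc` is the package's own quality criterion, which makes the
choice internally consistent; like any partition-coefficient criterion
it has a known bias toward small `c` on poorly separated data.

## Parameters

| parameter | default | units / range | why |
|---|---|---|---|
| `hs.hms` | 30 | rows | small population typical of harmony search |
| `hs.hmcr` | 0.9 | probability | canonical memory-consideration rate |
| `hs.par_min`, `hs.par_max` | 0.3, 0.9 | probability | classic PAR endpoints for the linear ramp |
| `hs.bw_min`, `hs.bw_max` | 0.01, 0.1 | normalized intensity | fine vs. coarse step on a [0,1] range |
| `hs.max_iterations` | 2000 | iterations | ample for c ≤ 5 scalar centers |
| `rough.boundary_threshold` | 0.05 | normalized intensity | 5% of the range: pixels closer than typical noise to two centers are genuinely ambiguous |
| `rough.w_low` | 0.75 | (0.5, 1) | customary rough-k-means lower weight; certain members dominate |
| `rough.knn_k` | 5 | neighbors | small odd-ish neighborhood, robust majority |
| `rough.max_rounds` | 100 | rounds | k-means-style iteration converges far sooner |
| `rough.stop_threshold` | 1e-4 | normalized intensity | center shift below display precision |
| `fcm.fuzzifier` | 2.0 | — | standard FCM fuzzifier |
| `fcm.epsilon` | 1e-5 | normalized intensity | max center shift at convergence |
| `fcm.max_iter` | 100 | passes | FCM on 1-D data converges in tens of passes |
| `pipeline.fitness` | `l2` | — | within-cluster sum of squares, consistent with `J_m` at crisp memberships; `l1` available |

Randomness: every run owns a single `numpy` generator consumed in a
documented fixed order (memory init rows, then six fixed-length draws
per improvisation), so seeded runs are bit-reproducible. The pipeline
derives decorrelated child seeds for the optimizer, the memory
perturbations and the random-init baseline from one user seed via
`SeedSequence`.

## What the phantoms emulate — and what they do not

The generator produces piecewise-constant class regions (stripes,
equal-area nested annuli, or Voronoi cells), adds i.i.d. Gaussian
intensity noise per class, optionally multiplies by a smooth zero-mean
low-order-polynomial bias field (amplitude-normalized so its peak
deviation equals the requested fraction), and clips to [0, 1]. Class
proportions are fixed by the geometry, so test statistics see
deterministic class sizes. This captures the statistical structure the
method assumes — k intensity classes, additive noise, slow multiplicative
inhomogeneity — but not anatomy, partial-volume mixing, Rician noise, or
MR sequence physics. Passing tests therefore demonstrate correct
behavior of the algorithms under their own model; they do not certify
performance on real acquisitions.

Segmentation accuracy against ground truth is the pixel agreement
maximized over all label permutations (exhaustive, intended for c ≤ 6).

## Numerical choices and degenerate inputs

- Pitch-adjusted components are clipped to the box; replacement ties
  keep the incumbent; the memory-consideration row is drawn
  independently per dimension.
- Membership columns sum to 1 within 1e-10; the objective trace is
  non-increasing within 1e-8 relative tolerance (the alternating
  updates are coordinate minimizers).
- Candidate center vectors are sorted before use, collapsing the
  permutation symmetry of the search space (scalar features only).
- Coincident candidate centers make the rough margin test degenerate
  and are rejected; an empty lower approximation aborts the KNN vote
  with advice to lower `boundary_threshold`; a cluster with zero total
  membership weight aborts the center update naming the cluster.
- Constant images are rejected at load (no contrast to cluster); RGB
  inputs are reduced by ITU-R 601 luminance; intensities are min-max
  rescaled so an 8-bit image maps exactly to v/255.
- Near-coincident points whose inverse-distance powers overflow are
  resolved by crisp assignment to the nearest center.

## Problem sizes in the shipped tests

Unit and property suites run on vectors of tens to hundreds of points.
End-to-end checks use 128×128 phantoms for parameter recovery and
cluster-count selection, and 64×64 phantoms for the 50-pair
improved-vs-baseline comparisons; benchmark sanity uses 10-D test
functions at 20,000 iterations. These sizes are the package's chosen
test conditions; all are generated at run time from seeds.

## Known limitations

- Intensity-only features: classes that overlap in gray level cannot be
  separated, and strong bias fields must be corrected upstream.
- The feedback-driven bandwidth schedule saturates at `bw_max` for most
  of a typical run on [0, 1] data (the statistic exceeds `t_max/2` only
  near collapse and is otherwise large relative to its multiplier), so
  its practical effect is front-loaded.
- `Vpc`-based selection of `c` inherits the partition coefficient's
  bias toward crisper, smaller partitions.
- On well-separated synthetic data, randomly initialized FCM reaches
  the same basin as the optimized initialization; the optimized start
  then shows up as fewer FCM iterations and a tighter harmony memory
  rather than a large validity gap.
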