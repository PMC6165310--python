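# Methods

## Problem setting and assumptions

The estimator targets a single, roughly mirror-symmetric object (a sweet
pepper is the motivating case) captured from one viewpoint, so that only
the camera-facing surface is present in the cloud. Inputs are assumed
pre-filtered (no background, no statistical outliers) and expressed in
centimetres in the camera frame; the viewpoint defaults to the origin with
+z into the scene. The method is purely geometric: it uses positions and
surface normals, no colour or intensity.

## Pipeline

**Normal estimation.** Normals come from local plane fits: for each point,
the covariance of its k nearest neighbours (the query point excluded) is
eigendecomposed and the eigenvector of the smallest eigenvalue taken. k
defaults to 30 — appropriate for depth-camera clouds of a few hundred to a
few thousand points; results are stable for k in 10–50. Normals are
oriented toward the viewpoint (n·(p_v − p) > 0); the visibility predicates
below are meaningless for unoriented PCA normals. Eigenvalue ties
(degenerate neighbourhoods) resolve to the deterministic eigensolver output
and are counted in a log warning rather than failing the run.

**Centroid search.** The true fruit centre lies behind the visible cap, so
the coordinate mean is useless as a centre estimate. Candidates are drawn
from an axis-aligned Gaussian centred at the cloud mean with per-axis
standard deviation equal to the bounding-box extent ("auto"), which places
mass both in front of and behind the cap; 2000 candidates give roughly
millimetre resolution at negligible cost. Two objectives are provided:
`distance_std` (default) — the standard deviation of the candidate's
distances to all cloud points, which is zero exactly at the centre of a
sphere and small near the centre of a spheroid, even from a one-sided cap —
and `rms_distance`, the root-mean-square distance, whose true minimiser is
the cap's coordinate mean; it is kept as the literal alternative but does
not recover the centre of a partial view. The search is deterministic for a
fixed seed.

The `distance_std` argmin is *not* exactly the ellipsoid centre when the
half-axes differ: on the benchmark spheroid (2.5, 2.5, 2 cm) the estimate
is systematically a few millimetres too deep. This bias is intrinsic to
the centre-by-equidistance idea on non-spherical shapes and is the dominant
error source of the full pipeline (see Limitations).

**Candidate planes.** u² planes through the estimated centroid, normals on
a spherical grid with half-step offsets: α over (0, π), β over (−π/2, π/2).
All normals therefore have x > 0 — one hemisphere, sufficient because
planes are undirected. u must exceed 4; the default u = 6 (36 planes) is
the published operating point. Grid resolution bounds achievable accuracy:
at u = 6 no grid normal is closer than ~15° to a horizontal direction,
which is exactly the tilt observed in the winning planes on clean spheroid
clouds.

**Visibility filtering.** For a candidate plane, a point contributes to the
score only if (a) it faces the camera and (b) its mirror image would too:
the reflected normal ñ = n − 2 n_p (n·n_p) must satisfy ñ·(p_v − p̈) > 0
for the reflected point p̈. Points failing (b) sit opposite an occluded
region; their reflections land where no data can exist, so they carry no
evidence about the plane.

**Scoring.** Each contributing point adds S = d + τ·ξ: d is the Euclidean
distance from p̈ to its nearest cloud point (searched over the *entire*
cloud — the filters decide which points are scored, not which may serve as
partners), and ξ ∈ [0, π] is the unsigned angle in radians between ñ and
that neighbour's normal. τ = 3π by default, making a 0.1 rad normal
mismatch cost ≈ 0.94 cm; the radian reading is the only one that makes a
weight of 3π dimensionally sensible at centimetre scale. Nearest-neighbour
ties break to the lower point index; plane ties to the lower plane index; a
plane with no scorable points is unrankable (+inf).

Per-plane aggregation is the **mean** of per-point scores. Summation is
available as an option but is biased in a way that breaks the method on
partial views: planes oriented near the viewing ray reflect the visible cap
onto the occluded back, so the partner filter discards almost every point,
and the few surviving rim points reflect nearly onto themselves — a sum
over 10 near-zero terms beats a sum over 900 small ones, and the selected
plane degenerates to the view-aligned family. On the benchmark clouds, sum
aggregation yields ≈ 22° mean axis error versus ≈ 2° for the mean, and a
method that "adds the scores" can only have worked with a fixed or
comparable count of scored points per plane. The per-point mean preserves
the scoring idea while making planes with different filter survivor counts
commensurable.

**Axis.** γ = n_p × v̂ with v̂ the unit vector from centroid to viewpoint,
then normalised (the raw cross product has norm sin∠(n_p, v̂)) and
sign-canonicalised (largest-magnitude component positive); axes are
undirected throughout. n_p ∥ v̂ is a degenerate-geometry error.

## Simulator

`sample_ellipsoid_surface` draws unit-sphere directions, maps them through
the half-axis scaling, and accepts each with probability proportional to
the local area distortion, giving an area-uniform sample of the ellipsoid;
exact outward normals are attached. `cull_invisible` keeps points with
n·(p_v − p) > 0 — back-face culling, the correct visibility model for a
convex body seen from outside. Optional isotropic Gaussian noise is applied
*after* the culling decision so visibility is decided on clean geometry.

The benchmark sweep is 45 clouds: centres (3, 5, z₀) cm — the lateral
offset models a fruit away from the optical axis — for z₀ = 25…69 cm step
1 cm, half-axes (2.5, 2.5, 2) cm, 2000 pre-cull samples (≈ 900–1000
visible), no noise. The depth range quoted for the sweep (25–70 cm at
1 cm) contains 46 values while the cloud count is 45; the count is taken
as authoritative and the sweep ends at 69 cm (configurable). 2000 samples
approximate the density of a filtered consumer-depth-camera cloud at these
ranges.

What the simulator does **not** model: sensor noise curves (axial/lateral
error growth with distance), quantisation, flying pixels, occlusion by
other objects, and non-ellipsoidal fruit shape (lobes, concavities). The
depth-invariance result on clean spheroids therefore shows the *geometric*
claim — angle errors do not grow with distance under perspective projection
— not robustness to distance-dependent sensor degradation.

## Ground truth for simulated clouds

A spheroid (x₁ = y₁) is rotationally symmetric about the vertical line
through its centre: every plane containing that line is a true symmetry
plane, so "the" true axis is underdetermined and some convention is
required. The convention used: the reference for an estimated axis is the
ideal γ implied by the true symmetry plane *nearest the winning plane* —
project the winning normal to horizontal, cross with the true viewing ray
(viewpoint minus true centre), normalise. This penalises the winning
plane's out-of-family tilt and the centroid error, while not punishing the
roll angle that rotational symmetry genuinely leaves free. For triaxial
ellipsoids (all half-axes distinct) the true planes are the three principal
planes; the reference is the realizable axis of the best-matching one.

## Evaluation harness

`run_simulation_experiment` regenerates the sweep per repetition with
per-repetition seeds derived from one master seed (SeedSequence), runs the
full pipeline (normals re-estimated, not the simulator's analytic ones) and
tabulates per-run angle errors; degenerate runs are recorded as missing,
counted, and excluded from means. Summaries: overall mean, per-depth means,
and their spread (max − min). `run_dataset_evaluation` applies the same
pipeline to a directory of cloud files with references from a simulator
manifest or from peduncle clouds (reference axis = fruit centre → peduncle
centre); clouds without references or unreadable files are skipped with
warnings so one bad file cannot abort a batch.

Observed behaviour at the default operating point (45 depths × 50
repetitions, seed 0): overall mean ≈ 2°, all per-depth means ≤ 4°, spread
≈ 2.5°. The single-run error distribution is heavy-tailed (≈ 2% of runs
exceed 10°, driven by centroid-bias-induced plane misselection), which is
why per-depth means over few repetitions fluctuate more than the
per-repetition mean suggests.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy` Generators seeded from explicit
  integers; derived seeds use `SeedSequence` and stay below 2³¹.
- arccos arguments are clamped to [−1, 1]; scores near zero carry ~1e−7
  noise from arccos near 1.
- Exact nearest-neighbour distance ties resolve to the lower index (two-way
  ties; deeper ties are measure-zero for real data).
- Empty clouds, k ≥ n, u ≤ 4, zero-length axes and all-culled views raise
  typed errors; the CLI maps parameter/I-O/degeneracy errors to exit codes
  2/3/4.

## Limitations

- The centroid search inherits the equidistance assumption; strongly
  non-spherical or heavily occluded fruit biases it, and with it the plane
  anchor. On triaxial test shapes this bias, not the scorer, dominates
  selection noise at u = 6.
- The u = 6 grid cannot represent planes closer than ~15° to horizontal
  normals; accuracy is grid-limited before it is data-limited.
- Occlusion by foliage or neighbouring fruit is out of scope (inputs are
  assumed to be a clean single-fruit partial view).
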