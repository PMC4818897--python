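# Methods

This document defines the geometric model, the algorithms, every tunable
parameter (with units, defaults, and rationale), and the numerical choices
behind `elbow4d`. All lengths are millimetres, all angles degrees.

## 1. Two-rings hinge axis

The elbow flexion–extension axis is modelled as the line through the centers
of two circles fitted to the articular rims of the trochlea (medial) and the
capitellum (lateral).

- **Input**: a `LandmarkSet` of ≥3 points per ring (JSON with `trochlea` and
  `capitellum` arrays).
- **Exactly 3 points**: the circumcircle is computed in closed form via
  barycentric weights. Triples whose triangle area is below `1e-9`
  (scaled by the squared point spread) raise `DegenerateLandmarksError`
  naming the offending group.
- **More than 3 points**: the best-fit plane comes from an SVD of the
  centered points, and the in-plane circle from the algebraic (Kåsa)
  least-squares fit. The RMS radial residual is reported on the `Ring`.
- **Axis**: points from the trochlear center toward the capitellar center.
  Centers closer than `MIN_CENTER_SEPARATION = 1.0 mm` raise
  `UnstableAxisError` (the direction would be dominated by fit noise).
- **Diagnostics** (serialized with the axis): both ring radii, RMS
  residuals, and the inter-center distance.
- `axis_error(a, b)` returns the orientation-agnostic angle between
  directions and the line–line distance, used for all closure checks.
- `snap_to_surface` optionally projects picked landmarks to the nearest
  mesh surface point before fitting.

## 2. Kinematics

The forearm is posed by the proper rigid rotation of `angle −
reference_angle` about the fitted axis (Rodrigues rotation via
`scipy.spatial.transform.Rotation`; translation `t = p − R p` fixes the axis
pointwise). Sweeps are absolute poses of the *original* mesh — never
accumulated frame-to-frame — so orthonormality, enclosed volume, and
per-vertex axis distance are preserved to floating-point accuracy across
arbitrarily long sweeps. `pose_sequence(start, stop, step)` includes both
endpoints; if the range is not an exact multiple of the step, the stop angle
is appended.

## 3. Impingement quantification

At each flexion angle the humerus (static) and the posed forearm are
rasterized on a common axis-aligned voxel grid covering the intersection of
their bounding boxes padded by one voxel (a disjoint-box shortcut returns
zero immediately).

- **Rasterization**: scanline parity along +z through voxel-column centers
  with a half-open (top-left) edge rule; a voxel is occupied iff its center
  is inside the mesh (center containment, not partial-volume weighting).
- **Overlap volume**: `count(A ∧ B) · voxel³`. The error is a surface
  layer effect, O(voxel) × contact area; halving the voxel size roughly
  halves it. Default `voxel_size = 0.5 mm` (clinically negligible volume
  error on ~10 mm articular radii); acceptance oracles use 0.25 mm.
- **Face labels**: faces whose centroid lies inside the other mesh, tested
  by parity ray casting with a tiny fixed rigid rotation of the whole scene
  (~1e-5 rad) to break exact vertex/edge ties; used for red highlighting in
  exported PLY frames.
- **Sweep** (`flexion_sweep`): volumes over `[start, stop]` at `step`
  (default 1°, range −10°…140° in the CLI). The impingement-free arc is the
  **longest contiguous run** of angles with volume ≤ `contact_threshold`
  (default 0 mm³); its bounds are `first_contact_extension` /
  `first_contact_flexion`. A positive threshold treats sub-threshold
  grazing contact as free, and widens the arc monotonically.
- **Report targets** (`report_targets`): overlap at 0° and 140°, the usual
  post-debridement extension/flexion goals.
- A grid budget of 1.5×10⁸ cells raises `ResourceLimitError` before memory
  exhaustion.

## 4. Synthetic phantom

The phantom is a hinge elbow with analytically known ground truth, built as
a single star-shaped polar surface per bone (no mesh booleans, so
watertightness is guaranteed by construction):

| parameter | default | meaning |
|---|---|---|
| `trochlea_radius` | 10.0 | trochlear cylinder radius, x ∈ [−6, 6] |
| `capitellum_radius` | 8.0 | capitellar sphere radius |
| `inter_center_distance` | 30.0 | trochlea-to-capitellum center distance |
| `clearance` | 1.0 | radial gap between trochlea and forearm cup |
| `trochlea_arc_deg` | 360 | articular arc of the trochlea (for forearm-side osteophytes) |
| `shaft_length` | 35.0 | humeral shaft extent |
| `mesh_resolution` | 0.5 | target surface facet size |
| `seed` | 0 | landmark sampling seed |

The forearm is a cup sector spanning 120°–240° around the trochlea (inner
radius `trochlea_radius + clearance`, wall 4 mm, x ∈ [−5, 5]) with a distal
shaft. Osteophytes are spherical bosses of radius `size_mm` seated on the
trochlear surface (humeral) or cup inner surface (forearm).

**Closed-form contact**: a boss of radius *s* seated at radius *r_b*
contacts the opposing surface at radius *r_s* over a circumferential
half-width β with `cos β = (r_b² + r_s² − s²) / (2 r_b r_s)`; the
first-contact flexion angle is the rotation that brings the boss within β
of the cup (or articular-arc) edge. `humeral_osteophyte_for_contact`
inverts this to *place* a boss contacting first at any requested angle —
the ground truth for the end-to-end sweep test. Bosses deeper than the cup
wall, or forearm bosses against a full 360° trochlea (which would impinge
at every angle), raise `PhantomSpecError`.

**Landmarks** (`sample_landmarks`): three random circumferential stations
per ring (pairwise separation ≥ 20°, avoiding osteophyte footprints and
non-articular sectors), perturbed by isotropic Gaussian noise `noise_sd`.
With `noise_sd = 0` the two-rings fit recovers the true axis to < 1e-6° and
< 1e-6 mm, which is the axis-fit acceptance criterion.

## 5. Reliability statistics

From the two-way subjects × raters ANOVA decomposition (BMS/JMS/EMS/WMS):

- **ICC(1,1)** — one-way random, single measure: `(BMS − WMS) / (BMS +
  (k−1) WMS)`; exact F-distribution confidence bounds. Used for
  repeat sessions of one observer.
- **ICC(2,1)** — two-way random, absolute agreement, single measure:
  `(BMS − EMS) / (BMS + (k−1) EMS + k (JMS − EMS)/n)`; Satterthwaite-style
  confidence bounds. Used between observers (a constant rater bias lowers
  it, unlike consistency forms).
- Both match `pingouin.intraclass_corr` to 1e-9 and a from-definitions
  brute-force oracle to 1e-10 in the test suite. Zero-variance grids raise
  `UndefinedICCError`.
- Interpretation: > 0.75 *excellent*, 0.4–0.75 *fair to good*, < 0.4
  *poor*.
- Cohort helpers: mean/sample-SD summaries, paired t (all-zero differences
  return t = 0, p = 1; zero-variance nonzero differences raise
  `DegenerateTestError`), Welch t, and a bundled 11-case range-of-motion
  table whose rows satisfy `arc = flexion + extension` (extension deficits
  are signed negative).

## 6. Acceptance script

`scripts/acceptance.py --seed S --out results.json` recomputes, from
scratch: the example-cohort means and paired-t; noiseless axis-fit closure
errors; the sphere-lens (closed form 5000π/12) and half-overlapped-cube
voxel oracles; end-to-end recovery of a designed 120° contact angle via a
1° sweep at 0.25 mm voxels; and a simulated reliability experiment — 11
phantoms with osteophyte contact angles drawn from U[105°, 130°] and sizes
from U[2, 4] mm, landmarked by 2 observers × 2 sessions at 0.1 mm noise,
each session rated by the first-contact flexion angle from a 1° sweep at
0.5 mm voxels — reporting intra-observer ICC(1,1) and inter-observer
ICC(2,1). All randomness derives from the single `--seed` through
`numpy.random.SeedSequence`.

The rated quantity is the contact *angle* rather than the raw overlap
volume: with a 1 mm articular clearance, the volume at a fixed deep-flexion
pose is extremely sensitive to sub-millimetre axis errors, and a
reliability experiment rating it is dominated by that sensitivity rather
than by between-subject differences. The sensitivity itself is documented
by the volume mean also included in the output.

## 7. Scope and limitations

- The phantom is a hinge with circular cross-sections; it validates the
  geometry/kinematics/statistics pipeline, not anatomical realism.
- Voxel overlap uses center containment; volumes carry an O(voxel)
  surface-layer error and exact contact onset is resolved only to the sweep
  step. Ground-truth contact angles therefore come from the closed form,
  not from voxel sweeps.
- ICC confidence intervals assume the standard normal-theory ANOVA model.
- STL input must be watertight after vertex welding (tolerance 1e-6 mm);
  open meshes are rejected with their open-edge count rather than
  "repaired" silently.
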