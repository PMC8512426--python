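# Methods

This note documents the models, conventions, parameter choices and
limitations behind `glovescan`, in the order data flows through the
package.

## Measurement model and conventions

Each pose sample is a time-stamped 3-D position (mm) plus a unit
quaternion (scalar-first `(w, x, y, z)`) rotating sensor-local axes into
the base-station frame.  Units are millimetres and seconds everywhere.
Frames are right-handed; azimuth is measured in the x–y plane from +x
toward +y and wrapped to `[0, 360)`, elevation from the x–y plane toward
+z in `[-90, +90]`.  Quaternions whose norm deviates from 1 by more than
1e-6 are rejected; coordinates beyond the tracker's nominal 75 cm cubic
working volume (±750 mm) trigger a warning, not an error, since the
hardware degrades gracefully near the boundary.

The emulated tracker has a 3-D position accuracy of 1.4 mm RMS.  The
simulator realizes this as isotropic per-axis Gaussian noise with
σ = 1.4/√3 ≈ 0.808 mm, so the root-mean-square of the full 3-D
displacement is 1.4 mm (verified to ±5% on 10⁵ samples).

## Frame compensation

Every glove sample is re-expressed in the frame of the object-mounted
reference sensor: `p_obj = Rᵀ(p − t_ref)` with `(R, t_ref)` the
reference pose.  Because glove and reference streams are asynchronous in
general, each glove sample is paired with the reference sample *nearest
in time* (ties toward the earlier sample; no interpolation — the
simplest contract, and interpolation is deliberately out of scope).  For
any rigid motion applied simultaneously to the object and its mounted
sensor this compensation reproduces the static scene exactly; the
property-based tests assert it to 1e-9 mm for random rigid motions and
the end-to-end motion check to 1e-6 mm.

## The two-stage filter

**Selection.**  Directions around a reference point are partitioned into
an equal-angle azimuth × elevation grid (`n_az = ⌈360/Δ⌉`,
`n_el = ⌈180/Δ⌉`, floor-indexed; azimuth 360 wraps to sector 0, the +90°
pole clamps into the top row).  Equal-angle is the simplest faithful
partition of "solid angular sectors of user-specified size"; its known
drawback — near-pole sectors subtend far smaller solid angles than
equatorial ones — is accepted and discussed under *Limitations*.  Per
non-empty sector the minimal-radius point is kept.  Ties (equal radii,
equidistant references, equidistant times) break toward earliest time,
then lowest sensor id, then input order, making every run bit-reproducible.
Points coincident with a reference point (r = 0) have no direction; they
are skipped with a logged warning rather than failing the run.

With several reference points each raw sample is hard-assigned to the
Euclidean-nearest reference (ties to lowest id) and validated only
there; the output is the union over references.

**Outlier rejection.**  The selected points are re-binned on a coarse
grid of `coarse_factor × Δ` degrees (default factor 4, capped at 90°).
In each coarse sector holding at least `min_sector_count` points
(default 3), the mean radius r̄ — candidate included, reading "the
average of the data within the section" literally — defines the cutoff
`(1 + τ)·r̄` with τ = 0.20 by default.  Points beyond the cutoff are
dropped.  Under-populated sectors pass through: a mean over one or two
points is uninformative and would make the rule self-certifying.  The
outlier stage runs exactly once per pipeline invocation; it is *not*
idempotent (removing points shifts the means), whereas the selection
stage is (asserted by test).

**Statelessness.**  The only supported incremental mode is re-running
the whole pipeline on the union of old and new raw data.
`SessionRecord` packages this as an append-only buffer with an optional
re-filter cadence (`refilter_every` N samples), replacing the original
two-thread acquire/filter design with a sequential contract that has
identical outputs and is testable without concurrency machinery.  Every
snapshot records the buffer prefix that produced it and is exactly
reproducible from that prefix.

Default filter parameters: Δ = 4° (the resolution at which the full
method is benchmarked), coarse factor 4, τ = 0.20, minimum coarse-sector
count 3.

## Simulator

The simulator replaces the glove hardware with parametric surfaces
carrying closed-form unsigned distance oracles:

* **sphere** (default R = 100 mm);
* **capped_cylinder** (default R = 35 mm, h = 200 mm — a 7 cm × 20 cm
  test object; axis along +z from 0 to h);
* **foot_like** — a composite of a heel/ankle sphere (R = 45 mm) and a
  sole modelled as a sphere-swept tapered cone (length 220 mm,
  cross-section radius 40 mm tapering by 0.6 toward the toe).  Each
  component has an exact analytic distance; the composite distance is
  their minimum, exact everywhere outside the union and an upper bound
  only inside component overlaps.  An exact oracle was deliberately
  preferred over anatomical realism.

Surface sampling is approximately area-uniform per component with
rejection of points interior to another component, so sampled points are
on the true surface to 1e-9 mm and carry outward unit normals.

A trace interleaves three sample types, chosen i.i.d. per sample:
gross outliers with probability `gross_outlier_rate` (displaced
`gross_outlier_magnitude` mm in a random direction), otherwise transit
with probability `fraction_transit`, otherwise surface.  **Transit
samples are anchored at the most recently emitted surface sample** and
displaced along that anchor's outward normal by a uniform lift (default
10–100 mm): the hand lifts off from where it last touched.  This
anchoring matters: it guarantees that on a sphere with a central
reference the anchor strictly dominates its lifted copies in the same
viewing direction, so noise-free filtering recovers the surface to
numerical precision — the exactness benchmark.  Free-flight transit
arcs between strokes are not modelled.

Sensor noise is applied to the object-frame point *before* any rigid
object motion is applied.  Physically tracker noise lives in the base
frame, but for isotropic Gaussian noise the two are distributionally
identical, and object-frame noise makes the moving and static runs of
the same seed agree exactly after compensation — which is what the
motion-compensation checks assert.

Rigid motion is a constant-rate rotation about an axis plus a constant
translation velocity, identity at t = 0; the mounted reference sensor is
carried along and emitted at every sample timestamp (exactly
synchronized poses).  The simulated reference sensor is mounted at the
model-frame origin with identity orientation, so compensated clouds live
directly in model coordinates and the analytic oracles apply; the
compensation math is still exercised nontrivially whenever the object
moves, and unit tests cover arbitrary mounting poses.

Glove-sensor multiplicity is emulated by cycling sensor ids 1..3 over
consecutive samples with a fixed per-sensor time micro-offset; there is
no hand-kinematics model and no positional offset between sensors (a
positional offset would break the exact correspondence between labels
and geometry).  Sample rate defaults to 100 Hz.

## Standard fixtures

All quality numbers refer to fixtures pinned in `glovescan.fixtures`:

| fixture | shape | n | transit | noise σ/axis | gross | refs | Δ |
|---|---|---|---|---|---|---|---|
| sphere | R = 100 | 20 000 | 50%, lift 10–100 mm | 0 | 0 | centre | 5° |
| cylinder | R = 35, h = 200 | 10 000 | 50%, lift 10–100 mm | 0 | 0 | axis h/4, 3h/4 | 5° |
| noisy foot | foot_like | 30 000 | 50%, lift 10–100 mm | 0.808 mm | 1% @ 200 mm | bridge + ankle | 4° |

The foot session length (30 000 samples, five minutes at 100 Hz) matches
the scale at which progressive build-up is demonstrated (prefixes of
10k/20k/30k at Δ = 1°).  Motion checks use 20 s of the foot trace with
30°/s rotation plus 20 mm/s translation, short enough that the object
stays inside the working volume.

What passing on these fixtures does **not** show: real scans have
spatially correlated stroke paths, adaptive re-scanning of sparse areas
by the user, sensor-mounting offsets between glove and skin (the
hardware's dominant error source, explicitly uncalibrated here), field
distortion and latency.  The fixtures isolate the filtering mathematics
from all of these.

## Evaluation

Cloud quality is measured as unsigned per-point distance to ground
truth, either analytically (parametric models) or against a triangle
mesh.  Mesh distance is the exact point-to-triangle minimum — interior
projection or nearest edge, never vertex-only, which would bias means
upward — pruned by a cKDTree on mesh vertices (yielding a per-point
upper bound) and triangle centroids (candidate sets guaranteed to
contain the minimizer).  The mesh and analytic paths cross-check each
other on a finely meshed sphere to within the chordal error of the mesh,
and the mesh path is additionally verified against a dense
surface-sampling nearest-neighbour oracle.

Filter behaviour against simulator truth labels is summarized as a 2×2
kept/dropped × surface/non-surface table.  The headline *kept-nonsurface
rate* is P(kept | truly off-surface) — the leak rate of invalid data;
the complementary purity view (share of the retained cloud that is
off-surface) is exposed as `kept_purity`.

## Numerical choices and degenerate inputs

* Radians never appear in public interfaces; all angles are degrees.
* CSV round-trips are guaranteed at 6 significant digits (written with
  `%.9g`).
* Empty inputs: an empty raw cloud filters to an empty cloud; distance
  reports and PLY export over empty clouds are errors (XYZ export of an
  empty cloud is permitted).
* The selectivity of an empty raw set is undefined and raises.
* A sweep requires strictly positive, ascending angular sizes;
  duplicates are allowed and must produce identical percentages.

## Known limitations

* **Equal-angle sectors near the poles.**  Azimuth sectors degenerate to
  slivers near elevation ±90°, so occupancy there is sparse; lone lifted
  samples landing in a surface-free sliver are retained by design (the
  coarse outlier stage catches only those beyond 20% of the local mean
  radius, so lifts below ~0.2·r̄ can persist).  This bounds the leak
  rate at roughly 4% on the noisy-foot fixture.  Equal-area partitions
  (HEALPix-like) would remove the artifact but are out of scope.
* **Multi-reference worst case on capped shapes.**  Adding reference
  points improves retained-point density at oblique angles, but on the
  capped cylinder the axial references sit closer to the end caps, where
  lifted samples swing through larger viewing angles and leak more
  often; the *worst-case* (maximum) retained distance can therefore be
  larger with two references than with one, even though coverage
  improves.  Reference placement should account for nearby high-curvature
  faces, not only obliquity.
* The outlier rule is scale-relative (20% of mean radius): it is
  insensitive to small absolute lifts near large radii and aggressive
  near small radii.
* `foot_like` is a geometric phantom, not an anatomical model; results
  on it quantify the algorithm, not clinical accuracy.
* Orientation data is carried through I/O but unused by filtering;
  classifying natural vs. manipulated shape, sensor calibration, and
  surface reconstruction from the validated cloud are all out of scope.
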