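"""Synthetic glove-scan generator standing in for the tracking hardware.

Emulates a clinician sweeping a sensing glove over a solid object inside
an electromagnetic tracker volume: on-surface strokes corrupted by
Gaussian sensor noise, lifted transit motion between strokes, occasional
gross outliers, and optional rigid motion of the scanned object observed
by an object-mounted reference sensor.

Ground-truth surfaces are parametric shapes with closed-form unsigned
distance functions, so every emitted sample carries an exact
point-to-surface distance oracle and a truth label in
``{surface, transit, gross_outlier}``.

The noise level defaults to the tracker datasheet figure of 1.4 mm RMS
3-D position error; with isotropic per-axis Gaussian noise this means
sigma = 1.4/sqrt(3) mm per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigurationError
from .geometry import IDENTITY_QUATERNION, PoseSample, ReferencePoint

#: Tracker 3-D RMS position accuracy, mm (hardware datasheet).
SENSOR_RMS_MM = 1.4

#: Per-axis Gaussian sigma reproducing the 3-D RMS figure.
SENSOR_SIGMA_PER_AXIS_MM = SENSOR_RMS_MM / np.sqrt(3.0)

LABEL_SURFACE = "surface"
LABEL_TRANSIT = "transit"
LABEL_GROSS = "gross_outlier"

_ON_SURFACE_TOL = 1e-9


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ConfigurationError("zero-length axis")
    return v / n


def _random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sd_round_cone(p, a, b, r1, r2):
    """Signed distance to a sphere-swept segment with linearly varying radius.

    ``a``/``b`` are segment endpoints with sphere radii ``r1``/``r2``
    (``r1 >= r2``).  Vectorized over (n, 3) ``p``.
    """
    p = np.atleast_2d(p)
    ba = b - a
    l2 = float(ba @ ba)
    rr = r1 - r2
    a2 = l2 - rr * rr
    if a2 <= 0:
        raise ConfigurationError("round cone degenerate: segment shorter than radius taper")
    il2 = 1.0 / l2
    pa = p - a
    y = pa @ ba
    z = y - l2
    w = pa * l2 - np.outer(y, ba)
    x2 = np.einsum("ij,ij->i", w, w)
    y2 = y * y * l2
    z2 = z * z * l2
    k = np.sign(rr) * rr * rr * x2
    d_b = np.sqrt(x2 + z2) * il2 - r2
    d_a = np.sqrt(x2 + y2) * il2 - r1
    d_side = (np.sqrt(x2 * a2 * il2) + y * rr) * il2 - r1
    out = np.where(
        np.sign(z) * a2 * z2 > k, d_b, np.where(np.sign(y) * a2 * y2 < k, d_a, d_side)
    )
    return out


@dataclass(frozen=True)
class SurfaceModel:
    """Parametric ground-truth shape with an exact unsigned distance oracle.

    Kinds
    -----
    ``sphere``
        ``radius`` mm, centred at the origin.
    ``capped_cylinder``
        ``radius``, ``height`` mm; axis along +z from z=0 to z=height.
    ``foot_like``
        Composite of analytic primitives: a sphere-swept tapered cone for
        the sole (length ``sole_length`` along +x, cross-section radius
        ``sole_width/2`` tapering by ``toe_taper`` toward the toe, axis at
        z = ``sole_height``) plus a heel/ankle sphere of radius
        ``heel_radius`` above the heel end.  The composite distance is the
        minimum over component distances: exact outside the union
        (upper-bound-exact inside component overlaps).
    """

    kind: str
    params: dict = field(default_factory=dict)

    _DEFAULTS = {
        "sphere": {"radius": 100.0},
        "capped_cylinder": {"radius": 35.0, "height": 200.0},
        "foot_like": {
            "heel_radius": 45.0,
            "sole_length": 220.0,
            "sole_width": 80.0,
            "sole_height": 45.0,
            "toe_taper": 0.6,
        },
    }

    def __post_init__(self):
        if self.kind not in self._DEFAULTS:
            raise ConfigurationError(f"unknown shape kind {self.kind!r}")
        merged = dict(self._DEFAULTS[self.kind])
        unknown = set(self.params) - set(merged)
        if unknown:
            raise ConfigurationError(f"unknown parameters for {self.kind}: {sorted(unknown)}")
        merged.update(self.params)
        object.__setattr__(self, "params", merged)

    # -- foot_like component geometry -------------------------------------
    def _foot_parts(self):
        p = self.params
        r0 = p["sole_width"] / 2.0
        r1 = p["toe_taper"] * r0
        a = np.array([0.0, 0.0, p["sole_height"]])
        b = np.array([p["sole_length"], 0.0, p["sole_height"]])
        heel_c = np.array([0.0, 0.0, p["sole_height"] + 0.6 * p["heel_radius"]])
        return a, b, r0, r1, heel_c, p["heel_radius"]

    def distance(self, points) -> np.ndarray:
        """Exact unsigned distance (mm) from each point to the surface."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "sphere":
            d = np.abs(np.linalg.norm(p, axis=1) - self.params["radius"])
        elif self.kind == "capped_cylinder":
            R, h = self.params["radius"], self.params["height"]
            rho = np.hypot(p[:, 0], p[:, 1])
            dx = rho - R
            dy = np.abs(p[:, 2] - h / 2.0) - h / 2.0
            inside = np.minimum(np.maximum(dx, dy), 0.0)
            outside = np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0))
            d = np.abs(inside + outside)
        else:
            a, b, r0, r1, heel_c, heel_r = self._foot_parts()
            d_sole = _sd_round_cone(p, a, b, r0, r1)
            d_heel = np.linalg.norm(p - heel_c, axis=1) - heel_r
            d = np.minimum(np.abs(d_sole), np.abs(d_heel))
        return d if np.asarray(points).ndim == 2 else d

    def surface_distance(self, point) -> float:
        """Scalar convenience wrapper around :meth:`distance`."""
        return float(self.distance(np.asarray(point, dtype=float).reshape(1, 3))[0])

    def contains(self, points) -> np.ndarray:
        """True where a point is strictly inside the solid."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "sphere":
            return np.linalg.norm(p, axis=1) < self.params["radius"]
        if self.kind == "capped_cylinder":
            R, h = self.params["radius"], self.params["height"]
            rho = np.hypot(p[:, 0], p[:, 1])
            return (rho < R) & (p[:, 2] > 0) & (p[:, 2] < h)
        a, b, r0, r1, heel_c, heel_r = self._foot_parts()
        in_sole = _sd_round_cone(p, a, b, r0, r1) < 0
        in_heel = np.linalg.norm(p - heel_c, axis=1) < heel_r
        return in_sole | in_heel

    def sample_surface(self, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` surface points with outward unit normals.

        Sampling is approximately area-uniform per component; points interior
        to another component of a composite are rejected so every returned
        point satisfies ``distance(p) <= 1e-9``.
        """
        pts = np.empty((0, 3))
        nrm = np.empty((0, 3))
        while len(pts) < n:
            cand_p, cand_n = self._propose_surface(max(n - len(pts), 32), rng)
            keep = self.distance(cand_p) <= _ON_SURFACE_TOL
            pts = np.vstack([pts, cand_p[keep]])
            nrm = np.vstack([nrm, cand_n[keep]])
        return pts[:n], nrm[:n]

    def _propose_surface(self, n, rng):
        if self.kind == "sphere":
            d = _random_unit_vectors(rng, n)
            return self.params["radius"] * d, d
        if self.kind == "capped_cylinder":
            R, h = self.params["radius"], self.params["height"]
            area_side = 2 * np.pi * R * h
            area_cap = np.pi * R * R
            which = rng.uniform(0, area_side + 2 * area_cap, size=n)
            phi = rng.uniform(0, 2 * np.pi, size=n)
            pts = np.empty((n, 3))
            nrm = np.empty((n, 3))
            side = which < area_side
            z = rng.uniform(0, h, size=n)
            pts[side] = np.c_[R * np.cos(phi[side]), R * np.sin(phi[side]), z[side]]
            nrm[side] = np.c_[np.cos(phi[side]), np.sin(phi[side]), np.zeros(side.sum())]
            caps = ~side
            rad = R * np.sqrt(rng.uniform(0, 1, size=n))
            top = which >= area_side + area_cap
            zc = np.where(top, h, 0.0)
            nz = np.where(top, 1.0, -1.0)
            pts[caps] = np.c_[
                rad[caps] * np.cos(phi[caps]), rad[caps] * np.sin(phi[caps]), zc[caps]
            ]
            nrm[caps] = np.c_[np.zeros(caps.sum()), np.zeros(caps.sum()), nz[caps]]
            return pts, nrm
        return self._propose_foot(n, rng)

    def _propose_foot(self, n, rng):
        a, b, r0, r1, heel_c, heel_r = self._foot_parts()
        L = float(np.linalg.norm(b - a))
        u = (b - a) / L
        sin_t = (r0 - r1) / L
        cos_t = np.sqrt(1.0 - sin_t**2)
        slant = np.sqrt(L * L - (r0 - r1) ** 2) / cos_t  # lateral slant length
        area_heel = 4 * np.pi * heel_r**2
        area_cap_a = 2 * np.pi * r0**2 * (1 + sin_t)
        area_cap_b = 2 * np.pi * r1**2 * (1 - sin_t)
        area_lat = np.pi * (r0 + r1) * slant
        areas = np.array([area_heel, area_cap_a, area_cap_b, area_lat])
        comp = rng.choice(4, size=n, p=areas / areas.sum())
        pts = np.empty((n, 3))
        nrm = np.empty((n, 3))
        dirs = _random_unit_vectors(rng, n)
        for ci in range(4):
            m = comp == ci
            k = int(m.sum())
            if k == 0:
                continue
            if ci == 0:
                pts[m] = heel_c + heel_r * dirs[m]
                nrm[m] = dirs[m]
            elif ci in (1, 2):
                c, r = (a, r0) if ci == 1 else (b, r1)
                d = dirs[m]
                # keep only the exposed cap of the end sphere
                proj = d @ u
                bad = (proj > sin_t) if ci == 1 else (proj < sin_t)
                d[bad] *= -1.0  # mirror: preserves uniformity on the cap
                proj = d @ u
                still = (proj > sin_t) if ci == 1 else (proj < sin_t)
                d[still] = np.array([0.0, 0.0, -1.0]) if ci == 1 else _unit(u)
                pts[m] = c + r * d
                nrm[m] = d
            else:
                s = _taper_param(rng, int(m.sum()), r0, r1)
                phi = rng.uniform(0, 2 * np.pi, size=k)
                # radial basis perpendicular to the x-aligned axis
                v = np.c_[np.zeros(k), np.cos(phi), np.sin(phi)]
                w = sin_t * u + cos_t * v
                c = a + np.outer(s, (b - a))
                r = r0 + s * (r1 - r0)
                pts[m] = c + r[:, None] * w
                nrm[m] = w
        return pts, nrm


def _taper_param(rng, k, r0, r1):
    """Axial parameter s in [0,1] with density proportional to local radius."""
    # inverse-CDF sampling of r(s) = r0 + s (r1 - r0)
    uu = rng.uniform(0, 1, size=k)
    if abs(r1 - r0) < 1e-12:
        return uu
    return (np.sqrt(r0 * r0 + uu * (r1 * r1 - r0 * r0)) - r0) / (r1 - r0)


@dataclass(frozen=True)
class TraceConfig:
    """Parameters of a simulated scanning session.

    ``noise_sigma`` is the per-axis Gaussian sigma in mm (default reproduces
    the tracker's 1.4 mm 3-D RMS).  ``fraction_transit`` of samples are
    lifted off the surface along the local normal by a uniform
    ``lift_range`` distance, emulating the hand travelling through air.
    ``gross_outlier_rate`` samples are thrown ``gross_outlier_magnitude``
    mm in a random direction, emulating tracker glitches.
    """

    n_samples: int = 10_000
    fraction_transit: float = 0.5
    lift_range: tuple[float, float] = (10.0, 100.0)
    noise_sigma: float = SENSOR_SIGMA_PER_AXIS_MM
    gross_outlier_rate: float = 0.0
    gross_outlier_magnitude: float = 200.0
    seed: int = 0
    n_glove_sensors: int = 3
    sample_rate_hz: float = 100.0

    def __post_init__(self):
        if not (0.0 <= self.fraction_transit <= 1.0):
            raise ConfigurationError("fraction_transit must be in [0, 1]")
        if not (0.0 <= self.gross_outlier_rate <= 1.0):
            raise ConfigurationError("gross_outlier_rate must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.lift_range[0] < 0 or self.lift_range[1] < self.lift_range[0]:
            raise ConfigurationError("lift_range must satisfy 0 <= lo <= hi")
        if self.n_samples < 0 or self.n_glove_sensors < 1:
            raise ConfigurationError("n_samples >= 0 and n_glove_sensors >= 1 required")


@dataclass(frozen=True)
class RigidMotion:
    """Time-parameterized rigid motion of the scanned object.

    Rotation by ``angular_rate_deg_s`` degrees/second about ``axis`` through
    ``center``, plus translation at ``velocity_mm_s``.  Identity at t=0.
    """

    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    angular_rate_deg_s: float = 0.0
    velocity_mm_s: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def transform(self, points: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Apply the motion at per-point times ``t`` to (n, 3) ``points``."""
        points = np.atleast_2d(points)
        t = np.asarray(t, dtype=float).reshape(len(points))
        axis = _unit(self.axis)
        rotvec = np.outer(np.deg2rad(self.angular_rate_deg_s) * t, axis)
        rot = Rotation.from_rotvec(rotvec)
        c = np.asarray(self.center, dtype=float)
        v = np.asarray(self.velocity_mm_s, dtype=float)
        return rot.apply(points - c) + c + np.outer(t, v)

    def rotations(self, t: np.ndarray) -> Rotation:
        axis = _unit(self.axis)
        return Rotation.from_rotvec(
            np.outer(np.deg2rad(self.angular_rate_deg_s) * np.asarray(t, float), axis)
        )


@dataclass
class ScanTrace:
    """Output of :func:`generate_trace`.

    ``samples`` are glove readings in the (possibly moving) base frame;
    ``reference_stream`` is the object-mounted sensor sampled at the same
    timestamps; ``labels`` hold the ground truth per glove sample.
    """

    samples: list
    labels: list
    reference_stream: list
    model: SurfaceModel
    #: Pre-noise object-frame positions (surface/lifted/gross targets); the
    #: per-sample 3-D position error is ``object-frame sample - true_positions``.
    true_positions: np.ndarray = None

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.samples]).reshape(-1, 3)


#: Mounting pose of the simulated reference sensor in the model frame.
#: Identity by construction, so frame-compensated coordinates coincide with
#: model coordinates and analytic distance oracles apply directly; the
#: compensation math is still exercised whenever the object moves.
_REF_SENSOR_OFFSET = np.zeros(3)
_REF_SENSOR_QUAT = IDENTITY_QUATERNION.copy()


def generate_trace(
    model: SurfaceModel, cfg: TraceConfig, motion: RigidMotion | None = None
) -> ScanTrace:
    """Simulate one scanning session over ``model``.

    Deterministic given ``cfg.seed``.  Sensor noise, lifts and gross
    displacements are applied in the object frame; if ``motion`` is given the
    noisy object-frame points and the mounted reference-sensor pose are then
    both carried into the moving base frame, so that frame compensation
    against the emitted reference stream exactly reproduces the static scene.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    surf, normals = model.sample_surface(n, rng) if n else (np.empty((0, 3)), np.empty((0, 3)))

    is_gross = rng.uniform(size=n) < cfg.gross_outlier_rate
    is_transit = (~is_gross) & (rng.uniform(size=n) < cfg.fraction_transit)
    labels = np.where(is_gross, LABEL_GROSS, np.where(is_transit, LABEL_TRANSIT, LABEL_SURFACE))

    # Transit samples model the hand lifting off from where it last touched:
    # each is anchored at the most recent surface-labelled sample (leading
    # transits borrow the first surface anchor), displaced along that
    # anchor's outward normal.  Anchoring at *emitted* surface samples is
    # what makes the lifted copy strictly farther than its anchor in the
    # same viewing direction, so noise-free filtering recovers the surface
    # exactly.
    is_surface = ~(is_gross | is_transit)
    anchor = np.arange(n)
    surf_order = np.flatnonzero(is_surface)
    if surf_order.size and n:
        last = np.maximum.accumulate(np.where(is_surface, np.arange(n), -1))
        last = np.where(last >= 0, last, surf_order[0])
        anchor = np.where(is_transit, last, anchor)

    obj_pts = surf[anchor]
    lifts = rng.uniform(*cfg.lift_range, size=n)
    obj_pts[is_transit] += normals[anchor[is_transit]] * lifts[is_transit, None]
    gross_dirs = _random_unit_vectors(rng, n) if n else np.empty((0, 3))
    obj_pts[is_gross] += gross_dirs[is_gross] * cfg.gross_outlier_magnitude
    clean = obj_pts.copy()
    if cfg.noise_sigma > 0:
        obj_pts = obj_pts + rng.normal(scale=cfg.noise_sigma, size=(n, 3))

    t = np.arange(n) / cfg.sample_rate_hz
    sensor_ids = 1 + (np.arange(n) % cfg.n_glove_sensors)
    # fixed per-sensor time micro-offset: sensors report in a round-robin burst
    t = t + (sensor_ids - 1) * (0.1 / cfg.sample_rate_hz / max(cfg.n_glove_sensors, 1))

    ref_rot_obj = Rotation.from_quat(_REF_SENSOR_QUAT, scalar_first=True)
    if motion is None:
        base_pts = obj_pts
        ref_pos = np.tile(_REF_SENSOR_OFFSET, (n, 1))
        ref_quat = np.tile(_REF_SENSOR_QUAT, (n, 1))
    else:
        base_pts = motion.transform(obj_pts, t)
        rot = motion.rotations(t)
        ref_pos = motion.transform(np.tile(_REF_SENSOR_OFFSET, (n, 1)), t)
        ref_quat = (rot * ref_rot_obj).as_quat(scalar_first=True)
        # renormalize against accumulated float error
        ref_quat = ref_quat / np.linalg.norm(ref_quat, axis=1, keepdims=True)

    samples = [
        PoseSample(int(sensor_ids[i]), float(t[i]), base_pts[i], IDENTITY_QUATERNION)
        for i in range(n)
    ]
    reference_stream = [
        PoseSample(0, float(t[i]), ref_pos[i], ref_quat[i]) for i in range(n)
    ]
    return ScanTrace(
        samples=samples,
        labels=list(labels),
        reference_stream=reference_stream,
        model=model,
        true_positions=clean,
    )


def plant_reference_points(model: SurfaceModel, k: int) -> list[ReferencePoint]:
    """``k`` reference points strictly interior to ``model``.

    Placement rules: sphere — along the vertical diameter (centre for k=1);
    capped cylinder — evenly spaced on the axis at heights ``(i+1/2) h/k``;
    foot_like — a fixed anchor list (bridge of the foot, ankle, heel, toe),
    at most 4.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if model.kind == "sphere":
        R = model.params["radius"]
        zs = 0.8 * R * ((2 * np.arange(k) + 1) / k - 1)
        pts = [np.array([0.0, 0.0, z]) for z in zs]
    elif model.kind == "capped_cylinder":
        h = model.params["height"]
        pts = [np.array([0.0, 0.0, (i + 0.5) * h / k]) for i in range(k)]
    else:
        p = model.params
        a, b, r0, r1, heel_c, heel_r = model._foot_parts()
        anchors = [
            a + 0.45 * (b - a),          # bridge of the foot
            heel_c,                       # ankle
            a,                            # heel end of the sole
            a + 0.85 * (b - a),          # toe
        ]
        if k > len(anchors):
            raise ConfigurationError(
                f"foot_like supports at most {len(anchors)} reference points"
            )
        pts = anchors[:k]
    refs = [ReferencePoint(id=i, position=pt) for i, pt in enumerate(pts)]
    inside = model.contains(np.array([r.position for r in refs]))
    if not np.all(inside):
        raise ConfigurationError("planted reference point falls outside the model")
    return refs
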