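"""Pose representation, rigid-frame compensation and spherical coordinates.

All positions are millimetres, all times seconds.  Orientations are unit
quaternions in scalar-first ``(w, x, y, z)`` order, rotating sensor-local
axes into base-station axes.  The frame conventions used throughout the
package:

* right-handed Cartesian frames;
* azimuth in degrees, measured in the x-y plane from +x toward +y,
  wrapped to ``[0, 360)``;
* elevation in degrees, measured from the x-y plane toward +z,
  in ``[-90, +90]``.

Re-expressing every glove sample in the frame of a sensor rigidly mounted
on the scanned object cancels object motion: if the object (and with it
the mounted reference sensor) moves rigidly during the scan, the
object-frame cloud is unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateDirectionError, InvalidOrientationError, NoReferenceError

#: Half-side of the tracker working volume (750 mm = 75 cm cube).
WORKING_VOLUME_HALF_SIDE_MM = 750.0

#: Maximum deviation of a quaternion norm from 1 before it is rejected.
QUATERNION_NORM_TOL = 1e-6

IDENTITY_QUATERNION = np.array([1.0, 0.0, 0.0, 0.0])


class WorkingVolumeWarning(UserWarning):
    """A coordinate lies outside the tracker's specified working volume."""


@dataclass(frozen=True)
class PoseSample:
    """One time-stamped 6-DoF reading from one sensor, base-station frame.

    Parameters
    ----------
    sensor_id
        Small integer sensor label; the object-mounted reference sensor
        conventionally uses id 0.
    t
        Acquisition time in seconds.
    position
        3-vector in mm, base-station frame.
    orientation
        Unit quaternion ``(w, x, y, z)``.
    """

    sensor_id: int
    t: float
    position: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: IDENTITY_QUATERNION.copy())

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        quat = np.asarray(self.orientation, dtype=float).reshape(4)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "orientation", quat)
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(quat)):
            raise ValueError("PoseSample coordinates must be finite")
        if abs(np.linalg.norm(quat) - 1.0) > QUATERNION_NORM_TOL:
            raise InvalidOrientationError(
                f"quaternion norm {np.linalg.norm(quat):.6g} deviates from 1"
            )
        if np.any(np.abs(pos) > WORKING_VOLUME_HALF_SIDE_MM):
            warnings.warn(
                f"sample at t={self.t:.4g}s lies outside the nominal "
                f"{2 * WORKING_VOLUME_HALF_SIDE_MM / 10:.0f} cm working volume",
                WorkingVolumeWarning,
                stacklevel=2,
            )

    def rotation(self) -> Rotation:
        """Orientation as a scipy Rotation (sensor-local -> base frame)."""
        return Rotation.from_quat(self.orientation, scalar_first=True)


@dataclass(frozen=True)
class ObjectFramePoint:
    """A glove sample re-expressed in the object (reference-sensor) frame."""

    position: np.ndarray
    sensor_id: int
    t: float

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        object.__setattr__(self, "position", pos)
        if not np.all(np.isfinite(pos)):
            raise ValueError("ObjectFramePoint coordinates must be finite")


@dataclass(frozen=True)
class ReferencePoint:
    """An origin inside the object anchoring the sector filter."""

    id: int
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float).reshape(3)
        object.__setattr__(self, "position", pos)
        if not np.all(np.isfinite(pos)):
            raise ValueError("ReferencePoint coordinates must be finite")


@dataclass(frozen=True)
class SphericalCoordinate:
    """Radius (mm) + direction (azimuth/elevation, degrees) about an origin."""

    r: float
    azimuth: float
    elevation: float


def to_object_frame(sample: PoseSample, ref_pose: PoseSample) -> ObjectFramePoint:
    """Re-express ``sample`` in the frame of the object-mounted reference sensor.

    Computes ``R^T (p - t_ref)`` where ``R`` is the reference orientation as a
    rotation matrix and ``t_ref`` its position.  ``sensor_id`` and ``t`` pass
    through unchanged.
    """
    rel = sample.position - ref_pose.position
    pos = ref_pose.rotation().inv().apply(rel)
    return ObjectFramePoint(position=pos, sensor_id=sample.sensor_id, t=sample.t)


def to_object_frame_many(
    positions: np.ndarray, ref_positions: np.ndarray, ref_quats: np.ndarray
) -> np.ndarray:
    """Vectorized frame compensation for ``n`` samples with per-sample reference poses.

    Parameters
    ----------
    positions : (n, 3) base-frame glove positions, mm.
    ref_positions : (n, 3) matched reference-sensor positions.
    ref_quats : (n, 4) matched reference-sensor quaternions, scalar-first.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    rel = positions - np.atleast_2d(ref_positions)
    rot = Rotation.from_quat(np.atleast_2d(ref_quats), scalar_first=True)
    return rot.inv().apply(rel)


def match_reference_pose(sample: PoseSample, ref_stream) -> PoseSample:
    """Return the reference sample nearest in time; ties break toward the earlier one.

    ``ref_stream`` must be non-empty and time-sorted.  Samples before the first
    or after the last reference clamp to the extremes.
    """
    refs = list(ref_stream)
    if not refs:
        raise NoReferenceError("reference stream is empty")
    times = np.array([r.t for r in refs])
    idx = match_reference_indices(np.array([sample.t]), times)[0]
    return refs[idx]


def match_reference_indices(sample_times: np.ndarray, ref_times: np.ndarray) -> np.ndarray:
    """Vectorized nearest-in-time matching; ties toward the earlier reference."""
    ref_times = np.asarray(ref_times, dtype=float)
    if ref_times.size == 0:
        raise NoReferenceError("reference stream is empty")
    sample_times = np.asarray(sample_times, dtype=float)
    right = np.searchsorted(ref_times, sample_times, side="left")
    right = np.clip(right, 0, ref_times.size - 1)
    left = np.clip(right - 1, 0, ref_times.size - 1)
    # earlier wins on ties: strict inequality required to prefer the right side
    d_left = np.abs(sample_times - ref_times[left])
    d_right = np.abs(ref_times[right] - sample_times)
    return np.where(d_right < d_left, right, left)


def to_spherical(p: np.ndarray, origin: np.ndarray) -> SphericalCoordinate:
    """Spherical coordinates of ``p`` about ``origin`` (degrees, mm).

    Raises :class:`DegenerateDirectionError` when ``p`` coincides with the
    origin (no direction defined).  At the poles (elevation +/-90) the azimuth
    is defined as 0 by convention.
    """
    v = np.asarray(p, dtype=float) - np.asarray(origin, dtype=float)
    r = float(np.linalg.norm(v))
    if r == 0.0:
        raise DegenerateDirectionError("point coincides with the origin")
    az, el = _direction_angles(v[np.newaxis, :])
    return SphericalCoordinate(r=r, azimuth=float(az[0]), elevation=float(el[0]))


def from_spherical(sph: SphericalCoordinate, origin: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_spherical`."""
    az = np.deg2rad(sph.azimuth)
    el = np.deg2rad(sph.elevation)
    direction = np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    return np.asarray(origin, dtype=float) + sph.r * direction


def _direction_angles(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Azimuth in [0, 360) and elevation in [-90, 90] for (n, 3) vectors."""
    rho = np.hypot(v[:, 0], v[:, 1])
    az = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    az = np.where(rho == 0.0, 0.0, np.mod(az, 360.0))
    el = np.degrees(np.arctan2(v[:, 2], rho))
    return az, el


def spherical_about(points: np.ndarray, origin: np.ndarray):
    """Vectorized spherical decomposition: returns ``(r, azimuth, elevation)`` arrays."""
    v = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(origin, dtype=float)
    r = np.linalg.norm(v, axis=1)
    az, el = _direction_angles(v)
    return r, az, el
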