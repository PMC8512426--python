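"""Volume-minimization selection and coarse-sector outlier rejection.

The filter turns an unorganized object-frame sample cloud into a surface
estimate in two stages, anchored on one or more user-chosen reference
points placed strictly inside the scanned object:

1. **Selection** — directions around each reference point are partitioned
   into solid angular sectors (an equal-angle azimuth x elevation grid of
   user-chosen angular size).  Within each sector only the sample closest
   to the reference point is retained; the retained set encloses the
   reference point in the smallest volume, which for a solid object is
   the surface seen from inside.

2. **Outlier rejection** — a lone sample in a sector is kept by stage 1
   no matter how far away it is.  A second pass therefore bins the
   *selected* points on a coarser angular grid, computes each coarse
   sector's mean radius, and drops points more than a fractional
   threshold (default 20%) further out than that mean.

With several reference points, each sample is validated only by the
reference it is closest to, and the final cloud is the union over
references.  The pipeline is stateless: incremental scanning re-runs the
full filter on the entire accumulated raw buffer, so previously rejected
samples can be re-admitted and vice versa as data accumulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .geometry import ObjectFramePoint, ReferencePoint, SphericalCoordinate, spherical_about

logger = logging.getLogger(__name__)

# Per-point provenance codes.
SELECTED = "selected"
DROPPED_NOT_CLOSEST = "dropped_not_closest"
DROPPED_OUTLIER = "dropped_outlier"

_STATUS_NAMES = (SELECTED, DROPPED_NOT_CLOSEST, DROPPED_OUTLIER)


@dataclass(frozen=True)
class SectorGrid:
    """Equal-angle partition of directions into azimuth x elevation sectors.

    ``angular_size`` is in degrees, in (0, 90].  Sectors are floor-indexed;
    azimuth 360 wraps to sector 0 and the +90 elevation pole clamps into the
    topmost row.  Near-pole sectors subtend smaller solid angles than
    equatorial ones; the partition is equal-angle, not equal-area.
    """

    angular_size: float

    def __post_init__(self):
        if not (0.0 < self.angular_size <= 90.0):
            raise ConfigurationError(
                f"angular_size must be in (0, 90] degrees, got {self.angular_size}"
            )

    @property
    def n_az(self) -> int:
        return int(np.ceil(360.0 / self.angular_size))

    @property
    def n_el(self) -> int:
        return int(np.ceil(180.0 / self.angular_size))

    def sector_of(self, azimuth, elevation):
        """Vectorized sector lookup; accepts scalars or arrays (degrees)."""
        az = np.mod(np.asarray(azimuth, dtype=float), 360.0)
        el = np.asarray(elevation, dtype=float)
        i_az = np.minimum(np.floor(az / self.angular_size).astype(np.int64), self.n_az - 1)
        i_el = np.minimum(
            np.floor((el + 90.0) / self.angular_size).astype(np.int64), self.n_el - 1
        )
        return i_az, i_el

    def flat_index(self, i_az, i_el):
        return np.asarray(i_el, dtype=np.int64) * self.n_az + np.asarray(i_az, dtype=np.int64)


def sector_index(sph: SphericalCoordinate, grid: SectorGrid) -> tuple[int, int]:
    """Sector ``(i_az, i_el)`` of a single spherical coordinate."""
    i_az, i_el = grid.sector_of(sph.azimuth, sph.elevation)
    return int(i_az), int(i_el)


@dataclass(frozen=True)
class FilterConfig:
    """Knobs of the two-stage filter.

    Parameters
    ----------
    fine_angular_size
        Selection-grid sector size in degrees.  Smaller values preserve
        finer features but retain more noise and invalid samples.
    coarse_factor
        The outlier grid uses ``coarse_factor * fine_angular_size`` degree
        sectors (capped at 90), so each coarse sector pools enough selected
        points for a meaningful mean radius.
    outlier_threshold
        Fractional radius excess over the coarse-sector mean beyond which a
        point is rejected; 0.20 rejects points more than 20% further out
        than the sector average.
    min_sector_count
        Coarse sectors holding fewer selected points than this pass through
        unfiltered (a mean over 1-2 points is uninformative).
    """

    fine_angular_size: float = 4.0
    coarse_factor: float = 4.0
    outlier_threshold: float = 0.20
    min_sector_count: int = 3

    def __post_init__(self):
        if self.fine_angular_size <= 0 or self.fine_angular_size > 90:
            raise ConfigurationError("fine_angular_size must be in (0, 90] degrees")
        if self.coarse_factor < 1:
            raise ConfigurationError("coarse_factor must be >= 1")
        if not (0.0 < self.outlier_threshold < 1.0):
            raise ConfigurationError("outlier_threshold must be in (0, 1)")
        if self.min_sector_count < 2:
            raise ConfigurationError("min_sector_count must be >= 2")

    @property
    def fine_grid(self) -> SectorGrid:
        return SectorGrid(self.fine_angular_size)

    @property
    def coarse_grid(self) -> SectorGrid:
        return SectorGrid(min(self.coarse_factor * self.fine_angular_size, 90.0))


class ValidatedCloud:
    """Filter output: every input point with per-point provenance.

    Attributes (all length-n arrays aligned with the raw input order):

    * ``positions`` — (n, 3) object-frame coordinates, mm
    * ``sensor_ids``, ``times`` — carried through from the input
    * ``ref_ids`` — id of the reference point each sample was assigned to
      (-1 for degenerate points coincident with their reference)
    * ``sector_az``, ``sector_el`` — fine-grid sector indices (-1 degenerate)
    * ``status`` — one of ``selected``, ``dropped_not_closest``,
      ``dropped_outlier`` per point
    """

    def __init__(self, positions, sensor_ids, times, ref_ids, sector_az, sector_el, status):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.sensor_ids = np.asarray(sensor_ids, dtype=np.int64).reshape(n)
        self.times = np.asarray(times, dtype=float).reshape(n)
        self.ref_ids = np.asarray(ref_ids, dtype=np.int64).reshape(n)
        self.sector_az = np.asarray(sector_az, dtype=np.int64).reshape(n)
        self.sector_el = np.asarray(sector_el, dtype=np.int64).reshape(n)
        self.status = np.asarray(status, dtype=object).reshape(n)

    @classmethod
    def empty(cls) -> "ValidatedCloud":
        z = np.empty((0,))
        return cls(np.empty((0, 3)), z, z, z, z, z, np.empty((0,), dtype=object))

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def selected_mask(self) -> np.ndarray:
        return self.status == SELECTED

    @property
    def selected_points(self) -> np.ndarray:
        """(k, 3) array of retained object-frame positions."""
        return self.positions[self.selected_mask]

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.selected_mask))

    def selected_cloud_points(self) -> list[ObjectFramePoint]:
        idx = np.flatnonzero(self.selected_mask)
        return [
            ObjectFramePoint(self.positions[i], int(self.sensor_ids[i]), float(self.times[i]))
            for i in idx
        ]

    def to_frame(self):
        """Provenance table as a pandas DataFrame (for CSV export)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "sensor_id": self.sensor_ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "ref_id": self.ref_ids,
                "sector_az": self.sector_az,
                "sector_el": self.sector_el,
                "status": self.status,
            }
        )


def _as_arrays(points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a list of ObjectFramePoint or an (n,3) array-like."""
    if isinstance(points, ValidatedCloud):
        raise TypeError("pass raw points, not a ValidatedCloud")
    seq = list(points) if not isinstance(points, np.ndarray) else points
    if len(seq) == 0:
        return np.empty((0, 3)), np.empty(0, dtype=np.int64), np.empty(0)
    if isinstance(seq[0], ObjectFramePoint):
        pos = np.array([p.position for p in seq])
        sid = np.array([p.sensor_id for p in seq], dtype=np.int64)
        t = np.array([p.t for p in seq])
        return pos, sid, t
    pos = np.asarray(seq, dtype=float).reshape(-1, 3)
    n = len(pos)
    return pos, np.zeros(n, dtype=np.int64), np.zeros(n)


def assign_to_nearest_reference(points, refs: list[ReferencePoint]) -> np.ndarray:
    """Assign each point to the Euclidean-nearest reference; ties to lowest id.

    Returns an array of reference *ids* aligned with the input order.
    """
    if not refs:
        raise ConfigurationError("at least one reference point is required")
    ids = [r.id for r in refs]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("reference point ids must be unique")
    order = np.argsort(ids, kind="stable")
    ref_pos = np.array([refs[i].position for i in order])
    ref_ids = np.array([ids[i] for i in order], dtype=np.int64)
    pos, _, _ = _as_arrays(points)
    if len(pos) == 0:
        return np.empty(0, dtype=np.int64)
    # argmin returns the first minimum; refs sorted by id => ties to lowest id
    d2 = ((pos[:, None, :] - ref_pos[None, :, :]) ** 2).sum(axis=2)
    return ref_ids[np.argmin(d2, axis=1)]


def _select_min_per_group(keys: np.ndarray, r: np.ndarray, t: np.ndarray, sid: np.ndarray):
    """Indices of the minimal-radius member of each group.

    Ties break toward earliest time, then lowest sensor id, then input order.
    """
    order = np.lexsort((np.arange(len(keys)), sid, t, r, keys))
    sorted_keys = keys[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = sorted_keys[1:] != sorted_keys[:-1]
    return order[first]


def select_closest_per_sector(
    points, origin: ReferencePoint, grid: SectorGrid,
    sensor_ids=None, times=None,
) -> ValidatedCloud:
    """Keep, per non-empty fine sector, only the point closest to ``origin``.

    Points coincident with the origin have no direction and are skipped with
    a warning (status ``dropped_not_closest``, sector -1).  When ``points``
    is a bare coordinate array, ``sensor_ids`` and ``times`` may supply the
    tie-breaking metadata (both default to zeros).
    """
    pos, sid, t = _as_arrays(points)
    if sensor_ids is not None:
        sid = np.asarray(sensor_ids, dtype=np.int64).reshape(len(pos))
    if times is not None:
        t = np.asarray(times, dtype=float).reshape(len(pos))
    n = len(pos)
    status = np.full(n, DROPPED_NOT_CLOSEST, dtype=object)
    sec_az = np.full(n, -1, dtype=np.int64)
    sec_el = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return ValidatedCloud(pos, sid, t, np.full(0, origin.id), sec_az, sec_el, status)
    r, az, el = spherical_about(pos, origin.position)
    ok = r > 0.0
    if not np.all(ok):
        logger.warning(
            "%d point(s) coincide with reference %d; skipped",
            int(np.count_nonzero(~ok)),
            origin.id,
        )
    i_az, i_el = grid.sector_of(az[ok], el[ok])
    sec_az[ok] = i_az
    sec_el[ok] = i_el
    flat = grid.flat_index(i_az, i_el)
    idx_ok = np.flatnonzero(ok)
    winners = idx_ok[_select_min_per_group(flat, r[ok], t[ok], sid[ok])]
    status[winners] = SELECTED
    ref_ids = np.full(n, origin.id, dtype=np.int64)
    ref_ids[~ok] = -1
    return ValidatedCloud(pos, sid, t, ref_ids, sec_az, sec_el, status)


def reject_outliers(
    selected: ValidatedCloud,
    origin: ReferencePoint,
    coarse_grid: SectorGrid,
    threshold: float = 0.20,
    min_sector_count: int = 3,
) -> ValidatedCloud:
    """Drop selected points far outside their coarse sector's mean radius.

    Within each coarse sector holding at least ``min_sector_count`` selected
    points, the mean radius r-bar is computed (candidate included) and every
    point with ``r > (1 + threshold) * r-bar`` is re-flagged
    ``dropped_outlier``.  Under-populated sectors pass through unchanged.
    """
    if threshold <= 0:
        raise ConfigurationError("outlier threshold must be positive")
    status = selected.status.copy()
    sel = np.flatnonzero(selected.selected_mask)
    if sel.size:
        pos = selected.positions[sel]
        r, az, el = spherical_about(pos, origin.position)
        flat = coarse_grid.flat_index(*coarse_grid.sector_of(az, el))
        uniq, inv, counts = np.unique(flat, return_inverse=True, return_counts=True)
        sums = np.bincount(inv, weights=r, minlength=len(uniq))
        mean_r = sums / counts
        drop = (counts[inv] >= min_sector_count) & (r > (1.0 + threshold) * mean_r[inv])
        status[sel[drop]] = DROPPED_OUTLIER
    return ValidatedCloud(
        selected.positions,
        selected.sensor_ids,
        selected.times,
        selected.ref_ids,
        selected.sector_az,
        selected.sector_el,
        status,
    )


def filter_pipeline(
    all_points, refs: list[ReferencePoint], config: FilterConfig | None = None
) -> ValidatedCloud:
    """Full two-stage filter over the entire accumulated dataset.

    Composition: assign each point to its nearest reference, run per-reference
    sector selection on the fine grid, then per-reference coarse-sector
    outlier rejection.  Output provenance covers every input point in input
    order.  The only supported incremental mode is re-running this function
    on the union of old and new raw data.
    """
    if config is None:
        config = FilterConfig()
    pos, sid, t = _as_arrays(all_points)
    n = len(pos)
    if not refs:
        raise ConfigurationError("at least one reference point is required")
    if n == 0:
        return ValidatedCloud.empty()
    assigned = assign_to_nearest_reference(pos, refs)
    ref_ids = np.full(n, -1, dtype=np.int64)
    sec_az = np.full(n, -1, dtype=np.int64)
    sec_el = np.full(n, -1, dtype=np.int64)
    status = np.full(n, DROPPED_NOT_CLOSEST, dtype=object)
    fine = config.fine_grid
    coarse = config.coarse_grid
    for ref in sorted(refs, key=lambda r: r.id):
        mask = np.flatnonzero(assigned == ref.id)
        if mask.size == 0:
            continue
        frag = select_closest_per_sector(
            pos[mask], ref, fine, sensor_ids=sid[mask], times=t[mask]
        )
        frag = reject_outliers(
            frag, ref, coarse, config.outlier_threshold, config.min_sector_count
        )
        ref_ids[mask] = frag.ref_ids
        sec_az[mask] = frag.sector_az
        sec_el[mask] = frag.sector_el
        status[mask] = frag.status
    out = ValidatedCloud(pos, sid, t, ref_ids, sec_az, sec_el, status)
    logger.info(
        "filter_pipeline: %d raw -> %d selected (%.1f%%), %d dropped_not_closest, "
        "%d dropped_outlier",
        n,
        out.n_selected,
        100.0 * out.n_selected / n,
        int(np.count_nonzero(out.status == DROPPED_NOT_CLOSEST)),
        int(np.count_nonzero(out.status == DROPPED_OUTLIER)),
    )
    return out


def selectivity(raw_count: int, kept_count: int) -> float:
    """Percentage of raw samples surviving filtering."""
    if raw_count <= 0:
        raise ConfigurationError("selectivity undefined for raw_count = 0")
    if not (0 <= kept_count <= raw_count):
        raise ConfigurationError("kept_count must be in [0, raw_count]")
    return 100.0 * kept_count / raw_count


def compute_reference_point(
    samples, window: tuple[float, float], reference_sensor_id: int, ref_id: int = 0
) -> ReferencePoint:
    """Mean position of all non-reference-sensor samples within a time window.

    This is how a user marks a reference point with the glove itself: hold the
    glove sensors inside/around the target location for a moment and average.
    """
    t0, t1 = window
    acc = []
    for s in samples:
        if s.sensor_id == reference_sensor_id:
            continue
        if t0 <= s.t <= t1:
            acc.append(s.position)
    if not acc:
        raise ConfigurationError(f"no non-reference samples in window [{t0}, {t1}]")
    return ReferencePoint(id=ref_id, position=np.mean(np.array(acc), axis=0))
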