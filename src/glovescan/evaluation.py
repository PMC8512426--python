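"""Quality metrics for validated clouds.

Two distance back-ends measure how far retained points lie from the
ground truth: an exact point-to-triangle-mesh distance (the standard
cloud-to-mesh comparison against an independently acquired mesh) and its
analytic twin against a parametric :class:`~glovescan.simulator.SurfaceModel`.
Both report unsigned distances.

Mesh distances are exact point-to-triangle minima (never vertex-only,
which biases means upward), pruned with a cKDTree over mesh vertices and
triangle centroids.

When simulator truth labels are available, :func:`label_confusion`
summarizes filter behaviour as a 2x2 kept/dropped vs surface/non-surface
table; the kept-nonsurface rate (fraction of invalid samples that
survive filtering) quantifies how much off-surface data leaks through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import AlignmentError, ConfigurationError, EmptyInputError
from .filtering import FilterConfig, ValidatedCloud, filter_pipeline, selectivity
from .simulator import LABEL_SURFACE, SurfaceModel


@dataclass(frozen=True)
class DistanceReport:
    """Per-point distances (mm) of a cloud to a ground-truth surface."""

    distances: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float).reshape(-1)
        if d.size == 0:
            raise EmptyInputError("distance report over an empty cloud")
        object.__setattr__(self, "distances", d)

    @property
    def count(self) -> int:
        return int(self.distances.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def median(self) -> float:
        return float(np.median(self.distances))

    @property
    def max(self) -> float:
        return float(np.max(self.distances))

    def summary(self) -> dict:
        return {
            "count": self.count,
            "mean_mm": self.mean,
            "median_mm": self.median,
            "max_mm": self.max,
        }


@dataclass(frozen=True)
class SelectivityCurve:
    """Retained percentage as a function of selection-sector angular size."""

    angular_sizes: tuple
    retained_percent: tuple

    def as_rows(self):
        return list(zip(self.angular_sizes, self.retained_percent))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 filter-vs-truth counts on a labelled synthetic trace."""

    kept_surface: int
    kept_nonsurface: int
    dropped_surface: int
    dropped_nonsurface: int

    @property
    def n_surface(self) -> int:
        return self.kept_surface + self.dropped_surface

    @property
    def n_nonsurface(self) -> int:
        return self.kept_nonsurface + self.dropped_nonsurface

    @property
    def kept_nonsurface_rate(self) -> float:
        """Fraction of truly off-surface samples that survive filtering."""
        if self.n_nonsurface == 0:
            return 0.0
        return self.kept_nonsurface / self.n_nonsurface

    @property
    def kept_surface_rate(self) -> float:
        """Fraction of truly on-surface samples that survive filtering."""
        if self.n_surface == 0:
            return 0.0
        return self.kept_surface / self.n_surface

    @property
    def kept_purity(self) -> float:
        """Fraction of the retained cloud that is truly on-surface."""
        kept = self.kept_surface + self.kept_nonsurface
        return self.kept_surface / kept if kept else 0.0


def _cloud_positions(cloud) -> np.ndarray:
    if isinstance(cloud, ValidatedCloud):
        pts = cloud.selected_points
    else:
        pts = np.atleast_2d(np.asarray(cloud, dtype=float))
    if pts.size == 0:
        raise EmptyInputError("empty cloud")
    return pts.reshape(-1, 3)


def _point_segment_sq(p, a, b):
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.einsum("ij,ij->i", p - a, ab) / np.where(denom == 0, 1.0, denom)
    t = np.clip(np.where(denom == 0, 0.0, t), 0.0, 1.0)
    c = a + t[:, None] * ab
    d = p - c
    return np.einsum("ij,ij->i", d, d)


def point_triangle_distance(points: np.ndarray, tri_a, tri_b, tri_c) -> np.ndarray:
    """Exact distance from each point to its paired triangle (row-wise).

    Interior projections use the plane distance; otherwise the minimum over
    the three edge segments.  Degenerate (collinear) triangles fall back to
    edge distances automatically.
    """
    p = np.atleast_2d(points)
    a, b, c = (np.atleast_2d(x) for x in (tri_a, tri_b, tri_c))
    e0, e1 = b - a, c - a
    n = np.cross(e0, e1)
    nn = np.einsum("ij,ij->i", n, n)
    d = p - a
    # barycentric coordinates of the in-plane projection
    dot00 = np.einsum("ij,ij->i", e0, e0)
    dot01 = np.einsum("ij,ij->i", e0, e1)
    dot11 = np.einsum("ij,ij->i", e1, e1)
    dot0p = np.einsum("ij,ij->i", e0, d)
    dot1p = np.einsum("ij,ij->i", e1, d)
    det = dot00 * dot11 - dot01 * dot01
    safe_det = np.where(det <= 0, 1.0, det)
    u = (dot11 * dot0p - dot01 * dot1p) / safe_det
    v = (dot00 * dot1p - dot01 * dot0p) / safe_det
    inside = (det > 0) & (u >= 0) & (v >= 0) & (u + v <= 1)
    plane_sq = np.where(
        nn > 0, np.einsum("ij,ij->i", d, n) ** 2 / np.where(nn == 0, 1.0, nn), np.inf
    )
    edge_sq = np.minimum(
        _point_segment_sq(p, a, b),
        np.minimum(_point_segment_sq(p, b, c), _point_segment_sq(p, a, c)),
    )
    return np.sqrt(np.where(inside, plane_sq, edge_sq))


def cloud_to_mesh_distances(cloud, mesh) -> DistanceReport:
    """Exact unsigned distance from each retained point to a triangle mesh.

    ``mesh`` is any object with ``vertices`` (v, 3) and ``faces`` (f, 3)
    attributes (e.g. a ``trimesh.Trimesh``); it need not be watertight.
    """
    pts = _cloud_positions(cloud)
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if len(faces) == 0 or len(verts) == 0:
        raise EmptyInputError("mesh has no triangles")
    tri = verts[faces]  # (f, 3, 3)
    centroids = tri.mean(axis=1)
    tri_radius = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    # upper bound from the nearest vertex guarantees the candidate set is complete
    upper, _ = cKDTree(verts).query(pts)
    ctree = cKDTree(centroids)
    out = np.empty(len(pts))
    neighbor_lists = ctree.query_ball_point(pts, upper + tri_radius + 1e-12)
    for i, cand in enumerate(neighbor_lists):
        cand = np.asarray(cand, dtype=np.int64)
        t = tri[cand]
        d = point_triangle_distance(
            np.broadcast_to(pts[i], (len(cand), 3)), t[:, 0], t[:, 1], t[:, 2]
        )
        out[i] = d.min()
    return DistanceReport(distances=out)


def cloud_to_model_distances(cloud, model: SurfaceModel) -> DistanceReport:
    """Analytic twin of :func:`cloud_to_mesh_distances` for parametric shapes."""
    pts = _cloud_positions(cloud)
    return DistanceReport(distances=model.distance(pts))


def selectivity_sweep(
    raw_points, refs, config_template: FilterConfig, angular_sizes
) -> SelectivityCurve:
    """Run the full pipeline once per angular size and record retention.

    ``angular_sizes`` must be positive and sorted ascending; the filter is
    otherwise configured from ``config_template`` (only the fine angular
    size varies; the coarse grid follows through ``coarse_factor``).
    """
    sizes = [float(s) for s in angular_sizes]
    if not sizes or any(s <= 0 for s in sizes):
        raise ConfigurationError("angular sizes must be positive")
    if sorted(sizes) != sizes:
        raise ConfigurationError("angular sizes must be sorted ascending")
    percents = []
    for s in sizes:
        cfg = FilterConfig(
            fine_angular_size=s,
            coarse_factor=config_template.coarse_factor,
            outlier_threshold=config_template.outlier_threshold,
            min_sector_count=config_template.min_sector_count,
        )
        vc = filter_pipeline(raw_points, refs, cfg)
        percents.append(selectivity(len(vc), vc.n_selected))
    return SelectivityCurve(angular_sizes=tuple(sizes), retained_percent=tuple(percents))


def label_confusion(validated: ValidatedCloud, truth_labels) -> ConfusionCounts:
    """Cross-tabulate filter decisions against simulator truth labels.

    ``truth_labels`` must align one-to-one with the raw samples the cloud
    was filtered from (same order).
    """
    labels = np.asarray(truth_labels, dtype=object)
    if len(labels) != len(validated):
        raise AlignmentError(
            f"{len(labels)} labels for {len(validated)} samples"
        )
    kept = validated.selected_mask
    is_surface = labels == LABEL_SURFACE
    return ConfusionCounts(
        kept_surface=int(np.count_nonzero(kept & is_surface)),
        kept_nonsurface=int(np.count_nonzero(kept & ~is_surface)),
        dropped_surface=int(np.count_nonzero(~kept & is_surface)),
        dropped_nonsurface=int(np.count_nonzero(~kept & ~is_surface)),
    )


def plot_selectivity(curve: SelectivityCurve, path) -> None:
    """Save a selectivity-vs-angular-size curve (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.plot(curve.angular_sizes, curve.retained_percent, marker="o")
    ax.set_xlabel("sector angular size (deg)")
    ax.set_ylabel("retained data (%)")
    ax.set_ylim(0, 100)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_distance_histogram(report: DistanceReport, path, bins: int = 50) -> None:
    """Save a histogram of cloud-to-surface distances (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.hist(report.distances, bins=bins)
    ax.set_xlabel("distance to ground truth (mm)")
    ax.set_ylabel("points")
    fig.savefig(path, dpi=120)
    plt.close(fig)
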