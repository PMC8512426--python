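"""File formats: pose-sample CSV, point-cloud XYZ/PLY, label files, reports.

The sample CSV dialect is fully pinned: comma separator, dot decimal,
UTF-8, mandatory header, columns ``t, sensor_id, x, y, z, qw, qx, qy,
qz`` (any column order; the header is authoritative).  Values round-trip
losslessly at 6 significant digits.

Clouds are written either as whitespace-separated ``xyz`` triples or as
ascii PLY with a per-vertex ``status`` property carrying filter
provenance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInputError, RowParseError, SchemaError
from .filtering import SELECTED, ValidatedCloud
from .geometry import PoseSample

SAMPLE_COLUMNS = ["t", "sensor_id", "x", "y", "z", "qw", "qx", "qy", "qz"]

_FLOAT_FMT = "%.9g"  # > 6 significant digits, compact


def write_samples_csv(samples, path) -> None:
    """Write pose samples in the pinned CSV dialect."""
    rows = np.array(
        [
            [s.t, s.sensor_id, *s.position, *s.orientation]
            for s in samples
        ]
    ).reshape(-1, 9)
    df = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    df["sensor_id"] = df["sensor_id"].astype(np.int64)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_samples_csv(path) -> list[PoseSample]:
    """Read pose samples; header-keyed, so column order is irrelevant.

    Raises :class:`SchemaError` naming any missing column and
    :class:`RowParseError` with the 1-based file line of the first
    non-numeric cell.
    """
    df = pd.read_csv(path)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if df.empty:
        return []
    numeric = df[SAMPLE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1) & ~df[SAMPLE_COLUMNS].isna().any(axis=1)
    bad |= df[SAMPLE_COLUMNS].isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowParseError(
            f"non-numeric cell in data row {row + 1} (file line {row + 2})",
            line=row + 2,
        )
    return [
        PoseSample(
            sensor_id=int(r.sensor_id),
            t=float(r.t),
            position=np.array([r.x, r.y, r.z]),
            orientation=np.array([r.qw, r.qx, r.qy, r.qz]),
        )
        for r in numeric.itertuples(index=False)
    ]


def write_labels_csv(labels, path) -> None:
    """Side-car ground-truth label file: ``index, label`` per raw sample."""
    pd.DataFrame({"index": np.arange(len(labels)), "label": list(labels)}).to_csv(
        path, index=False
    )


def read_labels_csv(path) -> list[str]:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise SchemaError("missing column(s): label")
    return [str(x) for x in df["label"]]


def write_cloud(cloud, path, fmt: str = "xyz") -> None:
    """Write a cloud as ``xyz`` triples or ascii PLY with a status property.

    ``cloud`` is a :class:`ValidatedCloud` (all points written, status kept)
    or a bare (n, 3) array (status ``selected`` assumed).  PLY requires a
    non-empty cloud; xyz may be empty.
    """
    if fmt not in ("xyz", "ply"):
        raise ConfigurationError(f"unknown cloud format {fmt!r}")
    if isinstance(cloud, ValidatedCloud):
        pts = cloud.selected_points if fmt == "xyz" else cloud.positions
        status = None if fmt == "xyz" else cloud.status
    else:
        pts = np.atleast_2d(np.asarray(cloud, dtype=float)).reshape(-1, 3)
        status = np.full(len(pts), SELECTED, dtype=object)
    path = Path(path)
    if fmt == "xyz":
        np.savetxt(path, pts, fmt=_FLOAT_FMT)
        return
    if len(pts) == 0:
        raise EmptyInputError("refusing to write an empty PLY cloud")
    statuses = sorted(set(status))
    code = {s: i for i, s in enumerate(statuses)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        for i, s in enumerate(statuses):
            fh.write(f"comment status {i} = {s}\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar status\nend_header\n")
        for p, s in zip(pts, status):
            fh.write(
                f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {code[s]}\n"
            )


def read_cloud(path, fmt: str | None = None):
    """Read a cloud written by :func:`write_cloud`.

    Returns ``(points, status)`` where ``status`` is None for xyz files.
    """
    path = Path(path)
    if fmt is None:
        fmt = "ply" if path.suffix.lower() == ".ply" else "xyz"
    if fmt == "xyz":
        pts = np.loadtxt(path, ndmin=2)
        return pts.reshape(-1, 3), None
    if fmt != "ply":
        raise ConfigurationError(f"unknown cloud format {fmt!r}")
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0] != "ply":
        raise SchemaError("not an ascii PLY file")
    names: dict[int, str] = {}
    n_vertex = 0
    body_at = 0
    for i, ln in enumerate(lines[1:], start=1):
        if ln.startswith("comment status "):
            _, _, idx, _, name = ln.split(maxsplit=4)
            names[int(idx)] = name
        elif ln.startswith("element vertex"):
            n_vertex = int(ln.split()[-1])
        elif ln == "end_header":
            body_at = i + 1
            break
    pts = np.empty((n_vertex, 3))
    status = np.empty(n_vertex, dtype=object)
    for j in range(n_vertex):
        parts = lines[body_at + j].split()
        pts[j] = [float(x) for x in parts[:3]]
        status[j] = names.get(int(parts[3]), str(parts[3]))
    return pts, status


def load_mesh(path):
    """Load a triangle mesh (PLY/OBJ/STL) via trimesh."""
    import trimesh

    mesh = trimesh.load(str(path), force="mesh")
    if mesh.faces.shape[0] == 0:
        raise EmptyInputError(f"{path} contains no triangles")
    return mesh


def write_report_json(report: dict, path) -> None:
    import json

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")


def write_report_csv(rows, path, columns) -> None:
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
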