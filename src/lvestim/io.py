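"""File formats and run manifests.

Point tables (wall samples and displacement fields) are CSV with mandatory
header ``x,y,z[,ux,uy,uz]`` in mm; surfaces are CSV or PLY point clouds with a
JSON sidecar (``<file>.meta.json``) carrying the label and time tag; results
and manifests are JSON; configuration is YAML.  Coordinates are 3-D Cartesian
with the origin at the shell centre.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .mechanics import DisplacementField, Surface

__all__ = [
    "FormatError",
    "read_point_table",
    "write_point_table",
    "read_surface",
    "write_surface",
    "read_config",
    "write_config",
    "RunManifest",
    "write_manifest",
]

POINT_COLUMNS = ("x", "y", "z")
VECTOR_COLUMNS = ("ux", "uy", "uz")


class FormatError(ValueError):
    """Raised for malformed on-disk artefacts."""


def read_point_table(path):
    """Read a CSV point table; returns ``(points, vectors_or_None)``.

    Rejects missing columns, non-numeric entries and non-finite values with
    the offending line number (header = line 1).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as err:
        raise FormatError(f"{path}: cannot parse CSV ({err})") from err
    for col in POINT_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_vectors = all(c in frame.columns for c in VECTOR_COLUMNS)
    cols = list(POINT_COLUMNS) + (list(VECTOR_COLUMNS) if has_vectors else [])
    data = frame[cols].apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~np.isfinite(data)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise FormatError(
            f"{path}: non-numeric or non-finite value at line {row + 2}")
    points = data[:, :3]
    vectors = data[:, 3:6] if has_vectors else None
    return points, vectors


def write_point_table(path, points, vectors=None) -> None:
    """Write points (and optionally paired displacement vectors) as CSV."""
    points = np.asarray(points, dtype=float)
    data = {c: points[:, i] for i, c in enumerate(POINT_COLUMNS)}
    if vectors is not None:
        vectors = np.asarray(vectors, dtype=float)
        if vectors.shape != points.shape:
            raise ValueError("vectors must match points in shape")
        data.update({c: vectors[:, i] for i, c in enumerate(VECTOR_COLUMNS)})
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_displacement_field(path, field: DisplacementField) -> None:
    write_point_table(path, field.points, field.vectors)


def read_displacement_field(path) -> DisplacementField:
    points, vectors = read_point_table(path)
    if vectors is None:
        raise FormatError(f"{path}: displacement columns ux,uy,uz missing")
    return DisplacementField(points=points, vectors=vectors)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_surface(surface: Surface, path) -> None:
    """Write a surface point cloud as PLY (ASCII) or CSV, with the label and
    time tag in a JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        cloud = trimesh.PointCloud(surface.points)
        path.write_bytes(cloud.export(file_type="ply", encoding="ascii"))
    elif path.suffix.lower() == ".csv":
        write_point_table(path, surface.points)
    else:
        raise FormatError(f"unsupported surface format {path.suffix!r}")
    _sidecar(path).write_text(json.dumps(
        {"label": surface.label, "time_tag": surface.time_tag}))


def read_surface(path) -> Surface:
    """Read a PLY or CSV surface written by :func:`write_surface`."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"{path}: missing or empty surface file")
    if path.suffix.lower() == ".ply":
        loaded = trimesh.load(path, file_type="ply", process=False)
        points = np.asarray(loaded.vertices, dtype=float)
    elif path.suffix.lower() == ".csv":
        points, _ = read_point_table(path)
    else:
        raise FormatError(f"unsupported surface format {path.suffix!r}")
    meta = {"label": "endo", "time_tag": "reference"}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return Surface(label=meta["label"], time_tag=meta["time_tag"], points=points)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    model_hash: str | None = None
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.package_version:
            from . import __version__
            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")


def model_digest(model) -> str:
    """SHA-256 over the surrogate's weights and normalisation constants."""
    h = hashlib.sha256()
    h.update(model.net_.weight_hash().encode())
    for arr in (model.input_center_, model.input_halfwidth_):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2, default=str))
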