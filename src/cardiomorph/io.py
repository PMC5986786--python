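"""File input/output: TIFF rasters, GeoJSON meshes, CSV geometry tables.

All coordinates on disk are µm in one shared image frame (x right, y
down, origin at the top-left pixel corner).  Rasters are single-plane
TIFFs with the pixel size recorded in the image description; meshes are
GeoJSON FeatureCollections with one polygon feature per cell.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .mesh import Cell, CellMesh, InputError, PixelGrid, mesh_from_polygons
from .outline import TracedOutline

__all__ = [
    "write_grid",
    "read_grid",
    "write_mesh_geojson",
    "read_mesh_geojson",
    "write_points_csv",
    "read_points_csv",
    "read_outline_csv",
    "read_landmarks",
    "read_avj_midline",
    "read_inputs",
]

LANDMARK_NAMES = ("lm1", "lm2", "lm3", "lm4")


def write_grid(path, grid: PixelGrid) -> None:
    tifffile.imwrite(
        str(path),
        grid.values,
        description=json.dumps({"pixel_size_um": grid.pixel_size}),
    )


def read_grid(path, pixel_size: float | None = None) -> PixelGrid:
    """Read a single-plane TIFF; pixel size from the description tag unless
    overridden."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        values = tf.asarray()
        if pixel_size is None:
            desc = tf.pages[0].description or ""
            try:
                pixel_size = float(json.loads(desc)["pixel_size_um"])
            except (ValueError, KeyError, TypeError):
                raise InputError(
                    f"{path} carries no pixel-size metadata; pass pixel_size explicitly"
                )
    if values.ndim != 2:
        raise InputError(f"{path}: expected a single-plane raster, got shape {values.shape}")
    return PixelGrid(values=values, pixel_size=pixel_size)


def write_mesh_geojson(path, mesh: CellMesh) -> None:
    feats = []
    for c in mesh.cells:
        ring = np.round(c.boundary, 9)
        coords = ring.tolist() + [ring[0].tolist()]
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [coords]},
                "properties": {
                    "id": c.id,
                    "is_boundary": bool(c.is_boundary),
                    "region": c.region,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": feats}
    Path(path).write_text(json.dumps(doc))


def read_mesh_geojson(path, snap_tol_um: float = 1e-6) -> CellMesh:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        doc = json.loads(path.read_text())
        feats = doc["features"]
    except (json.JSONDecodeError, KeyError) as e:
        raise InputError(f"{path}: malformed GeoJSON ({e})")
    cells = []
    for f in feats:
        props = f.get("properties", {})
        ring = np.asarray(f["geometry"]["coordinates"][0], dtype=float)
        cells.append(
            Cell(
                id=int(props["id"]),
                boundary=ring,
                is_boundary=bool(props.get("is_boundary", False)),
                region=props.get("region"),
            )
        )
    return mesh_from_polygons(cells, snap_tol_um=snap_tol_um)


def write_points_csv(path, named_points: dict[str, tuple[float, float]]) -> None:
    rows = [dict(name=k, x_um=v[0], y_um=v[1]) for k, v in named_points.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_points_csv(path) -> dict[str, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as e:  # malformed CSV
        raise InputError(f"{path}: unreadable CSV ({e})")
    for col in ("name", "x_um", "y_um"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return {str(r["name"]): np.array([r["x_um"], r["y_um"]]) for _, r in df.iterrows()}


def read_outline_csv(path) -> TracedOutline:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return TracedOutline(df[["x_um", "y_um"]].to_numpy())


def read_landmarks(path) -> dict[str, np.ndarray]:
    pts = read_points_csv(path)
    missing = [n for n in LANDMARK_NAMES if n not in pts]
    if missing:
        raise InputError(
            f"{path}: expected 4 landmarks {LANDMARK_NAMES}, missing {missing}"
        )
    return {n: pts[n] for n in LANDMARK_NAMES}


def read_avj_midline(path):
    """AVJ endpoints and midline direction from a named-points CSV
    (rows ``avj_1``, ``avj_2``, ``midline``)."""
    pts = read_points_csv(path)
    for n in ("avj_1", "avj_2", "midline"):
        if n not in pts:
            raise InputError(f"{path}: missing row {n!r}")
    return pts["avj_1"], pts["avj_2"], pts["midline"]


def read_inputs(
    labels_path,
    channel_paths: dict[str, str] | None = None,
    outline_path=None,
    landmarks_path=None,
    pixel_size: float | None = None,
):
    """Load and co-register the standard pipeline inputs.

    Returns ``(labels, channels, outline, landmarks)`` where missing
    optional inputs come back as None/empty.  Channels must match the
    label raster's shape and pixel size.
    """
    labels = read_grid(labels_path, pixel_size=pixel_size)
    labels.require_labels()
    channels: dict[str, PixelGrid] = {}
    for name, p in (channel_paths or {}).items():
        ch = read_grid(p, pixel_size=pixel_size)
        if ch.shape != labels.shape or not np.isclose(ch.pixel_size, labels.pixel_size):
            raise InputError(
                f"channel {name!r} is not co-registered with the labels "
                f"(shape {ch.shape} vs {labels.shape}, "
                f"pixel {ch.pixel_size} vs {labels.pixel_size})"
            )
        channels[name] = ch
    outline = read_outline_csv(outline_path) if outline_path else None
    landmarks = read_landmarks(landmarks_path) if landmarks_path else None
    return labels, channels, outline, landmarks
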