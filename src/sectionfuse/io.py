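"""Readers and writers for the formats the pipeline touches.

Images are plain TIFF or PNG (physical resolution supplied by the caller,
default 1 um/px); pointsets are CSV with ``x,y`` columns; polygon annotations
are GeoJSON FeatureCollections; masks are single-channel images with 0/255.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .core import (
    BinaryMask,
    FormatError,
    LabeledPolygon,
    PointSet2D,
    PolygonAnnotation,
    Raster2D,
    SchemaError,
    UnsupportedGeometryError,
)

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_image(path: str | os.PathLike, resolution_um: float = 1.0) -> Raster2D:
    """Read a TIFF or PNG image and attach its physical resolution."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            pixels = tifffile.imread(path)
        else:
            pixels = np.asarray(Image.open(path))
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
        pixels = pixels[:, :, :3]
    return Raster2D(pixels, resolution_um=resolution_um)


def write_image(raster: Raster2D, path: str | os.PathLike) -> None:
    path = Path(path)
    pixels = raster.pixels
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, pixels)
    else:
        if pixels.dtype != np.uint8:
            pixels = np.clip(pixels, 0, 255).astype(np.uint8)
        Image.fromarray(pixels).save(path)


def read_mask(path: str | os.PathLike, resolution_um: float = 1.0) -> BinaryMask:
    """Read a 0/255 single-channel image as a boolean mask."""
    raster = read_image(path, resolution_um)
    pixels = raster.pixels
    if pixels.ndim == 3:
        pixels = pixels[:, :, 0]
    return BinaryMask(pixels > 0, resolution_um=resolution_um)


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    write_image(
        Raster2D(mask.pixels.astype(np.uint8) * 255, mask.resolution_um), path
    )


def read_pointset(path: str | os.PathLike, space_tag: str = "") -> PointSet2D:
    """Read a CSV with numeric ``x,y`` columns, preserving row order."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such pointset file: {path}")
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise SchemaError(f"pointset {path} is missing column {col!r}")
    try:
        xy = df[["x", "y"]].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric coordinate in {path}: {exc}") from exc
    return PointSet2D(xy, space_tag=space_tag)


def write_pointset(pts: PointSet2D, path: str | os.PathLike) -> None:
    pd.DataFrame(pts.points, columns=["x", "y"]).to_csv(path, index=False)


def write_reference_matrix(ref, path_tiff, path_lookup) -> None:
    """Write a reference matrix as a 32-bit label TIFF + id lookup CSV."""
    tifffile.imwrite(path_tiff, ref.labels.astype(np.int32))
    pd.DataFrame(
        {"label": np.arange(1, len(ref.ids) + 1), "id": ref.ids}
    ).to_csv(path_lookup, index=False)


def read_reference_matrix(path_tiff, path_lookup, resolution_um: float = 1.0):
    """Read a label TIFF + lookup CSV pair written by write_reference_matrix."""
    from .omics import ReferenceMatrix

    labels = tifffile.imread(path_tiff).astype(np.int32)
    lookup = pd.read_csv(path_lookup)
    ids = list(lookup.sort_values("label")["id"])
    return ReferenceMatrix(labels, ids, resolution_um)


def _feature_label(props: dict) -> str:
    cls = props.get("classification")
    if isinstance(cls, dict) and "name" in cls:
        return str(cls["name"])
    if isinstance(cls, str):
        return cls
    return str(props.get("label", ""))


def _ring_to_array(ring: list) -> np.ndarray:
    arr = np.asarray(ring, dtype=float)
    if arr.shape[0] >= 2 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]  # GeoJSON closes rings explicitly; store open
    return arr


def read_geojson(path: str | os.PathLike) -> PolygonAnnotation:
    """Read a FeatureCollection of (Multi)Polygons with class labels."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such geojson file: {path}")
    with open(path) as fh:
        data = json.load(fh)
    features = data.get("features", [data] if "geometry" in data else [])
    shapes: list[LabeledPolygon] = []
    for feat in features:
        geom = feat.get("geometry", {})
        gtype = geom.get("type")
        label = _feature_label(feat.get("properties") or {})
        if gtype == "Polygon":
            polys = [geom["coordinates"]]
        elif gtype == "MultiPolygon":
            polys = geom["coordinates"]
        else:
            raise UnsupportedGeometryError(
                f"unsupported geometry type {gtype!r}; only Polygon/MultiPolygon"
            )
        for rings in polys:
            shapes.append(
                LabeledPolygon(
                    exterior=_ring_to_array(rings[0]),
                    holes=[_ring_to_array(r) for r in rings[1:]],
                    label=label,
                )
            )
    return PolygonAnnotation(shapes)


def _close_ring(arr: np.ndarray) -> list[list[float]]:
    closed = np.vstack([arr, arr[:1]])
    return [[round(float(x), 6), round(float(y), 6)] for x, y in closed]


def write_geojson(ann: PolygonAnnotation, path: str | os.PathLike) -> None:
    features = []
    for shape in ann.shapes:
        geom = {
            "type": "Polygon",
            "coordinates": [_close_ring(shape.exterior)]
            + [_close_ring(h) for h in shape.holes],
        }
        features.append(
            {
                "type": "Feature",
                "geometry": geom,
                "properties": {"label": shape.label,
                               "classification": {"name": shape.label}},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
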