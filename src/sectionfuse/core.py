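"""Core domain types shared by every stage of the pipeline.

Coordinate convention (used everywhere, stated once): pixel indices are
0-based, a point is ``(x, y) = (column, row)``, pixel centers sit at integer
coordinates, and image bounds are half-open ``[0, W) x [0, H)``.  Physical
coordinates are ``pixel coordinates * resolution_um``; no module converts
units ad hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SectionFuseError(Exception):
    """Base class for all package errors."""


class FormatError(SectionFuseError):
    """Unreadable or malformed input file."""


class SchemaError(SectionFuseError):
    """Tabular input does not match the expected schema."""


class UnsupportedGeometryError(SectionFuseError):
    """GeoJSON geometry type outside the polygon subset."""


class NoTissueError(SectionFuseError):
    """An operation that requires tissue received an empty mask."""


class DimensionError(SectionFuseError):
    """Shape mismatch between rasters that must share a grid."""


class ChainError(SectionFuseError):
    """Adjacent steps of a transform chain do not share a space."""


class OptimizationError(SectionFuseError):
    """Similarity became non-finite during registration."""


class IntegrityError(SectionFuseError):
    """Cross-referenced ids are missing or inconsistent."""


@dataclass
class Raster2D:
    """Intensity image with physical pixel size.

    ``pixels`` is ``(H, W)`` grayscale or ``(H, W, 3)`` RGB.  ``resolution_um``
    is isotropic microns per pixel.  ``origin`` is the physical offset of the
    center of pixel (0, 0) in microns.
    """

    pixels: np.ndarray
    resolution_um: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise DimensionError("Raster2D expects a 2-D or 2-D x channels grid")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (1, 3):
            raise DimensionError(
                f"channel count must be 1 or 3, got {self.pixels.shape[2]}"
            )
        if self.pixels.size == 0:
            raise DimensionError("empty pixel grid")
        if not self.resolution_um > 0:
            raise ValueError("resolution_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the pixel grid."""
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def is_rgb(self) -> bool:
        return self.n_channels == 3

    def to_gray(self) -> "Raster2D":
        """Luminance grayscale (0.299/0.587/0.114), float output."""
        if self.pixels.ndim == 2:
            return Raster2D(self.pixels.astype(np.float32), self.resolution_um, self.origin)
        w = np.asarray([0.299, 0.587, 0.114], dtype=np.float32)
        gray = self.pixels.astype(np.float32) @ w
        return Raster2D(gray, self.resolution_um, self.origin)


@dataclass
class BinaryMask:
    """Boolean tissue/annotation mask sharing a Raster2D's grid."""

    pixels: np.ndarray
    resolution_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise DimensionError("BinaryMask expects a 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def is_empty(self) -> bool:
        return not bool(self.pixels.any())

    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.resolution_um**2

    def centroid(self) -> tuple[float, float]:
        """(x, y) mean of true-pixel coordinates."""
        if self.is_empty:
            raise NoTissueError("centroid of an empty mask")
        rows, cols = np.nonzero(self.pixels)
        return float(cols.mean()), float(rows.mean())


@dataclass
class PointSet2D:
    """Ordered (x, y) points in pixel coordinates of a named image space."""

    points: np.ndarray
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.points.size and not np.all(np.isfinite(self.points)):
            raise ValueError("pointset contains non-finite coordinates")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class LabeledPolygon:
    """One polygon (outer ring + holes) with a free-text class label."""

    exterior: np.ndarray          # (N, 2) x,y; first vertex not repeated
    holes: list[np.ndarray] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.exterior = np.asarray(self.exterior, dtype=float).reshape(-1, 2)
        self.holes = [np.asarray(h, dtype=float).reshape(-1, 2) for h in self.holes]
        for ring in [self.exterior, *self.holes]:
            if ring.shape[0] < 3:
                raise ValueError("polygon rings need at least 3 vertices")


@dataclass
class PolygonAnnotation:
    """A collection of labeled polygons in pixel coordinates."""

    shapes: list[LabeledPolygon] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.shapes]

    def __len__(self) -> int:
        return len(self.shapes)
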