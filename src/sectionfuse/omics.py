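"""Grid projection of spot/pixel omics geometries into reference matrices.

Spot-based data (Visium-style circular capture areas on a hexagonal lattice)
and pixel-based data (MSI square raster cells) are rasterized into integer
*reference matrices* at stained-image resolution: 0 is background and label
k > 0 points at data point ``ids[k-1]``.  This turns parametric omics
geometry into an image that can be warped nonrigidly like any other raster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BinaryMask,
    DimensionError,
    IntegrityError,
    Raster2D,
    SectionFuseError,
)
from .transforms import AffineTransform

SPOT_DIAMETER_UM = 55.0
SPOT_PITCH_UM = 100.0
MSI_PITCH_UM = 30.0


@dataclass
class SpotGeometry:
    """Circular spots: ids, centers in microns (stained-image space), diameter."""

    ids: list
    centers_um: np.ndarray            # (N, 2) x, y
    diameter_um: float = SPOT_DIAMETER_UM
    pitch_um: float = SPOT_PITCH_UM

    def __post_init__(self) -> None:
        self.centers_um = np.asarray(self.centers_um, dtype=float).reshape(-1, 2)
        if len(self.ids) != len(set(self.ids)):
            raise IntegrityError("spot ids must be unique")
        if len(self.ids) != self.centers_um.shape[0]:
            raise IntegrityError("ids and centers differ in length")
        if self.diameter_um > self.pitch_um:
            raise SectionFuseError(
                "spot diameter exceeds pitch: circles would overlap"
            )

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class PixelGeometry:
    """Square omics pixels on a regular grid: origin + pitch + integer coords."""

    ids: list
    grid_xy: np.ndarray               # (N, 2) integer (col, row) grid coords
    origin_um: tuple[float, float] = (0.0, 0.0)
    pitch_um: float = MSI_PITCH_UM

    def __post_init__(self) -> None:
        self.grid_xy = np.asarray(self.grid_xy, dtype=int).reshape(-1, 2)
        if len(self.ids) != len(set(self.ids)):
            raise IntegrityError("pixel ids must be unique")
        if len(self.ids) != self.grid_xy.shape[0]:
            raise IntegrityError("ids and grid coords differ in length")
        cells = {tuple(rc) for rc in self.grid_xy}
        if len(cells) != len(self.ids):
            raise IntegrityError("one id per grid cell required")

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class ReferenceMatrix:
    """Integer label raster at stained-image resolution with an id lookup."""

    labels: np.ndarray                # (H, W) int32, 0 = background
    ids: list                         # label k -> ids[k-1]
    resolution_um: float = 1.0
    off_image: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DimensionError("reference matrix must be 2-D")
        if self.labels.max(initial=0) > len(self.ids):
            raise IntegrityError("label without a lookup entry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def id_of(self, label: int):
        return self.ids[label - 1]

    def label_of(self, data_id) -> int:
        return self.ids.index(data_id) + 1

    def pixel_counts(self) -> dict:
        counts = np.bincount(self.labels.ravel(), minlength=len(self.ids) + 1)
        return {self.ids[k - 1]: int(counts[k]) for k in range(1, len(self.ids) + 1)}


@dataclass
class MeasurementTable:
    """Data-point id -> vector of named molecular values."""

    frame: pd.DataFrame               # index: ids; columns: measure names

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise IntegrityError("duplicate data-point ids in measurement table")

    @property
    def measures(self) -> list[str]:
        return list(self.frame.columns)

    def values_for(self, ids) -> np.ndarray:
        missing = [i for i in ids if i not in self.frame.index]
        if missing:
            raise IntegrityError(f"missing source ids: {missing[:5]}")
        return self.frame.loc[list(ids)].to_numpy(dtype=float)


def project_spots(
    geom: SpotGeometry, image_shape: tuple[int, int], resolution_um: float = 1.0
) -> ReferenceMatrix:
    """Rasterize spot circles: a pixel gets a spot's label iff its center lies
    within the circle.  Overlaps are resolved to the lower id with a warning;
    fully off-image spots are reported in ``off_image``."""
    h, w = image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    r_px = (geom.diameter_um / 2.0) / resolution_um
    off_image = []
    overlap = False
    order = np.argsort(np.asarray(geom.ids, dtype=object))
    for k in order:
        cx, cy = geom.centers_um[k] / resolution_um
        x0 = max(0, int(np.ceil(cx - r_px)))
        x1 = min(w - 1, int(np.floor(cx + r_px)))
        y0 = max(0, int(np.ceil(cy - r_px)))
        y1 = min(h - 1, int(np.floor(cy + r_px)))
        if x0 > x1 or y0 > y1:
            off_image.append(geom.ids[k])
            continue
        yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
        if not inside.any():
            off_image.append(geom.ids[k])
            continue
        patch = labels[y0:y1 + 1, x0:x1 + 1]
        if (patch[inside] != 0).any():
            overlap = True
            inside &= patch == 0
        patch[inside] = k + 1
    if overlap:
        warnings.warn("overlapping spot circles; ties broken by lower id",
                      stacklevel=2)
    return ReferenceMatrix(labels, list(geom.ids), resolution_um, off_image)


def project_pixels(
    geom: PixelGeometry, image_shape: tuple[int, int], resolution_um: float = 1.0
) -> ReferenceMatrix:
    """Rasterize axis-aligned squares: raster cell centers in the half-open
    square ``[x0, x0 + pitch) x [y0, y0 + pitch)`` get the pixel's label."""
    h, w = image_shape
    labels = np.zeros((h, w), dtype=np.int32)
    pitch_px = geom.pitch_um / resolution_um
    ox, oy = (geom.origin_um[0] / resolution_um, geom.origin_um[1] / resolution_um)
    off_image = []
    for k, (gx, gy) in enumerate(geom.grid_xy):
        x0f = ox + gx * pitch_px
        y0f = oy + gy * pitch_px
        x0 = max(0, int(np.ceil(x0f)))
        x1 = min(w, int(np.ceil(x0f + pitch_px)))
        y0 = max(0, int(np.ceil(y0f)))
        y1 = min(h, int(np.ceil(y0f + pitch_px)))
        if x0 >= x1 or y0 >= y1:
            off_image.append(geom.ids[k])
            continue
        labels[y0:y1, x0:x1] = k + 1
    return ReferenceMatrix(labels, list(geom.ids), resolution_um, off_image)


def msi_feature_image(
    table: MeasurementTable,
    geom: PixelGeometry,
    target_resolution_um: float = 1.0,
) -> Raster2D:
    """First-principal-component feature image of pixel-based omics data.

    Mean-centered spectra are projected on the first principal axis; scores
    are min-max scaled to [0, 1] with the sign chosen so interior (on-tissue)
    pixels score above grid-border pixels, then the raster is upscaled to the
    stained image's resolution.
    """
    from scipy import ndimage as _ndi

    x = table.values_for(geom.ids)
    if x.shape[1] == 1:
        scores = x[:, 0].astype(float)
    else:
        centered = x - x.mean(axis=0)
        if np.allclose(centered, 0):
            raise SectionFuseError("constant spectra: degenerate first component")
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        scores = centered @ vt[0]

    gx = geom.grid_xy[:, 0] - geom.grid_xy[:, 0].min()
    gy = geom.grid_xy[:, 1] - geom.grid_xy[:, 1].min()
    grid = np.full((gy.max() + 1, gx.max() + 1), np.nan)
    grid[gy, gx] = scores
    present = ~np.isnan(grid)
    interior = present & _ndi.binary_erosion(present)
    border = present & ~interior
    if interior.any() and border.any():
        if np.nanmean(grid[interior]) < np.nanmean(grid[border]):
            grid = -grid
            scores = -scores
    lo, hi = np.nanmin(grid), np.nanmax(grid)
    if hi - lo < 1e-12:
        raise SectionFuseError("constant spectra: degenerate first component")
    grid = (grid - lo) / (hi - lo)
    grid[~present] = 0.0

    zoom = geom.pitch_um / target_resolution_um
    feat = _ndi.zoom(grid, zoom, order=1, mode="nearest", grid_mode=True)
    raster = Raster2D(feat.astype(np.float32), target_resolution_um)
    raster.scores = scores  # type: ignore[attr-defined]  # per-pixel PC1 scores
    return raster


def rigid_register_msi(
    feature: Raster2D,
    stained: Raster2D,
    stained_mask: BinaryMask | None = None,
    feature_mask: BinaryMask | None = None,
    opts=None,
) -> AffineTransform:
    """Rigid (rotation + translation) registration of an omics feature image
    to its own stained section, in stained original coordinates.

    The stained image is segmented (or the supplied masks are used directly),
    both images are cropped/padded to a uniform shape with a deformation
    border, and the rigid parameters are optimized under local NCC.  The
    stained grayscale is inverted so tissue polarity matches the feature
    image (high on tissue).
    """
    from .preprocess import prepare_pair, segment_tissue
    from .registration import RegistrationOptions, affine_register

    opts = opts or RegistrationOptions(working_size=512)
    if stained_mask is None:
        stained_mask = segment_tissue(stained)
    gray = stained.to_gray()
    inverted = Raster2D(gray.pixels.max() - gray.pixels, stained.resolution_um)
    if feature_mask is None:
        feature_mask = BinaryMask(
            feature.pixels > (feature.pixels.max() * 0.05), feature.resolution_um
        )
    pre_m, pre_f = prepare_pair(
        feature, inverted, feature_mask, stained_mask, for_stage="nonrigid",
        working_size=opts.working_size, pad_px=opts.pad_px,
    )
    a_work = affine_register(pre_m, pre_f, opts, rigid_only=True)
    return pre_f.to_working.inverse() @ a_work @ pre_m.to_working
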