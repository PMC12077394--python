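"""Affine transforms, displacement fields, and transform chains.

All transforms map points *forward* from moving space to fixed space; the
*backward* direction (fixed coordinate -> moving source coordinate) is what
image resampling consumes.  A :class:`TransformChain` composites a sequence
of steps into a single full-resolution :class:`DisplacementField`, which is
the only object ever used to warp data, so each data point is interpolated
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    BinaryMask,
    ChainError,
    DimensionError,
    LabeledPolygon,
    PointSet2D,
    PolygonAnnotation,
    Raster2D,
)


# ---------------------------------------------------------------------------
# Affine
# ---------------------------------------------------------------------------

@dataclass
class AffineTransform:
    """2-D affine map ``p_fixed = matrix @ p_moving + offset`` in (x, y)."""

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise ValueError("affine matrix is singular")

    # -- constructors -------------------------------------------------------
    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.eye(2), np.zeros(2))

    @staticmethod
    def translation(tx: float, ty: float) -> "AffineTransform":
        return AffineTransform(np.eye(2), np.array([tx, ty], dtype=float))

    @staticmethod
    def scaling(sx: float, sy: float | None = None) -> "AffineTransform":
        sy = sx if sy is None else sy
        return AffineTransform(np.diag([sx, sy]), np.zeros(2))

    @staticmethod
    def rotation(degrees: float, center: tuple[float, float] = (0.0, 0.0)) -> "AffineTransform":
        th = np.deg2rad(degrees)
        m = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.asarray(center, dtype=float)
        return AffineTransform(m, c - m @ c)

    @staticmethod
    def from_params(
        params: np.ndarray, center: tuple[float, float] = (0.0, 0.0)
    ) -> "AffineTransform":
        """Build from (tx, ty, rot_deg, log_sx, log_sy, shear) about ``center``."""
        tx, ty, rot, lsx, lsy, shear = np.asarray(params, dtype=float)
        th = np.deg2rad(rot)
        rotm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        scale = np.diag([np.exp(lsx), np.exp(lsy)])
        shearm = np.array([[1.0, shear], [0.0, 1.0]])
        m = rotm @ shearm @ scale
        c = np.asarray(center, dtype=float)
        return AffineTransform(m, c - m @ c + np.array([tx, ty]))

    # -- algebra ------------------------------------------------------------
    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        """``(A @ B)(p) == A(B(p))`` — apply ``other`` first."""
        return AffineTransform(
            self.matrix @ other.matrix, self.matrix @ other.offset + self.offset
        )

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset)

    # -- application --------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.matrix.T + self.offset

    # Step protocol used by TransformChain
    def forward_points(self, points: np.ndarray) -> np.ndarray:
        return self.apply(points)

    def backward_points(self, points: np.ndarray) -> np.ndarray:
        return self.inverse().apply(points)


def resize_map(from_shape: tuple[int, int], to_shape: tuple[int, int]) -> AffineTransform:
    """Affine taking coordinates of a ``from_shape`` grid onto a resized
    ``to_shape`` grid under the corner-aligned resampling convention
    ``x_to = (x_from + 0.5) * s - 0.5``."""
    sy = to_shape[0] / from_shape[0]
    sx = to_shape[1] / from_shape[1]
    return AffineTransform(np.diag([sx, sy]), np.array([0.5 * sx - 0.5, 0.5 * sy - 0.5]))


# ---------------------------------------------------------------------------
# Displacement fields
# ---------------------------------------------------------------------------

def _sample_field(disp: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinearly sample a (H, W, 2) displacement grid at (x, y) points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    coords = np.stack([pts[:, 1], pts[:, 0]])  # rows, cols
    dx = ndimage.map_coordinates(disp[:, :, 0], coords, order=1, mode="nearest")
    dy = ndimage.map_coordinates(disp[:, :, 1], coords, order=1, mode="nearest")
    return np.stack([dx, dy], axis=1)


def identity_grid(shape: tuple[int, int]) -> np.ndarray:
    """(H, W, 2) grid of (x, y) pixel-center coordinates."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return np.stack([xx, yy], axis=-1).astype(float)


def compose_disp(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    """Displacement of ``f_outer(f_inner(x))`` where ``f(x) = x + disp(x)``.

    ``inner`` lives on the grid the result is defined on; ``outer`` is sampled
    at the displaced positions.
    """
    grid = identity_grid(inner.shape[:2])
    target = (grid + inner).reshape(-1, 2)
    return inner + _sample_field(outer, target).reshape(inner.shape)


def invert_disp(disp: np.ndarray, iterations: int = 20, tol: float = 0.05) -> np.ndarray:
    """Fixed-point inverse of ``x -> x + disp(x)`` on the same grid."""
    grid = identity_grid(disp.shape[:2])
    inv = -disp.copy()
    for _ in range(iterations):
        sampled = _sample_field(disp, (grid + inv).reshape(-1, 2)).reshape(disp.shape)
        new = -sampled
        err = np.abs(new - inv).max()
        inv = new
        if err < tol:
            break
    return inv


@dataclass
class DisplacementField:
    """Dense nonparametric transform between a moving and a fixed grid.

    ``backward`` is (Hf, Wf, 2): for each fixed pixel, the displacement to its
    moving-space source, ``src = x + backward[x]``.  ``forward`` is
    (Hm, Wm, 2): for each moving pixel, the displacement to its fixed-space
    destination.  Either may be None and is derived lazily by fixed-point
    inversion of the other.
    """

    backward: np.ndarray | None = None
    forward: np.ndarray | None = None
    resolution_um: float = 1.0

    def __post_init__(self) -> None:
        for name in ("backward", "forward"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.ndim != 3 or arr.shape[2] != 2:
                    raise DimensionError(f"{name} field must be (H, W, 2)")
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"{name} field contains non-finite values")
                setattr(self, name, arr)
        if self.backward is None and self.forward is None:
            raise ValueError("a displacement field needs at least one direction")

    # -- lazy inversion -----------------------------------------------------
    def _ensure_backward(self) -> np.ndarray:
        if self.backward is None:
            self.backward = invert_disp(self.forward)
        return self.backward

    def _ensure_forward(self) -> np.ndarray:
        if self.forward is None:
            self.forward = invert_disp(self.backward)
        return self.forward

    @property
    def fixed_shape(self) -> tuple[int, int]:
        return self._ensure_backward().shape[:2]

    @property
    def moving_shape(self) -> tuple[int, int]:
        return self._ensure_forward().shape[:2]

    @staticmethod
    def from_affine(
        affine: AffineTransform,
        fixed_shape: tuple[int, int],
        moving_shape: tuple[int, int] | None = None,
        resolution_um: float = 1.0,
    ) -> "DisplacementField":
        moving_shape = moving_shape or fixed_shape
        gf = identity_grid(fixed_shape)
        back = affine.backward_points(gf.reshape(-1, 2)).reshape(gf.shape) - gf
        gm = identity_grid(moving_shape)
        fwd = affine.apply(gm.reshape(-1, 2)).reshape(gm.shape) - gm
        return DisplacementField(back, fwd, resolution_um)

    # -- step protocol ------------------------------------------------------
    def forward_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts + _sample_field(self._ensure_forward(), pts)

    def backward_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts + _sample_field(self._ensure_backward(), pts)

    # -- diagnostics --------------------------------------------------------
    def roundtrip_error(self, mask: np.ndarray | None = None) -> float:
        """Mean |backward∘forward − id| in px, optionally over a moving mask."""
        shape = self.moving_shape
        grid = identity_grid(shape).reshape(-1, 2)
        if mask is not None:
            grid = grid[np.asarray(mask, dtype=bool).reshape(-1)]
        rt = self.backward_points(self.forward_points(grid))
        return float(np.linalg.norm(rt - grid, axis=1).mean())

    def jacobian_determinant(self) -> np.ndarray:
        """Numerical Jacobian determinant of the backward map per fixed pixel."""
        back = self._ensure_backward()
        grid = identity_grid(back.shape[:2]) + back
        dx_dc = np.gradient(grid[:, :, 0], axis=1)
        dx_dr = np.gradient(grid[:, :, 0], axis=0)
        dy_dc = np.gradient(grid[:, :, 1], axis=1)
        dy_dr = np.gradient(grid[:, :, 1], axis=0)
        return dx_dc * dy_dr - dx_dr * dy_dc


# ---------------------------------------------------------------------------
# Rescaling between image resolutions
# ---------------------------------------------------------------------------

def rescale_transform(
    t: "AffineTransform | DisplacementField",
    from_shape: tuple[int, int],
    to_shape: tuple[int, int],
):
    """Express a transform computed on ``from_shape`` grids on ``to_shape`` grids.

    Affines are conjugated by the resize map; displacement grids are resampled
    with the vectors multiplied by the per-axis scale factors.
    """
    if min(from_shape) <= 0 or min(to_shape) <= 0:
        raise ValueError("shapes must be positive")
    s = resize_map(from_shape, to_shape)
    if isinstance(t, AffineTransform):
        return s @ t @ s.inverse()
    sy = to_shape[0] / from_shape[0]
    sx = to_shape[1] / from_shape[1]

    def _rescale(disp: np.ndarray | None) -> np.ndarray | None:
        if disp is None:
            return None
        zoomed = np.stack(
            [
                ndimage.zoom(disp[:, :, c], (sy, sx), order=1, grid_mode=True,
                             mode="nearest")
                for c in range(2)
            ],
            axis=-1,
        )
        zoomed[:, :, 0] *= sx
        zoomed[:, :, 1] *= sy
        return zoomed

    return DisplacementField(
        _rescale(t.backward), _rescale(t.forward), t.resolution_um
    )


# ---------------------------------------------------------------------------
# Transform chains
# ---------------------------------------------------------------------------

@dataclass
class TransformChain:
    """Ordered transform steps applied moving -> fixed, composited lazily.

    Steps are affines or displacement fields (anything with
    ``forward_points``/``backward_points``).  ``fixed_shape``/``moving_shape``
    give the full-resolution spaces at the two ends; the composite field is
    materialized once per shape and cached.
    """

    steps: list = field(default_factory=list)
    fixed_shape: tuple[int, int] | None = None
    moving_shape: tuple[int, int] | None = None
    resolution_um: float = 1.0
    _cache: DisplacementField | None = field(default=None, repr=False, compare=False)

    def forward_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        for step in self.steps:
            pts = step.forward_points(pts)
        return pts

    def backward_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        for step in reversed(self.steps):
            pts = step.backward_points(pts)
        return pts

    def appended(self, step) -> "TransformChain":
        return TransformChain(
            list(self.steps) + [step], self.fixed_shape, self.moving_shape,
            self.resolution_um,
        )

    def composite(self) -> DisplacementField:
        """Materialize the chain as one full-resolution displacement field."""
        if self._cache is not None:
            return self._cache
        if self.fixed_shape is None or self.moving_shape is None:
            raise ChainError("chain needs fixed_shape and moving_shape to composite")
        gf = identity_grid(self.fixed_shape)
        back = self.backward_points(gf.reshape(-1, 2)).reshape(gf.shape) - gf
        gm = identity_grid(self.moving_shape)
        fwd = self.forward_points(gm.reshape(-1, 2)).reshape(gm.shape) - gm
        self._cache = DisplacementField(back, fwd, self.resolution_um)
        return self._cache


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------

def _as_field(t) -> DisplacementField:
    if isinstance(t, TransformChain):
        return t.composite()
    if isinstance(t, DisplacementField):
        return t
    raise TypeError(f"cannot warp with {type(t).__name__}")


def warp_image(
    img: Raster2D,
    transform: "DisplacementField | TransformChain",
    interp: str = "linear",
    fill: float = 0.0,
) -> Raster2D:
    """Resample ``img`` onto the fixed grid through the backward map."""
    fld = _as_field(transform)
    back = fld._ensure_backward()
    grid = identity_grid(back.shape[:2]) + back
    coords = np.stack([grid[:, :, 1], grid[:, :, 0]])  # rows, cols
    order = 1 if interp == "linear" else 0
    pixels = np.asarray(img.pixels)
    if pixels.ndim == 2:
        out = ndimage.map_coordinates(
            pixels.astype(float), coords, order=order, mode="constant", cval=fill
        )
    else:
        out = np.stack(
            [
                ndimage.map_coordinates(
                    pixels[:, :, c].astype(float), coords, order=order,
                    mode="constant", cval=fill,
                )
                for c in range(pixels.shape[2])
            ],
            axis=-1,
        )
    if np.issubdtype(pixels.dtype, np.integer):
        info = np.iinfo(pixels.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(pixels.dtype)
    return Raster2D(out, img.resolution_um, img.origin)


def warp_mask(mask: BinaryMask, transform) -> BinaryMask:
    """Nearest-neighbor warp; output strictly boolean."""
    out = warp_image(
        Raster2D(mask.pixels.astype(np.uint8), mask.resolution_um),
        transform, interp="nearest", fill=0,
    )
    return BinaryMask(out.pixels > 0, mask.resolution_um)


def warp_labels(labels: np.ndarray, transform) -> np.ndarray:
    """Nearest-neighbor warp of an integer label raster (0 = background)."""
    fld = _as_field(transform)
    back = fld._ensure_backward()
    grid = identity_grid(back.shape[:2]) + back
    coords = np.stack([grid[:, :, 1], grid[:, :, 0]])
    return ndimage.map_coordinates(labels, coords, order=0, mode="constant", cval=0)


def warp_points(pts: PointSet2D, transform) -> PointSet2D:
    """Push points moving -> fixed through the forward map."""
    if len(pts) == 0:
        return PointSet2D(np.empty((0, 2)), pts.space_tag)
    out = (
        transform.forward_points(pts.points)
        if hasattr(transform, "forward_points")
        else _as_field(transform).forward_points(pts.points)
    )
    return PointSet2D(out, pts.space_tag)


def warp_geojson(ann: PolygonAnnotation, transform) -> PolygonAnnotation:
    """Warp every polygon vertex forward; topology (ring order, holes) kept."""
    fwd = transform.forward_points
    shapes = [
        LabeledPolygon(
            exterior=fwd(s.exterior),
            holes=[fwd(h) for h in s.holes],
            label=s.label,
        )
        for s in ann.shapes
    ]
    return PolygonAnnotation(shapes)
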