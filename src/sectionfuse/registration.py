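"""Affine and greedy diffeomorphic nonrigid registration.

Similarity is local normalized cross-correlation (windowed NCC averaged over
pixels), which is invariant to local linear intensity changes — the right
metric for differently stained serial sections.  The affine stage is a
seeded random rigid search at the coarsest pyramid level followed by
quasi-Newton refinement of the six affine parameters per level.  The
nonrigid stage is a greedy loop per level: compute the NCC gradient force,
smooth the update (pre-sigma), cap the per-iteration step at one pixel,
compose into the total field, and smooth the total (post-sigma), accepting
only improving steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize
from skimage.transform import resize

from .core import (
    BinaryMask,
    DimensionError,
    NoTissueError,
    OptimizationError,
    PointSet2D,
    Raster2D,
)
from .preprocess import PreprocessedImage, prepare_pair
from .transforms import (
    AffineTransform,
    DisplacementField,
    TransformChain,
    compose_disp,
    identity_grid,
    invert_disp,
    resize_map,
)

_EPS = 1e-6


@dataclass
class RegistrationOptions:
    """Tunable parameters of the two-stage registration.

    Defaults follow the canonical serial-section setup: NCC window radius 10
    (1% of the 1024 working resolution), pyramid factors 8/4/2/1, update
    smoothing pre_sigma 5 and total-field smoothing post_sigma 4.
    """

    ncc_window_px: int = 10
    pyramid_factors: tuple[int, ...] = (8, 4, 2, 1)
    pre_sigma: float = 5.0
    post_sigma: float = 4.0
    iterations_per_level: int = 100
    affine_maxiter: int = 40
    rigid_trials: int = 1000
    rigid_refine_top: int = 8
    seed: int = 0
    working_size: int = 1024
    pad_px: int | None = None
    conv_tol: float = 1e-5
    step_px: float = 1.0
    denoise: bool = True  # False: caller supplies already-denoised images

    def __post_init__(self) -> None:
        f = tuple(self.pyramid_factors)
        if f[-1] != 1 or any(a <= b for a, b in zip(f, f[1:])):
            raise ValueError("pyramid factors must be strictly decreasing, ending at 1")
        if self.pre_sigma < 0 or self.post_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        self.pyramid_factors = f


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def _norm_image(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=np.float32)
    s = a.std()
    return (a - a.mean()) / (s if s > 0 else 1.0)


def _ncc_terms(a: np.ndarray, b: np.ndarray, radius: int):
    size = 2 * int(radius) + 1

    def f(x):
        return ndimage.uniform_filter(x, size, mode="reflect")

    ma, mb = f(a), f(b)
    sab = f(a * b) - ma * mb
    saa = np.maximum(f(a * a) - ma * ma, 0.0)
    sbb = np.maximum(f(b * b) - mb * mb, 0.0)
    return ma, mb, sab, saa, sbb


def local_ncc(a, b, window_px: int = 10) -> float:
    """Mean windowed NCC over all pixels; zero-variance windows contribute 0."""
    a = np.asarray(a.pixels if isinstance(a, Raster2D) else a)
    b = np.asarray(b.pixels if isinstance(b, Raster2D) else b)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch {a.shape} vs {b.shape}")
    a, b = _norm_image(a), _norm_image(b)
    _, _, sab, saa, sbb = _ncc_terms(a, b, window_px)
    valid = (saa > _EPS) & (sbb > _EPS)
    ncc = np.zeros_like(sab)
    ncc[valid] = sab[valid] / np.sqrt(saa[valid] * sbb[valid])
    return float(np.clip(ncc, -1.0, 1.0).mean())


def _ncc_and_force(a: np.ndarray, b: np.ndarray, radius: int):
    """Mean local NCC of (a, b) plus the ascent force on ``a``'s grid."""
    _, _, sab, saa, sbb = _ncc_terms(a, b, radius)
    size = 2 * int(radius) + 1
    ma = ndimage.uniform_filter(a, size, mode="reflect")
    mb = ndimage.uniform_filter(b, size, mode="reflect")
    valid = (saa > _EPS) & (sbb > _EPS)
    ncc = np.zeros_like(sab)
    ncc[valid] = sab[valid] / np.sqrt(saa[valid] * sbb[valid])
    score = float(np.clip(ncc, -1, 1).mean())
    g = np.zeros_like(sab)
    denom = saa**1.5 * np.sqrt(sbb) + _EPS
    g[valid] = ((b - mb) * saa - (a - ma) * sab)[valid] / denom[valid]
    gy, gx = np.gradient(a)
    return score, g * gx, g * gy


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def center_of_mass_init(
    moving_mask: BinaryMask, fixed_mask: BinaryMask
) -> AffineTransform:
    """Translation mapping the moving-mask centroid onto the fixed centroid."""
    if moving_mask.is_empty or fixed_mask.is_empty:
        raise NoTissueError("center-of-mass init needs non-empty masks")
    mx, my = moving_mask.centroid()
    fx, fy = fixed_mask.centroid()
    return AffineTransform.translation(fx - mx, fy - my)


# ---------------------------------------------------------------------------
# Affine stage
# ---------------------------------------------------------------------------

def _pyramid(img: np.ndarray, factors) -> dict[int, np.ndarray]:
    out = {}
    for f in factors:
        if f == 1:
            out[f] = img
        else:
            shape = (max(8, img.shape[0] // f), max(8, img.shape[1] // f))
            out[f] = resize(img, shape, order=1, anti_aliasing=True).astype(np.float32)
    return out


def _warp_affine(img: np.ndarray, aff: AffineTransform) -> np.ndarray:
    """Sample ``img`` through the backward of ``aff`` (moving -> fixed map)."""
    inv = aff.inverse()
    m = inv.matrix
    t = inv.offset
    matrix_rc = np.array([[m[1, 1], m[1, 0]], [m[0, 1], m[0, 0]]])
    offset_rc = np.array([t[1], t[0]])
    return ndimage.affine_transform(
        img, matrix_rc, offset_rc, order=1, mode="constant", cval=0.0
    )


_PARAM_SCALE = np.array([10.0, 10.0, 2.0, 0.02, 0.02, 0.02])


def affine_register(
    moving: PreprocessedImage,
    fixed: PreprocessedImage,
    opts: RegistrationOptions | None = None,
    rigid_only: bool = False,
) -> AffineTransform:
    """Two-stage affine registration in the shared working space.

    Stage 1 is a seeded random search over rotations and translations around
    the center-of-mass initialization at the coarsest pyramid level; stage 2
    refines the affine parameters by L-BFGS ascent on local NCC per level.
    Returns the working-space moving -> fixed affine.
    """
    opts = opts or RegistrationOptions()
    a = _norm_image(moving.image.pixels)
    b = _norm_image(fixed.image.pixels)
    shape = a.shape
    center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
    pyr_a = _pyramid(a, opts.pyramid_factors)
    pyr_b = _pyramid(b, opts.pyramid_factors)

    com = center_of_mass_init(moving.mask, fixed.mask)
    t0 = com.offset

    def score(params: np.ndarray, f: int) -> float:
        aff = AffineTransform.from_params(params, center)
        s = resize_map(shape, pyr_a[f].shape)
        aff_lvl = s @ aff @ s.inverse()
        warped = _warp_affine(pyr_a[f], aff_lvl)
        val = local_ncc(warped, pyr_b[f], opts.ncc_window_px)
        if not np.isfinite(val):
            raise OptimizationError("non-finite similarity during affine search")
        return val

    # stage 1: seeded random rigid search at the coarsest level.  The best
    # few candidates are each briefly refined there (the NCC rotation basin
    # is only a few degrees wide, so a raw sample rarely sits at its floor)
    # and the winner seeds the pyramid.
    coarse = opts.pyramid_factors[0]
    rng = np.random.default_rng(opts.seed)
    span = 0.1 * shape[1]
    candidates = [np.array([t0[0], t0[1], 0.0, 0.0, 0.0, 0.0])]
    for _ in range(opts.rigid_trials):
        candidates.append(np.array(
            [
                t0[0] + rng.uniform(-span, span),
                t0[1] + rng.uniform(-span, span),
                rng.uniform(-180.0, 180.0),
                0.0, 0.0, 0.0,
            ]
        ))
    scored = sorted(candidates, key=lambda p: -score(p, coarse))

    # parameter bounds keep the optimizer inside invertible, plausible
    # affines: translation within half the frame, scale in [e^-0.7, e^0.7]
    half = 0.5 * shape[1]
    p_lo = np.array([-half, -half, -200.0, -0.7, -0.7, -0.6])
    p_hi = -p_lo

    def refine(p0: np.ndarray, f: int, n_free: int, maxiter: int) -> np.ndarray:
        def neg(z: np.ndarray) -> float:
            p = p0.copy()
            p[:n_free] = z * _PARAM_SCALE[:n_free]
            return -score(p, f)

        z0 = np.clip(p0[:n_free], p_lo[:n_free], p_hi[:n_free]) / _PARAM_SCALE[:n_free]
        bounds = list(zip(p_lo[:n_free] / _PARAM_SCALE[:n_free],
                          p_hi[:n_free] / _PARAM_SCALE[:n_free]))
        res = optimize.minimize(
            neg, z0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "eps": 1e-2, "ftol": 1e-9},
        )
        out = p0.copy()
        out[:n_free] = res.x * _PARAM_SCALE[:n_free]
        return out

    top = [refine(p, coarse, 3, 20) for p in scored[: opts.rigid_refine_top]]
    best = max(top, key=lambda p: score(p, coarse))

    # stage 2: quasi-Newton refinement per pyramid level, coarse to fine;
    # finer levels only polish, so their iteration budget shrinks
    n_free = 3 if rigid_only else 6
    params = best.copy()
    for i, f in enumerate(opts.pyramid_factors):
        maxiter = max(8, opts.affine_maxiter // (2**i))
        params = refine(params, f, n_free, maxiter)
    return AffineTransform.from_params(params, center)


# ---------------------------------------------------------------------------
# Nonrigid stage
# ---------------------------------------------------------------------------

def _smooth_field(u: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return u
    return np.stack(
        [ndimage.gaussian_filter(u[:, :, c], sigma) for c in range(2)], axis=-1
    )


def nonrigid_register(
    moving: PreprocessedImage,
    fixed: PreprocessedImage,
    init: AffineTransform,
    opts: RegistrationOptions | None = None,
) -> DisplacementField:
    """Greedy diffeomorphic refinement of ``init`` in working space.

    Returns the *residual* field U acting on the fixed working grid: the full
    backward map is ``init^-1 ∘ (id + U.backward)``, i.e. the chain
    moving -> fixed is ``U ∘ init``.  The NCC history is attached as
    ``field.ncc_history``, one list per pyramid level, non-decreasing within
    each level (greedy acceptance of improving steps only).
    """
    opts = opts or RegistrationOptions()
    a = _norm_image(moving.image.pixels)
    b = _norm_image(fixed.image.pixels)
    shape = a.shape
    history: list[list[float]] = []

    u: np.ndarray | None = None
    for f in opts.pyramid_factors:
        lvl_shape = (max(8, shape[0] // f), max(8, shape[1] // f))
        a_lvl = (a if f == 1 else
                 resize(a, lvl_shape, order=1, anti_aliasing=True).astype(np.float32))
        b_lvl = (b if f == 1 else
                 resize(b, lvl_shape, order=1, anti_aliasing=True).astype(np.float32))
        lvl_shape = a_lvl.shape
        s = resize_map(shape, lvl_shape)
        aff_back = (s @ init @ s.inverse()).inverse()

        if u is None:
            u = np.zeros((*lvl_shape, 2), dtype=float)
        else:
            zoom = (lvl_shape[0] / u.shape[0], lvl_shape[1] / u.shape[1])
            u = np.stack(
                [ndimage.zoom(u[:, :, c], zoom, order=1, mode="nearest")
                 for c in range(2)],
                axis=-1,
            )
            u[:, :, 0] *= zoom[1]
            u[:, :, 1] *= zoom[0]

        grid = identity_grid(lvl_shape)

        def warp_with(u_field: np.ndarray) -> np.ndarray:
            src = aff_back.apply((grid + u_field).reshape(-1, 2)).reshape(grid.shape)
            coords = np.stack([src[:, :, 1].ravel(), src[:, :, 0].ravel()])
            return ndimage.map_coordinates(
                a_lvl, coords, order=1, mode="constant", cval=0.0
            ).reshape(lvl_shape).astype(np.float32)

        warped = warp_with(u)
        cur, fx, fy = _ncc_and_force(warped, b_lvl, opts.ncc_window_px)
        level_history = [cur]
        history.append(level_history)
        step = opts.step_px
        for _ in range(opts.iterations_per_level):
            force = np.stack([fx, fy], axis=-1)
            delta = _smooth_field(force, opts.pre_sigma)
            mag = np.linalg.norm(delta, axis=-1).max()
            if mag < 1e-9:
                break
            delta *= step / mag
            cand = _smooth_field(compose_disp(u, delta), opts.post_sigma)
            warped_c = warp_with(cand)
            new, nfx, nfy = _ncc_and_force(warped_c, b_lvl, opts.ncc_window_px)
            if not np.isfinite(new):
                raise OptimizationError("non-finite similarity in nonrigid loop")
            if new > cur:
                gain = new - cur
                u, cur, fx, fy = cand, new, nfx, nfy
                level_history.append(cur)
                if gain < opts.conv_tol:
                    break
            else:
                step *= 0.5
                if step < 0.05:
                    break

    assert u is not None
    forward = invert_disp(u)
    fld = DisplacementField(backward=u, forward=forward,
                           resolution_um=moving.image.resolution_um)
    fld.ncc_history = history  # type: ignore[attr-defined]
    rt = fld.roundtrip_error(fixed.mask.pixels)
    fld.roundtrip_px = rt  # type: ignore[attr-defined]
    if rt > 2.0:
        warnings.warn(
            f"nonrigid field round-trip error {rt:.2f} px exceeds 2 px; "
            "the field may not be invertible everywhere",
            stacklevel=2,
        )
    return fld


# ---------------------------------------------------------------------------
# Landmark-based registration (fallback path)
# ---------------------------------------------------------------------------

class TPSTransform:
    """Thin-plate spline interpolating paired landmarks, both directions."""

    def __init__(self, moving_pts: np.ndarray, fixed_pts: np.ndarray):
        from scipy.interpolate import RBFInterpolator

        try:
            self._fwd = RBFInterpolator(
                moving_pts, fixed_pts, kernel="thin_plate_spline", smoothing=0.0
            )
            self._bwd = RBFInterpolator(
                fixed_pts, moving_pts, kernel="thin_plate_spline", smoothing=0.0
            )
        except np.linalg.LinAlgError as exc:
            raise OptimizationError(
                f"degenerate (collinear) landmarks for TPS: {exc}"
            ) from exc

    def forward_points(self, points: np.ndarray) -> np.ndarray:
        return self._fwd(np.asarray(points, dtype=float).reshape(-1, 2))

    def backward_points(self, points: np.ndarray) -> np.ndarray:
        return self._bwd(np.asarray(points, dtype=float).reshape(-1, 2))


def landmark_register(
    moving_pts: PointSet2D,
    fixed_pts: PointSet2D,
    model: str = "affine",
    fixed_shape: tuple[int, int] | None = None,
    moving_shape: tuple[int, int] | None = None,
) -> TransformChain:
    """Least-squares affine or exact thin-plate-spline from landmark pairs."""
    if len(moving_pts) != len(fixed_pts):
        raise DimensionError("landmark sets must have equal counts")
    m = moving_pts.points
    f = fixed_pts.points
    if model == "affine":
        if len(m) < 3:
            raise DimensionError("affine landmark fit needs >= 3 pairs")
        design = np.hstack([m, np.ones((len(m), 1))])
        sol, *_ = np.linalg.lstsq(design, f, rcond=None)
        step = AffineTransform(sol[:2].T, sol[2])
    elif model == "thin_plate_spline":
        if len(m) < 4:
            raise DimensionError("TPS needs >= 4 pairs")
        span = m.max(axis=0) - m.min(axis=0)
        if np.any(span < 1e-9) or np.linalg.matrix_rank(m - m.mean(axis=0)) < 2:
            raise OptimizationError("degenerate (collinear) landmarks for TPS")
        step = TPSTransform(m, f)
    else:
        raise ValueError(f"unknown landmark model {model!r}")
    return TransformChain([step], fixed_shape=fixed_shape, moving_shape=moving_shape)


# ---------------------------------------------------------------------------
# Full pairwise pipeline
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    """Composited original-space chain plus stage diagnostics."""

    chain: TransformChain                  # moving original -> fixed original
    affine_working: AffineTransform        # stage affine in working space
    nonrigid_working: DisplacementField | None
    ncc_history: list[list[float]] = dc_field(default_factory=list)

    @property
    def affine_chain(self) -> TransformChain:
        """The chain truncated to the affine stage (no nonrigid residual)."""
        steps = [s for s in self.chain.steps
                 if not isinstance(s, DisplacementField)]
        return TransformChain(steps, self.chain.fixed_shape,
                              self.chain.moving_shape, self.chain.resolution_um)


def register_pair(
    moving: Raster2D,
    fixed: Raster2D,
    moving_mask: BinaryMask | None = None,
    fixed_mask: BinaryMask | None = None,
    opts: RegistrationOptions | None = None,
    nonrigid: bool = True,
) -> RegistrationResult:
    """Preprocess, affine-register, nonrigid-refine, and composite."""
    from .preprocess import segment_tissue

    opts = opts or RegistrationOptions()
    if moving_mask is None:
        moving_mask = segment_tissue(moving)
    if fixed_mask is None:
        fixed_mask = segment_tissue(fixed)

    pre_m_a, pre_f_a = prepare_pair(
        moving, fixed, moving_mask, fixed_mask,
        for_stage="affine" if opts.denoise else "nonrigid",
        working_size=opts.working_size, pad_px=opts.pad_px,
    )
    affine = affine_register(pre_m_a, pre_f_a, opts)

    steps: list = [pre_m_a.to_working, affine]
    nr_field: DisplacementField | None = None
    history: list[list[float]] = []
    if nonrigid:
        pre_m_n, pre_f_n = prepare_pair(
            moving, fixed, moving_mask, fixed_mask, for_stage="nonrigid",
            working_size=opts.working_size, pad_px=opts.pad_px,
        )
        nr_field = nonrigid_register(pre_m_n, pre_f_n, affine, opts)
        history = list(getattr(nr_field, "ncc_history", []))
        steps.append(nr_field)
    steps.append(pre_f_a.to_working.inverse())

    chain = TransformChain(
        steps,
        fixed_shape=fixed.shape,
        moving_shape=moving.shape,
        resolution_um=fixed.resolution_um,
    )
    return RegistrationResult(chain, affine, nr_field, history)
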