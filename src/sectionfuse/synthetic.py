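"""Deterministic, seeded generators for every fixture the pipeline needs.

The generators emulate a serial-section multi-omics study at desk scale:
histology-like images of glandular tissue (elliptical glands with lumina in
textured stroma, H&E-ish palette on a white slide), smooth invertible
deformations between sections, hexagonal 55 um spots at 100 um pitch,
30 um square omics pixel grids, and molecular values correlated with the
gland/stroma ground truth by a stated effect size.  Every ground-truth
object (masks, label rasters, deformation fields, landmark tracks) is
exposed so downstream tests never re-derive it from rendered data.

One global seed per scene; substreams (image, deformation, omics, noise,
landmarks) are spawned from it in a fixed order, so identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import BinaryMask, PointSet2D, Raster2D
from .omics import (
    MeasurementTable,
    PixelGeometry,
    SpotGeometry,
)
from .transforms import DisplacementField, compose_disp, identity_grid

# palette (RGB, uint8): white slide, pink stroma, purple gland rim, pale lumen
_BACKGROUND = np.array([250.0, 250.0, 250.0])
_STROMA = np.array([214.0, 160.0, 190.0])
_GLAND_RIM = np.array([148.0, 92.0, 164.0])
_LUMEN = np.array([243.0, 237.0, 243.0])

# type_labels codes
BG, STROMA, GLAND_RIM, LUMEN = 0, 1, 2, 3


@dataclass
class Gland:
    cx: float
    cy: float
    a: float            # semi-major axis, px
    b: float            # semi-minor axis, px
    angle: float        # radians
    lumen_frac: float = 0.55


def _paint_ellipse(raster: np.ndarray, g: Gland, scale: float, value: int) -> None:
    a, b = g.a * scale, g.b * scale
    r = int(np.ceil(max(a, b))) + 1
    y0 = max(0, int(g.cy) - r)
    y1 = min(raster.shape[0], int(g.cy) + r + 1)
    x0 = max(0, int(g.cx) - r)
    x1 = min(raster.shape[1], int(g.cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - g.cx, yy - g.cy
    c, s = np.cos(g.angle), np.sin(g.angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    raster[y0:y1, x0:x1][inside] = value


def _rasterize(size: int, tissue: np.ndarray, glands: list[Gland]):
    """(type_labels, gland_map) rasters for a gland set."""
    types = np.where(tissue, STROMA, BG).astype(np.int32)
    gland_map = np.zeros((size, size), dtype=np.int32)
    for k, g in enumerate(glands):
        _paint_ellipse(types, g, 1.0, GLAND_RIM)
        _paint_ellipse(types, g, g.lumen_frac, LUMEN)
        _paint_ellipse(gland_map, g, 1.0, k + 1)
    types[~tissue] = BG
    gland_map[~tissue] = 0
    return types, gland_map


def _render(types: np.ndarray, texture: np.ndarray, rng: np.random.Generator,
            noise_sigma: float = 4.0) -> np.ndarray:
    """RGB rendering of a type raster with shared stroma texture + noise."""
    h, w = types.shape
    img = np.empty((h, w, 3), dtype=float)
    img[...] = _BACKGROUND
    img[types == STROMA] = _STROMA
    img[types == GLAND_RIM] = _GLAND_RIM
    img[types == LUMEN] = _LUMEN
    tex = texture[..., None] * np.array([18.0, 22.0, 18.0])
    on_tissue = types != BG
    img[on_tissue] += tex[on_tissue]
    img += rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


@dataclass
class SyntheticScene:
    """Ground truth of one synthetic section plus its seeded substreams."""

    seed: int
    size_px: int
    tissue_mask: BinaryMask
    type_labels: np.ndarray          # (H, W) int: 0 bg / 1 stroma / 2 rim / 3 lumen
    gland_map: np.ndarray            # (H, W) int: gland index + 1, 0 elsewhere
    glands: list[Gland]
    texture: np.ndarray              # (H, W) float, shared stroma texture
    image: Raster2D                  # rendered RGB, 1 um/px
    landmarks: PointSet2D
    streams: dict = field(default_factory=dict, repr=False)

    @property
    def gland_region(self) -> np.ndarray:
        """Boolean raster of glandular tissue (rim + lumen)."""
        return self.type_labels >= GLAND_RIM


def make_tissue_image(
    seed: int,
    size_px: int = 1500,
    n_glands: int = 40,
    n_landmarks: int = 60,
    noise_sigma: float = 4.0,
    gland_size_px: tuple[float, float] = (25.0, 55.0),
) -> SyntheticScene:
    """Generate one histology-like section with full ground truth."""
    if size_px < 256:
        raise ValueError("size_px must be >= 256")
    base = np.random.SeedSequence(seed)
    names = ("image", "deformation", "omics", "noise", "landmarks", "sections")
    streams = dict(zip(names, (np.random.default_rng(s) for s in base.spawn(6))))
    rng = streams["image"]

    # smooth tissue blob: radial perturbation of a disk
    c = size_px / 2.0
    r0 = 0.36 * size_px
    amps = rng.uniform(-0.08, 0.08, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    theta = np.arctan2(yy - c, xx - c)
    rad = np.sqrt((xx - c) ** 2 + (yy - c) ** 2)
    rb = r0 * (1.0 + sum(a * np.cos((k + 2) * theta + p)
                         for k, (a, p) in enumerate(zip(amps, phases))))
    tissue = rad <= rb

    # glands: dart-throwing with a minimum center separation
    glands: list[Gland] = []
    eroded = ndimage.binary_erosion(tissue, iterations=40)
    ys, xs = np.nonzero(eroded)
    tries = 0
    while len(glands) < n_glands and tries < n_glands * 60:
        tries += 1
        j = rng.integers(len(xs))
        gx, gy = float(xs[j]), float(ys[j])
        a = rng.uniform(*gland_size_px)
        b = a * rng.uniform(0.55, 1.0)
        if all((gx - g.cx) ** 2 + (gy - g.cy) ** 2 > (0.95 * (a + g.a)) ** 2
               for g in glands):
            glands.append(Gland(gx, gy, a, b, rng.uniform(0, np.pi)))

    types, gland_map = _rasterize(size_px, tissue, glands)
    texture = ndimage.gaussian_filter(rng.standard_normal((size_px, size_px)), 6.0)
    texture /= max(texture.std(), 1e-9)

    pixels = _render(types, texture, streams["noise"], noise_sigma)
    image = Raster2D(pixels, resolution_um=1.0)

    lm_rng = streams["landmarks"]
    lys, lxs = np.nonzero(ndimage.binary_erosion(tissue, iterations=25))
    pick = lm_rng.choice(len(lxs), size=min(n_landmarks, len(lxs)), replace=False)
    landmarks = PointSet2D(
        np.stack([lxs[pick], lys[pick]], axis=1).astype(float), space_tag="section0"
    )

    return SyntheticScene(
        seed=seed, size_px=size_px,
        tissue_mask=BinaryMask(tissue, 1.0),
        type_labels=types, gland_map=gland_map, glands=glands,
        texture=texture, image=image, landmarks=landmarks, streams=streams,
    )


# ---------------------------------------------------------------------------
# Deformations
# ---------------------------------------------------------------------------

def make_deformation(
    rng: np.random.Generator | int,
    shape: tuple[int, int],
    amplitude_px: float,
    smoothness_px: float = 80.0,
    n_bumps: int = 3,
    n_squarings: int = 10,
) -> DisplacementField:
    """Invertible smooth field: Gaussian-bump velocities exponentiated by
    scaling and squaring; forward and backward are both returned and are
    exact inverses to well below 0.1 px for default parameters."""
    if amplitude_px < 0:
        raise ValueError("amplitude must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h, w = shape
    # the field is smooth at the scale of smoothness_px, so the exponential
    # is integrated on a half-resolution grid for large frames and upscaled
    coarse = 2 if min(h, w) > 800 else 1
    ch, cw = (h + coarse - 1) // coarse, (w + coarse - 1) // coarse
    v = np.zeros((ch, cw, 2), dtype=float)
    if amplitude_px > 0:
        yy, xx = np.mgrid[0:ch, 0:cw] * float(coarse)
        for _ in range(n_bumps):
            cx = rng.uniform(0.25 * w, 0.75 * w)
            cy = rng.uniform(0.25 * h, 0.75 * h)
            direction = rng.uniform(0, 2 * np.pi)
            amp = rng.uniform(0.5, 1.0)
            bump = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                          / (2 * smoothness_px**2))
            v[:, :, 0] += amp * np.cos(direction) * bump
            v[:, :, 1] += amp * np.sin(direction) * bump
        vmax = np.linalg.norm(v, axis=-1).max()
        if vmax > 0:
            v *= amplitude_px / vmax / coarse  # coarse-grid pixel units
        # velocity gradient bound: |grad v| < 1 guarantees a diffeomorphism
        grads = [np.abs(np.gradient(v[:, :, c], axis=ax)).max()
                 for c in range(2) for ax in range(2)]
        if max(grads) > 0.95:
            raise ValueError(
                f"amplitude {amplitude_px} too large for smoothness "
                f"{smoothness_px}: velocity gradient {max(grads):.2f} "
                "risks a folded (non-invertible) field"
            )

    def _exp(vel: np.ndarray) -> np.ndarray:
        u = vel / (2**n_squarings)
        for _ in range(n_squarings):
            u = compose_disp(u, u)
        return u

    forward = _exp(v)
    backward = _exp(-v)
    if coarse > 1:
        from .transforms import rescale_transform

        fld = rescale_transform(
            DisplacementField(backward=backward, forward=forward),
            (ch, cw), (h, w),
        )
    else:
        fld = DisplacementField(backward=backward, forward=forward)
    jac = fld.jacobian_determinant()
    if jac.min() <= 0:
        raise ValueError(
            f"generated field folds (min Jacobian {jac.min():.3f}); "
            "reduce amplitude or increase smoothness"
        )
    return fld


# ---------------------------------------------------------------------------
# Serial sections
# ---------------------------------------------------------------------------

@dataclass
class SerialSections:
    """A synthetic series with per-section ground-truth maps to section 0.

    ``forward_to[i]`` maps section-0 coordinates into section ``i``;
    ``backward_to[i]`` maps section-``i`` coordinates back to section 0.
    ``landmarks[i]`` are the scene landmarks carried into section ``i``;
    ``landmark_valid[i]`` flags those whose gland survived the churn.
    """

    images: list[Raster2D]
    masks: list[BinaryMask]
    landmarks: list[PointSet2D]
    landmark_valid: list[np.ndarray]
    forward_to: list[np.ndarray]      # (H, W, 2) disp, section0 grid
    backward_to: list[np.ndarray]     # (H, W, 2) disp, section-i grid
    gland_sets: list[list[int]]       # surviving gland indices per section
    type_labels: list[np.ndarray]     # per-section tissue-type raster (warped)

    def gt_points(self, i: int, j: int, pts: np.ndarray) -> np.ndarray:
        """Ground-truth mapping of section-``i`` points into section ``j``."""
        from .transforms import _sample_field

        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        base = pts + _sample_field(self.backward_to[i], pts)
        return base + _sample_field(self.forward_to[j], base)


def make_serial_sections(
    scene: SyntheticScene,
    n: int = 5,
    drift_amplitude_px: float = 6.0,
    morph_rate: float = 0.15,
    smoothness_px: float = 120.0,
    noise_sigma: float = 4.0,
    rigid_rotation_deg: float = 10.0,
    rigid_translation_px: float | None = None,
    texture_correlation: float = 0.75,
    gland_jitter_px: float = 4.0,
    gland_size_jitter: float = 0.08,
) -> SerialSections:
    """Serial sections with accumulating smooth drift, per-step rigid
    placement jitter (each section lands on its own slide), gland churn, and
    stroma texture that decorrelates with axial distance.

    ``texture_correlation`` is the AR(1) coefficient between the stroma
    textures of adjacent sections: neighbors share most fine structure while
    distant sections share little, which is what makes direct registration
    of distant sections genuinely harder than stepping through neighbors.
    Gland cross-sections also evolve along the axis: per step each surviving
    gland's center random-walks by ``gland_jitter_px`` and its log-size by
    ``gland_size_jitter``, so distant sections share fewer and
    displaced glandular features.  ``rigid_translation_px`` defaults to 2%
    of the scene size per step.
    """
    from .transforms import AffineTransform, DisplacementField as _DF

    if n < 2:
        raise ValueError("a series needs n >= 2")
    rng = scene.streams["sections"]
    size = scene.size_px
    shape = (size, size)
    if rigid_translation_px is None:
        rigid_translation_px = 0.02 * size
    center = ((size - 1) / 2.0, (size - 1) / 2.0)

    zero = np.zeros((*shape, 2))
    forward_to = [zero.copy()]
    backward_to = [zero.copy()]
    present: list[int] = list(range(len(scene.glands)))
    gland_sets = [list(present)]
    altered_ever: set[int] = set()
    evolved: dict[int, Gland] = {k: scene.glands[k] for k in present}

    images: list[Raster2D] = []
    masks: list[BinaryMask] = []
    landmarks: list[PointSet2D] = []
    landmark_valid: list[np.ndarray] = []
    type_rasters: list[np.ndarray] = []

    lm0 = scene.landmarks.points
    lm_glands = scene.gland_map[
        lm0[:, 1].astype(int), lm0[:, 0].astype(int)
    ]  # gland index + 1 or 0

    texture = scene.texture.copy()
    rho = float(np.clip(texture_correlation, 0.0, 1.0))

    for i in range(n):
        if i > 0:
            if drift_amplitude_px > 0:
                step = make_deformation(rng, shape, drift_amplitude_px,
                                        smoothness_px)
                fstep, bstep = step.forward, step.backward
            else:
                fstep, bstep = zero.copy(), zero.copy()
            if rigid_rotation_deg > 0 or rigid_translation_px > 0:
                rig = (
                    AffineTransform.rotation(
                        rng.uniform(-rigid_rotation_deg, rigid_rotation_deg),
                        center,
                    )
                    @ AffineTransform.translation(
                        rng.uniform(-rigid_translation_px, rigid_translation_px),
                        rng.uniform(-rigid_translation_px, rigid_translation_px),
                    )
                )
                rig_fld = _DF.from_affine(rig, shape)
                fstep = compose_disp(rig_fld.forward, fstep)
                bstep = compose_disp(bstep, rig_fld.backward)
            forward_to.append(compose_disp(fstep, forward_to[-1]))
            backward_to.append(compose_disp(backward_to[-1], bstep))
            # churn: remove a morph_rate fraction of surviving glands
            n_alter = int(round(morph_rate * len(present)))
            if n_alter > 0 and present:
                altered = rng.choice(len(present), size=min(n_alter, len(present)),
                                     replace=False)
                for idx in sorted(altered, reverse=True):
                    altered_ever.add(present[idx])
                    del present[idx]
            gland_sets.append(list(present))
            # axial gland evolution: centers and sizes random-walk per step
            for k in present:
                g = evolved[k]
                scale = float(np.exp(rng.normal(0.0, gland_size_jitter)))
                evolved[k] = Gland(
                    cx=g.cx + rng.normal(0.0, gland_jitter_px),
                    cy=g.cy + rng.normal(0.0, gland_jitter_px),
                    a=g.a * scale, b=g.b * scale,
                    angle=g.angle + rng.normal(0.0, 0.6 * gland_size_jitter),
                    lumen_frac=g.lumen_frac,
                )

        if i > 0 and rho < 1.0:
            fresh = ndimage.gaussian_filter(
                rng.standard_normal(texture.shape), 6.0
            )
            fresh /= max(fresh.std(), 1e-9)
            texture = rho * texture + np.sqrt(1 - rho**2) * fresh

        types = np.where(scene.tissue_mask.pixels, STROMA, BG).astype(np.int32)
        for k in present:
            g = evolved[k]
            _paint_ellipse(types, g, 1.0, GLAND_RIM)
            _paint_ellipse(types, g, g.lumen_frac, LUMEN)
        types[~scene.tissue_mask.pixels] = BG

        rendered = _render(types, texture, rng, noise_sigma)
        if i == 0:
            img = rendered
            warped_types = types
            mask = scene.tissue_mask.pixels
        else:
            fld = DisplacementField(backward=backward_to[i])
            from .transforms import warp_image, warp_labels, warp_mask

            img = warp_image(
                Raster2D(rendered, 1.0), fld, interp="linear", fill=250.0
            ).pixels
            warped_types = warp_labels(types, fld)
            mask = warp_labels(scene.tissue_mask.pixels.astype(np.int32), fld) > 0

        images.append(Raster2D(img, 1.0))
        masks.append(BinaryMask(mask, 1.0))
        type_rasters.append(warped_types)

        from .transforms import _sample_field

        lm_i = lm0 + _sample_field(forward_to[i], lm0)
        landmarks.append(PointSet2D(lm_i, space_tag=f"section{i}"))
        valid = np.array([
            (g == 0) or (g - 1 in present) for g in lm_glands
        ])
        landmark_valid.append(valid)

    return SerialSections(
        images=images, masks=masks, landmarks=landmarks,
        landmark_valid=landmark_valid,
        forward_to=forward_to, backward_to=backward_to,
        gland_sets=gland_sets, type_labels=type_rasters,
    )


# ---------------------------------------------------------------------------
# Omics layers
# ---------------------------------------------------------------------------

@dataclass
class OmicsLayers:
    """Spot + pixel omics over one section, sharing its gland ground truth."""

    spots: SpotGeometry
    spot_table: MeasurementTable
    spot_gland_fraction: dict
    pixels: PixelGeometry
    pixel_table: MeasurementTable
    pixel_gland_fraction: dict
    annotation_labels: np.ndarray     # (H, W): 0 none / 1 stroma / 2 gland


def _gland_fraction_circle(gland: np.ndarray, cx: float, cy: float,
                           r: float) -> float:
    x0, x1 = max(0, int(cx - r)), min(gland.shape[1], int(cx + r) + 1)
    y0, y1 = max(0, int(cy - r)), min(gland.shape[0], int(cy + r) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    if not inside.any():
        return 0.0
    return float(gland[y0:y1, x0:x1][inside].mean())


def make_omics_layers(
    type_labels: np.ndarray,
    tissue_mask: np.ndarray,
    rng: np.random.Generator | int,
    spot_diameter_um: float = 55.0,
    spot_pitch_um: float = 100.0,
    msi_pitch_um: float = 30.0,
    effect: float = 1.0,
    noise: float = 0.15,
    resolution_um: float = 1.0,
    latent: np.ndarray | None = None,
    latent_weight: float = 0.0,
) -> OmicsLayers:
    """Hexagonal spot lattice + square pixel grid over one section.

    Spot values emulate a gene-signature score and pixel values a metabolite
    intensity, both ``baseline + effect * gland_fraction + N(0, noise)`` so
    the true cross-layer correlation is known by construction.  An optional
    smooth ``latent`` field (already in this section's coordinates) adds
    ``latent_weight * latent(x, y)`` to both value kinds, modeling biological
    co-variation *within* a tissue type that only a correct spatial
    integration can align.  The pixel table carries three channels
    (gland-high, stroma-high, total intensity) so a first principal
    component is meaningful.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    gland = (type_labels >= GLAND_RIM).astype(float)
    h, w = type_labels.shape
    if latent is None:
        latent = np.zeros((h, w))
        latent_weight = 0.0

    # hexagonal lattice: row pitch p*sqrt(3)/2, alternate rows offset p/2
    p_px = spot_pitch_um / resolution_um
    row_pitch = p_px * np.sqrt(3) / 2.0
    r_px = (spot_diameter_um / 2.0) / resolution_um
    centers = []
    row = 0
    y = row_pitch / 2.0
    while y < h:
        x = (p_px / 2.0) * (row % 2) + p_px / 2.0
        while x < w:
            if tissue_mask[int(y), int(x)]:
                centers.append((x, y))
            x += p_px
        y += row_pitch
        row += 1
    centers = np.asarray(centers, dtype=float)
    spot_ids = [f"SPOT_{k:04d}" for k in range(len(centers))]
    spots = SpotGeometry(spot_ids, centers * resolution_um,
                         spot_diameter_um, spot_pitch_um)

    spot_frac = {}
    gene = np.empty(len(centers))
    for k, (cx, cy) in enumerate(centers):
        frac = _gland_fraction_circle(gland, cx, cy, r_px)
        spot_frac[spot_ids[k]] = frac
        gene[k] = (1.0 + effect * frac
                   + latent_weight * latent[int(cy), int(cx)]
                   + rng.normal(0.0, noise))
    spot_table = MeasurementTable(
        pd.DataFrame({"gene_score": gene}, index=spot_ids)
    )

    # square pixel grid over the tissue bounding box
    m_px = msi_pitch_um / resolution_um
    rows_t, cols_t = np.nonzero(tissue_mask)
    x_min, y_min = cols_t.min(), rows_t.min()
    nx = int((cols_t.max() - x_min) // m_px) + 1
    ny = int((rows_t.max() - y_min) // m_px) + 1
    grid_xy, pix_frac_list, pix_latent = [], [], []
    for gy in range(ny):
        for gx in range(nx):
            x0 = int(x_min + gx * m_px)
            y0 = int(y_min + gy * m_px)
            patch = tissue_mask[y0:min(y0 + int(m_px), h),
                                x0:min(x0 + int(m_px), w)]
            if patch.size and patch.mean() > 0.5:
                grid_xy.append((gx, gy))
                gp = gland[y0:min(y0 + int(m_px), h), x0:min(x0 + int(m_px), w)]
                pix_frac_list.append(float(gp.mean()))
                lp = latent[y0:min(y0 + int(m_px), h), x0:min(x0 + int(m_px), w)]
                pix_latent.append(float(lp.mean()))
    grid_xy = np.asarray(grid_xy, dtype=int)
    pix_ids = [f"PX_{k:05d}" for k in range(len(grid_xy))]
    pixels = PixelGeometry(
        pix_ids, grid_xy,
        origin_um=(x_min * resolution_um, y_min * resolution_um),
        pitch_um=msi_pitch_um,
    )
    frac = np.asarray(pix_frac_list)
    met = (1.0 + effect * frac + latent_weight * np.asarray(pix_latent)
           + rng.normal(0.0, noise, size=len(frac)))
    met_stroma = 1.0 + effect * (1 - frac) + rng.normal(0.0, noise, size=len(frac))
    tic = 2.0 + rng.normal(0.0, noise, size=len(frac))
    pixel_table = MeasurementTable(
        pd.DataFrame(
            {"metabolite": met, "met_stroma": met_stroma, "tic": tic},
            index=pix_ids,
        )
    )
    pix_frac = dict(zip(pix_ids, frac))

    ann = np.zeros((h, w), dtype=np.int32)
    ann[tissue_mask] = 1
    ann[(type_labels >= GLAND_RIM)] = 2
    return OmicsLayers(spots, spot_table, spot_frac,
                       pixels, pixel_table, pix_frac, ann)
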