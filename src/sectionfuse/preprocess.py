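"""Build registration-ready image pairs.

The pipeline mirrors the standard serial-section workflow: segment the
tissue, optionally denoise (affine stage only), crop both images to their
tissue bounding boxes, pad to a common square, anti-alias smooth, downscale
to the working resolution, convert to grayscale, and pad a fixed border to
leave room for deformations.  Every geometric step is recorded as an exact
affine map from original to working space so results can be rescaled back
without drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import filters, morphology, restoration
from skimage.transform import resize

from ._meanshift import mean_shift_filter
from .core import BinaryMask, DimensionError, NoTissueError, Raster2D
from .transforms import AffineTransform, resize_map

SEGMENT_SIZE = 640        # segmentation working resolution
DENOISE_SIZE = 512        # mean-shift working resolution
WORKING_SIZE = 1024       # registration working resolution
PAD_PX = 100              # border pad at WORKING_SIZE scale


def segment_tissue(
    image: Raster2D,
    min_region_um2: float = 10_000.0,
    tissue_darker: bool = True,
    tv_weight: float = 0.1,
) -> BinaryMask:
    """Threshold-based tissue segmentation in the original image space.

    The image is resampled to 640x640 grayscale, total-variation denoised
    (Chambolle), Otsu-thresholded with tissue on the dark side of a light
    background, morphologically closed, filtered for small regions, and the
    mask resampled back to the original grid.
    """
    gray = image.to_gray().pixels.astype(float)
    h, w = gray.shape
    small = resize(gray, (SEGMENT_SIZE, SEGMENT_SIZE), order=1, anti_aliasing=True)
    rng_span = small.max() - small.min()
    if rng_span < 1e-9:
        warnings.warn("no tissue found: image is uniform", stacklevel=2)
        return BinaryMask(np.zeros((h, w), dtype=bool), image.resolution_um)
    norm = (small - small.min()) / rng_span
    den = restoration.denoise_tv_chambolle(norm, weight=tv_weight)
    thr = filters.threshold_otsu(den)
    mask = den < thr if tissue_darker else den > thr
    mask = morphology.closing(mask, morphology.disk(5))
    # area per 640-scale pixel in um^2
    px_area = (h / SEGMENT_SIZE) * (w / SEGMENT_SIZE) * image.resolution_um**2
    mask = filter_small_regions(
        BinaryMask(mask, np.sqrt(px_area)), min_region_um2
    ).pixels
    full = resize(mask.astype(float), (h, w), order=0, anti_aliasing=False) > 0.5
    if not full.any():
        warnings.warn("no tissue found after segmentation", stacklevel=2)
    return BinaryMask(full, image.resolution_um)


def filter_small_regions(mask: BinaryMask, min_area_um2: float) -> BinaryMask:
    """Drop 8-connected regions with physical area below ``min_area_um2``."""
    min_px = min_area_um2 / mask.resolution_um**2
    labeled, n = ndimage.label(mask.pixels, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return BinaryMask(mask.pixels.copy(), mask.resolution_um)
    areas = np.bincount(labeled.ravel())
    keep = areas >= min_px
    keep[0] = False
    return BinaryMask(keep[labeled], mask.resolution_um)


def denoise_mean_shift(
    image: Raster2D,
    spatial_radius: int = 20,
    color_radius: float = 15.0,
    max_iter: int = 10,
) -> Raster2D:
    """Edge-preserving mean-shift denoising of an RGB image.

    Resamples to 512x512, filters jointly in (x, y, H, S, V) with OpenCV-style
    8-bit HSV scaling (H in [0, 180], S and V in [0, 255]), and resamples
    back.  Grayscale input is rejected: denoising is defined on color.
    """
    if not image.is_rgb:
        raise DimensionError("mean-shift denoising requires a 3-channel image")
    h, w = image.shape
    rgb = image.pixels.astype(float) / 255.0
    small = resize(rgb, (DENOISE_SIZE, DENOISE_SIZE), order=1, anti_aliasing=True)
    hsv = skcolor.rgb2hsv(np.clip(small, 0, 1))
    hsv_scaled = hsv * np.array([180.0, 255.0, 255.0])
    filtered = mean_shift_filter(hsv_scaled, spatial_radius, color_radius, max_iter)
    hsv_out = np.clip(filtered / np.array([180.0, 255.0, 255.0]), 0, 1)
    rgb_out = skcolor.hsv2rgb(hsv_out)
    full = resize(rgb_out, (h, w), order=1, anti_aliasing=False)
    out = np.clip(full * 255.0, 0, 255)
    if image.pixels.dtype == np.uint8:
        out = out.astype(np.uint8)
    return Raster2D(out, image.resolution_um, image.origin)


@dataclass
class PreprocessedImage:
    """Working-space image plus the exact original->working bookkeeping."""

    image: Raster2D            # grayscale float at working resolution
    mask: BinaryMask           # tissue mask at working resolution
    to_working: AffineTransform  # original-space coords -> working-space coords
    original_shape: tuple[int, int] = (0, 0)
    steps: list[str] = field(default_factory=list)

    @property
    def working_shape(self) -> tuple[int, int]:
        return self.image.shape


def _background_value(pixels: np.ndarray) -> float | np.ndarray:
    """Median of the 1-px image border, per channel — the slide background."""
    border = np.concatenate(
        [pixels[0].reshape(-1, *pixels.shape[2:]),
         pixels[-1].reshape(-1, *pixels.shape[2:]),
         pixels[:, 0].reshape(-1, *pixels.shape[2:]),
         pixels[:, -1].reshape(-1, *pixels.shape[2:])]
    )
    return np.median(border, axis=0)


def _preprocess_one(
    image: Raster2D,
    mask: BinaryMask,
    square: int,
    bbox: tuple[int, int, int, int],
    working_size: int,
    pad_px: int,
) -> PreprocessedImage:
    y0, y1, x0, x1 = bbox
    crop = image.pixels[y0:y1, x0:x1].astype(float)
    mcrop = mask.pixels[y0:y1, x0:x1]
    ch, cw = crop.shape[:2]
    top = (square - ch) // 2
    bottom = square - ch - top
    left = (square - cw) // 2
    right = square - cw - left
    bg = _background_value(image.pixels.astype(float))
    if crop.ndim == 3:
        padded = np.empty((square, square, crop.shape[2]), dtype=float)
        padded[...] = bg
        padded[top:top + ch, left:left + cw] = crop
    else:
        padded = np.full((square, square), float(np.mean(bg)), dtype=float)
        padded[top:top + ch, left:left + cw] = crop
    mpad = np.zeros((square, square), dtype=bool)
    mpad[top:top + ch, left:left + cw] = mcrop

    smoothed = ndimage.gaussian_filter(
        padded, sigma=(2, 2) if padded.ndim == 2 else (2, 2, 0)
    )
    resized = resize(smoothed, (working_size, working_size), order=1,
                     anti_aliasing=False)
    if resized.ndim == 3:
        gray = Raster2D(resized, image.resolution_um).to_gray().pixels
    else:
        gray = resized
    mres = resize(mpad.astype(float), (working_size, working_size), order=0,
                  anti_aliasing=False) > 0.5

    final = np.pad(gray, pad_px, mode="constant",
                   constant_values=float(np.mean(bg)))
    mfinal = np.pad(mres, pad_px, mode="constant", constant_values=False)

    to_working = (
        AffineTransform.translation(pad_px, pad_px)
        @ resize_map((square, square), (working_size, working_size))
        @ AffineTransform.translation(left - x0, top - y0)
    )
    work_res = image.resolution_um * square / working_size
    return PreprocessedImage(
        image=Raster2D(final.astype(np.float32), work_res),
        mask=BinaryMask(mfinal, work_res),
        to_working=to_working,
        original_shape=image.shape,
    )


def prepare_pair(
    moving: Raster2D,
    fixed: Raster2D,
    moving_mask: BinaryMask | None = None,
    fixed_mask: BinaryMask | None = None,
    for_stage: str = "affine",
    working_size: int = WORKING_SIZE,
    pad_px: int | None = None,
    min_region_um2: float = 10_000.0,
    spatial_radius: int = 20,
    color_radius: float = 15.0,
) -> tuple[PreprocessedImage, PreprocessedImage]:
    """Produce the (moving, fixed) pair the registration stage consumes.

    ``for_stage='affine'`` applies mean-shift denoising first; the nonrigid
    stage repeats preprocessing without denoising so local features survive.
    ``pad_px`` defaults to the canonical 100 px border scaled with
    ``working_size``.
    """
    if for_stage not in ("affine", "nonrigid"):
        raise ValueError(f"unknown stage {for_stage!r}")
    if pad_px is None:
        pad_px = max(1, round(PAD_PX * working_size / WORKING_SIZE))

    masks = []
    for img, msk in ((moving, moving_mask), (fixed, fixed_mask)):
        if msk is None:
            msk = segment_tissue(img, min_region_um2=min_region_um2)
        if msk.is_empty:
            raise NoTissueError("empty tissue mask; cannot prepare pair")
        masks.append(msk)

    images = [moving, fixed]
    if for_stage == "affine":
        images = [
            denoise_mean_shift(img, spatial_radius, color_radius)
            if img.is_rgb else img
            for img in images
        ]

    bboxes = []
    for msk in masks:
        rows, cols = np.nonzero(msk.pixels)
        bboxes.append((rows.min(), rows.max() + 1, cols.min(), cols.max() + 1))
    square = max(
        max(b[1] - b[0], b[3] - b[2]) for b in bboxes
    )
    out = tuple(
        _preprocess_one(img, msk, square, bbox, working_size, pad_px)
        for img, msk, bbox in zip(images, masks, bboxes)
    )
    for pre in out:
        pre.steps.append(for_stage)
    return out
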