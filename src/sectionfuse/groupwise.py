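"""Groupwise registration of an ordered series of serial sections.

Neighbor sections are registered affinely pairwise; each moving section's
affine chain to the fixed section is the composition of neighbor affines.
The nonrigid stage then registers every moving section *directly* against
the fixed section, initialized from its chained affine, and composites the
result per section.  Sections are independent after the affine chain, so the
nonrigid stage runs through a pluggable ``map_fn`` (default: sequential).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import BinaryMask, ChainError, Raster2D, SectionFuseError
from .preprocess import prepare_pair, segment_tissue
from .registration import (
    RegistrationOptions,
    affine_register,
    nonrigid_register,
)
from .transforms import AffineTransform, TransformChain


@dataclass
class SectionSeries:
    """Ordered serial sections with an index of the common fixed section."""

    images: list[Raster2D]
    masks: list[BinaryMask | None] = field(default_factory=list)
    fixed_index: int | None = None  # default: last section
    skip: tuple[int, ...] = ()      # damaged sections bridged over

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise SectionFuseError("a series needs at least 2 sections")
        if not self.masks:
            self.masks = [None] * len(self.images)
        if self.fixed_index is None:
            self.fixed_index = len(self.images) - 1
        if not 0 <= self.fixed_index < len(self.images):
            raise SectionFuseError(f"fixed_index {self.fixed_index} out of range")
        if self.fixed_index in self.skip:
            raise SectionFuseError("cannot skip the fixed section")

    def __len__(self) -> int:
        return len(self.images)

    def resolved_masks(self) -> list[BinaryMask]:
        out = []
        for img, msk in zip(self.images, self.masks):
            out.append(msk if msk is not None else segment_tissue(img))
        return out


def _pairwise_affine_original(
    moving: Raster2D, fixed: Raster2D,
    moving_mask: BinaryMask, fixed_mask: BinaryMask,
    opts: RegistrationOptions,
) -> AffineTransform:
    """Affine in *original* coordinates so neighbor maps compose exactly.

    Inputs are expected to be denoised already (the series is denoised once
    per section rather than once per neighbor pair), so the geometric part
    of the affine-stage preprocessing is run without re-denoising.
    """
    pre_m, pre_f = prepare_pair(
        moving, fixed, moving_mask, fixed_mask, for_stage="nonrigid",
        working_size=opts.working_size, pad_px=opts.pad_px,
    )
    a_work = affine_register(pre_m, pre_f, opts)
    return pre_f.to_working.inverse() @ a_work @ pre_m.to_working


def serial_affine_chain(
    series: SectionSeries,
    opts: RegistrationOptions | None = None,
    map_fn=map,
) -> dict[int, AffineTransform]:
    """Original-space affine from each moving section to the fixed section."""
    opts = opts or RegistrationOptions()
    masks = series.resolved_masks()
    active = [i for i in range(len(series)) if i not in series.skip]
    fpos = active.index(series.fixed_index)

    from .preprocess import denoise_mean_shift

    denoised = {
        i: (denoise_mean_shift(series.images[i])
            if opts.denoise and series.images[i].is_rgb else series.images[i])
        for i in active
    }

    pairs = [(active[k], active[k + 1]) for k in range(len(active) - 1)]

    def _one(pair):
        i, j = pair
        try:
            return _pairwise_affine_original(
                denoised[i], denoised[j], masks[i], masks[j], opts
            )
        except SectionFuseError as exc:
            raise ChainError(f"neighbor registration {i}->{j} failed: {exc}") from exc

    neighbor = dict(zip(pairs, map_fn(_one, pairs)))

    chains: dict[int, AffineTransform] = {series.fixed_index: AffineTransform.identity()}
    # walk left of the fixed section: compose forward neighbor affines
    acc = AffineTransform.identity()
    for k in range(fpos - 1, -1, -1):
        acc = acc @ neighbor[(active[k], active[k + 1])]
        chains[active[k]] = acc
    # walk right: compose inverses
    acc = AffineTransform.identity()
    for k in range(fpos, len(active) - 1):
        acc = acc @ neighbor[(active[k], active[k + 1])].inverse()
        chains[active[k + 1]] = acc
    return chains


def groupwise_register(
    series: SectionSeries,
    opts: RegistrationOptions | None = None,
    map_fn=map,
) -> dict[int, TransformChain]:
    """Affine chain + direct nonrigid refinement per moving section."""
    opts = opts or RegistrationOptions()
    masks = series.resolved_masks()
    affines = serial_affine_chain(series, opts, map_fn)
    fixed_idx = series.fixed_index
    fixed_img = series.images[fixed_idx]
    fixed_mask = masks[fixed_idx]
    moving_ids = [i for i in range(len(series))
                  if i != fixed_idx and i not in series.skip]

    def _one(i: int) -> TransformChain:
        try:
            pre_m, pre_f = prepare_pair(
                series.images[i], fixed_img, masks[i], fixed_mask,
                for_stage="nonrigid",
                working_size=opts.working_size, pad_px=opts.pad_px,
            )
            init_work = pre_f.to_working @ affines[i] @ pre_m.to_working.inverse()
            fld = nonrigid_register(pre_m, pre_f, init_work, opts)
        except SectionFuseError as exc:
            raise ChainError(f"nonrigid stage failed for section {i}: {exc}") from exc
        return TransformChain(
            [pre_m.to_working, init_work, fld, pre_f.to_working.inverse()],
            fixed_shape=fixed_img.shape,
            moving_shape=series.images[i].shape,
            resolution_um=fixed_img.resolution_um,
        )

    return dict(zip(moving_ids, map_fn(_one, moving_ids)))
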