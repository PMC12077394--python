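"""Area-fraction-weighted fusion of source omics measurements into target spots.

After both geometries exist as reference matrices in the *target* image
space, the shared raster cells between each target spot and the registered
source pixels define per-spot area-fraction weights.  Source values are
aggregated per spot with weighted minimum/maximum/mean/std/median, then
coverage and tissue-type filters mirror the downstream analysis: spots with
less than 80% tissue coverage are removed, and tissue-type matching keeps
only spots whose label agrees between target and source sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BinaryMask, DimensionError, IntegrityError
from .omics import MeasurementTable, ReferenceMatrix
from .transforms import AffineTransform, TransformChain

STATS = ("min", "max", "mean", "std", "median")


@dataclass
class OverlapMap:
    """Per-target-spot area-fraction weights over source data points."""

    weights: dict                     # target id -> list of (source id, weight)
    cell_counts: dict = field(default_factory=dict)  # target id -> co-labeled cells
    cell_area_um2: float = 1.0

    def __getitem__(self, target_id):
        return self.weights[target_id]

    def __len__(self) -> int:
        return len(self.weights)


def overlap_weights(
    target_ref: ReferenceMatrix, source_ref: ReferenceMatrix
) -> OverlapMap:
    """Count co-labeled raster cells per (target, source) pair and normalize
    per target spot.  Both matrices must already share the target grid."""
    if target_ref.shape != source_ref.shape:
        raise DimensionError(
            "reference matrices must share the target image space "
            f"({target_ref.shape} vs {source_ref.shape}); register first"
        )
    t = target_ref.labels.ravel().astype(np.int64)
    s = source_ref.labels.ravel().astype(np.int64)
    both = (t > 0) & (s > 0)
    t, s = t[both], s[both]
    n_s = len(source_ref.ids) + 1
    pair_counts = np.bincount(t * n_s + s, minlength=(len(target_ref.ids) + 1) * n_s)
    weights: dict = {}
    counts: dict = {}
    nz = np.nonzero(pair_counts)[0]
    by_target: dict[int, list] = {}
    for code in nz:
        tl, sl = divmod(int(code), n_s)
        by_target.setdefault(tl, []).append((sl, int(pair_counts[code])))
    for tl, pairs in by_target.items():
        total = sum(c for _, c in pairs)
        tid = target_ref.id_of(tl)
        weights[tid] = [
            (source_ref.id_of(sl), c / total) for sl, c in pairs
        ]
        counts[tid] = total
    return OverlapMap(weights, counts, target_ref.resolution_um**2)


def weighted_stats(values: np.ndarray, weights: np.ndarray) -> dict:
    """Weighted summary: min/max are unweighted extremes of contributing
    values, mean is sum(w*v), std the population form, median the lower
    weighted median (smallest v with cumulative weight >= 0.5)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        return {k: np.nan for k in STATS}
    if values.shape != weights.shape:
        raise DimensionError("values and weights differ in length")
    mean = float(np.sum(weights * values))
    std = float(np.sqrt(np.sum(weights * (values - mean) ** 2)))
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    # lower weighted median; the epsilon keeps exact-half ties (e.g. equal
    # cell counts) from flipping on float cumsum error
    idx = min(int(np.searchsorted(cum, 0.5 - 1e-9)), len(values) - 1)
    median = float(values[order][idx])
    return {
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": mean,
        "std": std,
        "median": median,
    }


@dataclass
class FusedSpotTable:
    """Per-spot weighted statistics plus overlap bookkeeping.

    ``frame`` is indexed by target spot id with columns
    ``<measure>_<stat>`` plus ``overlap_area_um2`` and ``n_source_points``;
    spots without any overlap are present with NaN statistics and a
    ``no_overlap`` flag rather than silently dropped.
    """

    frame: pd.DataFrame
    measures: list[str]

    def spot_ids(self):
        return list(self.frame.index)


def fuse(source_table: MeasurementTable, weights: OverlapMap,
         all_target_ids=None) -> FusedSpotTable:
    """Aggregate source measurements into each target spot."""
    measures = source_table.measures
    target_ids = list(weights.weights) if all_target_ids is None else list(all_target_ids)
    rows = []
    for tid in target_ids:
        row: dict = {"spot_id": tid}
        pairs = weights.weights.get(tid)
        if not pairs:
            row["no_overlap"] = True
            row["overlap_area_um2"] = 0.0
            row["n_source_points"] = 0
            for m in measures:
                for s in STATS:
                    row[f"{m}_{s}"] = np.nan
        else:
            sids = [sid for sid, _ in pairs]
            w = np.array([wt for _, wt in pairs])
            vals = source_table.values_for(sids)
            row["no_overlap"] = False
            row["overlap_area_um2"] = weights.cell_counts.get(tid, 0) * weights.cell_area_um2
            row["n_source_points"] = len(sids)
            for j, m in enumerate(measures):
                stats = weighted_stats(vals[:, j], w)
                for s in STATS:
                    row[f"{m}_{s}"] = stats[s]
        rows.append(row)
    frame = pd.DataFrame(rows).set_index("spot_id")
    return FusedSpotTable(frame, list(measures))


# ---------------------------------------------------------------------------
# Coverage and tissue-type filters
# ---------------------------------------------------------------------------

def spot_coverage(
    target_ref: ReferenceMatrix, tissue_mask: BinaryMask
) -> dict:
    """Per-spot fraction of labeled cells lying inside the tissue mask."""
    if target_ref.shape != tissue_mask.shape:
        raise DimensionError("tissue mask must share the target image space")
    labels = target_ref.labels.ravel()
    inmask = tissue_mask.pixels.ravel()
    total = np.bincount(labels, minlength=len(target_ref.ids) + 1)
    inside = np.bincount(labels, weights=inmask.astype(float),
                         minlength=len(target_ref.ids) + 1)
    out = {}
    for k in range(1, len(target_ref.ids) + 1):
        if total[k] > 0:
            out[target_ref.id_of(k)] = float(inside[k] / total[k])
    return out


def filter_by_coverage(coverage: dict, threshold: float = 0.8) -> list:
    """Keep spots with coverage >= threshold ('less than' removal)."""
    return [sid for sid, frac in coverage.items() if frac >= threshold]


@dataclass
class SpotAnnotation:
    """Per-spot tissue-type label with per-label area fractions."""

    labels: dict                      # spot id -> label or None (unassigned)
    fractions: dict                   # spot id -> {label: fraction}


def assign_tissue_type(
    target_ref: ReferenceMatrix,
    annotation_labels: np.ndarray,
    label_names: dict | None = None,
    min_fraction: float = 0.5,
) -> SpotAnnotation:
    """Majority tissue type per spot from an annotation label raster already
    in the target image space (0 = unannotated)."""
    if target_ref.shape != annotation_labels.shape:
        raise DimensionError("annotation raster must share the target image space")
    spots = target_ref.labels.ravel()
    ann = annotation_labels.ravel().astype(np.int64)
    n_ann = int(ann.max()) + 1
    labels: dict = {}
    fractions: dict = {}
    total = np.bincount(spots, minlength=len(target_ref.ids) + 1)
    combo = np.bincount(spots * n_ann + ann,
                        minlength=(len(target_ref.ids) + 1) * n_ann)
    for k in range(1, len(target_ref.ids) + 1):
        if total[k] == 0:
            continue
        sid = target_ref.id_of(k)
        fr = {}
        for a in range(1, n_ann):
            c = combo[k * n_ann + a]
            if c:
                name = label_names[a] if label_names else a
                fr[name] = float(c / total[k])
        fractions[sid] = fr
        if fr:
            top = max(fr, key=fr.get)
            labels[sid] = top if fr[top] >= min_fraction else None
        else:
            labels[sid] = None
    return SpotAnnotation(labels, fractions)


def tissue_type_match(target_ann: SpotAnnotation, source_ann: SpotAnnotation) -> list:
    """Ids whose target and source labels are equal and both assigned."""
    out = []
    for sid, lab in target_ann.labels.items():
        if lab is None:
            continue
        other = source_ann.labels.get(sid)
        if other is not None and other == lab:
            out.append(sid)
    return out


# ---------------------------------------------------------------------------
# Sham control and export
# ---------------------------------------------------------------------------

def sham_rotate(chain: TransformChain, degrees: float = 180.0) -> TransformChain:
    """Append a rotation about the fixed-image center: the deliberately
    mis-registered negative control."""
    if chain.fixed_shape is None:
        raise DimensionError("sham rotation needs the chain's fixed_shape")
    h, w = chain.fixed_shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    return chain.appended(AffineTransform.rotation(degrees, center))


def export_fused(
    table: FusedSpotTable,
    path: str,
    mode: str = "wide_table",
    target_ref: ReferenceMatrix | None = None,
    stat: str = "mean",
):
    """Write fused spots as a wide CSV keyed by spot id, or paint them into a
    per-measure image stack over the target grid (written as TIFF)."""
    path = Path(path)
    if mode == "wide_table":
        if table.frame.index.has_duplicates:
            raise IntegrityError("duplicate spot ids on export")
        table.frame.to_csv(path, float_format="%.9f")
        return path
    if mode == "image_stack":
        import tifffile

        if target_ref is None:
            raise DimensionError("image_stack export needs the target reference matrix")
        lut = np.zeros(len(target_ref.ids) + 1, dtype=np.float32)
        pages = []
        for m in table.measures:
            col = table.frame[f"{m}_{stat}"]
            lut[:] = 0
            for sid, val in col.items():
                if np.isfinite(val):
                    lut[target_ref.label_of(sid)] = val
            pages.append(lut[target_ref.labels])
        tifffile.imwrite(path, np.stack(pages))
        return path
    raise ValueError(f"unknown export mode {mode!r}")


def read_fused(path: str) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
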