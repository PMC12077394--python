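"""Landmark-based registration accuracy metrics.

The target registration error of landmark pair *l* is the Euclidean distance
between the warped and the fixed landmark.  Each registration pair is
summarized by its median TRE; a dataset of pairs by the median of medians
(MM-TRE, robust) and the mean of medians (AM-TRE, outlier-sensitive).  At a
1 um/px export resolution all errors are in microns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DimensionError, PointSet2D, SectionFuseError


class UndefinedMetricError(SectionFuseError):
    """Metric requested on an empty input."""


@dataclass
class LandmarkPairSet:
    """Paired warped/fixed landmarks, matched by index."""

    warped: PointSet2D
    fixed: PointSet2D

    def __post_init__(self) -> None:
        if len(self.warped) != len(self.fixed):
            raise DimensionError(
                f"landmark counts differ: {len(self.warped)} vs {len(self.fixed)}"
            )

    def __len__(self) -> int:
        return len(self.warped)


def tre(pairs: LandmarkPairSet) -> np.ndarray:
    """Per-landmark Euclidean distances."""
    if len(pairs) == 0:
        raise UndefinedMetricError("TRE of an empty landmark set")
    return np.linalg.norm(pairs.warped.points - pairs.fixed.points, axis=1)


def median_tre(pairs: LandmarkPairSet) -> float:
    """Median TRE of one registration pair (even counts: midpoint)."""
    return float(np.median(tre(pairs)))


def mm_tre(pair_medians) -> float:
    """Median of per-pair median TREs over a set of registration pairs."""
    vals = np.asarray(list(pair_medians), dtype=float)
    if vals.size == 0:
        raise UndefinedMetricError("MM-TRE of an empty pair set")
    return float(np.median(vals))


def am_tre(pair_medians) -> float:
    """Mean of per-pair median TREs over a set of registration pairs."""
    vals = np.asarray(list(pair_medians), dtype=float)
    if vals.size == 0:
        raise UndefinedMetricError("AM-TRE of an empty pair set")
    return float(vals.mean())


@dataclass
class TREReport:
    """Full evaluation: per-landmark errors per pair plus dataset summaries."""

    per_pair_tre: list[np.ndarray]
    pair_medians: list[float]
    mm: float
    am: float

    @staticmethod
    def from_pairs(pair_sets: list[LandmarkPairSet]) -> "TREReport":
        per = [tre(p) for p in pair_sets]
        med = [float(np.median(t)) for t in per]
        return TREReport(per, med, mm_tre(med), am_tre(med))

    def to_dict(self) -> dict:
        return {
            "pair_medians": self.pair_medians,
            "mm_tre": self.mm,
            "am_tre": self.am,
            "n_pairs": len(self.pair_medians),
        }
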