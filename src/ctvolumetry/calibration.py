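"""Grayscale-threshold calibration.

The segmentation threshold controls where the partial-volume boundary
shell is cut, and therefore the sign and size of the volume error.  The
calibration procedure: segment a calibration volume at each threshold
in a sweep, compute the per-size mean percent error, reduce across size
classes to (min, median, max), fit an ordinary least-squares line to
median error versus threshold, and take the zero-error crossing as that
case's optimal threshold.  The global threshold is the rounded mean of
the per-case optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .measurement import match_to_spheres, measure_components
from .phantom import PhantomSpec
from .segmentation import SegmentationParams, segment
from .volume import CTVolume

__all__ = [
    "ThresholdErrorPoint", "ThresholdCalibration",
    "sweep_thresholds", "optimal_threshold", "global_threshold",
]


@dataclass(frozen=True)
class ThresholdErrorPoint:
    """Error summary of one threshold: min/median/max across size classes.

    ``flag`` is ``"ok"`` for a usable point, ``"empty"`` when no sphere
    was detected, or ``"degenerate"`` when segmentation produced an
    oversized merged component (threshold at or below background).
    """

    threshold: float
    median_error: float = float("nan")
    min_error: float = float("nan")
    max_error: float = float("nan")
    n_sizes: int = 0
    flag: str = "ok"

    def __post_init__(self) -> None:
        if self.flag == "ok" and not (
                self.min_error <= self.median_error <= self.max_error):
            raise ValueError("min <= median <= max violated")


@dataclass
class ThresholdCalibration:
    case_id: str
    points: list[ThresholdErrorPoint]
    optimal_threshold: float = float("nan")


def sweep_thresholds(
    volume: CTVolume,
    spec: PhantomSpec,
    thresholds: list[float],
    seg: SegmentationParams,
    exclude_diameters: tuple[float, ...] = (),
) -> list[ThresholdErrorPoint]:
    """Segment at each threshold and summarize percent error by size.

    For each threshold the volume is segmented with ``seg`` (its
    ``threshold`` field overridden), components are matched to the
    phantom spheres, errors are averaged within each size class over
    detected replicates, and the min/median/max across size classes is
    recorded.  Degenerate outcomes are flagged, not raised.
    """
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    voxel_diag = float(np.sqrt(2 * volume.pixel_size_xy ** 2
                               + volume.slice_thickness ** 2))
    max_true = max(s.true_volume for s in spec.spheres)
    points = []
    for thr in sorted(thresholds):
        params = SegmentationParams(
            threshold=thr, min_volume=seg.min_volume,
            min_neighbors=seg.min_neighbors, connectivity=seg.connectivity,
            neighbor_connectivity=seg.neighbor_connectivity)
        labeled = segment(volume, params)
        comps = measure_components(labeled)
        if comps and max(c.volume_mm3 for c in comps) > 2.0 * max_true:
            points.append(ThresholdErrorPoint(threshold=thr, flag="degenerate"))
            continue
        ms = match_to_spheres(comps, spec, voxel_diagonal=voxel_diag)
        ms = [m for m in ms
              if not any(np.isclose(m.true_diameter, d)
                         for d in exclude_diameters)]
        by_size: dict[float, list[float]] = {}
        for m in ms:
            if m.detected:
                by_size.setdefault(m.true_diameter, []).append(m.percent_error)
        if not by_size:
            points.append(ThresholdErrorPoint(threshold=thr, flag="empty"))
            continue
        means = np.array([np.mean(v) for v in by_size.values()])
        points.append(ThresholdErrorPoint(
            threshold=thr, median_error=float(np.median(means)),
            min_error=float(means.min()), max_error=float(means.max()),
            n_sizes=len(means)))
    return points


def optimal_threshold(points: list[ThresholdErrorPoint]) -> float:
    """Zero crossing of the OLS line through (threshold, median error).

    Only points flagged ``"ok"`` enter the fit; at least two with
    distinct thresholds are required.  A zero slope (errors independent
    of threshold) has no crossing and raises.
    """
    ok = [p for p in points if p.flag == "ok"]
    ts = np.array([p.threshold for p in ok], dtype=float)
    if len(np.unique(ts)) < 2:
        raise ValueError("need >= 2 non-degenerate points with distinct "
                         "thresholds")
    es = np.array([p.median_error for p in ok], dtype=float)
    slope, intercept = np.polyfit(ts, es, 1)
    scale = max(1.0, float(np.max(np.abs(es)))) / float(np.ptp(ts))
    if abs(slope) < 1e-9 * scale:
        raise ValueError("median error does not depend on threshold; "
                         "no zero crossing")
    return float(-intercept / slope)


def global_threshold(case_optima: list[float]) -> int:
    """Rounded arithmetic mean of the per-case optimal thresholds (HU)."""
    if not case_optima:
        raise ValueError("case_optima must be non-empty")
    return int(round(float(np.mean(case_optima))))
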