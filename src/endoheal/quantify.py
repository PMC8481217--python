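"""Wound-area time series, normalization and group aggregation.

Per-ROI masks become area series; non-excluded ROIs of a zone are averaged
(raw areas) to reduce noise and single events; the zone series is then
normalized to its first time point; normalized zone series are finally
averaged across independent experiments into a group curve (mean ± SEM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.segmentation import find_boundaries

from .segmentation import WoundMask

__all__ = [
    "WoundAreaSeries",
    "NormalizedSeries",
    "GroupCurve",
    "measure_area",
    "zone_series",
    "normalize",
    "group_curve",
    "percent_faster",
    "compare_to_reference",
]


@dataclass(frozen=True)
class WoundAreaSeries:
    """Per-ROI (or per-zone) wound area over time."""

    roi_id: str
    zone: str
    time_points: np.ndarray      # hours
    area: np.ndarray             # µm²
    missing: np.ndarray = None   # bool per time point: no usable value
    partial: np.ndarray = None   # bool per time point: some contributing ROI missing
    excluded: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points, dtype=float)
        a = np.asarray(self.area, dtype=float)
        if a.shape != t.shape:
            raise ValueError("area and time_points must have equal length")
        miss = (np.zeros(t.shape, dtype=bool) if self.missing is None
                else np.asarray(self.missing, dtype=bool))
        part = (np.zeros(t.shape, dtype=bool) if self.partial is None
                else np.asarray(self.partial, dtype=bool))
        if miss.shape != t.shape or part.shape != t.shape:
            raise ValueError("missing/partial flags must match time_points in length")
        if np.any(a[~miss] < 0):
            raise ValueError("areas must be non-negative")
        object.__setattr__(self, "time_points", t)
        object.__setattr__(self, "area", a)
        object.__setattr__(self, "missing", miss)
        object.__setattr__(self, "partial", part)


@dataclass(frozen=True)
class NormalizedSeries:
    """Zone wound area over time, scaled to the first time point."""

    zone: str
    time_points: np.ndarray
    normalized_area: np.ndarray
    experiment: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points, dtype=float)
        v = np.asarray(self.normalized_area, dtype=float)
        if v.shape != t.shape:
            raise ValueError("normalized_area must match time_points in length")
        object.__setattr__(self, "time_points", t)
        object.__setattr__(self, "normalized_area", v)


@dataclass(frozen=True)
class GroupCurve:
    """Across-experiment mean ± SEM of the normalized wound area."""

    condition: str
    time_points: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray

    def value_at(self, t: float) -> float:
        """Group mean at time ``t`` (linear interpolation between grid points)."""
        return float(np.interp(t, self.time_points, self.mean))


def measure_area(mask: WoundMask) -> float:
    """Wound area in µm²: wound-pixel count × pixel_size²."""
    return mask.wound_pixels * mask.pixel_size ** 2


def zone_series(per_roi_series: list[WoundAreaSeries], zone: str) -> WoundAreaSeries:
    """Average raw areas of the zone's non-excluded ROIs at each time point.

    Time points where some ROI is missing use the mean of the available
    ROIs and are flagged; a time point with no available ROI is NaN and
    flagged missing.
    """
    members = [s for s in per_roi_series if s.zone == zone and not s.excluded]
    if not members:
        raise ValueError(f"no non-excluded ROI series in zone {zone!r}")
    t = members[0].time_points
    for s in members[1:]:
        if not np.array_equal(s.time_points, t):
            raise ValueError("ROI series must share a common time grid")
    areas = np.stack([s.area for s in members])
    miss = np.stack([s.missing for s in members])
    all_missing = miss.all(axis=0)
    sums = np.where(miss, 0.0, areas).sum(axis=0)
    counts = (~miss).sum(axis=0)
    mean = sums / np.maximum(counts, 1)
    return WoundAreaSeries(
        roi_id=f"zone:{zone}", zone=zone, time_points=t,
        area=mean, missing=all_missing, partial=miss.any(axis=0),
    )


def normalize(series: WoundAreaSeries) -> NormalizedSeries:
    """Divide by the first-time-point area (which must be positive)."""
    a0 = series.area[0]
    if series.missing[0] or a0 <= 0:
        raise ValueError(
            f"series {series.roi_id!r}: first-time-point area is zero or missing; "
            "the ROI had no wound and must be excluded upstream"
        )
    return NormalizedSeries(
        zone=series.zone, time_points=series.time_points,
        normalized_area=series.area / a0,
    )


def group_curve(per_experiment: list[NormalizedSeries], condition: str) -> GroupCurve:
    """Mean and SEM across experiments at each time point.

    SEM uses the sample standard deviation (n−1 denominator) divided by
    √n.  With a single experiment the mean is returned and the SEM is NaN
    (unavailable).
    """
    if not per_experiment:
        raise ValueError("no experiments supplied")
    t = per_experiment[0].time_points
    for s in per_experiment[1:]:
        if not np.array_equal(s.time_points, t):
            raise ValueError("experiments must share a common time grid")
    values = np.stack([s.normalized_area for s in per_experiment])
    n = values.shape[0]
    mean = values.mean(axis=0)
    if n >= 2:
        sem = values.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.full_like(mean, np.nan)
    return GroupCurve(condition=condition, time_points=t, mean=mean,
                      sem=sem, n=np.full(t.shape, n, dtype=int))


def percent_faster(curve_a: GroupCurve, curve_b: GroupCurve, t: float) -> float:
    """Percent excess healed fraction of condition b over reference a at t.

    Healing is measured as the healed fraction 1 − normalized area; the
    result is 100 × [(1−mean_b) − (1−mean_a)] / (1−mean_a).
    """
    healed_a = 1.0 - curve_a.value_at(t)
    healed_b = 1.0 - curve_b.value_at(t)
    if healed_a <= 0:
        raise ValueError("reference condition has healed fraction 0 at t; "
                         "percent comparison undefined")
    return 100.0 * (healed_b - healed_a) / healed_a


def compare_to_reference(auto_mask: WoundMask, reference_mask: WoundMask) -> dict:
    """Agreement between an automatic mask and a reference (e.g. manual) mask.

    Returns the Jaccard index of the wound classes, the relative area
    error of the automatic mask, and the automatic mask's boundary contour
    for overlay export.
    """
    a, r = auto_mask.mask, reference_mask.mask
    if a.shape != r.shape:
        raise ValueError("masks must have the same shape")
    inter = int((a & r).sum())
    union = int((a | r).sum())
    jaccard = inter / union if union else 1.0
    area_ref = int(r.sum())
    rel_err = (int(a.sum()) - area_ref) / area_ref if area_ref else np.nan
    return {
        "jaccard": jaccard,
        "relative_area_error": rel_err,
        "contour": find_boundaries(a, mode="inner"),
    }
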