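"""Histogram-valley segmentation of wound vs. endothelium.

Each ROI crop of each frame is segmented independently: contrast-stretch
the 16-bit crop, convert to 8-bit, build the 256-bin histogram, smooth it
with a moving average (window 10), and threshold at the valley after the
first prominent peak.  The wound (denuded lumen) is the dark class, so
pixels at or below the threshold are wound; the monolayer is the bright
class.

The histogram of a wounded ROI is bimodal: a high peak at the wound gray
value and a second, smaller peak at the cell gray value.  When a wound has
fully closed the histogram loses its dark mode and becomes unimodal; that
is reported as a :class:`SegmentationError` so the pipeline can fall back
to the last usable threshold for that ROI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationError",
    "SmoothedHistogram",
    "ThresholdResult",
    "WoundMask",
    "preprocess",
    "to_8bit",
    "histogram_and_smooth",
    "find_threshold",
    "binarize",
    "segment_roi",
]

U16_MAX = 65535


class SegmentationError(RuntimeError):
    """Raised when no wound/cell bimodality is found in a histogram."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class SmoothedHistogram:
    """A 256-bin 8-bit histogram and its moving-average-smoothed counts."""

    counts: np.ndarray       # smoothed, float
    raw_counts: np.ndarray   # integer counts, sums to the pixel count
    window: int


@dataclass(frozen=True)
class ThresholdResult:
    """Valley-after-first-peak threshold with peak diagnostics."""

    threshold: int
    first_peak: int
    valley: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.first_peak < self.valley <= 255):
            raise ValueError("expected first_peak < valley <= 255")
        if self.threshold != self.valley:
            raise ValueError("threshold must equal the valley gray level")


@dataclass(frozen=True)
class WoundMask:
    """Binary wound/endothelium partition of an ROI crop (True = wound)."""

    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "mask", m)

    @property
    def wound_pixels(self) -> int:
        return int(self.mask.sum())


def preprocess(roi_crop: np.ndarray, clip_percentiles: tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """Contrast-stretch a 16-bit crop to the full range.

    Intensities are linearly rescaled so the lower clip percentile maps to
    0 and the upper to 65535, with clipping outside.  A constant image is
    returned unchanged (with a warning) since it has no contrast to expand.
    """
    crop = np.asarray(roi_crop)
    if crop.size == 0:
        raise ValueError("empty crop")
    lo, hi = np.percentile(crop, clip_percentiles)
    if hi <= lo:
        logger.warning("constant ROI crop: contrast stretch skipped")
        return crop.astype(np.uint16, copy=True)
    stretched = (crop.astype(float) - lo) / (hi - lo) * U16_MAX
    return np.clip(np.rint(stretched), 0, U16_MAX).astype(np.uint16)


def to_8bit(image: np.ndarray) -> np.ndarray:
    """16-bit to 8-bit conversion: v8 = floor(v16 / 256)."""
    return (np.asarray(image) // 256).astype(np.uint8)


def histogram_and_smooth(image8: np.ndarray, window: int = 10) -> SmoothedHistogram:
    """256-bin histogram smoothed with a truncated moving average.

    The window is centred on each bin (for an even window, one extra bin on
    the high side) and truncated at the histogram ends: boundary bins
    average only the data actually contained in the window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    img = np.asarray(image8)
    raw = np.bincount(img.ravel(), minlength=256)[:256].astype(np.int64)
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate(([0], np.cumsum(raw)))
    idx = np.arange(256)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, 256)
    counts = (csum[hi] - csum[lo]) / (hi - lo)
    return SmoothedHistogram(counts=counts, raw_counts=raw, window=window)


def _plateau_local_maxima(counts: np.ndarray) -> list[int]:
    """Leftmost indices of plateaus that are local maxima (edges included)."""
    n = len(counts)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left_ok = i == 0 or counts[i - 1] < counts[i]
        right_ok = j == n - 1 or counts[j + 1] < counts[i]
        if left_ok and right_ok and counts[i] > 0 and not (i == 0 and j == n - 1):
            peaks.append(i)
        i = j + 1
    return peaks


def _prominence(counts: np.ndarray, peak: int) -> float:
    """Topographic prominence: height above the higher of the two side bases.

    Each base is the minimum count between the peak and the nearest
    strictly higher bin on that side (or the histogram end).
    """
    h = counts[peak]
    lmin = h
    i = peak - 1
    while i >= 0 and counts[i] <= h:
        lmin = min(lmin, counts[i])
        i -= 1
    rmin = h
    i = peak + 1
    while i < len(counts) and counts[i] <= h:
        rmin = min(rmin, counts[i])
        i += 1
    return float(h - max(lmin, rmin))


def find_threshold(hist: SmoothedHistogram, prominence_frac: float = 0.05) -> ThresholdResult:
    """Valley-after-first-peak threshold selection on a smoothed histogram.

    The wound and cell modes are identified as the two *most prominent*
    plateau local maxima (topographic prominence; ties broken toward the
    lower gray level).  Residual Poisson ripple and percentile-saturation
    spikes that survive the window-10 smoothing have inherently small
    prominence, while genuine modes rise far above the deep valley that
    separates them, so ranking by prominence is robust across the large
    swings in relative mode height as the wound closes.

    The first (dark) mode is the wound; the threshold is the gray level
    of the minimum count strictly between the two modes, ties broken
    toward the lowest gray level.  The histogram is declared unimodal —
    and a :class:`SegmentationError` raised — when the second-ranked
    peak's prominence falls below ``prominence_frac`` of the global
    maximum count.
    """
    counts = np.asarray(hist.counts, dtype=float)
    peaks = _plateau_local_maxima(counts)
    cmax = counts.max() if counts.size else 0.0
    min_prom = prominence_frac * cmax
    proms = {p: _prominence(counts, p) for p in peaks}
    ranked = sorted(peaks, key=lambda p: (-proms[p], p))
    diagnostics = {
        "peaks": peaks,
        "prominences": proms,
        "ranked": ranked,
        "min_prominence": min_prom,
    }
    if len(ranked) < 2 or proms[ranked[1]] < min_prom:
        raise SegmentationError(
            "histogram is unimodal: no valley between a wound and a cell mode",
            diagnostics=diagnostics,
        )
    first_peak, second_peak = sorted(ranked[:2])
    interior = counts[first_peak + 1:second_peak]
    valley = int(first_peak + 1 + np.argmin(interior))
    return ThresholdResult(threshold=valley, first_peak=first_peak,
                           valley=valley, diagnostics=diagnostics)


def binarize(image8: np.ndarray, threshold: int, pixel_size: float = 1.0) -> WoundMask:
    """Classify pixels at or below the threshold as wound (the dark class)."""
    if not (0 <= threshold <= 255):
        raise ValueError("threshold must be an 8-bit gray level")
    return WoundMask(mask=np.asarray(image8) <= threshold, pixel_size=pixel_size)


def segment_roi(
    roi_crop: np.ndarray,
    pixel_size: float,
    clip_percentiles: tuple[float, float] = (1.0, 99.0),
    window: int = 10,
    prominence_frac: float = 0.05,
) -> tuple[WoundMask, ThresholdResult]:
    """Full single-ROI segmentation: stretch, 8-bit, histogram, threshold."""
    enhanced = preprocess(roi_crop, clip_percentiles)
    img8 = to_8bit(enhanced)
    hist = histogram_and_smooth(img8, window=window)
    result = find_threshold(hist, prominence_frac=prominence_frac)
    return binarize(img8, result.threshold, pixel_size=pixel_size), result
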