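"""Image-stack, ROI and results I/O.

Stacks are multi-page 16-bit grayscale TIFFs with a small JSON sidecar
(``<stack>.meta.json``) carrying the acquisition metadata the TIFF tags do
not reliably hold (pixel size in µm, frame interval in hours, time
origin).  ROI sets are plain JSON.  Results are CSV tables plus a run
manifest that echoes the configuration and seeds so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "TimeLapseStack",
    "RoiSpec",
    "RoiSet",
    "read_stack",
    "write_stack",
    "load_rois",
    "save_rois",
    "make_roi_grid",
    "write_results",
    "write_mask_stack",
]

VALID_ZONES = ("upstream", "stented")


@dataclass(frozen=True)
class TimeLapseStack:
    """An ordered sequence of 2-D intensity frames with acquisition metadata.

    ``frames`` is a (n_frames, rows, cols) uint16 array; ``pixel_size`` is
    µm/pixel, ``frame_interval`` hours, and ``t0`` the time of the first
    frame after stenting (hours).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        object.__setattr__(self, "frames", f)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in hours."""
        return self.t0 + np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class RoiSpec:
    """A zone-labelled rectangular region, 0-based half-open coordinates."""

    id: str
    zone: str
    rect: tuple[int, int, int, int]  # (row_start, col_start, row_stop, col_stop)
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.zone not in VALID_ZONES:
            raise ValueError(f"ROI {self.id!r}: unknown zone {self.zone!r} "
                             f"(expected one of {VALID_ZONES})")
        r0, c0, r1, c1 = self.rect
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"ROI {self.id!r}: empty rect {self.rect}")

    def validate_within(self, frame_shape: tuple[int, int]) -> None:
        r0, c0, r1, c1 = self.rect
        rows, cols = frame_shape
        if not (0 <= r0 and r1 <= rows and 0 <= c0 and c1 <= cols):
            raise ValueError(
                f"ROI {self.id!r}: rect {self.rect} outside frame shape {frame_shape}"
            )

    def crop(self, frame: np.ndarray) -> np.ndarray:
        r0, c0, r1, c1 = self.rect
        return frame[r0:r1, c0:c1]


@dataclass(frozen=True)
class RoiSet:
    """A collection of static ROIs maintained over all frames of a stack."""

    rois: tuple[RoiSpec, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise ValueError("ROI ids must be unique")
        object.__setattr__(self, "rois", tuple(self.rois))

    def for_zone(self, zone: str, include_excluded: bool = False) -> list[RoiSpec]:
        return [r for r in self.rois
                if r.zone == zone and (include_excluded or not r.excluded)]

    @property
    def active(self) -> list[RoiSpec]:
        return [r for r in self.rois if not r.excluded]

    @property
    def zones(self) -> list[str]:
        seen = []
        for r in self.rois:
            if r.zone not in seen:
                seen.append(r.zone)
        return seen


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_stack(stack: TimeLapseStack, path) -> None:
    """Write a stack as a multi-page 16-bit TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    frames = np.asarray(stack.frames)
    if frames.dtype != np.uint16:
        raise ValueError("stack frames must be uint16")
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_h": stack.frame_interval,
        "t0_h": stack.t0,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))


def read_stack(
    path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    t0: float | None = None,
) -> TimeLapseStack:
    """Read a multi-page TIFF stack.

    Metadata is taken from the ``.meta.json`` sidecar when present;
    explicit arguments override it.  8-bit input is promoted to 16-bit by
    scaling (v × 257) and logged.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (FileNotFoundError, PermissionError):
        raise
    except Exception as exc:  # tifffile raises assorted types on bad files
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages of equal shape, got ndim={frames.ndim}")
    if frames.dtype == np.uint8:
        logger.info("%s: promoting 8-bit stack to 16-bit (v*257)", path)
        frames = frames.astype(np.uint16) * 257
    elif frames.dtype != np.uint16:
        raise ValueError(f"{path}: unsupported dtype {frames.dtype} (expected uint8/uint16)")

    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    ps = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    fi = frame_interval if frame_interval is not None else meta.get("frame_interval_h")
    tz = t0 if t0 is not None else meta.get("t0_h", 0.0)
    if ps is None or fi is None:
        raise ValueError(
            f"{path}: pixel_size/frame_interval not in sidecar; pass them explicitly"
        )
    return TimeLapseStack(frames=frames, pixel_size=float(ps),
                          frame_interval=float(fi), t0=float(tz))


def write_mask_stack(masks: np.ndarray, path) -> None:
    """Write boolean masks as a multi-page 8-bit TIFF with values 0/255."""
    arr = (np.asarray(masks, dtype=bool).astype(np.uint8)) * 255
    if arr.ndim == 2:
        arr = arr[None, ...]
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


def save_rois(roiset: RoiSet, path) -> None:
    payload = {
        "rois": [
            {"id": r.id, "zone": r.zone, "rect": list(r.rect),
             "excluded": r.excluded, "reason": r.reason}
            for r in roiset.rois
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_rois(path, frame_shape: tuple[int, int] | None = None) -> RoiSet:
    """Load and validate a JSON ROI file.

    Excluded ROIs are retained but flagged; downstream zone averages skip
    them.  When ``frame_shape`` is given, every rect is checked against it.
    """
    payload = json.loads(Path(path).read_text())
    rois = []
    for entry in payload["rois"]:
        spec = RoiSpec(
            id=str(entry["id"]),
            zone=entry["zone"],
            rect=tuple(int(v) for v in entry["rect"]),
            excluded=bool(entry.get("excluded", False)),
            reason=str(entry.get("reason", "")),
        )
        if frame_shape is not None:
            spec.validate_within(frame_shape)
        rois.append(spec)
    return RoiSet(tuple(rois))


def make_roi_grid(
    frame_shape: tuple[int, int],
    n_upstream: int = 4,
    n_stented: int = 8,
    row_margin: int = 0,
) -> RoiSet:
    """Default ROI layout: column slices spanning the wound band.

    The frame is split into ``n_upstream + n_stented`` equal column
    slices covering all rows (minus an optional margin); the first slices
    are labelled upstream (flow arrives from the left), the rest stented.
    """
    rows, cols = frame_shape
    n = n_upstream + n_stented
    if n < 1 or cols < n:
        raise ValueError("frame too narrow for requested ROI count")
    edges = np.linspace(0, cols, n + 1).astype(int)
    rois = []
    for i in range(n):
        zone = "upstream" if i < n_upstream else "stented"
        k = i + 1 if i < n_upstream else i - n_upstream + 1
        rois.append(RoiSpec(
            id=f"{zone[:2]}{k:02d}", zone=zone,
            rect=(row_margin, int(edges[i]), rows - row_margin, int(edges[i + 1])),
        ))
    return RoiSet(tuple(rois))


def write_results(tables: dict[str, pd.DataFrame], outdir, manifest: dict | None = None) -> dict:
    """Write result tables as CSV plus a run manifest.

    ``tables`` maps a short name (e.g. ``roi_areas``, ``zone_series``,
    ``group_curves``, ``ttest``) to a populated DataFrame.  Returns the
    mapping of table name to written path.  Refuses to write anything if a
    table is empty.
    """
    if not tables:
        raise ValueError("no tables to write")
    for name, df in tables.items():
        if df is None or len(df) == 0:
            raise ValueError(f"table {name!r} is empty; nothing written")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    manifest = dict(manifest or {})
    manifest.setdefault("software", "endoheal 0.1.0")
    manifest["timestamp"] = datetime.datetime.now().isoformat(timespec="seconds")
    manifest["tables"] = {k: str(v.name) for k, v in written.items()}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    written["run_manifest"] = outdir / "run_manifest.json"
    return written
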