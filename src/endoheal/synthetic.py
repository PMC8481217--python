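"""Synthetic fluorescence time-lapse generator with known wound ground truth.

Emulates a CM-DiI-labelled endothelial monolayer imaged on an inverted
epifluorescence microscope at low magnification: bright, textured cell
regions, a dark denuded wound band whose two fronts advance toward the
centerline over time, photometric noise, and the artefacts the mask
refinement stages are designed to remove (isolated bright cells inside the
wound, small dark gaps inside the monolayer, optional stent-strut
occlusions and imperfection regions).

The wound is a straight longitudinal band: the centerline is horizontal
and the two fronts are parallel up to a smooth roughness perturbation.
Ground truth is defined by the band alone — injected islands and specks
never change it, because the analysis filters are supposed to remove them.

Default acquisition parameters mirror the study conditions: 1280×1024
frames at 1.66 µm/pixel, 2 frames per hour over 48 h (97 frames).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .io import TimeLapseStack

__all__ = [
    "SceneConfig",
    "WoundTrajectory",
    "GroundTruth",
    "make_trajectory",
    "render_frame",
    "generate_stack",
    "generate_experiment_set",
    "BARE_CONTROL_POINTS",
    "EG_CONTROL_POINTS",
]

U16_MAX = 65535

# Printed group-mean normalized wound areas at 0/20/40/48 h for the two
# stent conditions; used as default ground-truth closure trajectories.
BARE_CONTROL_POINTS = ((0.0, 20.0, 40.0, 48.0), (1.0, 0.74, 0.60, 0.57))
EG_CONTROL_POINTS = ((0.0, 20.0, 40.0, 48.0), (1.0, 0.65, 0.42, 0.38))


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a rendered time-lapse scene.

    Intensities are 16-bit gray levels; lengths are µm; times are hours.
    ``isolated_cell_rate`` and ``gap_rate`` are expected counts per frame
    (Poisson) of bright single-cell islands inside the wound and of small
    dark specks inside the endothelium, respectively.
    """

    image_shape: tuple[int, int] = (1024, 1280)
    pixel_size: float = 1.66
    frame_interval: float = 0.5
    n_frames: int = 97
    cell_diameter: float = 30.0
    cell_intensity_mean: float = 22000.0
    cell_intensity_sd: float = 5000.0
    wound_intensity_mean: float = 3000.0
    wound_intensity_sd: float = 800.0
    noise_sd: float = 1200.0
    front_roughness: float = 15.0
    isolated_cell_rate: float = 8.0
    gap_rate: float = 8.0
    strut_rects: tuple[tuple[int, int, int, int], ...] = ()
    imperfection_rects: tuple[tuple[int, int, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise ValueError("image_shape must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be at least 2")
        if self.cell_intensity_mean <= self.wound_intensity_mean:
            raise ValueError(
                "cell_intensity_mean must exceed wound_intensity_mean "
                "(the wound is the dark class)"
            )
        for rect in tuple(self.strut_rects) + tuple(self.imperfection_rects):
            r0, c0, r1, c1 = rect
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise ValueError(f"rectangle {rect} outside image_shape {self.image_shape}")


@dataclass(frozen=True)
class WoundTrajectory:
    """Piecewise-linear ground-truth wound half-width over time (µm)."""

    time_points: np.ndarray
    half_width_um: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points, dtype=float)
        h = np.asarray(self.half_width_um, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time_points must be strictly increasing with length >= 2")
        if h.shape != t.shape:
            raise ValueError("half_width_um must match time_points in length")
        if np.any(h < 0):
            raise ValueError("half_width_um must be non-negative")
        object.__setattr__(self, "time_points", t)
        object.__setattr__(self, "half_width_um", h)

    @property
    def horizon(self) -> float:
        return float(self.time_points[-1])

    def half_width(self, t: float) -> float:
        """Linearly interpolated half-width at time ``t`` (µm)."""
        t0, t1 = self.time_points[0], self.time_points[-1]
        if t < t0 or t > t1:
            raise ValueError(f"t={t} outside trajectory domain [{t0}, {t1}]")
        return float(np.interp(t, self.time_points, self.half_width_um))


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame ground-truth wound masks and areas for a generated stack."""

    masks: np.ndarray          # (n_frames, rows, cols) bool
    area_um2: np.ndarray       # µm² per frame
    normalized_area: np.ndarray  # area / area at frame 0
    pixel_size: float

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


def make_trajectory(
    control_times,
    control_areas,
    initial_half_width: float = 500.0,
) -> WoundTrajectory:
    """Convert a normalized-area closure curve into front positions.

    For a straight band the wound area is proportional to its half-width,
    so a normalized-area fraction ``a(t)`` maps to a half-width
    ``a(t) * initial_half_width``.  The fractions must start at exactly 1
    (normalization is relative to the first time point).
    """
    t = np.asarray(control_times, dtype=float)
    a = np.asarray(control_areas, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("control_times must be strictly increasing with length >= 2")
    if a.shape != t.shape:
        raise ValueError("control_areas must match control_times in length")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("control_areas must lie in [0, 1]")
    if a[0] != 1.0:
        raise ValueError("first control fraction must be exactly 1 (normalization origin)")
    if initial_half_width <= 0:
        raise ValueError("initial_half_width must be positive")
    return WoundTrajectory(t, a * initial_half_width)


class _SceneTextures:
    """Static per-scene fields, derived deterministically from the config seed.

    The monolayer texture and the front roughness profiles are fixed for
    the whole stack: cells fill space as the fronts advance, but the
    texture pattern and the ragged front shape persist between frames.
    """

    def __init__(self, config: SceneConfig):
        rows, cols = config.image_shape
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0)))
        px = config.pixel_size

        # Cell monolayer: overlapping soft-edged blobs of roughly one cell
        # diameter, with per-blob intensity jitter, riding on a floor that
        # keeps the cell class strictly brighter than the wound class.
        d_px = max(config.cell_diameter / px, 2.0)
        sigma = d_px / 4.0
        floor = max(0.0, config.cell_intensity_mean - 2.5 * config.cell_intensity_sd)
        blob_area = np.pi * (d_px / 2.0) ** 2
        n_blobs = max(int(2.0 * rows * cols / blob_area), 1)
        impulses = np.zeros((rows, cols), dtype=float)
        rr = rng.integers(0, rows, size=n_blobs)
        cc = rng.integers(0, cols, size=n_blobs)
        amp = np.clip(rng.normal(1.0, 0.35, size=n_blobs), 0.2, None)
        np.add.at(impulses, (rr, cc), amp)
        raw = gaussian_filter(impulses, sigma=sigma, mode="reflect")
        mean_raw = raw.mean()
        if mean_raw > 0:
            raw = raw / mean_raw * (config.cell_intensity_mean - floor)
        self.cell_field = floor + raw

        # Wound bed: dim residue texture, clipped so that with zero noise
        # its histogram is disjoint from the cell class.
        wound = rng.normal(
            config.wound_intensity_mean, config.wound_intensity_sd, size=(rows, cols)
        )
        lo = config.wound_intensity_mean - 2.5 * config.wound_intensity_sd
        hi = config.wound_intensity_mean + 2.5 * config.wound_intensity_sd
        self.wound_field = np.clip(wound, max(lo, 0.0), hi)

        # Smooth zero-mean front perturbations, correlated over ~5 cell
        # diameters, one profile per front (px units).
        corr = 2.5 * config.cell_diameter / px
        profiles = []
        for _ in range(2):
            p = gaussian_filter1d(rng.standard_normal(cols), sigma=corr, mode="wrap")
            sd = p.std()
            if sd > 0 and config.front_roughness > 0:
                p = p / sd * (config.front_roughness / px)
            else:
                p = np.zeros(cols)
            profiles.append(p - p.mean())
        self.rough_top, self.rough_bottom = profiles


def _band_mask(config: SceneConfig, textures: _SceneTextures, half_width_um: float) -> np.ndarray:
    rows, cols = config.image_shape
    hw_px = half_width_um / config.pixel_size
    if hw_px < 0.5:  # fully closed: roughness must not leave residual wound
        return np.zeros((rows, cols), dtype=bool)
    center = (rows - 1) / 2.0
    top = np.round(center - hw_px + textures.rough_top)
    bottom = np.round(center + hw_px + textures.rough_bottom)
    r_idx = np.arange(rows)[:, None]
    return (r_idx >= top[None, :]) & (r_idx < bottom[None, :])


def _stamp_disc(image: np.ndarray, r: int, c: int, radius_px: float, value: float) -> None:
    rows, cols = image.shape
    rad = int(np.ceil(radius_px))
    r0, r1 = max(r - rad, 0), min(r + rad + 1, rows)
    c0, c1 = max(c - rad, 0), min(c + rad + 1, cols)
    rr, cc = np.ogrid[r0:r1, c0:c1]
    disc = (rr - r) ** 2 + (cc - c) ** 2 <= radius_px ** 2
    image[r0:r1, c0:c1][disc] = value


def render_frame(
    config: SceneConfig,
    trajectory: WoundTrajectory,
    t: float,
    rng: np.random.Generator | int | None = None,
    _textures: _SceneTextures | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame at time ``t`` and its ground-truth wound mask.

    Returns a 16-bit frame and a boolean mask (True = wound).  Frame
    randomness (island/speck placement, noise) comes from ``rng``; the
    static scene texture is derived from ``config.seed`` so that repeated
    calls with the same inputs are bit-identical.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    textures = _textures if _textures is not None else _SceneTextures(config)
    mask = _band_mask(config, textures, trajectory.half_width(t))

    frame = np.where(mask, textures.wound_field, textures.cell_field)

    px = config.pixel_size
    # Isolated bright cells that migrated into the wound (filter stage 1 target).
    n_islands = rng.poisson(config.isolated_cell_rate)
    wound_idx = np.flatnonzero(mask.ravel())
    if wound_idx.size and n_islands:
        picks = rng.choice(wound_idx, size=n_islands)
        radius = 0.3 * config.cell_diameter / px
        for flat in picks:
            val = max(
                rng.normal(config.cell_intensity_mean, config.cell_intensity_sd / 2),
                config.cell_intensity_mean - 2.5 * config.cell_intensity_sd,
            )
            _stamp_disc(frame, *divmod(int(flat), mask.shape[1]), radius, val)

    # Small dark gaps between cells in the monolayer (filter stage 2/3 target).
    n_specks = rng.poisson(config.gap_rate)
    endo_idx = np.flatnonzero(~mask.ravel())
    if endo_idx.size and n_specks:
        picks = rng.choice(endo_idx, size=n_specks)
        radius = 0.15 * config.cell_diameter / px
        for flat in picks:
            val = rng.normal(config.wound_intensity_mean, config.wound_intensity_sd)
            _stamp_disc(frame, *divmod(int(flat), mask.shape[1]), radius, max(val, 0.0))

    # Opaque stent struts and imperfection regions occlude fluorescence.
    for r0, c0, r1, c1 in config.strut_rects:
        frame[r0:r1, c0:c1] = 0.0
    for r0, c0, r1, c1 in config.imperfection_rects:
        frame[r0:r1, c0:c1] *= 0.25

    if config.noise_sd > 0:
        frame = frame + rng.normal(0.0, config.noise_sd, size=frame.shape)
    frame = np.clip(np.rint(frame), 0, U16_MAX).astype(np.uint16)
    return frame, mask


def generate_stack(
    config: SceneConfig, trajectory: WoundTrajectory
) -> tuple[TimeLapseStack, GroundTruth]:
    """Render a full time-lapse stack plus its per-frame ground truth."""
    textures = _SceneTextures(config)
    ss = np.random.SeedSequence((config.seed, 1))
    frame_seeds = ss.spawn(config.n_frames)
    frames = np.empty((config.n_frames, *config.image_shape), dtype=np.uint16)
    masks = np.empty((config.n_frames, *config.image_shape), dtype=bool)
    for i in range(config.n_frames):
        t = i * config.frame_interval
        frames[i], masks[i] = render_frame(
            config, trajectory, t,
            rng=np.random.default_rng(frame_seeds[i]), _textures=textures,
        )
    areas = masks.sum(axis=(1, 2)).astype(float) * config.pixel_size ** 2
    if areas[0] <= 0:
        raise ValueError("ground-truth wound area at frame 0 is zero; nothing to normalize")
    truth = GroundTruth(
        masks=masks,
        area_um2=areas,
        normalized_area=areas / areas[0],
        pixel_size=config.pixel_size,
    )
    stack = TimeLapseStack(
        frames=frames,
        pixel_size=config.pixel_size,
        frame_interval=config.frame_interval,
    )
    return stack, truth


def generate_experiment_set(
    config: SceneConfig,
    trajectory: WoundTrajectory,
    n_experiments: int = 5,
    base_seed: int | None = None,
) -> list[tuple[TimeLapseStack, GroundTruth]]:
    """Independent replicate stacks sharing geometry/config, distinct seeds.

    Experiment ``i`` uses seed ``base_seed + i`` (``base_seed`` defaults to
    ``config.seed``), so replicate sets are reproducible as a whole.
    """
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    if base_seed is None:
        base_seed = config.seed
    out = []
    for i in range(n_experiments):
        cfg = dataclasses.replace(config, seed=base_seed + i)
        out.append(generate_stack(cfg, trajectory))
    return out
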