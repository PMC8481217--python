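"""End-to-end orchestration: generate → segment → refine → quantify → compare.

The analysis of one stack follows the per-ROI flow of the automated
protocol: every ROI of every frame is independently contrast-stretched,
converted to 8-bit, histogram-thresholded at the valley after the first
peak, binarized, and refined with the three-stage mask filters; the wound
area is then measured from the refined mask.  When a late frame of a
nearly healed ROI loses its dark histogram mode (unimodal histogram), the
threshold of the nearest earlier frame of the same ROI is substituted;
if no earlier threshold exists the ROI-frame is marked missing.

Aggregation (configurable, default ``zone_mean_then_normalize``): raw ROI
areas → zone mean over non-excluded ROIs → normalize the zone series to
its first time point → average normalized zone series across experiments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .io import (RoiSet, TimeLapseStack, load_rois, make_roi_grid, read_stack,
                 save_rois, write_mask_stack, write_results, write_stack)
from .quantify import (GroupCurve, NormalizedSeries, WoundAreaSeries,
                       group_curve, normalize, percent_faster, zone_series)
from .refinement import RefinementParams, refine
from .segmentation import SegmentationError, WoundMask, binarize, segment_roi
from .stats import ComparisonResult, compare_conditions
from .synthetic import SceneConfig, make_trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SegParams",
    "RunConfig",
    "analyze_roi",
    "analyze_stack",
    "analyze_experiment",
    "analyze_experiment_set",
    "run_generate",
    "run_analyze",
    "run_compare",
]

REPORT_TIMES = (20.0, 40.0, 48.0)


@dataclass(frozen=True)
class SegParams:
    """Segmentation parameters: percentile stretch, histogram smoothing window,
    and the minimum peak prominence as a fraction of the modal count."""

    clip_percentiles: tuple[float, float] = (1.0, 99.0)
    window: int = 10
    prominence_frac: float = 0.05


@dataclass
class RunConfig:
    """Configuration of a full run (defaults mirror the study conditions)."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    conditions: dict = field(default_factory=lambda: {
        "Bare": synthetic.BARE_CONTROL_POINTS,
        "eG": synthetic.EG_CONTROL_POINTS,
    })
    n_experiments: int = 5
    initial_half_width: float = 500.0
    seg: SegParams = field(default_factory=SegParams)
    refine: RefinementParams = field(default_factory=RefinementParams)
    aggregation: str = "zone_mean_then_normalize"
    alpha: float = 0.05
    seed: int = 0
    n_upstream_rois: int = 4
    n_stented_rois: int = 8

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "scene" in raw:
            scene = raw["scene"]
            if "image_shape" in scene:
                scene["image_shape"] = tuple(scene["image_shape"])
            kwargs["scene"] = SceneConfig(**scene)
        if "conditions" in raw:
            kwargs["conditions"] = {
                name: (tuple(v["times"]), tuple(v["fractions"]))
                for name, v in raw["conditions"].items()
            }
        if "seg" in raw:
            seg = raw["seg"]
            if "clip_percentiles" in seg:
                seg["clip_percentiles"] = tuple(seg["clip_percentiles"])
            kwargs["seg"] = SegParams(**seg)
        if "refine" in raw:
            kwargs["refine"] = RefinementParams(**raw["refine"])
        for key in ("n_experiments", "initial_half_width", "aggregation",
                    "alpha", "seed", "n_upstream_rois", "n_stented_rois"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def analyze_roi(
    stack: TimeLapseStack,
    roi,
    seg: SegParams | None = None,
    params: RefinementParams | None = None,
) -> tuple[WoundAreaSeries, list[dict]]:
    """Segment, refine and measure one ROI across all frames.

    Returns the per-frame area series and a list of per-frame log records
    (threshold, per-stage areas, fallback/missing flags).
    """
    seg = seg or SegParams()
    params = params or RefinementParams()
    px = stack.pixel_size
    areas = np.zeros(stack.n_frames)
    missing = np.zeros(stack.n_frames, dtype=bool)
    records = []
    # Fallback threshold is carried in RAW 16-bit intensity space: the
    # per-frame percentile stretch of a healed (wound-free) frame maps the
    # cell mode across the whole range, so an 8-bit threshold from an
    # earlier frame would be meaningless after re-stretching.
    last_threshold_raw: float | None = None
    for i in range(stack.n_frames):
        crop = roi.crop(stack.frames[i])
        rec = {"roi_id": roi.id, "zone": roi.zone, "frame": i,
               "time_h": float(stack.times[i]), "fallback": False}
        try:
            mask, th = segment_roi(crop, px, seg.clip_percentiles,
                                   seg.window, seg.prominence_frac)
            lo, hi = np.percentile(crop, seg.clip_percentiles)
            last_threshold_raw = lo + (th.threshold + 1) * 256 / 65536 * (hi - lo)
            rec["threshold"] = th.threshold
        except SegmentationError:
            if last_threshold_raw is None:
                missing[i] = True
                rec.update(threshold=None, missing=True)
                records.append(rec)
                continue
            # unimodal histogram (e.g. fully healed ROI): reuse the
            # nearest earlier wound/cell intensity boundary of this ROI
            mask = WoundMask(mask=crop < last_threshold_raw, pixel_size=px)
            rec.update(threshold=last_threshold_raw, fallback=True)
        refined, ledger = refine(mask, params)
        areas[i] = refined.wound_pixels * px * px
        rec.update(missing=False, **ledger)
        records.append(rec)
    return (
        WoundAreaSeries(roi_id=roi.id, zone=roi.zone, time_points=stack.times,
                        area=areas, missing=missing, excluded=roi.excluded),
        records,
    )


def analyze_stack(
    stack: TimeLapseStack,
    rois: RoiSet,
    seg: SegParams | None = None,
    params: RefinementParams | None = None,
) -> tuple[list[WoundAreaSeries], list[dict]]:
    """Analyze every non-excluded ROI of one stack."""
    series, records = [], []
    for roi in rois.rois:
        if roi.excluded:
            logger.info("ROI %s excluded (%s); skipped", roi.id, roi.reason or "no reason")
            continue
        s, r = analyze_roi(stack, roi, seg, params)
        series.append(s)
        records.extend(r)
    return series, records


def analyze_experiment(
    stack: TimeLapseStack,
    rois: RoiSet,
    seg: SegParams | None = None,
    params: RefinementParams | None = None,
    aggregation: str = "zone_mean_then_normalize",
    experiment: str = "",
) -> tuple[dict[str, NormalizedSeries], list[WoundAreaSeries], list[dict]]:
    """Per-zone normalized series for one experiment.

    ``aggregation`` is either ``zone_mean_then_normalize`` (default: mean
    raw ROI areas per zone, then normalize) or ``normalize_then_zone_mean``
    (normalize each ROI first, then average the normalized series).
    """
    roi_series, records = analyze_stack(stack, rois, seg, params)
    zones = {}
    for zone in rois.zones:
        if not rois.for_zone(zone):
            continue
        if aggregation == "zone_mean_then_normalize":
            zs = zone_series(roi_series, zone)
            ns = normalize(zs)
        elif aggregation == "normalize_then_zone_mean":
            per_roi = [normalize(s) for s in roi_series if s.zone == zone]
            values = np.stack([p.normalized_area for p in per_roi]).mean(axis=0)
            ns = NormalizedSeries(zone=zone, time_points=per_roi[0].time_points,
                                  normalized_area=values)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        zones[zone] = NormalizedSeries(zone=zone, time_points=ns.time_points,
                                       normalized_area=ns.normalized_area,
                                       experiment=experiment)
    return zones, roi_series, records


def analyze_experiment_set(
    stacks: list[TimeLapseStack],
    rois: RoiSet,
    condition: str,
    seg: SegParams | None = None,
    params: RefinementParams | None = None,
    aggregation: str = "zone_mean_then_normalize",
) -> tuple[dict[str, GroupCurve], dict[str, list[NormalizedSeries]]]:
    """Group curves per zone for a set of replicate experiment stacks."""
    per_zone: dict[str, list[NormalizedSeries]] = {}
    for k, stack in enumerate(stacks):
        zones, _, _ = analyze_experiment(stack, rois, seg, params, aggregation,
                                         experiment=f"{condition}-{k + 1}")
        for zone, ns in zones.items():
            per_zone.setdefault(zone, []).append(ns)
    curves = {zone: group_curve(series, condition)
              for zone, series in per_zone.items()}
    return curves, per_zone


def replicate_study_condition(
    control_points,
    base_seed: int,
    condition: str = "condition",
    image_shape: tuple[int, int] = (512, 512),
    initial_half_width: float = 200.0,
    n_experiments: int = 5,
    scene: SceneConfig | None = None,
) -> dict[str, GroupCurve]:
    """Synthetic parameter-recovery run for one stent condition.

    Generates ``n_experiments`` replicate stacks whose ground-truth
    normalized-area trajectory passes through ``control_points`` (times in
    hours, fractions), with seeds ``base_seed + 1 .. base_seed +
    n_experiments``, then runs the full segmentation → refinement →
    quantification pipeline and returns the per-zone group curves.

    The default scene is the standard acquisition configuration at a
    512×512 crop scale; the initial half-width is scaled accordingly so
    the band occupies the same fraction of the frame as at full size.
    """
    scene = scene or SceneConfig(image_shape=image_shape)
    traj = make_trajectory(*control_points, initial_half_width=initial_half_width)
    pairs = synthetic.generate_experiment_set(
        dataclasses.replace(scene, seed=base_seed + 1), traj,
        n_experiments=n_experiments, base_seed=base_seed + 1)
    rois = make_roi_grid(scene.image_shape)
    curves, _ = analyze_experiment_set([s for s, _ in pairs], rois, condition)
    return curves


# ---------------------------------------------------------------------------
# Disk-based runs


def run_generate(config: RunConfig, outdir) -> Path:
    """Generate the synthetic dataset described by ``config`` onto disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rois = make_roi_grid(config.scene.image_shape,
                         n_upstream=config.n_upstream_rois,
                         n_stented=config.n_stented_rois)
    save_rois(rois, outdir / "rois.json")
    manifest = {
        "scene": dataclasses.asdict(config.scene),
        "conditions": {},
        "n_experiments": config.n_experiments,
        "initial_half_width": config.initial_half_width,
        "seed": config.seed,
    }
    for ci, (name, (times, fractions)) in enumerate(config.conditions.items()):
        traj = make_trajectory(times, fractions, config.initial_half_width)
        base_seed = config.seed + 1000 * ci
        cdir = outdir / name
        cdir.mkdir(exist_ok=True)
        pairs = synthetic.generate_experiment_set(
            dataclasses.replace(config.scene, seed=base_seed), traj,
            config.n_experiments, base_seed=base_seed)
        exp_files = []
        for k, (stack, truth) in enumerate(pairs):
            stem = f"exp_{k + 1:02d}"
            write_stack(stack, cdir / f"{stem}.tif")
            write_mask_stack(truth.masks, cdir / f"{stem}_truth_masks.tif")
            pd.DataFrame({
                "frame": np.arange(truth.n_frames),
                "time_h": stack.times,
                "area_um2": truth.area_um2,
                "normalized_area": truth.normalized_area,
            }).to_csv(cdir / f"{stem}_truth.csv", index=False)
            exp_files.append(f"{name}/{stem}.tif")
        manifest["conditions"][name] = {
            "times": list(times), "fractions": list(fractions),
            "base_seed": base_seed, "stacks": exp_files,
        }
    (outdir / "dataset_manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def run_analyze(dataset_dir, outdir, config: RunConfig | None = None) -> dict:
    """Analyze a generated dataset directory; write CSV results + manifest."""
    config = config or RunConfig()
    dataset_dir = Path(dataset_dir)
    mpath = dataset_dir / "dataset_manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"dataset manifest not found: {mpath}")
    manifest = json.loads(mpath.read_text())
    rois = load_rois(dataset_dir / "rois.json",
                     tuple(manifest["scene"]["image_shape"]))
    roi_rows, zone_rows, norm_rows, curve_rows, record_rows = [], [], [], [], []
    curves_by_condition_zone: dict[tuple[str, str], GroupCurve] = {}
    series_by_condition_zone: dict[tuple[str, str], list[NormalizedSeries]] = {}
    for cond, info in manifest["conditions"].items():
        per_zone: dict[str, list[NormalizedSeries]] = {}
        for k, rel in enumerate(info["stacks"]):
            stack = read_stack(dataset_dir / rel)
            zones, roi_series, records = analyze_experiment(
                stack, rois, config.seg, config.refine, config.aggregation,
                experiment=f"{cond}-{k + 1}")
            record_rows.extend(
                {**r, "condition": cond, "experiment": k + 1} for r in records)
            for s in roi_series:
                for t, a, miss in zip(s.time_points, s.area, s.missing):
                    roi_rows.append({"condition": cond, "experiment": k + 1,
                                     "roi_id": s.roi_id, "zone": s.zone,
                                     "time_h": t, "area_um2": a, "missing": miss})
            for zone, ns in zones.items():
                per_zone.setdefault(zone, []).append(ns)
                for t, v in zip(ns.time_points, ns.normalized_area):
                    norm_rows.append({"condition": cond, "experiment": k + 1,
                                      "zone": zone, "time_h": t,
                                      "normalized_area": v})
        for zone, series in per_zone.items():
            gc = group_curve(series, cond)
            curves_by_condition_zone[(cond, zone)] = gc
            series_by_condition_zone[(cond, zone)] = series
            for t, m, s, n in zip(gc.time_points, gc.mean, gc.sem, gc.n):
                curve_rows.append({"condition": cond, "zone": zone, "time_h": t,
                                   "mean": m, "sem": s, "n": n})
    tables = {
        "roi_areas": pd.DataFrame(roi_rows),
        "normalized_series": pd.DataFrame(norm_rows),
        "group_curves": pd.DataFrame(curve_rows),
        "segmentation_log": pd.DataFrame(record_rows),
    }
    write_results(tables, outdir, manifest={
        "dataset": str(dataset_dir), "seed": manifest.get("seed"),
        "aggregation": config.aggregation,
        "seg": dataclasses.asdict(config.seg),
        "refine": dataclasses.asdict(config.refine),
    })
    return {"curves": curves_by_condition_zone,
            "series": series_by_condition_zone, "outdir": Path(outdir)}


def run_compare(
    analysis: dict,
    condition_a: str,
    condition_b: str,
    zone: str = "stented",
    alpha: float = 0.05,
    report_times=REPORT_TIMES,
    outdir=None,
) -> dict:
    """Compare two analyzed conditions: per-timepoint t tests + percent-faster.

    ``analysis`` is the return value of :func:`run_analyze` (or a dict of
    the same shape built in memory).  Report times off the acquisition
    grid are linearly interpolated and flagged.
    """
    series = analysis["series"]
    curves = analysis["curves"]
    for cond in (condition_a, condition_b):
        if (cond, zone) not in series:
            raise KeyError(f"condition {cond!r} zone {zone!r} not in analysis")
    comp = compare_conditions(series[(condition_a, zone)],
                              series[(condition_b, zone)], alpha=alpha)
    ca, cb = curves[(condition_a, zone)], curves[(condition_b, zone)]
    rows = []
    for t in report_times:
        on_grid = bool(np.any(np.isclose(ca.time_points, t)))
        rows.append({
            "time_h": t,
            "mean_a": ca.value_at(t), "mean_b": cb.value_at(t),
            "percent_faster_b_vs_a": percent_faster(ca, cb, t),
            "interpolated": not on_grid,
        })
    report = pd.DataFrame(rows)
    ttable = pd.DataFrame({
        "time_h": comp.time_points, "t": comp.t_statistic,
        "df": comp.degrees_of_freedom, "p": comp.p_value,
        "significant": comp.significant,
    })
    if outdir is not None:
        write_results({"ttest": ttable, "percent_faster": report}, outdir,
                      manifest={"condition_a": condition_a,
                                "condition_b": condition_b, "zone": zone,
                                "alpha": alpha,
                                "first_significant_time": comp.first_significant_time})
    return {"comparison": comp, "percent_faster": report, "ttest_table": ttable}
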