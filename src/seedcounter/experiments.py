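"""Benchmark protocols: reusable drivers for the package's own accuracy
experiments on synthetic scenes.

These mirror the physical benchmarking protocols the pipeline is designed
for: a decreasing-count series (N, N-1, ... with reshuffling between
shots), a five-variety dimension panel measured grain by grain against
ground truth, a touching-pair separation suite, and a metric-calibration
sweep over all paper presets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import PAPER_PRESETS, SheetDetectConfig, detect_sheet
from .metrics import (
    CountSeries,
    DimensionSeries,
    EvaluationReport,
    evaluate_counting,
    evaluate_dimensions,
)
from .pipeline import match_measurements_to_truth, process_image
from .segmentation import binarize_sheet, filter_grains, split_touching
from .synthetic import (
    SceneSpec,
    generate_count_experiment,
    generate_scene,
    generate_variety_panel,
)

__all__ = [
    "count_experiment_report",
    "dimension_panel_report",
    "touching_pair_success_rate",
    "max_scale_error_across_presets",
    "COUNT_SCENE_SPEC",
    "PANEL_SCENE_SPEC",
]

# Study conditions: 50 grains poured on A4, moderate shadow and sensor
# noise.  Counting series are rendered at 4 px/mm (sufficient for counting;
# keeps a 40-scene series tractable), dimension panels at 8 px/mm so that a
# 2.3 mm grain width spans ~18 px.
COUNT_SCENE_SPEC = SceneSpec(
    n_grains=50, shadow_strength=0.2, noise_sigma=5.0, px_per_mm_render=4.0
)
PANEL_SCENE_SPEC = SceneSpec(
    shadow_strength=0.2, noise_sigma=5.0, px_per_mm_render=8.0
)


def _sheet_config(spec: SceneSpec) -> SheetDetectConfig:
    # rectify at the render resolution: no information above it anyway
    return SheetDetectConfig(px_per_mm=spec.px_per_mm_render)


def count_experiment_report(
    seed: int, tilt_deg: float = 0.0, start_n: int = 50, steps: int = 40,
    base: SceneSpec | None = None,
) -> EvaluationReport:
    """Run the decreasing-count protocol and score the counts."""
    base = replace(base or COUNT_SCENE_SPEC, tilt_deg=tilt_deg, seed=seed)
    cfg = _sheet_config(base)
    true_counts, est_counts = [], []
    for img, truth in generate_count_experiment(base, start_n, steps):
        result = process_image(img, base.paper, cfg)
        true_counts.append(truth.count)
        est_counts.append(result.count)
    return evaluate_counting(CountSeries(tuple(true_counts), tuple(est_counts)))


def dimension_panel_report(
    seed: int, tilt_deg: float = 0.0, base: SceneSpec | None = None,
):
    """Measure the five-variety panel grain by grain.

    Returns ``(report, counts_exact)`` where ``report`` scores length and
    width against ground truth and ``counts_exact`` says whether every
    panel scene was counted exactly.
    """
    base = replace(base or PANEL_SCENE_SPEC, tilt_deg=tilt_deg)
    cfg = _sheet_config(base)
    tl, el, tw, ew = [], [], [], []
    counts_exact = True
    for name, img, truth in generate_variety_panel(seed=seed, base=base):
        result = process_image(img, base.paper, cfg)
        if result.count != truth.count:
            counts_exact = False
            continue
        for g, m in match_measurements_to_truth(result.measurements, truth):
            tl.append(g.length_mm)
            el.append(m.length_mm)
            tw.append(g.width_mm)
            ew.append(m.width_mm)
    report = evaluate_dimensions(
        DimensionSeries(tuple(tl), tuple(el), tuple(tw), tuple(ew))
    )
    return report, counts_exact


def touching_pair_success_rate(
    seed: int, n_scenes: int = 100, iou_threshold: float = 0.8
):
    """Fraction of touching-pair scenes split into two labels with
    per-instance IoU above threshold.

    Each scene holds exactly one touching pair (overlap <= 10%) on a small
    sheet; success requires two final labels, each overlapping its
    ground-truth instance with IoU >= ``iou_threshold``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_scenes) % (2 ** 31)
    ok = 0
    for s in seeds:
        spec = SceneSpec(
            paper=PAPER_PRESETS["a5"], n_grains=2, touching_pairs=1,
            seed=int(s), px_per_mm_render=6.0,
        )
        img, truth = generate_scene(spec)
        sheet = detect_sheet(img, spec.paper, _sheet_config(spec))
        mask = binarize_sheet(sheet)
        lm = filter_grains(
            split_touching(mask, px_per_mm=1.0 / sheet.scale_x), sheet.scale_x
        )
        if lm.n_grains != 2:
            continue
        ox, oy = truth.sheet_origin_px
        x0, y0 = int(round(ox + 0.5)), int(round(oy + 0.5))
        H, W = sheet.raster.shape[:2]
        crop = truth.labels[y0:y0 + H, x0:x0 + W]
        ious = []
        for k in (1, 2):
            tmask = crop == k
            best = max(
                (tmask & (lm.labels == j)).sum()
                / max((tmask | (lm.labels == j)).sum(), 1)
                for j in (1, 2)
            )
            ious.append(best)
        if min(ious) >= iou_threshold:
            ok += 1
    return ok, n_scenes


def max_scale_error_across_presets(seed: int, px_per_mm: float = 3.0) -> float:
    """Worst relative metric-calibration error over all paper presets (%)."""
    worst = 0.0
    for paper in PAPER_PRESETS.values():
        spec = SceneSpec(
            paper=paper, n_grains=0, seed=seed, px_per_mm_render=px_per_mm
        )
        img, _ = generate_scene(spec)
        sheet = detect_sheet(img, paper, SheetDetectConfig(px_per_mm=px_per_mm))
        h_px, w_px = sheet.raster.shape[:2]
        err_w = abs(w_px * sheet.scale_x - paper.width_mm) / paper.width_mm
        err_h = abs(h_px * sheet.scale_y - paper.height_mm) / paper.height_mm
        worst = max(worst, err_w, err_h)
    return 100.0 * worst
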