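"""End-to-end image -> measurements pipeline and truth-matching helpers."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .errors import EvaluationError
from .geometry import PaperSpec, RectifiedSheet, SheetDetectConfig, detect_sheet
from .morphometry import GrainMeasurement, measure_all
from .segmentation import (
    CalibrationProfile,
    GrainLabelMap,
    SegmentationConfig,
    binarize_sheet,
    filter_grains,
    refine_local_hsv,
    split_touching,
)

__all__ = ["PipelineResult", "process_image", "match_measurements_to_truth"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one image yields: the rectified sheet, the grain label
    map, the per-grain measurements and the count."""

    sheet: RectifiedSheet
    labelmap: GrainLabelMap
    measurements: list
    count: int
    timings: dict = field(default_factory=dict)


def process_image(
    image: np.ndarray,
    paper: PaperSpec,
    sheet_config: SheetDetectConfig | None = None,
    seg_config: SegmentationConfig | None = None,
    profile: CalibrationProfile | None = None,
) -> PipelineResult:
    """Detect the sheet, segment grains, and measure them.

    HSV refinement runs only when both ``seg_config.use_hsv`` and a
    calibration ``profile`` are available; the watershed split is applied
    unless disabled in ``seg_config``.
    """
    seg = seg_config or SegmentationConfig()
    timings = {}
    t0 = time.perf_counter()
    sheet = detect_sheet(image, paper, sheet_config)
    timings["detect_sheet"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    mask = binarize_sheet(sheet, seg)
    if seg.use_hsv and profile is not None:
        mask = refine_local_hsv(sheet, mask, profile, seg.hsv_margin_frac)
    if seg.use_watershed:
        labelmap = split_touching(
            mask,
            px_per_mm=1.0 / sheet.scale_x,
            split_depth_mm=seg.split_depth_mm,
        )
    else:
        labelmap = GrainLabelMap(ndimage.label(mask)[0])
    labelmap = filter_grains(
        labelmap, sheet.scale_x, seg.min_area_mm2, seg.max_area_mm2,
        seg.border_band_mm,
    )
    timings["segment"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    measurements, count = measure_all(labelmap, sheet)
    timings["measure"] = time.perf_counter() - t0
    log.info(
        "pipeline: %d grains (detect %.2fs, segment %.2fs, measure %.2fs)",
        count, timings["detect_sheet"], timings["segment"], timings["measure"],
    )
    return PipelineResult(sheet, labelmap, measurements, count, timings)


def match_measurements_to_truth(
    measurements: list, truth, max_dist_mm: float = 5.0
) -> list:
    """Pair measured grains with ground-truth grains by centroid distance.

    Ground-truth centers live in sheet-mm coordinates; measured centroids
    come from the rectified raster, whose origin may be rotated 180 degrees
    relative to the generator's sheet frame, so the assignment is computed
    for both orientations and the lower-cost one kept.  Returns a list of
    ``(GrainTruth, GrainMeasurement)`` pairs; raises
    :class:`EvaluationError` if any pair is farther than ``max_dist_mm``.
    """
    meas = [m for m in measurements if m.centroid_xy_mm is not None]
    if len(meas) != len(truth.grains):
        raise EvaluationError(
            f"cannot match {len(meas)} measurements to {len(truth.grains)} "
            f"true grains"
        )
    t_xy = np.array([g.center_mm for g in truth.grains])
    m_xy = np.array([m.centroid_xy_mm for m in meas])
    rows, cols, dists = assign_by_centroid(t_xy, m_xy)
    pairs = []
    for r, c, d in zip(rows, cols, dists):
        if d > max_dist_mm:
            raise EvaluationError(
                f"unmatched grain: nearest centroid {d:.2f} mm away"
            )
        pairs.append((truth.grains[r], meas[c]))
    return pairs


def assign_by_centroid(t_xy: np.ndarray, m_xy: np.ndarray):
    """Optimal one-to-one pairing of two equal-size centroid sets (mm).

    The measured frame may be rotated 180 degrees relative to the truth
    frame (the rectifier cannot tell the sheet's top from its bottom), so
    the assignment is computed for both orientations and the lower-cost
    one returned as ``(truth_idx, meas_idx, pair_distances)``.
    """
    if len(t_xy) != len(m_xy) or len(t_xy) == 0:
        raise EvaluationError(
            f"centroid sets differ in size: {len(t_xy)} vs {len(m_xy)}"
        )
    paper_wh = t_xy.max(axis=0) + t_xy.min(axis=0)  # flip anchor
    best = None
    for flip in (False, True):
        cand = paper_wh - m_xy if flip else m_xy
        d = np.linalg.norm(t_xy[:, None, :] - cand[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(d)
        cost = d[rows, cols].sum()
        if best is None or cost < best[0]:
            best = (cost, rows, cols, d[rows, cols])
    _, rows, cols, dists = best
    return rows, cols, dists
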