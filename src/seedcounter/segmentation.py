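"""Grain segmentation on the rectified sheet.

Grains are dark, roughly convex objects on light paper.  The stages are:

1. coarse foreground extraction by adaptive thresholding (polarity inverted
   relative to sheet detection: darker than the local paper level);
2. optional local HSV refinement: each coarse component's neighbourhood is
   scored by histogram back-projection against a calibration color profile,
   which strips attached shadow lobes;
3. marker-controlled watershed on the distance transform to split touching
   grains;
4. plausibility filtering by physical area bounds and a border exclusion
   band.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage import segmentation as skseg
from skimage.filters import threshold_local, threshold_otsu

from .errors import CalibrationError, ParameterError
from .geometry import PaperSpec, RectifiedSheet, SheetDetectConfig, detect_sheet, to_grayscale

__all__ = [
    "CalibrationProfile",
    "GrainLabelMap",
    "SegmentationConfig",
    "binarize_sheet",
    "calibrate_from_single_seed",
    "refine_local_hsv",
    "split_touching",
    "filter_grains",
]

log = logging.getLogger(__name__)

HSV_BINS = (16, 8, 8)


@dataclass
class SegmentationConfig:
    """Knobs of the grain segmenter (physical units in mm)."""

    window_mm: float = 15.0          # adaptive window; several grain diameters
    min_contrast: float = 15.0       # floor on the Otsu residual threshold
    fixed_offset: float | None = None  # bypass Otsu with a fixed contrast cut
    split_depth_mm: float = 0.4      # h-maxima suppression depth for markers
    min_area_mm2: float = 2.0
    max_area_mm2: float = 60.0
    border_band_mm: float = 2.0
    hsv_margin_frac: float = 0.25    # local-window dilation for refinement
    use_hsv: bool = True
    use_watershed: bool = True


@dataclass
class CalibrationProfile:
    """Color statistics of a reference seed, learned from a single-seed image.

    ``hsv_histogram`` is a normalized (16, 8, 8) hue/saturation/value
    histogram over [0, 1]^3; the per-channel acceptance intervals hold the
    central 99% of the seed-pixel mass.
    """

    hsv_histogram: np.ndarray
    value_range: tuple
    saturation_range: tuple
    reference_area_mm2: float

    def __post_init__(self):
        h = np.asarray(self.hsv_histogram, float)
        if h.shape != HSV_BINS:
            raise ParameterError(f"histogram must have shape {HSV_BINS}")
        total = h.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            if total <= 0:
                raise ParameterError("histogram must have positive mass")
            h = h / total
        self.hsv_histogram = h
        for name, (lo, hi) in (
            ("value_range", self.value_range),
            ("saturation_range", self.saturation_range),
        ):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ParameterError(f"{name} must lie within [0, 1]")

    def to_dict(self) -> dict:
        return {
            "hsv_bins": list(HSV_BINS),
            "hsv_histogram": self.hsv_histogram.ravel().tolist(),
            "value_range": list(self.value_range),
            "saturation_range": list(self.saturation_range),
            "reference_area_mm2": self.reference_area_mm2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationProfile":
        hist = np.asarray(d["hsv_histogram"], float).reshape(tuple(d["hsv_bins"]))
        return cls(
            hsv_histogram=hist,
            value_range=tuple(d["value_range"]),
            saturation_range=tuple(d["saturation_range"]),
            reference_area_mm2=float(d["reference_area_mm2"]),
        )


class GrainLabelMap:
    """Integer label raster (0 = background, k >= 1 = grain k) with
    on-demand contour tracing."""

    def __init__(self, labels: np.ndarray):
        self.labels = np.asarray(labels)
        self._contours = None

    @property
    def n_grains(self) -> int:
        return int(self.labels.max())

    @property
    def contours(self) -> dict:
        """Closed (x, y) pixel-polygons, one per label."""
        if self._contours is None:
            self._contours = {}
            objects = ndimage.find_objects(self.labels)
            for k, sl in enumerate(objects, start=1):
                if sl is None:
                    continue
                pad = np.pad((self.labels[sl] == k).astype(float), 1)
                cs = skmeasure.find_contours(pad, 0.5)
                if not cs:
                    continue
                c = max(cs, key=len)
                # (row, col) in padded crop -> (x, y) in full image
                xy = np.column_stack([
                    c[:, 1] - 1 + sl[1].start,
                    c[:, 0] - 1 + sl[0].start,
                ])
                self._contours[k] = xy
        return self._contours

    def masks(self):
        for k in range(1, self.n_grains + 1):
            yield k, self.labels == k


def _local_paper_level(gray: np.ndarray, window_px: int) -> np.ndarray:
    return threshold_local(gray, block_size=window_px, method="mean", offset=0.0)


def binarize_sheet(
    sheet: RectifiedSheet, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Coarse grain foreground: pixels darker than the local paper level.

    The contrast cut is chosen by Otsu's method on the (local mean - gray)
    residual, floored at ``min_contrast`` so a blank sheet yields an empty
    mask; this places the cut near the midpoint of the intensity ramp at
    grain boundaries, independent of shadows.
    """
    cfg = config or SegmentationConfig()
    gray = to_grayscale(sheet.raster)
    window = max(3, int(round(cfg.window_mm / sheet.scale_x)) | 1)
    residual = _local_paper_level(gray, window) - gray
    if cfg.fixed_offset is not None:
        cut = cfg.fixed_offset
    else:
        pos = residual[residual > 0]
        if pos.size < 2:
            return np.zeros(gray.shape, bool)
        cut = max(float(threshold_otsu(residual)), cfg.min_contrast)
    return residual > cut


def split_touching(
    mask: np.ndarray,
    *,
    px_per_mm: float = 10.0,
    split_depth_mm: float = 0.4,
) -> GrainLabelMap:
    """Split touching grains with a marker-controlled watershed.

    Markers are the regional maxima of the Euclidean distance transform
    after h-maxima suppression with depth ``split_depth_mm`` (converted to
    pixels): the contact neck between two touching convex grains is a dip
    deeper than h, while the ridge along a single elongated grain is not,
    so each grain contributes exactly one marker.  The watershed floods the
    inverted distance transform restricted to the mask, so the union of the
    output labels equals the input foreground exactly.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return GrainLabelMap(np.zeros(mask.shape, np.int32))
    dist = ndimage.distance_transform_edt(mask)
    h = max(0.5, split_depth_mm * px_per_mm)
    # h-maxima markers: regional maxima of the h-reconstruction, so that a
    # ridge whose internal dips are shallower than h yields ONE connected
    # marker (the flat zone spans the dips), while a contact neck deeper
    # than h blocks the reconstruction and separates the markers
    rec = skmorph.reconstruction(dist - h, dist, method="dilation")
    peaks = skmorph.local_maxima(rec, connectivity=2) & mask
    markers, _ = ndimage.label(peaks, structure=np.ones((3, 3), int))
    # every foreground component must own at least one marker, else its
    # pixels would be lost by the masked watershed
    comps, n_comps = ndimage.label(mask)
    next_id = int(markers.max())
    has_marker = set(np.unique(comps[markers > 0])) - {0}
    for c in range(1, n_comps + 1):
        if c not in has_marker:
            inside = comps == c
            flat = np.where(inside.ravel(), dist.ravel(), -1.0)
            next_id += 1
            markers.ravel()[int(np.argmax(flat))] = next_id
    ws = skseg.watershed(-dist, markers, mask=mask, connectivity=1)
    return GrainLabelMap(_relabel_consecutive(ws))


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels)
    vals = vals[vals != 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        out[labels == old] = new
    return out


def filter_grains(
    labelmap: GrainLabelMap,
    scale_mm_per_px: float,
    min_area_mm2: float = 2.0,
    max_area_mm2: float = 60.0,
    border_band_mm: float = 2.0,
) -> GrainLabelMap:
    """Reject implausible labels: debris and sheet-edge artifacts.

    Removes labels whose physical area falls outside
    ``[min_area_mm2, max_area_mm2]`` and labels intersecting the border
    exclusion band, then relabels consecutively.
    """
    if min_area_mm2 >= max_area_mm2:
        raise ParameterError("min_area_mm2 must be < max_area_mm2")
    labels = labelmap.labels
    band_px = int(round(border_band_mm / scale_mm_per_px))
    h, w = labels.shape
    border = np.zeros((h, w), bool)
    if band_px > 0:
        border[:band_px, :] = True
        border[-band_px:, :] = True
        border[:, :band_px] = True
        border[:, -band_px:] = True
    px_area = scale_mm_per_px ** 2
    keep = np.zeros(labels.shape, np.int32)
    for k in range(1, int(labels.max()) + 1):
        region = labels == k
        area = region.sum() * px_area
        if area < min_area_mm2 or area > max_area_mm2:
            continue
        if np.any(region & border):
            continue
        keep[region] = k
    return GrainLabelMap(_relabel_consecutive(keep))


def _hsv_of(raster: np.ndarray) -> np.ndarray:
    img = np.asarray(raster)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    return skcolor.rgb2hsv(img)


def _hsv_histogram(hsv_pixels: np.ndarray) -> np.ndarray:
    hist, _ = np.histogramdd(
        hsv_pixels, bins=HSV_BINS, range=((0, 1), (0, 1), (0, 1))
    )
    return hist / hist.sum()


def _central_interval(values: np.ndarray, mass: float = 0.99) -> tuple:
    lo, hi = np.quantile(values, [(1 - mass) / 2, 1 - (1 - mass) / 2])
    return float(lo), float(hi)


def build_profile(
    hsv_pixels: np.ndarray, reference_area_mm2: float
) -> CalibrationProfile:
    """Color profile from an (N, 3) array of HSV seed pixels."""
    return CalibrationProfile(
        hsv_histogram=_hsv_histogram(hsv_pixels),
        value_range=_central_interval(hsv_pixels[:, 2]),
        saturation_range=_central_interval(hsv_pixels[:, 1]),
        reference_area_mm2=reference_area_mm2,
    )


def calibrate_from_single_seed(
    image: np.ndarray,
    paper: PaperSpec,
    sheet_config: SheetDetectConfig | None = None,
    seg_config: SegmentationConfig | None = None,
) -> CalibrationProfile:
    """Learn a color profile from a photo of one seed on the sheet.

    The sheet is detected and segmented without HSV refinement; exactly one
    plausible component must remain, else a :class:`CalibrationError`
    reporting the count is raised.
    """
    cfg = seg_config or SegmentationConfig()
    sheet = detect_sheet(image, paper, sheet_config)
    mask = binarize_sheet(sheet, cfg)
    labelmap = filter_grains(
        GrainLabelMap(ndimage.label(mask)[0]),
        sheet.scale_x,
        cfg.min_area_mm2,
        cfg.max_area_mm2,
        cfg.border_band_mm,
    )
    n = labelmap.n_grains
    if n != 1:
        raise CalibrationError(
            f"calibration needs exactly one seed, found {n}", n_found=n
        )
    hsv = _hsv_of(sheet.raster)
    seed_mask = labelmap.labels == 1
    pixels = hsv[seed_mask]
    area = float(seed_mask.sum()) * sheet.scale_x * sheet.scale_y
    return build_profile(pixels, area)


def refine_local_hsv(
    sheet: RectifiedSheet,
    coarse_mask: np.ndarray,
    profile: CalibrationProfile | None,
    margin_frac: float = 0.25,
) -> np.ndarray:
    """Refine each coarse component against the calibration color profile.

    For every component, a window (its bounding box dilated by
    ``margin_frac``) is converted to HSV and scored by histogram
    back-projection; pixels outside the profile's saturation/value
    acceptance intervals score zero.  The refined component is the Otsu
    thresholding of the score map inside the window.  Back-projection is
    insensitive to brightness gradients within the acceptance intervals,
    which strips shadow lobes attached to grains.  No pixel outside the
    windows is ever modified; a component with no pixel matching the
    profile is dropped with a warning.
    """
    coarse = np.asarray(coarse_mask, bool)
    if profile is None:
        log.warning("no calibration profile: HSV refinement skipped")
        return coarse.copy()
    hsv = _hsv_of(sheet.raster)
    bins = np.array(HSV_BINS)
    idx = np.minimum((hsv * bins).astype(int), bins - 1)
    scores = profile.hsv_histogram[idx[..., 0], idx[..., 1], idx[..., 2]]
    s_lo, s_hi = profile.saturation_range
    v_lo, v_hi = profile.value_range
    gate = (
        (hsv[..., 1] >= s_lo) & (hsv[..., 1] <= s_hi)
        & (hsv[..., 2] >= v_lo) & (hsv[..., 2] <= v_hi)
    )
    scores = np.where(gate, scores, 0.0)

    comps, n = ndimage.label(coarse)
    refined = np.zeros_like(coarse)
    for k, sl in enumerate(ndimage.find_objects(comps), start=1):
        if sl is None:
            continue
        h0, h1 = sl[0].start, sl[0].stop
        w0, w1 = sl[1].start, sl[1].stop
        mh = int(round((h1 - h0) * margin_frac)) + 1
        mw = int(round((w1 - w0) * margin_frac)) + 1
        H, W = coarse.shape
        win = (slice(max(0, h0 - mh), min(H, h1 + mh)),
               slice(max(0, w0 - mw), min(W, w1 + mw)))
        local = scores[win]
        positive = local[local > 0]
        if positive.size == 0:
            log.warning("component %d matches no profile color; dropped", k)
            continue
        if np.unique(local).size < 2:
            cut = 0.0
        else:
            cut = threshold_otsu(local)
        refined[win] |= local > max(cut, 0.0)
    return refined
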