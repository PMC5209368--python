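"""Paper-sheet detection and metric rectification.

The sheet of paper is the metric anchor of the whole pipeline: its physical
size is known, so once its four corners are found in the photograph, a
projective transform maps its interior onto an axis-aligned raster with a
known millimetre-per-pixel scale.

Detection follows the classic document-detection chain: grayscale
conversion, adaptive binarization (the sheet is a light tetragon on a dark
background), Canny edge detection restricted to the sheet outline,
probabilistic Hough segments whose lengths fall within a fraction band of
the image side, single-linkage clustering of the segments by mutual angle
and perpendicular distance into the four sides, total-least-squares line
fits per side, and corner recovery by intersecting adjacent boundary lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import transform as sktransform

from .errors import (
    FitError,
    GeometryError,
    InvalidInputError,
    ParameterError,
    SheetNotFoundError,
)

__all__ = [
    "PaperSpec",
    "PAPER_PRESETS",
    "LineSegment",
    "BoundaryLine",
    "SheetQuad",
    "RectifiedSheet",
    "SheetDetectConfig",
    "to_grayscale",
    "binarize_adaptive",
    "detect_boundary_segments",
    "cluster_segments",
    "fit_boundary_line",
    "intersect_boundaries",
    "rectify",
    "detect_sheet",
]

# Luminance weights of the grayscale conversion (ITU-R BT.709, as used by
# scikit-image).  Exposed so tests and docs can refer to one definition.
LUMA_WEIGHTS = (0.2125, 0.7154, 0.0721)


@dataclass(frozen=True)
class PaperSpec:
    """A named physical sheet size in millimetres.

    ``width_mm`` is the short side, ``height_mm`` the long side.
    """

    name: str
    width_mm: float
    height_mm: float

    def __post_init__(self):
        if not (0 < self.width_mm <= self.height_mm):
            raise ParameterError(
                f"paper {self.name!r}: need 0 < width_mm <= height_mm, "
                f"got {self.width_mm} x {self.height_mm}"
            )

    @property
    def aspect(self) -> float:
        """Long side over short side."""
        return self.height_mm / self.width_mm

    @property
    def area_mm2(self) -> float:
        return self.width_mm * self.height_mm

    @classmethod
    def from_string(cls, text: str) -> "PaperSpec":
        """Parse a preset name (``"A4"``) or ``"<W>x<H>mm"`` user size."""
        key = text.strip().lower()
        if key in PAPER_PRESETS:
            return PAPER_PRESETS[key]
        cleaned = key.removesuffix("mm")
        if "x" in cleaned:
            try:
                w, h = (float(p) for p in cleaned.split("x", 1))
            except ValueError:
                raise ParameterError(f"cannot parse paper size {text!r}")
            if w > h:
                w, h = h, w
            return cls(name=text.strip(), width_mm=w, height_mm=h)
        raise ParameterError(
            f"unknown paper {text!r}; use a preset "
            f"({', '.join(sorted(PAPER_PRESETS))}) or WxHmm"
        )


# ISO 216 A/B series (B series = ISO, not JIS) plus North-American sizes.
PAPER_PRESETS = {
    "a3": PaperSpec("A3", 297.0, 420.0),
    "a4": PaperSpec("A4", 210.0, 297.0),
    "a5": PaperSpec("A5", 148.0, 210.0),
    "b4": PaperSpec("B4", 250.0, 353.0),
    "b5": PaperSpec("B5", 176.0, 250.0),
    "b6": PaperSpec("B6", 125.0, 176.0),
    "letter": PaperSpec("Letter", 215.9, 279.4),
    "legal": PaperSpec("Legal", 215.9, 355.6),
}


def _canonical_angle_offset(p0, p1):
    """Angle in [0, pi) and signed perpendicular offset of the line p0-p1.

    The offset is the dot product of a point on the line with the unit
    normal ``(-sin a, cos a)``; it is deterministic given the endpoints
    because the angle is folded into [0, pi).
    """
    d = np.asarray(p1, float) - np.asarray(p0, float)
    ang = math.atan2(d[1], d[0]) % math.pi
    if ang >= math.pi - 1e-12:
        ang = 0.0
    n = np.array([-math.sin(ang), math.cos(ang)])
    off = float(np.asarray(p0, float) @ n)
    return ang, off


@dataclass(frozen=True)
class LineSegment:
    """A Hough line segment with derived angle/offset annotation."""

    p0: tuple
    p1: tuple
    angle: float = field(init=False)
    offset: float = field(init=False)

    def __post_init__(self):
        ang, off = _canonical_angle_offset(self.p0, self.p1)
        object.__setattr__(self, "angle", ang)
        object.__setattr__(self, "offset", off)

    @property
    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def sample_pixels(self) -> np.ndarray:
        """(N, 2) points at roughly unit spacing along the segment."""
        n = max(2, int(math.ceil(self.length)) + 1)
        t = np.linspace(0.0, 1.0, n)[:, None]
        return np.asarray(self.p0, float) + t * (
            np.asarray(self.p1, float) - np.asarray(self.p0, float)
        )


@dataclass(frozen=True)
class BoundaryLine:
    """Infinite line in normal form: ``p . (-sin a, cos a) = offset``."""

    angle: float
    offset: float

    @property
    def normal(self) -> np.ndarray:
        return np.array([-math.sin(self.angle), math.cos(self.angle)])


@dataclass(frozen=True)
class SheetQuad:
    """Four sheet corners in image coordinates, ordered TL, TR, BR, BL.

    Image convention: x to the right, y downward, 0-based pixel centers.
    """

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, float)
        if v.shape != (4, 2):
            raise GeometryError(f"quad needs 4 vertices, got shape {v.shape}")
        object.__setattr__(self, "vertices", v)
        if self.area <= 0:
            raise GeometryError("degenerate quad: area <= 0")
        if not self.is_convex:
            raise GeometryError("sheet quad is not convex")

    @property
    def area(self) -> float:
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)

    @property
    def is_convex(self) -> bool:
        v = self.vertices
        crosses = []
        for i in range(4):
            a = v[(i + 1) % 4] - v[i]
            b = v[(i + 2) % 4] - v[(i + 1) % 4]
            crosses.append(a[0] * b[1] - a[1] * b[0])
        crosses = np.array(crosses)
        return bool(np.all(crosses > 0) or np.all(crosses < 0))

    def side_lengths(self) -> np.ndarray:
        """Lengths of (top, right, bottom, left) edges."""
        v = self.vertices
        return np.array([
            np.linalg.norm(v[1] - v[0]),
            np.linalg.norm(v[2] - v[1]),
            np.linalg.norm(v[3] - v[2]),
            np.linalg.norm(v[0] - v[3]),
        ])

    @staticmethod
    def order_vertices(points) -> "SheetQuad":
        """Order four arbitrary corner points as TL, TR, BR, BL."""
        pts = np.asarray(points, float)
        if pts.shape != (4, 2):
            raise GeometryError("need exactly four points")
        s = pts.sum(axis=1)
        d = pts[:, 1] - pts[:, 0]  # y - x
        tl = pts[np.argmin(s)]
        br = pts[np.argmax(s)]
        tr = pts[np.argmin(d)]
        bl = pts[np.argmax(d)]
        return SheetQuad(np.array([tl, tr, br, bl]))


@dataclass
class RectifiedSheet:
    """Perspective-corrected sheet raster with its metric calibration.

    ``scale_x``/``scale_y`` are millimetres per pixel along the raster width
    and height; ``homography`` maps rectified (x, y) pixel coordinates back
    into the source image.
    """

    raster: np.ndarray
    scale_x: float
    scale_y: float
    paper: PaperSpec
    quad: SheetQuad | None = None
    homography: np.ndarray | None = None

    @property
    def shape(self):
        return self.raster.shape

    def px_to_mm(self, xy_px) -> np.ndarray:
        return np.asarray(xy_px, float) * np.array([self.scale_x, self.scale_y])


@dataclass
class SheetDetectConfig:
    """Tunable parameters of the sheet detector (all lengths in pixels
    unless suffixed otherwise)."""

    window_frac: float = 0.125       # adaptive window as fraction of short side
    binarize_offset: float = 10.0
    canny_sigma: float = 2.0
    gradient_low_frac: float = 0.66  # hysteresis thresholds as multiples of
    gradient_high_frac: float = 1.33 # the median gradient magnitude
    boundary_band_px: int = 5        # edge band around the sheet mask outline
    edge_dilate_px: int = 1          # thicken edges so Hough tolerates pixel jitter
    min_len_frac: float = 0.2
    max_len_frac: float = 0.8
    hough_threshold_frac: float = 0.2
    hough_line_gap: int = 10
    hough_rng: int = 0
    angle_tol_deg: float = 5.0
    dist_tol_frac: float = 0.02      # of the image diagonal
    min_sheet_area_frac: float = 0.05
    min_sheet_contrast: float = 20.0
    aspect_tol: float = 0.10
    px_per_mm: float = 10.0


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance-weighted grayscale conversion, output float in [0, 255]."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidInputError("expected a 3-channel color image")
    if img.shape[0] < 64 or img.shape[1] < 64:
        raise InvalidInputError("image too small (need >= 64x64 pixels)")
    gray = skcolor.rgb2gray(img)
    if img.dtype == np.uint8:
        gray = gray * 255.0
    return gray


def binarize_adaptive(gray: np.ndarray, window_px: int, offset: float) -> np.ndarray:
    """Adaptive (local-mean) binarization.

    Foreground is every pixel brighter than the mean of its ``window_px``
    neighbourhood minus ``offset``; with a window larger than the structures
    of interest the light sheet maps to foreground on a dark background.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ParameterError(f"window_px must be odd and >= 3, got {window_px}")
    g = np.asarray(gray, float)
    thresh = skfilters.threshold_local(
        g, block_size=window_px, method="mean", offset=offset
    )
    return g > thresh


def detect_boundary_segments(
    edges: np.ndarray,
    image_dims: tuple,
    min_frac: float = 0.2,
    max_frac: float = 0.8,
    *,
    hough_threshold: int = 10,
    line_gap: int = 10,
    rng: int = 0,
) -> list:
    """Probabilistic-Hough segments plausibly lying on the sheet boundary.

    ``image_dims`` is (height, width).  A segment is kept when its length is
    within ``[min_frac, max_frac]`` of the image side matching its
    orientation: near-horizontal segments are compared with the width,
    near-vertical with the height.
    """
    if not (0 < min_frac < max_frac <= 1):
        raise ParameterError("need 0 < min_frac < max_frac <= 1")
    h, w = image_dims
    if not np.any(edges):
        return []
    min_len = int(math.ceil(min_frac * min(h, w)))
    raw = sktransform.probabilistic_hough_line(
        edges.astype(bool),
        threshold=hough_threshold,
        line_length=min_len,
        line_gap=line_gap,
        rng=rng,
    )
    segments = []
    for p0, p1 in raw:
        seg = LineSegment(tuple(map(float, p0)), tuple(map(float, p1)))
        # fold angle: within pi/4 of horizontal -> compare with image width
        near_horizontal = min(seg.angle, math.pi - seg.angle) < math.pi / 4
        side = w if near_horizontal else h
        if min_frac * side <= seg.length <= max_frac * side:
            segments.append(seg)
    return segments


def _angle_diff(a: float, b: float) -> float:
    """Circular distance between two undirected line angles in [0, pi)."""
    d = abs(a - b) % math.pi
    return min(d, math.pi - d)


def _pair_distance(s1: LineSegment, s2: LineSegment, angle_tol, dist_tol) -> bool:
    """True when two segments belong to the same sheet side."""
    d_ang = _angle_diff(s1.angle, s2.angle)
    if d_ang > angle_tol:
        return False
    # offsets are signed w.r.t. the folded angle; when the two angles sit on
    # opposite sides of the 0/pi wrap the normals point opposite ways
    wrapped = abs(s1.angle - s2.angle) > math.pi / 2
    off2 = -s2.offset if wrapped else s2.offset
    return abs(s1.offset - off2) <= dist_tol


def cluster_segments(
    segments: list,
    angle_tol: float = math.radians(5.0),
    dist_tol: float = 20.0,
) -> list:
    """Group boundary segments into the four sheet sides.

    Single-linkage clustering on (angle, offset): two segments join when
    both their mutual angle and their perpendicular distance are within
    tolerance.  The four retained clusters are, per orientation pair, the
    two heaviest (by total segment length) clusters; they correspond to the
    two pairs of opposite sheet sides.

    Returns ``[side_a0, side_a1, side_b0, side_b1]`` where the first two
    clusters share one orientation and the last two the perpendicular one.
    """
    if len(segments) < 4:
        raise SheetNotFoundError(
            f"need at least 4 boundary segments, got {len(segments)}",
            stage="cluster_segments",
            sides_found=0,
        )
    n = len(segments)
    # union-find single linkage
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _pair_distance(segments[i], segments[j], angle_tol, dist_tol):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(segments[i])
    clusters = sorted(
        groups.values(), key=lambda c: -sum(s.length for s in c)
    )

    # split clusters into two orientation families around the dominant angle
    def mean_angle(cluster):
        # average on the doubled circle to respect the pi-wraparound
        c = np.mean([math.cos(2 * s.angle) for s in cluster])
        s = np.mean([math.sin(2 * s.angle) for s in cluster])
        return (math.atan2(s, c) / 2) % math.pi

    dominant = mean_angle(clusters[0])
    fam_a = [c for c in clusters if _angle_diff(mean_angle(c), dominant) < math.pi / 4]
    fam_b = [c for c in clusters if _angle_diff(mean_angle(c), dominant) >= math.pi / 4]

    chosen = []
    for fam in (fam_a, fam_b):
        picked = []
        for c in fam:  # already sorted heaviest-first
            if len(picked) == 2:
                break
            # opposite sides must be separated in offset
            if all(
                not _pair_distance(c[0], p[0], angle_tol, dist_tol) for p in picked
            ):
                picked.append(c)
        chosen.extend(picked)
    if len(chosen) < 4:
        raise SheetNotFoundError(
            f"recovered only {len(chosen)} sheet sides",
            stage="cluster_segments",
            sides_found=len(chosen),
        )
    return chosen[:4]


def fit_boundary_line(cluster: list) -> BoundaryLine:
    """Total-least-squares line through the pixels of a segment cluster.

    Minimizes the summed squared perpendicular distance from points sampled
    at unit spacing along every segment in the cluster.
    """
    if not cluster:
        raise FitError("empty segment cluster")
    pts = np.vstack([s.sample_pixels() for s in cluster])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    if float(np.trace(cov)) < 1e-12:
        raise FitError("degenerate cluster: all pixels coincident")
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, int(np.argmax(evals))]
    ang = math.atan2(direction[1], direction[0]) % math.pi
    if ang >= math.pi - 1e-12:
        ang = 0.0
    n = np.array([-math.sin(ang), math.cos(ang)])
    return BoundaryLine(angle=ang, offset=float(centroid @ n))


def _intersect_two(l1: BoundaryLine, l2: BoundaryLine) -> np.ndarray:
    a = np.vstack([l1.normal, l2.normal])
    b = np.array([l1.offset, l2.offset])
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    if abs(det) < 1e-9:
        raise GeometryError(
            f"near-parallel boundary lines (angles {math.degrees(l1.angle):.2f} "
            f"and {math.degrees(l2.angle):.2f} deg): no stable intersection"
        )
    return np.linalg.solve(a, b)


def intersect_boundaries(lines: list) -> SheetQuad:
    """Corner recovery: intersect each line of one near-parallel pair with
    each line of the other pair and order the four corners TL, TR, BR, BL.

    ``lines`` must be ``[a0, a1, b0, b1]`` with (a0, a1) and (b0, b1) the
    two near-parallel pairs, as produced by :func:`cluster_segments` +
    :func:`fit_boundary_line`.
    """
    if len(lines) != 4:
        raise GeometryError(f"need exactly 4 boundary lines, got {len(lines)}")
    a0, a1, b0, b1 = lines
    if _angle_diff(a0.angle, a1.angle) > math.radians(30) or _angle_diff(
        b0.angle, b1.angle
    ) > math.radians(30):
        raise GeometryError("lines are not grouped as two near-parallel pairs")
    pts = [
        _intersect_two(la, lb) for la in (a0, a1) for lb in (b0, b1)
    ]
    return SheetQuad.order_vertices(pts)


def rectify(
    image: np.ndarray,
    quad: SheetQuad,
    paper: PaperSpec,
    px_per_mm: float,
    *,
    aspect_tol: float = 0.10,
    on_aspect_mismatch: str = "error",
) -> RectifiedSheet:
    """Warp the sheet quad onto an axis-aligned, metrically calibrated raster.

    The output raster is always portrait (short side horizontal); when the
    quad lies landscape in the image, the corner correspondence is cyclically
    rotated so the homography involves no reflection.  The pixel scale is
    ``paper.width_mm / raster_width`` per axis (equal to ``1/px_per_mm`` up
    to the sub-pixel rounding of the raster size).
    """
    if px_per_mm <= 0:
        raise ParameterError("px_per_mm must be positive")
    sides = quad.side_lengths()
    w_img = 0.5 * (sides[0] + sides[2])  # top + bottom
    h_img = 0.5 * (sides[1] + sides[3])  # right + left
    landscape = w_img > h_img
    long_px, short_px = (w_img, h_img) if landscape else (h_img, w_img)
    quad_aspect = long_px / short_px
    rel_dev = abs(quad_aspect - paper.aspect) / paper.aspect
    if rel_dev > aspect_tol:
        msg = (
            f"sheet aspect {quad_aspect:.3f} deviates from "
            f"{paper.name} aspect {paper.aspect:.3f} by {rel_dev:.1%}"
        )
        if on_aspect_mismatch == "error":
            raise GeometryError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)

    out_w = int(round(paper.width_mm * px_per_mm))
    out_h = int(round(paper.height_mm * px_per_mm))
    # corner coordinates of the raster footprint (pixel i spans i +- 0.5)
    dst = np.array(
        [[-0.5, -0.5], [out_w - 0.5, -0.5], [out_w - 0.5, out_h - 0.5], [-0.5, out_h - 0.5]]
    )
    src = quad.vertices
    if landscape:
        src = np.roll(src, -1, axis=0)  # TR,BR,BL,TL: right edge becomes top
    tform = sktransform.ProjectiveTransform.from_estimate(dst, src)
    if not tform:
        raise GeometryError("homography estimation failed")
    img = np.asarray(image)
    warped = sktransform.warp(
        img, tform, output_shape=(out_h, out_w), order=1, mode="edge",
        preserve_range=True,
    )
    raster = np.clip(warped, 0, 255).astype(np.uint8) if img.dtype == np.uint8 else warped
    return RectifiedSheet(
        raster=raster,
        scale_x=paper.width_mm / out_w,
        scale_y=paper.height_mm / out_h,
        paper=paper,
        quad=quad,
        homography=tform.params.copy(),
    )


def _sheet_mask(gray: np.ndarray, cfg: SheetDetectConfig) -> np.ndarray:
    short = min(gray.shape)
    window = int(cfg.window_frac * short)
    window = max(3, window | 1)
    mask = binarize_adaptive(gray, window, cfg.binarize_offset)
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SheetNotFoundError("no bright region found", stage="binarize")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    sheet = ndimage.binary_fill_holes(labels == best)
    if sheet.sum() < cfg.min_sheet_area_frac * gray.size:
        raise SheetNotFoundError(
            "largest bright region too small to be the sheet", stage="binarize"
        )
    inside = float(gray[sheet].mean())
    outside_mask = ~sheet
    if outside_mask.sum() == 0:
        raise SheetNotFoundError("bright region fills the frame", stage="binarize")
    outside = float(gray[outside_mask].mean())
    if inside - outside < cfg.min_sheet_contrast:
        raise SheetNotFoundError(
            f"insufficient sheet/background contrast "
            f"({inside:.1f} vs {outside:.1f})",
            stage="binarize",
        )
    return sheet


def detect_sheet(
    image: np.ndarray,
    paper: PaperSpec,
    config: SheetDetectConfig | None = None,
) -> RectifiedSheet:
    """End-to-end sheet detection and rectification.

    Composes grayscale conversion, adaptive binarization, Canny edges
    restricted to a band around the candidate sheet outline, Hough segment
    detection, side clustering, line fitting, corner intersection and the
    projective warp.  Raises :class:`SheetNotFoundError` (with the failing
    stage) or :class:`GeometryError` when any step cannot recover the sheet.
    """
    cfg = config or SheetDetectConfig()
    gray = to_grayscale(image)
    sheet = _sheet_mask(gray, cfg)

    gx = ndimage.sobel(gray, axis=1)
    gy = ndimage.sobel(gray, axis=0)
    grad = np.hypot(gx, gy)
    med = float(np.median(grad))
    low = cfg.gradient_low_frac * med
    high = cfg.gradient_high_frac * med
    if high <= low or high == 0:
        low, high = None, None  # flat image: let Canny use its defaults
    edges = skfeature.canny(
        gray, sigma=cfg.canny_sigma, low_threshold=low, high_threshold=high
    )
    outline = sheet ^ ndimage.binary_erosion(sheet)
    band = ndimage.binary_dilation(
        outline, structure=np.ones((3, 3), bool), iterations=cfg.boundary_band_px
    )
    edges &= band
    if not np.any(edges):
        raise SheetNotFoundError("no edges on the sheet outline", stage="canny")
    if cfg.edge_dilate_px > 0:
        # single-pixel jitter in the Canny chain fragments the Hough walk;
        # a thin dilation keeps the boundary traversable end to end
        edges = ndimage.binary_dilation(
            edges, np.ones((3, 3), bool), iterations=cfg.edge_dilate_px
        )

    h, w = gray.shape
    segments = detect_boundary_segments(
        edges,
        (h, w),
        cfg.min_len_frac,
        cfg.max_len_frac,
        hough_threshold=max(10, int(cfg.hough_threshold_frac * min(h, w))),
        line_gap=cfg.hough_line_gap,
        rng=cfg.hough_rng,
    )
    diag = math.hypot(h, w)
    clusters = cluster_segments(
        segments,
        angle_tol=math.radians(cfg.angle_tol_deg),
        dist_tol=cfg.dist_tol_frac * diag,
    )
    lines = [fit_boundary_line(c) for c in clusters]
    quad = intersect_boundaries(lines)
    return rectify(
        image,
        quad,
        paper,
        cfg.px_per_mm,
        aspect_tol=cfg.aspect_tol,
        on_aspect_mismatch="error",
    )
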