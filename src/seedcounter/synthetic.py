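"""Ground-truthed synthetic grain-on-paper scenes.

Renders the input the pipeline is designed for: a bright sheet of known
physical size on a dark background, scattered with dark ellipsoidal grains
of known millimetre dimensions, optionally with touching pairs, a linear
shadow gradient, additive Gaussian sensor noise, and an out-of-plane
perspective tilt.  Every scene carries full ground truth (per-grain
dimensions, instance label raster in sheet coordinates, the warp
homography), so each pipeline stage can be scored without external data.

Grains are modelled as anti-aliased filled ellipses (optionally egg-shaped
via two half-ellipses sharing the major axis) — an idealization of real
grains matching the pipeline's ellipse-based morphometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import transform as sktransform

from .errors import CapacityError, ParameterError
from .geometry import PAPER_PRESETS, PaperSpec

__all__ = [
    "SceneSpec",
    "GrainTruth",
    "GroundTruth",
    "VARIETY_DIMENSIONS",
    "generate_scene",
    "generate_count_experiment",
    "generate_variety_panel",
]

# Mean grain length/width (mm) of the five wheat varieties the pipeline is
# benchmarked on: oval Alcedo, elongated Synthetic, small Alen'kaya, and the
# intermediate 84/98w and Purple Chance.
VARIETY_DIMENSIONS = {
    "Alcedo": (7.0, 3.6),
    "Synthetic": (8.0, 2.3),
    "Alenkaya": (5.0, 2.4),
    "84/98w": (6.5, 2.6),
    "Purple Chance": (7.0, 2.9),
}


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of one synthetic scene.

    Distributions are (mean, sd, low, high) truncated normals in mm.
    Colors are HSV triplets in [0, 1]^3.  ``tilt_deg`` is the out-of-plane
    rotation of the sheet plane about a horizontal axis; ``shadow_strength``
    scales a linear illumination gradient across the sheet (0 = none);
    ``noise_sigma`` is the additive Gaussian sigma on the 0-255 scale.
    """

    paper: PaperSpec = PAPER_PRESETS["a4"]
    n_grains: int = 50
    grain_length_mm: tuple = (7.0, 0.5, 5.0, 9.0)
    grain_width_mm: tuple = (3.2, 0.3, 2.0, 4.2)
    grain_color_hsv: tuple = (0.08, 0.55, 0.35)
    grain_color_jitter: tuple = (0.02, 0.08, 0.08)
    background_color_hsv: tuple = (0.6, 0.25, 0.12)
    paper_value: float = 0.92
    touching_pairs: int = 0
    egg_factor: float = 0.0          # 0 = pure ellipse; 0.3 = marked egg shape
    tilt_deg: float = 0.0
    shadow_strength: float = 0.0
    noise_sigma: float = 0.0
    brightness: float = 1.0
    seed: int = 0
    px_per_mm_render: float = 6.0
    margin_frac: float = 0.15        # dark border around the sheet
    edge_clearance_mm: float = 5.0
    min_clearance_px: int = 2

    def __post_init__(self):
        if self.n_grains < 0 or 2 * self.touching_pairs > self.n_grains:
            raise ParameterError("need 0 <= 2*touching_pairs <= n_grains")
        if self.px_per_mm_render <= 0:
            raise ParameterError("px_per_mm_render must be positive")


@dataclass(frozen=True)
class GrainTruth:
    """Ground truth for one grain, in sheet coordinates (mm)."""

    grain_id: int
    center_mm: tuple
    length_mm: float
    width_mm: float
    orientation_rad: float
    area_mm2: float           # analytic pi/4 * L * W
    touching_partner: int | None = None


@dataclass
class GroundTruth:
    """Scene-level ground truth.

    ``labels`` is the instance label raster over the pre-warp canvas;
    ``homography`` maps pre-warp canvas (x, y) pixels to the rendered
    image; ``sheet_origin_px`` is the canvas position of the sheet's
    top-left corner, so sheet-mm coordinates convert to canvas pixels as
    ``origin + mm * px_per_mm``.
    """

    grains: list
    labels: np.ndarray
    homography: np.ndarray
    sheet_origin_px: tuple
    px_per_mm: float
    corners_image: np.ndarray   # sheet corners in the rendered image, TL,TR,BR,BL

    @property
    def count(self) -> int:
        return len(self.grains)

    def center_canvas_px(self, grain: GrainTruth) -> np.ndarray:
        return np.asarray(self.sheet_origin_px) + np.asarray(grain.center_mm) * self.px_per_mm

    def center_image_px(self, grain: GrainTruth) -> np.ndarray:
        p = np.append(self.center_canvas_px(grain), 1.0)
        q = self.homography @ p
        return q[:2] / q[2]


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    # simple rejection; distributions here are far from degenerate
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def _ellipse_coverage(shape, center, a, b, theta, egg=0.0, supersample=3):
    """Anti-aliased coverage raster of a filled (possibly egg) ellipse.

    ``a``/``b`` are semi-axes in px.  With ``egg > 0`` the semi-minor axis
    is ``b*(1+egg)`` on one side of the major axis and ``b*(1-egg)`` on the
    other, producing an asymmetric, egg-like outline.
    """
    h, w = shape
    ss = supersample
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    yy = np.arange(h)[:, None, None, None] + sub[None, None, :, None]
    xx = np.arange(w)[None, :, None, None] + sub[None, None, None, :]
    dx = xx - center[0]
    dy = yy - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    b_eff = b * np.where((-dx * st + dy * ct) >= 0, 1.0 + egg, 1.0 - egg)
    v = (-dx * st + dy * ct) / b_eff
    inside = (u * u + v * v) <= 1.0
    return inside.mean(axis=(2, 3))


def _hsv_to_rgb255(hsv) -> np.ndarray:
    rgb = skcolor.hsv2rgb(np.asarray(hsv, float).reshape(1, 1, 3))[0, 0]
    return rgb * 255.0


def _tilt_homography(shape, tilt_deg):
    """Projective map emulating an out-of-plane camera tilt.

    The sheet plane is rotated by ``tilt_deg`` about the horizontal axis
    through the canvas center and projected by a pinhole camera at distance
    twice the canvas height (moderate, realistic perspective).
    """
    h, w = shape
    if abs(tilt_deg) < 1e-9:
        return np.eye(3), (h, w)
    tau = math.radians(tilt_deg)
    z0 = 2.0 * h
    cx, cy = w / 2.0, h / 2.0

    def project(pts):
        pts = np.asarray(pts, float)
        x = pts[:, 0] - cx
        y = pts[:, 1] - cy
        denom = z0 + y * math.sin(tau)
        return np.column_stack([
            cx + z0 * x / denom,
            cy + z0 * y * math.cos(tau) / denom,
        ])

    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
    proj = project(corners)
    # shift so the projected canvas stays inside a same-margin frame
    shift = proj.min(axis=0)
    proj -= shift
    out_w = int(math.ceil(proj[:, 0].max())) + 1
    out_h = int(math.ceil(proj[:, 1].max())) + 1
    tf = sktransform.ProjectiveTransform.from_estimate(corners, proj)
    if not tf:
        raise ParameterError("degenerate tilt homography")
    return tf.params, (out_h, out_w)


def generate_scene(spec: SceneSpec):
    """Render one scene; returns ``(image_uint8_rgb, GroundTruth)``.

    Deterministic given ``spec`` (including its seed): calling twice yields
    bit-identical images.  Raises :class:`CapacityError` when the requested
    grains cannot be placed with the required clearances.
    """
    rng = np.random.default_rng(spec.seed)
    ppm = spec.px_per_mm_render
    paper = spec.paper
    sheet_w = int(round(paper.width_mm * ppm))
    sheet_h = int(round(paper.height_mm * ppm))
    margin = int(round(spec.margin_frac * max(sheet_w, sheet_h)))
    H, W = sheet_h + 2 * margin, sheet_w + 2 * margin

    bg = _hsv_to_rgb255(spec.background_color_hsv)
    paper_rgb = np.full(3, spec.paper_value * 255.0)
    canvas = np.empty((H, W, 3), float)
    canvas[:] = bg
    canvas[margin:margin + sheet_h, margin:margin + sheet_w] = paper_rgb

    labels = np.zeros((H, W), np.int32)
    occupied = np.zeros((H, W), bool)

    clear_mm = spec.edge_clearance_mm
    grains: list[GrainTruth] = []
    n_single = spec.n_grains - 2 * spec.touching_pairs

    def sample_dims():
        L = float(_truncnorm(rng, *spec.grain_length_mm))
        Wd = float(_truncnorm(rng, *spec.grain_width_mm))
        if Wd > L:  # width may not exceed length
            L, Wd = Wd, L
        return L, Wd

    def grain_color():
        jit = rng.normal(0.0, 1.0, 3) * np.asarray(spec.grain_color_jitter)
        hsv = np.clip(np.asarray(spec.grain_color_hsv) + jit, 0, 1)
        hsv[0] = hsv[0] % 1.0
        return _hsv_to_rgb255(hsv)

    struct = np.ones((3, 3), bool)

    # grains are rasterized and blended on bounding-box crops; a "crop" is
    # (coverage, mask, window) with window = (y0, y1, x0, x1)
    def paint(crop, color, gid):
        cov, mask, (y0, y1, x0, x1) = crop
        canvas[y0:y1, x0:x1] = (
            canvas[y0:y1, x0:x1] * (1 - cov[..., None]) + color * cov[..., None]
        )
        labels[y0:y1, x0:x1][mask] = gid
        occupied[y0:y1, x0:x1] |= mask

    def raster_grain(center_px, L, Wd, theta):
        a = 0.5 * L * ppm
        b = 0.5 * Wd * ppm
        pad = int(math.ceil(max(a, b * (1 + spec.egg_factor)))) + 3 + spec.min_clearance_px
        x0 = max(0, int(center_px[0]) - pad)
        x1 = min(W, int(center_px[0]) + pad + 1)
        y0 = max(0, int(center_px[1]) - pad)
        y1 = min(H, int(center_px[1]) + pad + 1)
        cov = _ellipse_coverage(
            (y1 - y0, x1 - x0), (center_px[0] - x0, center_px[1] - y0),
            a, b, theta, egg=spec.egg_factor,
        )
        return cov, cov >= 0.5, (y0, y1, x0, x1)

    def placement_ok(crop, extra_mask_full=None):
        cov, mask, (y0, y1, x0, x1) = crop
        if not mask.any():
            return False
        grown = ndimage.binary_dilation(mask, struct, iterations=spec.min_clearance_px)
        occ = occupied[y0:y1, x0:x1]
        if extra_mask_full is not None:
            occ = occ | extra_mask_full[y0:y1, x0:x1]
        return not np.any(grown & occ)

    gid = 0
    max_tries = 200
    # --- isolated grains -------------------------------------------------
    for _ in range(n_single):
        L, Wd = sample_dims()
        placed = False
        for _try in range(max_tries):
            theta = rng.uniform(0, math.pi)
            half = 0.5 * L  # conservative in-sheet bound
            cx_mm = rng.uniform(clear_mm + half, paper.width_mm - clear_mm - half)
            cy_mm = rng.uniform(clear_mm + half, paper.height_mm - clear_mm - half)
            center_px = (margin + cx_mm * ppm, margin + cy_mm * ppm)
            crop = raster_grain(center_px, L, Wd, theta)
            if placement_ok(crop):
                gid += 1
                paint(crop, grain_color(), gid)
                grains.append(GrainTruth(
                    grain_id=gid, center_mm=(cx_mm, cy_mm), length_mm=L,
                    width_mm=Wd, orientation_rad=theta,
                    area_mm2=math.pi / 4 * L * Wd,
                ))
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could not place grain {gid + 1}/{spec.n_grains} "
                f"after {max_tries} tries"
            )

    # --- touching pairs ---------------------------------------------------
    for _ in range(spec.touching_pairs):
        L1, W1 = sample_dims()
        L2, W2 = sample_dims()
        placed = False
        for _try in range(max_tries):
            th1 = rng.uniform(0, math.pi)
            half = 0.5 * (L1 + L2)  # pair fits inside the clearance zone
            cx_mm = rng.uniform(clear_mm + half, paper.width_mm - clear_mm - half)
            cy_mm = rng.uniform(clear_mm + half, paper.height_mm - clear_mm - half)
            c1 = (margin + cx_mm * ppm, margin + cy_mm * ppm)
            crop1 = raster_grain(c1, L1, W1, th1)
            if not placement_ok(crop1):
                continue
            m1_full = np.zeros((H, W), bool)
            _, m1, (a0, a1, b0, b1) = crop1
            m1_full[a0:a1, b0:b1] = m1
            m1_grown = ndimage.binary_dilation(m1_full, struct)
            th2 = rng.uniform(0, math.pi)
            phi = rng.uniform(0, 2 * math.pi)
            dvec = np.array([math.cos(phi), math.sin(phi)])
            # slide the partner inward until the masks first touch
            d = 0.5 * (max(L1, W1) + max(L2, W2)) * ppm + 2
            hit = None
            while d > 0:
                c2 = (c1[0] + d * dvec[0], c1[1] + d * dvec[1])
                crop2 = raster_grain(c2, L2, W2, th2)
                _, m2, (y0, y1, x0, x1) = crop2
                if not placement_ok(crop2):  # checks third grains; m1 not painted yet
                    break
                m2_full = np.zeros((H, W), bool)
                m2_full[y0:y1, x0:x1] = m2
                overlap = np.count_nonzero(m1_full & m2_full)
                if overlap > 0 or np.any(m1_grown & m2_full):
                    if overlap <= 0.10 * min(m1_full.sum(), m2_full.sum()):
                        hit = (c2, crop2)
                    break
                d -= 0.5
            if hit is None:
                continue
            c2, crop2 = hit
            gid += 1
            id1 = gid
            paint(crop1, grain_color(), id1)
            gid += 1
            id2 = gid
            # overlap pixels go to the second grain; instance masks in tests
            # come from the label raster
            paint(crop2, grain_color(), id2)
            mm1 = ((c1[0] - margin) / ppm, (c1[1] - margin) / ppm)
            mm2 = ((c2[0] - margin) / ppm, (c2[1] - margin) / ppm)
            grains.append(GrainTruth(id1, mm1, L1, W1, th1,
                                     math.pi / 4 * L1 * W1, touching_partner=id2))
            grains.append(GrainTruth(id2, mm2, L2, W2, th2,
                                     math.pi / 4 * L2 * W2, touching_partner=id1))
            placed = True
            break
        if not placed:
            raise CapacityError("could not place a touching pair")

    # --- illumination ------------------------------------------------------
    if spec.shadow_strength > 0:
        phi = rng.uniform(0, 2 * math.pi)
        yy, xx = np.mgrid[0:H, 0:W]
        t = (xx * math.cos(phi) + yy * math.sin(phi)).astype(float)
        t = (t - t.min()) / max(float(np.ptp(t)), 1.0)
        canvas *= (1.0 - spec.shadow_strength * t)[..., None]
    if spec.brightness != 1.0:
        canvas *= spec.brightness

    # --- perspective warp ---------------------------------------------------
    hom, out_shape = _tilt_homography((H, W), spec.tilt_deg)
    if np.allclose(hom, np.eye(3)):
        rendered = canvas
    else:
        tf = sktransform.ProjectiveTransform(matrix=hom)
        rendered = sktransform.warp(
            canvas, tf.inverse, output_shape=out_shape, order=1,
            mode="constant", cval=float(bg.mean()), preserve_range=True,
        )
        # warp fills with a gray constant; repaint outside with background
        ones = sktransform.warp(
            np.ones((H, W)), tf.inverse, output_shape=out_shape, order=0,
            mode="constant", cval=0.0, preserve_range=True,
        )
        rendered = np.where(ones[..., None] > 0, rendered, bg)

    # --- sensor noise -------------------------------------------------------
    if spec.noise_sigma > 0:
        rendered = rendered + rng.normal(0, spec.noise_sigma, rendered.shape)
    image = np.clip(rendered, 0, 255).astype(np.uint8)

    corners_canvas = np.array([
        [margin - 0.5, margin - 0.5],
        [margin + sheet_w - 0.5, margin - 0.5],
        [margin + sheet_w - 0.5, margin + sheet_h - 0.5],
        [margin - 0.5, margin + sheet_h - 0.5],
    ])
    ch = np.column_stack([corners_canvas, np.ones(4)]) @ hom.T
    corners_image = ch[:, :2] / ch[:, 2:3]

    truth = GroundTruth(
        grains=grains,
        labels=labels,
        homography=hom,
        sheet_origin_px=(margin - 0.5, margin - 0.5),
        px_per_mm=ppm,
        corners_image=corners_image,
    )
    return image, truth


def generate_count_experiment(
    spec: SceneSpec, start_n: int = 50, steps: int = 40
):
    """Decreasing-count series: scenes with start_n, start_n-1, ... grains.

    Emulates the counting protocol of pouring N grains, removing one and
    reshuffling between photographs; placement is re-randomized per scene
    from seeds derived from ``spec.seed``.
    """
    if start_n < steps:
        raise ParameterError("start_n must be >= steps")
    seeds = np.random.SeedSequence(spec.seed).generate_state(steps) % (2 ** 31)
    out = []
    for i in range(steps):
        s = replace(spec, n_grains=start_n - i, seed=int(seeds[i]))
        out.append(generate_scene(s))
    return out


def generate_variety_panel(seed: int = 0, base: SceneSpec | None = None):
    """Five 50-grain scenes centered on the five varieties' mean dimensions.

    Length/width are sampled with sd 0.3 mm about each variety's printed
    mean, so the panel spans lengths 5-8 mm and widths 2.3-3.6 mm.
    Returns ``[(name, image, truth), ...]``.
    """
    base = base or SceneSpec()
    seeds = np.random.SeedSequence(seed).generate_state(len(VARIETY_DIMENSIONS))
    panel = []
    for (name, (L, Wd)), s in zip(VARIETY_DIMENSIONS.items(), seeds):
        spec = replace(
            base,
            n_grains=50,
            touching_pairs=0,
            grain_length_mm=(L, 0.3, L - 1.2, L + 1.2),
            grain_width_mm=(Wd, 0.3, max(1.2, Wd - 1.2), Wd + 1.2),
            seed=int(s % (2 ** 31)),
        )
        img, truth = generate_scene(spec)
        panel.append((name, img, truth))
    return panel
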