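"""Sheet detection and rectification tests."""

import math

import numpy as np
import pytest

from seedcounter.errors import (
    GeometryError,
    InvalidInputError,
    ParameterError,
    SheetNotFoundError,
)
from seedcounter.geometry import (
    LUMA_WEIGHTS,
    PAPER_PRESETS,
    BoundaryLine,
    LineSegment,
    PaperSpec,
    SheetDetectConfig,
    SheetQuad,
    binarize_adaptive,
    cluster_segments,
    detect_boundary_segments,
    detect_sheet,
    fit_boundary_line,
    intersect_boundaries,
    rectify,
    to_grayscale,
)
from seedcounter.synthetic import SceneSpec, generate_scene


# ---------------------------------------------------------------- PaperSpec

def test_paper_presets_complete_and_ordered():
    assert set(PAPER_PRESETS) == {"a3", "a4", "a5", "b4", "b5", "b6", "letter", "legal"}
    for spec in PAPER_PRESETS.values():
        assert 0 < spec.width_mm <= spec.height_mm


def test_paper_from_string_user_defined():
    p = PaperSpec.from_string("300x200mm")
    assert (p.width_mm, p.height_mm) == (200.0, 300.0)
    with pytest.raises(ParameterError):
        PaperSpec.from_string("a9")
    with pytest.raises(ParameterError):
        PaperSpec("bad", -1, 100)


# ------------------------------------------------------------- to_grayscale

def test_grayscale_achromatic_and_pure_channels():
    white = np.full((64, 64, 3), 255, np.uint8)
    assert np.allclose(to_grayscale(white), 255.0)
    black = np.zeros((64, 64, 3), np.uint8)
    assert np.allclose(to_grayscale(black), 0.0)
    blue = np.zeros((64, 64, 3), np.uint8)
    blue[..., 2] = 255
    assert np.allclose(to_grayscale(blue), LUMA_WEIGHTS[2] * 255.0, atol=1e-6)


def test_grayscale_rejects_bad_input():
    with pytest.raises(InvalidInputError):
        to_grayscale(np.zeros((64, 64), np.uint8))
    with pytest.raises(InvalidInputError):
        to_grayscale(np.zeros((10, 10, 3), np.uint8))


# -------------------------------------------------------- binarize_adaptive

def brute_local_mean(gray, window):
    """Oracle: reflect-padded double-loop local mean."""
    half = window // 2
    # edge handling mirrors including the border pixel (scipy "reflect")
    padded = np.pad(gray.astype(float), half, mode="symmetric")
    out = np.empty_like(gray, dtype=float)
    for y in range(gray.shape[0]):
        for x in range(gray.shape[1]):
            out[y, x] = padded[y:y + window, x:x + window].mean()
    return out


def test_adaptive_binarization_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    gray = rng.uniform(0, 255, (40, 48))
    window, offset = 11, 10.0
    mask = binarize_adaptive(gray, window, offset)
    oracle = gray > brute_local_mean(gray, window) - offset
    assert np.array_equal(mask, oracle)


def test_bright_rectangle_on_dark_field():
    gray = np.full((80, 80), 30.0)
    gray[25:55, 20:60] = 200.0
    # window spanning the structures: local mean blends both populations
    mask = binarize_adaptive(gray, 79, 10.0)
    assert mask[25:55, 20:60].all()
    assert not mask[:20].any() and not mask[60:].any()


def test_gradient_lit_sheet_fully_foreground():
    gray = np.full((80, 80), 30.0)
    gray[20:60, 15:65] = np.linspace(160, 220, 50)[None, :]
    mask = binarize_adaptive(gray, 79, 10.0)
    assert mask[20:60, 15:65].all()


def test_uniform_raster_single_sided():
    mask = binarize_adaptive(np.full((40, 40), 128.0), 11, 10.0)
    assert mask.all() or not mask.any()


def test_binarize_rejects_even_window():
    with pytest.raises(ParameterError):
        binarize_adaptive(np.zeros((10, 10)), 10, 5)


# ------------------------------------------------- detect_boundary_segments

def rect_edges(shape=(300, 400), top=60, bottom=240, left=80, right=320, rot_deg=0.0):
    edges = np.zeros(shape, bool)
    corners = np.array(
        [[left, top], [right, top], [right, bottom], [left, bottom]], float
    )
    if rot_deg:
        c = np.array([shape[1] / 2, shape[0] / 2])
        th = math.radians(rot_deg)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        corners = (corners - c) @ R.T + c
    for i in range(4):
        p, q = corners[i], corners[(i + 1) % 4]
        for t in np.linspace(0, 1, 600):
            x, y = p + t * (q - p)
            edges[int(round(y)), int(round(x))] = True
    return edges


def test_segments_on_axis_aligned_rectangle():
    edges = rect_edges()
    segs = detect_boundary_segments(edges, edges.shape, 0.2, 0.8)
    assert len(segs) >= 4
    angles = [min(s.angle, math.pi - s.angle) for s in segs]
    assert all(a < math.radians(2) or abs(a - math.pi / 2) < math.radians(2)
               for a in angles)


def test_blank_edge_map_gives_empty_list():
    assert detect_boundary_segments(np.zeros((100, 100), bool), (100, 100)) == []


def test_rotated_rectangle_angles():
    edges = rect_edges(rot_deg=10.0)
    segs = detect_boundary_segments(edges, edges.shape, 0.2, 0.9)
    got = sorted({round(math.degrees(s.angle)) for s in segs})
    for a in got:
        assert min(abs(a - 10), abs(a - 100)) <= 1.0


# ---------------------------------------------------------- cluster_segments

def side_segment(x0, y0, x1, y1):
    return LineSegment((float(x0), float(y0)), (float(x1), float(y1)))


def rect_side_segments(split=True):
    # rectangle x in [0,100], y in [0,50]; two collinear fragments per side
    segs = []
    for (a, b) in (((0, 0), (100, 0)), ((0, 50), (100, 50))):
        if split:
            segs.append(side_segment(a[0], a[1], (a[0] + b[0]) / 2 - 2, b[1]))
            segs.append(side_segment((a[0] + b[0]) / 2 + 2, a[1], b[0], b[1]))
        else:
            segs.append(side_segment(*a, *b))
    for x in (0, 100):
        if split:
            segs.append(side_segment(x, 0, x, 23))
            segs.append(side_segment(x, 27, x, 50))
        else:
            segs.append(side_segment(x, 0, x, 50))
    return segs


def test_two_fragments_per_side_cluster_to_four_pairs():
    clusters = cluster_segments(rect_side_segments(), dist_tol=5.0)
    assert len(clusters) == 4
    assert sorted(len(c) for c in clusters) == [2, 2, 2, 2]


def test_four_exact_sides_are_singletons():
    clusters = cluster_segments(rect_side_segments(split=False), dist_tol=5.0)
    assert len(clusters) == 4
    assert all(len(c) == 1 for c in clusters)


def test_outlier_segments_are_discarded():
    segs = rect_side_segments()
    outliers = [
        side_segment(20, 10, 45, 37),
        side_segment(60, 40, 90, 12),
        side_segment(10, 30, 40, 45),
        side_segment(55, 5, 80, 30),
    ]
    clusters = cluster_segments(segs + outliers, dist_tol=5.0)
    assert len(clusters) == 4
    kept = [s for c in clusters for s in c]
    assert all(o not in kept for o in outliers)
    assert sorted(len(c) for c in clusters) == [2, 2, 2, 2]


def test_too_few_sides_raises_with_count():
    segs = [side_segment(0, 0, 100, 0), side_segment(0, 50, 100, 50)]
    with pytest.raises(SheetNotFoundError):
        cluster_segments(segs, dist_tol=5.0)
    three_sides = rect_side_segments()[:-2]  # drop one vertical side
    with pytest.raises(SheetNotFoundError) as err:
        cluster_segments(three_sides, dist_tol=5.0)
    assert err.value.sides_found == 3


# ----------------------------------------------------------- fit / intersect

def test_fit_line_contains_single_segment():
    seg = side_segment(10, 20, 110, 20)
    line = fit_boundary_line([seg])
    assert line.angle == pytest.approx(0.0, abs=1e-9)
    assert line.offset == pytest.approx(20.0, abs=1e-9)


def test_fit_line_two_collinear_segments():
    line = fit_boundary_line([side_segment(0, 5, 40, 5), side_segment(60, 5, 100, 5)])
    assert line.offset == pytest.approx(5.0, abs=1e-9)


def test_fit_line_midline_of_symmetric_pair():
    # equal pixel counts at y=10 and y=14 -> least-squares midline y=12
    line = fit_boundary_line(
        [side_segment(0, 10, 100, 10), side_segment(0, 14, 100, 14)]
    )
    assert line.angle == pytest.approx(0.0, abs=1e-9)
    assert line.offset == pytest.approx(12.0, abs=1e-9)


def test_intersect_axis_aligned():
    lines = [
        BoundaryLine(math.pi / 2, 0.0),    # x = 0 (vertical)
        BoundaryLine(math.pi / 2, -100.0), # x = 100
        BoundaryLine(0.0, 0.0),            # y = 0
        BoundaryLine(0.0, 50.0),           # y = 50
    ]
    quad = intersect_boundaries(lines)
    assert np.allclose(
        quad.vertices, [[0, 0], [100, 0], [100, 50], [0, 50]], atol=1e-9
    )


def test_intersect_rotated():
    th = math.radians(30)
    c, s = math.cos(th), math.sin(th)
    corners = np.array([[0, 0], [100, 0], [100, 50], [0, 50]], float) @ np.array(
        [[c, s], [-s, c]]
    )
    corners += 200.0  # keep TL/BR ordering unambiguous
    lines = []
    for i, j in ((0, 1), (3, 2), (0, 3), (1, 2)):
        lines.append(
            fit_boundary_line([side_segment(*corners[i], *corners[j])])
        )
    quad = intersect_boundaries([lines[2], lines[3], lines[0], lines[1]])
    assert np.allclose(np.sort(quad.vertices, axis=0),
                       np.sort(corners, axis=0), atol=1e-6)


def test_intersect_parallel_raises():
    lines = [
        BoundaryLine(0.0, 10.0),
        BoundaryLine(0.0, 40.0),
        BoundaryLine(0.0, 10.0),  # coincident with first, parallel pair broken
        BoundaryLine(0.0, 10.0),
    ]
    with pytest.raises(GeometryError):
        intersect_boundaries(lines)


def test_quad_requires_convexity():
    with pytest.raises(GeometryError):
        SheetQuad(np.array([[0, 0], [10, 0], [2, 2], [0, 10]], float))


# ------------------------------------------------------------------ rectify

def test_rectify_arithmetic_a4_at_10ppm():
    quad = SheetQuad(np.array([[0, 0], [209, 0], [209, 296], [0, 296]], float) * 2)
    sheet = rectify(
        np.zeros((700, 600, 3), np.uint8), quad, PAPER_PRESETS["a4"], 10.0,
        aspect_tol=0.2,
    )
    assert sheet.raster.shape[:2] == (2970, 2100)
    assert sheet.scale_x == pytest.approx(0.1, rel=1e-6)
    assert sheet.scale_y == pytest.approx(0.1, rel=1e-6)


def test_rectify_identity_recovers_crop():
    rng = np.random.default_rng(1)
    img = rng.integers(0, 255, (320, 260, 3), dtype=np.uint8)
    img = np.asarray(img)
    # quad exactly the target footprint of a 21x29.7 mm "paper" at 10 px/mm
    paper = PaperSpec("mini", 21.0, 29.7)
    quad = SheetQuad(np.array(
        [[-0.5, -0.5], [209.5, -0.5], [209.5, 296.5], [-0.5, 296.5]]
    ))
    sheet = rectify(img, quad, paper, 10.0)
    assert np.mean(np.abs(
        sheet.raster.astype(int) - img[:297, :210].astype(int)
    )) < 1.0


def test_rectify_aspect_mismatch():
    quad = SheetQuad(np.array([[0, 0], [100, 0], [100, 100], [0, 100]], float))
    with pytest.raises(GeometryError):
        rectify(np.zeros((200, 200, 3), np.uint8), quad, PAPER_PRESETS["a4"], 1.0)


# ------------------------------------------------------------- detect_sheet

@pytest.fixture(scope="module")
def clean_scene():
    spec = SceneSpec(n_grains=12, seed=5, px_per_mm_render=4.0)
    return spec, *generate_scene(spec)


def test_detect_sheet_clean_scene_scale_and_corners(clean_scene):
    spec, img, truth = clean_scene
    sheet = detect_sheet(img, spec.paper, SheetDetectConfig(px_per_mm=4.0))
    w_px = sheet.raster.shape[1]
    h_px = sheet.raster.shape[0]
    assert abs(w_px * sheet.scale_x - spec.paper.width_mm) / spec.paper.width_mm < 0.005
    assert abs(h_px * sheet.scale_y - spec.paper.height_mm) / spec.paper.height_mm < 0.005
    assert np.abs(sheet.quad.vertices - truth.corners_image).max() < 2.0


def test_detect_sheet_tilted_scene():
    spec = SceneSpec(n_grains=12, seed=6, px_per_mm_render=4.0, tilt_deg=20.0)
    img, truth = generate_scene(spec)
    sheet = detect_sheet(img, spec.paper, SheetDetectConfig(px_per_mm=4.0))
    assert np.abs(sheet.quad.vertices - truth.corners_image).max() < 3.0


def test_detect_sheet_all_dark_raises():
    dark = np.full((400, 300, 3), 15, np.uint8)
    with pytest.raises(SheetNotFoundError):
        detect_sheet(dark, PAPER_PRESETS["a4"])


def test_scale_conservation_across_presets():
    for name, paper in PAPER_PRESETS.items():
        spec = SceneSpec(paper=paper, n_grains=0, seed=11, px_per_mm_render=3.0)
        img, _ = generate_scene(spec)
        sheet = detect_sheet(img, paper, SheetDetectConfig(px_per_mm=3.0))
        h_px, w_px = sheet.raster.shape[:2]
        assert abs(w_px * sheet.scale_x - paper.width_mm) / paper.width_mm < 0.005, name
        assert abs(h_px * sheet.scale_y - paper.height_mm) / paper.height_mm < 0.005, name


def test_rotation_equivariance_90deg(clean_scene):
    spec, img, _ = clean_scene
    cfg = SheetDetectConfig(px_per_mm=4.0)
    ref = detect_sheet(img, spec.paper, cfg).raster.astype(float)
    rot = detect_sheet(np.rot90(img).copy(), spec.paper, cfg).raster.astype(float)
    assert rot.shape == ref.shape
    # orientation normalization leaves a 180-degree ambiguity
    diff = min(
        np.mean(np.abs(rot - ref)),
        np.mean(np.abs(rot[::-1, ::-1] - ref)),
    )
    assert diff < 5.0


def test_corner_error_monotone_in_noise():
    """Mean corner error does not decrease as sensor noise grows."""
    sigmas = [0, 5, 10, 20]
    means = []
    for sigma in sigmas:
        errs = []
        for seed in range(20):
            spec = SceneSpec(
                paper=PAPER_PRESETS["b6"], n_grains=5, seed=300 + seed,
                px_per_mm_render=3.0, noise_sigma=float(sigma),
            )
            img, truth = generate_scene(spec)
            sheet = detect_sheet(img, spec.paper, SheetDetectConfig(px_per_mm=3.0))
            errs.append(np.abs(sheet.quad.vertices - truth.corners_image).mean())
        means.append(np.mean(errs))
    for lo, hi in zip(means, means[1:]):
        assert hi >= lo - 0.05  # tie tolerance for float jitter
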