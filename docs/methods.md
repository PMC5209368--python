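# Methods

`seedcounter` measures cereal grains from a single photograph of seeds
scattered on a sheet of paper of known physical size. This note records the
models, the defaults and the design decisions behind each stage, and what
the synthetic benchmark does and does not demonstrate.

## Metric anchor: the paper sheet

The only calibration object is the sheet itself. Its physical size
(`PaperSpec`; presets A3, A4, A5, B4, B5, B6, Letter, Legal — the B series
uses ISO 216 dimensions, with user-defined `WxHmm` sizes accepted) is known,
so once its four corners are found in the image, an 8-DOF projective
transform maps its interior onto an axis-aligned raster whose scale is
`width_mm / raster_width` millimetres per pixel. We use a full perspective
homography rather than an affine map: out-of-plane camera tilt produces
keystone distortion that an affine transform cannot undo.

Detection chain and defaults (all configurable in `SheetDetectConfig`):

1. **Grayscale** — ITU-R BT.709 luminance weights (0.2125, 0.7154, 0.0721).
2. **Adaptive binarization** — foreground = pixel > local mean − offset;
   window = 1/8 of the shorter image side (rounded to odd), offset = 10
   intensity levels. The window must be much larger than a grain so grains
   do not punch holes in the sheet mask; the largest bright component,
   hole-filled, is the sheet candidate. Candidates covering < 5 % of the
   frame or with < 20 intensity levels of contrast against the background
   are rejected early (`SheetNotFoundError`).
3. **Edges** — Canny with σ = 2 and hysteresis thresholds 0.66× / 1.33× the
   median Sobel gradient magnitude (removes per-image threshold tuning),
   intersected with a 5 px band around the sheet-mask outline so grain
   edges do not vote. The surviving edges are dilated by one pixel:
   single-pixel jitter in the Canny chain otherwise fragments the
   probabilistic Hough walk into sub-threshold pieces.
4. **Hough segments** — probabilistic Hough with vote threshold and minimum
   length 20 % of the matching image side, maximum gap 10 px, seeded RNG
   (deterministic); segments longer than 80 % of their side are discarded
   (they are usually image-border artifacts). Near-horizontal segments are
   compared against the image width, near-vertical against the height.
5. **Side clustering** — single-linkage clustering on (angle mod π,
   perpendicular offset), tolerances 5° and 2 % of the image diagonal, with
   sign-consistent handling of the 0/π angle wrap. The two heaviest
   clusters (total segment length) per orientation family give the four
   sides; interior/outlier segments end up in light clusters and are
   dropped. Fewer than four recoverable sides raises `SheetNotFoundError`
   carrying the number found.
6. **Line fit** — total least squares (perpendicular distance) on points
   sampled at unit spacing along every segment of a cluster.
7. **Corners** — adjacent-pair line intersections, ordered TL, TR, BR, BL
   (x right, y down, 0-based pixel centers); convexity is verified.
8. **Rectification** — corner correspondence onto the portrait target
   rectangle at `px_per_mm` (default 10); if the quad lies landscape the
   correspondence is cyclically rotated, never mirrored. A quad aspect
   ratio deviating more than 10 % from the paper's raises an error by
   default (perspective foreshortening stays well under that at the tilts
   the detector handles).

On clean synthetic scenes corner recovery is sub-pixel (≈ 0.4 px at 4
px/mm); the scale-conservation identity `raster_px × mm_per_px = paper
dimension` holds to rounding (≪ 0.5 %) by construction of the target raster.

## Grain segmentation

Grains are dark on light paper. Stages (`SegmentationConfig`):

- **Coarse mask** — residual = local paper level (15 mm mean window) −
  gray; the cut is Otsu's threshold on the residual, floored at 15 levels.
  Otsu places the cut near the midpoint of the anti-aliased edge ramp,
  which keeps the boundary unbiased (a fixed small offset would dilate
  every grain by up to half a pixel — a 3–7 % width error at working
  resolutions); the floor returns an empty mask on a blank sheet. A fixed
  offset is available (`fixed_offset`) for atypical contrast.
- **Local HSV refinement** (optional, needs a calibration profile) — per
  coarse component, a window (bounding box dilated 25 %) is scored by
  back-projection against the profile's 16×8×8 HSV histogram, gated by the
  profile's central-99 % saturation/value intervals, and re-thresholded by
  Otsu within the window. Shadows keep the paper's hue/saturation, so
  attached shadow lobes score zero and are stripped; refinement cannot
  touch pixels outside the windows. Without a profile the stage is a
  pass-through (the two features — HSV refinement and watershed splitting —
  are independently switchable).
- **Calibration** — from a photo of a single seed on the sheet: the unique
  plausible component's HSV pixels build the histogram and intervals; zero
  or multiple candidates raise `CalibrationError` with the count.
- **Watershed split** — markers are the regional maxima of the
  h-reconstruction of the Euclidean distance transform (suppression depth
  h = 0.4 mm, converted to pixels, floor 0.5 px), flooding the inverted
  distance transform restricted to the mask. The marker construction
  matters: taking the regional maxima *of the reconstruction* keeps one
  connected marker per convex grain even when discretization dents the
  distance ridge by less than h, while a contact neck between two touching
  grains (deeper than h) blocks the reconstruction and yields two markers.
  Scoring only pixels whose reconstruction residue reaches h (a common
  shortcut) disconnects the ridge plateau and over-segments elongated
  grains. Any foreground component without a marker receives one at its
  distance maximum, so the union of labels always equals the input mask.
- **Plausibility filter** — labels outside [2, 60] mm² (brackets wheat
  grain sizes; configurable) or touching a 2 mm border band (sheet-edge
  shadows) are removed; labels are then consecutive. 4-connectivity for
  components, 8-connectivity for contour tracing.

## Morphometry

Each labeled region is reduced to the ellipse sharing its second-order
central moments: full axis lengths are `4·√eigenvalue` of the coordinate
covariance (exact for a filled ellipse), the orientation is the principal
eigenvector angle, and area is pixel count × pixel area. Length and width
are the full major/minor axes, matching how grain dimensions are quoted
(e.g. a wheat grain "7 mm long, 3.6 mm wide").

The **centroid offset** descriptor is the distance between the region's
pixel center of mass and the intersection point of its principal axes. For
a moment-fitted ellipse the axes intersect at the moment centroid by
construction, which would make the descriptor identically zero; we instead
take the axes-intersection point as the midpoint of the region's extent
along each principal direction. For a true ellipse this coincides with the
center; for an egg-shaped grain the center of mass shifts toward the fat
end while the extent midpoint does not, so the descriptor measures
longitudinal asymmetry. This operational definition is the package's own
choice — the descriptor has no standard definition — and is the only
reading under which it is not degenerate.

Anisotropic pixel scales beyond 1 % trigger a warning and use the mean
scale for axis lengths (area always uses the exact per-axis product).
Moment fits agree with a brute-force double-loop computation to 1e-9
relative; axes of analytic ellipse rasters are recovered within 1 % (the
discretization adds ~1/12 px² per-axis variance, negligible above ~10 px).

## Accuracy statistics

`mae` is the mean absolute deviation; `mape` is **always percent** (2.0
means 2 %) — reported values near 0.03 in some published grain-counting
tables are ambiguous between fraction and percent, so the convention is
fixed here and stated prominently. `pearson` requires n ≥ 3 and nonzero
variance; a perfect zero-residual series, where r is formally undefined, is
reported as 1.0 with an explicit `r_degenerate` flag instead of an error,
so a perfect pipeline does not fail its own evaluation. Dimension series
report the average of the length-wise and width-wise MAE (and MAPE) with
r_length and r_width kept separate.

## Synthetic scenes

The generator renders exactly the input the pipeline expects: a bright
sheet (value 0.92) on a dark background (HSV 0.60/0.25/0.12), dark
ellipsoidal grains (HSV 0.08/0.55/0.35 with per-grain jitter), optional
egg-shaping, a linear shadow gradient, additive Gaussian sensor noise
applied after an out-of-plane perspective warp (pinhole camera at twice the
canvas height), and full ground truth (per-grain dimensions, instance
labels, the warp homography). Grain length/width are truncated normals;
placement enforces ≥ 2 px pairwise clearance and ≥ 5 mm from sheet edges;
designated touching pairs are slid into contact with ≤ 10 % mask overlap.
Generation is bit-deterministic given the spec (including its seed).

Study conditions used by the benchmark drivers (`experiments` module):
50 grains on A4, shadow strength 0.2, noise σ = 5. Counting series render
at 4 px/mm — counting needs no more, and it keeps a 40-scene series around
a minute — while dimension panels render at 8 px/mm so the narrowest
variety's width (2.3 mm) spans ~18 px, where the sub-pixel binarization
bias is comfortably below 1 %. The five-variety panel centers its
length/width distributions (sd 0.3 mm) on the published means of five wheat
varieties: Alcedo 7.0/3.6, Synthetic 8.0/2.3, Alen'kaya 5.0/2.4, 84/98w
6.5/2.6, Purple Chance 7.0/2.9 mm.

What passing synthetic benchmarks shows — and does not. The scenes exercise
geometry, illumination gradients, sensor noise, touching contacts and
perspective exactly as modelled; they do not model specular shimmer,
defocus, JPEG artifacts, non-elliptical grain outlines, chaff/debris, or
lens distortion. Real-photograph accuracy is bounded below by the synthetic
numbers; published mobile-capture experiments with physical grains report
dimension errors near 8 %, whereas the synthetic panel yields ≲ 0.5 %
because physical nuisances are absent by construction.

## Known limitations

- One sheet per image, light-on-dark only; no radial lens-distortion model.
- Touching-pair resolution assumes single-layer contact; stacked grains are
  merged or mis-split.
- HSV refinement assumes the calibration seed's variety matches the
  measured grains.
- The centroid-offset descriptor depends on the operational definition
  above; values are comparable within this package but not across tools.
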