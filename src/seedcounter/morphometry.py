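"""Per-grain metric shape descriptors.

Each labeled grain region is reduced to the ellipse with the same
second-order central moments: the full major/minor axis lengths are
``4 * sqrt(eigenvalue)`` of the normalized covariance matrix of the pixel
coordinates, reported in millimetres as grain length and width.  Area is
the pixel count times the pixel area.  The *centroid offset* descriptor is
the distance between the raw pixel center of mass and the center of the
fitted principal-axes ellipse; it is zero for centrally symmetric grains
and grows with egg-like asymmetry.

The axes-intersection point of a moment ellipse coincides with the moment
centroid by construction, so the fitted-ellipse center is computed from the
*contour-bounded support* of the ellipse rather than the raw pixels: we
take the intersection point of the principal axes as the center of the
ellipse refitted to the region's convex outline. In practice we use the
midpoint of the region's extent along the principal axes, which for a true
ellipse equals its center and for an asymmetric grain differs from the
center of mass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import FitError, ParameterError

__all__ = ["GrainMeasurement", "fit_principal_ellipse", "measure_grain", "measure_all"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrainMeasurement:
    """Metric descriptors of one grain.

    ``length_mm``/``width_mm`` are the full principal-axis extents,
    ``centroid_offset_mm`` the distance between the region's center of mass
    and the intersection point of its principal axes, ``centroid_xy_mm``
    the center-of-mass position on the sheet.
    """

    grain_id: int
    length_mm: float | None
    width_mm: float | None
    area_mm2: float | None
    centroid_offset_mm: float | None
    orientation_rad: float | None
    centroid_xy_mm: tuple | None

    def __post_init__(self):
        if self.length_mm is not None:
            if not (self.length_mm >= self.width_mm > 0):
                raise FitError(
                    f"grain {self.grain_id}: need length >= width > 0, got "
                    f"{self.length_mm} / {self.width_mm}"
                )


def _region_coords(region: np.ndarray) -> tuple:
    """(x, y) pixel-center coordinate arrays of the True pixels."""
    mask = np.asarray(region, bool)
    ys, xs = np.nonzero(mask)
    return xs.astype(float), ys.astype(float)


def fit_principal_ellipse(region: np.ndarray):
    """Moment-based ellipse fit of a binary region.

    Returns ``(center, major_axis_len, minor_axis_len, orientation)`` in
    pixel units; ``orientation`` is the angle of the major axis in
    ``[0, pi)`` (x right, y down).  ``center`` is the intersection point of
    the principal axes: the midpoint of the region's extent along each
    principal direction (equal to the moment centroid for symmetric
    regions, offset from it for asymmetric ones).

    Axis lengths are ``4 * sqrt(eigenvalues)`` of the coordinate covariance,
    which is exact for a filled ellipse.
    """
    xs, ys = _region_coords(region)
    n = xs.size
    if n < 8:
        raise FitError(f"region too small for ellipse fit ({n} pixels)")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    # second-order central moments (biased, population form)
    mxx = float(dx @ dx) / n
    myy = float(dy @ dy) / n
    mxy = float(dx @ dy) / n
    cov = np.array([[mxx, mxy], [mxy, myy]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[0] <= 1e-12:
        raise FitError("degenerate region: zero variance along an axis")
    minor = 4.0 * math.sqrt(evals[0])
    major = 4.0 * math.sqrt(evals[1])
    v = evecs[:, 1]
    orientation = math.atan2(v[1], v[0]) % math.pi
    # principal-axes intersection: midpoint of the extent along each axis
    u = evecs[:, 1]  # major direction
    w = evecs[:, 0]  # minor direction
    proj_u = dx * u[0] + dy * u[1]
    proj_w = dx * w[0] + dy * w[1]
    mid_u = 0.5 * (proj_u.max() + proj_u.min())
    mid_w = 0.5 * (proj_w.max() + proj_w.min())
    center = np.array([cx, cy]) + mid_u * u + mid_w * w
    return center, major, minor, orientation


def measure_grain(
    region: np.ndarray,
    scale_x: float,
    scale_y: float,
    grain_id: int = 1,
    contour=None,
) -> GrainMeasurement:
    """Convert one labeled region into millimetre descriptors.

    ``scale_x``/``scale_y`` are mm per pixel.  Anisotropic scales beyond 1%
    trigger a warning and the mean scale is used for the axis lengths (area
    always uses the exact per-axis product).
    """
    if scale_x <= 0 or scale_y <= 0:
        raise ParameterError("pixel scales must be positive")
    if abs(scale_x - scale_y) / scale_x > 0.01:
        log.warning(
            "anisotropic pixel scale (%.4g vs %.4g); axis lengths use the mean",
            scale_x, scale_y,
        )
    s = 0.5 * (scale_x + scale_y)
    center, major, minor, orientation = fit_principal_ellipse(region)
    xs, ys = _region_coords(region)
    com = np.array([xs.mean(), ys.mean()])
    offset_mm = float(np.linalg.norm(com - center)) * s
    area_mm2 = float(xs.size) * scale_x * scale_y
    return GrainMeasurement(
        grain_id=grain_id,
        length_mm=major * s,
        width_mm=minor * s,
        area_mm2=area_mm2,
        centroid_offset_mm=offset_mm,
        orientation_rad=orientation,
        centroid_xy_mm=(com[0] * scale_x, com[1] * scale_y),
    )


def measure_all(labelmap, sheet) -> tuple:
    """Measure every grain of a label map on a rectified sheet.

    Returns ``(measurements, count)``; grains whose moment fit fails are
    still counted and reported with null shape fields.
    """
    labels = labelmap.labels if hasattr(labelmap, "labels") else np.asarray(labelmap)
    n_labels = int(labels.max())
    out = []
    for k in range(1, n_labels + 1):
        region = labels == k
        try:
            out.append(
                measure_grain(region, sheet.scale_x, sheet.scale_y, grain_id=k)
            )
        except FitError as exc:
            log.warning("grain %d: %s", k, exc)
            out.append(
                GrainMeasurement(
                    grain_id=k,
                    length_mm=None,
                    width_mm=None,
                    area_mm2=None,
                    centroid_offset_mm=None,
                    orientation_rad=None,
                    centroid_xy_mm=None,
                )
            )
    return out, n_labels
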