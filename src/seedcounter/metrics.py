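"""Accuracy statistics for grain counting and morphometry.

Implements the error measures used to benchmark the pipeline against a
ground-truth series: mean absolute error

    MAE = (1/M) * sum_j |N_j - N'_j|

mean absolute percentage error, reported in percent,

    MAPE = (100/M) * sum_j |N_j - N'_j| / N_j

and the sample Pearson correlation between the true and estimated series.
``MAPE`` always returns percent (2.0 means 2%).

Counting experiments yield a single (MAE, MAPE, r_N) triple.  Dimension
experiments score length and width separately and report the *average* of
the two MAE values and of the two MAPE values, with the two correlations
r_l and r_w kept separate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EvaluationError, InvalidInputError

__all__ = [
    "CountSeries",
    "DimensionSeries",
    "EvaluationReport",
    "mae",
    "mape",
    "pearson",
    "evaluate_counting",
    "evaluate_dimensions",
]


def _as_series(true, est):
    t = np.asarray(true, dtype=float)
    e = np.asarray(est, dtype=float)
    if t.ndim != 1 or e.ndim != 1:
        raise InvalidInputError("series must be one-dimensional")
    if t.size == 0:
        raise InvalidInputError("series must be nonempty")
    if t.shape != e.shape:
        raise InvalidInputError(
            f"series length mismatch: {t.size} true vs {e.size} estimated"
        )
    return t, e


def mae(true, est) -> float:
    """Mean absolute error between a true and an estimated series."""
    t, e = _as_series(true, est)
    return float(np.mean(np.abs(t - e)))


def mape(true, est) -> float:
    """Mean absolute percentage error, in percent.

    Requires every true value to be nonzero (it is the denominator).
    """
    t, e = _as_series(true, est)
    if np.any(t == 0):
        raise InvalidInputError("mape undefined: true series contains zeros")
    return float(100.0 * np.mean(np.abs(t - e) / np.abs(t)))


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Raises :class:`InvalidInputError` if either series has zero variance or
    fewer than 3 points.
    """
    xa, ya = _as_series(x, y)
    if xa.size < 3:
        raise InvalidInputError("pearson requires at least 3 points")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise InvalidInputError("pearson undefined: zero variance series")
    r = float(xc @ yc) / (sx * sy)
    return max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class CountSeries:
    """Paired true and estimated grain counts over a series of images."""

    true_counts: tuple
    estimated_counts: tuple

    def __post_init__(self):
        t = np.asarray(self.true_counts)
        e = np.asarray(self.estimated_counts)
        if t.shape != e.shape or t.ndim != 1 or t.size == 0:
            raise InvalidInputError("count series must be equal-length, nonempty")
        if np.any(t <= 0):
            raise InvalidInputError("true counts must be positive")


@dataclass(frozen=True)
class DimensionSeries:
    """Per-grain paired reference and estimated lengths and widths (mm).

    Pairing is by grain identity: the physical protocol places each grain in
    a strict order so row ``i`` of every array refers to the same grain.
    """

    true_length_mm: tuple
    est_length_mm: tuple
    true_width_mm: tuple
    est_width_mm: tuple

    def __post_init__(self):
        arrs = [np.asarray(a, dtype=float) for a in (
            self.true_length_mm, self.est_length_mm,
            self.true_width_mm, self.est_width_mm)]
        n = arrs[0].size
        if n == 0 or any(a.ndim != 1 or a.size != n for a in arrs):
            raise InvalidInputError("dimension series must be equal-length, nonempty")


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy summary for one experiment series.

    ``mape`` is in percent.  For counting series ``r`` holds r_N; for
    dimension series ``r_length``/``r_width`` are filled and ``mae``/``mape``
    are the averages of the length-wise and width-wise values.
    ``r_degenerate`` flags a perfect zero-residual series where the Pearson
    correlation is formally undefined and is reported as 1.0.
    """

    mae: float
    mape: float
    r: float | None = None
    r_length: float | None = None
    r_width: float | None = None
    r_degenerate: bool = False
    detail: dict = field(default_factory=dict)


def _safe_pearson(t, e):
    """Pearson r, treating an exactly-identical pair of series as r=1."""
    try:
        return pearson(t, e), False
    except InvalidInputError:
        if np.array_equal(np.asarray(t, float), np.asarray(e, float)):
            return 1.0, True
        raise


def evaluate_counting(series: CountSeries) -> EvaluationReport:
    """MAE, MAPE and Pearson r_N for a grain-count series."""
    t, e = series.true_counts, series.estimated_counts
    r, degen = _safe_pearson(t, e)
    return EvaluationReport(mae=mae(t, e), mape=mape(t, e), r=r, r_degenerate=degen)


def evaluate_dimensions(series: DimensionSeries) -> EvaluationReport:
    """Averaged MAE/MAPE over length and width, with separate r_l and r_w."""
    tl, el = series.true_length_mm, series.est_length_mm
    tw, ew = series.true_width_mm, series.est_width_mm
    mae_l, mae_w = mae(tl, el), mae(tw, ew)
    mape_l, mape_w = mape(tl, el), mape(tw, ew)
    try:
        r_l, deg_l = _safe_pearson(tl, el)
        r_w, deg_w = _safe_pearson(tw, ew)
    except InvalidInputError as exc:
        raise EvaluationError(str(exc)) from exc
    return EvaluationReport(
        mae=0.5 * (mae_l + mae_w),
        mape=0.5 * (mape_l + mape_w),
        r_length=r_l,
        r_width=r_w,
        r_degenerate=deg_l or deg_w,
        detail={
            "mae_length": mae_l, "mae_width": mae_w,
            "mape_length": mape_l, "mape_width": mape_w,
        },
    )
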