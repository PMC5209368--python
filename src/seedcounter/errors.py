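"""Exception hierarchy for the seedcounter pipeline.

Each pipeline stage raises a distinct error type so that batch drivers can
report per-image failures with stage provenance and map them to exit codes.
"""


class SeedCounterError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(SeedCounterError):
    """Malformed input data (wrong shape, wrong dtype, too small)."""


class ParameterError(SeedCounterError):
    """Invalid configuration or operation parameter."""


class SheetNotFoundError(SeedCounterError):
    """The paper sheet could not be located in the image.

    Parameters
    ----------
    stage : str
        Pipeline stage that failed (e.g. ``"cluster_segments"``).
    sides_found : int, optional
        Number of sheet sides recovered before the failure.
    """

    def __init__(self, message, stage=None, sides_found=None):
        super().__init__(message)
        self.stage = stage
        self.sides_found = sides_found


class GeometryError(SeedCounterError):
    """Degenerate geometry (parallel boundary lines, non-convex quad)."""


class FitError(SeedCounterError):
    """A least-squares or moment fit is degenerate."""


class CalibrationError(SeedCounterError):
    """Single-seed calibration failed.

    Attributes
    ----------
    n_found : int
        Number of plausible seed components detected.
    """

    def __init__(self, message, n_found=None):
        super().__init__(message)
        self.n_found = n_found


class CapacityError(SeedCounterError):
    """Synthetic scene could not place all requested grains."""


class EvaluationError(SeedCounterError):
    """Truth/prediction series mismatch during evaluation."""
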