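"""Exception hierarchy for ssikit."""


class SsikitError(Exception):
    """Base class for all ssikit errors."""


class TreeValidationError(SsikitError):
    """A coronary tree violates a schema or geometric invariant."""


class TopologyError(SsikitError):
    """The segment graph is not a forest of per-artery rooted trees."""


class DegenerateNetworkError(SsikitError):
    """The vascular network cannot carry flow (e.g. all outlets closed)."""


class SolverConvergenceError(SsikitError):
    """The network solver failed to reach the residual tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateFitError(SsikitError):
    """A regression is undefined (zero variance in the regressor)."""


class AlignmentError(SsikitError):
    """Predictions and clinical observations do not share the same ids."""
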