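"""Exception hierarchy shared across the pipeline stages."""


class MosaiqError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MosaiqError):
    """A required column or channel is missing from a measurement table."""


class IntegrityError(MosaiqError):
    """Table content violates an invariant (e.g. duplicated cell ids)."""


class DimensionError(MosaiqError):
    """Array shapes are inconsistent."""


class DegenerateThresholdError(MosaiqError):
    """No foreground/background intensity separation exists (constant image)."""


class InsufficientBackgroundError(MosaiqError):
    """Too few background pixels remain after foreground dilation."""


class DegenerateDistributionError(MosaiqError):
    """All sampled intensities fall in a single histogram bin."""


class FitError(MosaiqError):
    """A model fit failed to converge; carries the iteration trace if any."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class ZeroVarianceError(MosaiqError):
    """Expression levels are constant; a correlation scale is undefined."""


class TriangulationError(MosaiqError):
    """Cell positions are degenerate (collinear/coincident); no triangulation."""


class InsufficientComponentsError(MosaiqError):
    """Mixture has fewer components than the number of requested labels."""


class AttenuationError(MosaiqError):
    """Diffusion attenuation too large; (I - alpha*W) is singular."""


class GeometryError(MosaiqError):
    """A region-of-interest polygon is invalid (self-intersecting)."""


class InsufficientDataError(MosaiqError):
    """A statistical comparison group is empty after filtering."""


class ParameterError(MosaiqError):
    """A simulation or algorithm parameter is outside its valid range."""


class PrecondError(MosaiqError):
    """An operation's precondition is not met (e.g. unlabeled cells)."""


class AlignmentError(MosaiqError):
    """Two label vectors refer to different cell sets."""


class PairingError(MosaiqError):
    """Benchmark results cannot be paired across classifiers."""
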