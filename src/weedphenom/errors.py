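"""Exception hierarchy."""


class WeedPhenomError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(WeedPhenomError, ValueError):
    """A parameter is outside its documented valid range."""


class InputError(WeedPhenomError, ValueError):
    """An input payload is unusable (empty cloud, too few points, ...)."""


class UnitError(WeedPhenomError):
    """Metric operation applied to uncalibrated data, or scale applied twice."""


class DegenerateInputError(WeedPhenomError, ValueError):
    """Input is degenerate for the requested computation (constant image,
    collinear points, zero variance, coincident marker endpoints, ...)."""


class DetectionError(WeedPhenomError):
    """A required image feature (e.g. the reference square) was not found."""


class LayoutError(WeedPhenomError):
    """Leaf silhouettes cannot be packed into the requested canvas."""


class JoinError(WeedPhenomError):
    """Paired tables could not be joined; carries the orphan identifiers."""

    def __init__(self, message: str, orphans=()):
        super().__init__(message)
        self.orphans = list(orphans)
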