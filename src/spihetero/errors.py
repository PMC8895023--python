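"""Exception types shared across the pipeline."""


class SpiheteroError(Exception):
    """Base class for package errors."""


class SizeError(SpiheteroError):
    """Particle does not fit the real-space field of view."""


class BandLimitError(SpiheteroError):
    """Requested reciprocal-space samples fall outside the volume extent."""


class ConfigurationError(SpiheteroError):
    """Inconsistent or invalid parameters."""


class UndefinedSimilarityError(SpiheteroError):
    """Too few valid samples to define a common-line correlation."""


class GeometryMismatchError(SpiheteroError):
    """Feature/pattern geometry differs from the one a model was built for."""


class OversamplingError(SpiheteroError):
    """Support is not small enough relative to the field for phase retrieval."""


class DependencyError(SpiheteroError):
    """A pipeline stage is missing an upstream artifact."""
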