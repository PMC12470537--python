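"""Exception hierarchy for the ctiq package."""


class CTIQError(Exception):
    """Base class for all ctiq errors."""


class FormatError(CTIQError):
    """An image or config file could not be read or written in the requested format."""


class ConfigError(CTIQError):
    """An evaluation configuration failed validation."""


class GeometryError(CTIQError):
    """A phantom specification or ROI layout is geometrically invalid."""


class NoisePreconditionError(CTIQError):
    """The signal-dependent variance term would be negative at some pixel."""


class EstimationInfeasibleError(CTIQError):
    """Too few homogeneous patches survive selection for a noise-parameter estimate."""


class IllConditionedSlopeWarning(UserWarning):
    """Patch means span less than ~1 HU; the Poisson slope is unidentifiable."""


class DegenerateNoiseError(CTIQError):
    """A noise-normalised ratio metric (SNR, CNR) has a zero denominator."""


class ZeroDynamicRangeError(CTIQError):
    """The reference image is flat, so range-normalised metrics are undefined."""


class UndefinedMetricError(CTIQError):
    """A metric's defining ratio is 0/0 on the given inputs (e.g. UQI or FSIM on featureless images)."""
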