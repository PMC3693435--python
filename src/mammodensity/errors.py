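"""Exception hierarchy for the density-assessment pipeline."""


class MammoError(Exception):
    """Base class for all package errors."""


class FormatError(MammoError):
    """An input file exists but is not in a supported raster format."""


class ParameterError(MammoError, ValueError):
    """A user-supplied parameter violates its contract."""


class SegmentationError(MammoError):
    """Breast segmentation failed or was requested out of order."""


class DensityUndefinedError(MammoError):
    """PD is undefined because the segmented breast contains no pixels."""


class AgreementUndefinedError(MammoError):
    """An agreement statistic is undefined for the given readings."""


class ConfigError(MammoError):
    """A batch session configuration is malformed."""
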