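"""Exception hierarchy shared across the package."""


class StrideKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StrideKitError):
    """A file does not conform to the documented CSV/JSON dialect."""


class SamplingError(StrideKitError):
    """Timestamps are not a uniform grid within tolerance, or fs is invalid."""


class ParameterError(StrideKitError):
    """A parameter value is outside its valid domain."""


class DetectionError(StrideKitError):
    """Event detection cannot proceed on the given signal."""


class TrialRejectedError(StrideKitError):
    """Too few valid gait cycles were found to analyse the trial."""
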