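"""Exception types raised across the package."""


class FollowerKitError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FollowerKitError, ValueError):
    """A parameter violates its documented domain (e.g. fwhm <= 0)."""


class WindowError(FollowerKitError, ValueError):
    """A baseline or response window does not fit inside the trace."""


class DegenerateBaselineError(FollowerKitError, ValueError):
    """The baseline fluorescence mean is <= 0, so the dF/F ratio is undefined."""


class NoAdmissibleShiftError(FollowerKitError, ValueError):
    """The exclusion zone leaves no admissible circular shift."""


class SchemaError(FollowerKitError, ValueError):
    """An input file does not match the expected on-disk layout."""
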