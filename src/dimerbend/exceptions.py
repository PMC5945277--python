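"""Exception hierarchy shared by all dimerbend modules."""


class DimerbendError(Exception):
    """Base class for all package-specific errors."""


class InputError(DimerbendError, ValueError):
    """A file or argument could not be read or parsed."""


class ConsistencyError(DimerbendError, ValueError):
    """Inputs disagree in shape, atom count, or ordering."""


class DegeneracyError(DimerbendError, ValueError):
    """An operation hit a degenerate input (zero variance, collinear atoms, ...)."""


class InsufficientDataError(DimerbendError, ValueError):
    """Too few frames/samples/blocks to carry out the computation."""


class ConfigurationError(DimerbendError, ValueError):
    """A configuration value is out of range or inconsistent."""


class ConnectivityError(DimerbendError, ValueError):
    """Umbrella-window histograms do not form a connected chain."""


class OutOfRangeError(DimerbendError, ValueError):
    """A requested position lies outside the occupied range of a profile."""


class NoBarrierError(DegeneracyError):
    """A profile has fewer than two basins, so no dividing barrier exists."""
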