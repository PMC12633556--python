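"""Exception hierarchy for waveminer.

All errors derive from :class:`WaveMinerError` so callers can catch the
package's failures with a single except clause; each subclass marks the
contract that was violated (file format, data integrity, grid geometry,
parameter validation, or a mathematically undefined result).
"""


class WaveMinerError(Exception):
    """Base class for all waveminer errors."""


class FormatError(WaveMinerError):
    """An input file does not match its declared layout (missing dataset/column)."""


class IntegrityError(WaveMinerError):
    """Data is internally inconsistent (e.g. spike on a channel absent from the map)."""


class GeometryError(WaveMinerError):
    """Electrode/pixel geometry is invalid (irregular grid, no valid pixels, bad offset)."""


class ParameterError(WaveMinerError):
    """A parameter value is invalid for the given data."""


class UndefinedResultError(WaveMinerError):
    """The requested quantity is mathematically undefined for this input."""
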