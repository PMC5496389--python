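"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2 (caller mistakes: bad
parameters, inconsistent options).  ``DataError`` maps to exit code 3
(the data itself is unusable: wrong grid, corrupt file, empty ROI).
"""


class CmrQuantError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CmrQuantError):
    """Invalid configuration, parameters or option combination."""


class ProtocolError(ConfigurationError):
    """Acquisition protocol is inconsistent with the requested operation."""


class DataError(CmrQuantError):
    """Input data is inconsistent, corrupt or unusable."""


class DimensionError(DataError):
    """Array grids that must agree do not."""


class UndefinedStatisticsError(DataError):
    """Statistics requested over an empty set of valid voxels."""


class InsufficientDataError(DataError):
    """Too few observations for a reportable fit."""


class UndefinedSlopeError(DataError):
    """Regression abscissa has zero variance; the slope is undefined."""
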