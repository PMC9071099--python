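"""Exception hierarchy for ddrquant.

All errors derive from :class:`DDRQuantError` so callers can catch the
package's failures with a single except clause; most also derive from
``ValueError`` because they signal invalid inputs.
"""


class DDRQuantError(Exception):
    """Base class for all ddrquant errors."""


class InvalidRangeError(DDRQuantError, ValueError):
    """Concentration series endpoints are nonpositive or inverted."""


class PackingError(DDRQuantError, RuntimeError):
    """Rejection sampling could not place the requested number of objects."""


class ConfigurationError(DDRQuantError, ValueError):
    """A required condition, sample or parameter is missing from a config/map."""


class GeometryError(DDRQuantError, ValueError):
    """Image/label-map shapes do not match."""


class InvalidStackError(DDRQuantError, ValueError):
    """A z-stack is empty or its planes are inconsistent."""


class InsufficientDataError(DDRQuantError, ValueError):
    """Too few points or rows for the requested fit/analysis."""


class DegenerateControlError(DDRQuantError, ValueError):
    """Solvent-control summary is unusable (e.g. nonpositive mean for fold change)."""


class FitError(DDRQuantError, RuntimeError):
    """A curve fit failed to converge; carries diagnostics in ``args``."""


class InvalidDistanceError(DDRQuantError, ValueError):
    """A distance matrix is not symmetric/zero-diagonal/nonnegative."""
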