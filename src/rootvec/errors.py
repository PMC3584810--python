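"""Exception hierarchy for rootvec.

Everything raised on purpose by the package derives from :class:`RootVecError`,
so callers (and the CLI) can catch one base class.
"""


class RootVecError(Exception):
    """Base class for all rootvec errors."""


class FormatError(RootVecError):
    """Malformed RSML or raster grid file (bad unit, nesting, values...)."""


class SeriesError(RootVecError):
    """Inconsistent soil-grid time series (shape/geometry/timestamp problems)."""


class GeometryError(RootVecError):
    """Invalid geometric input (empty polyline, negative diameter...)."""


class TopologyError(RootVecError):
    """Operation would break the root-system forest (cycle, order > 3...)."""


class ParameterError(RootVecError):
    """Invalid user-supplied parameters."""


class ResamplingError(RootVecError):
    """Raster downsampling with a non-integer factor or non-divisible shape."""


class AnalysisError(RootVecError):
    """A trait/aggregation computation is undefined for the given input."""


class SystemValidationError(RootVecError):
    """A RootSystem failed validation where a valid one is required."""
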