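"""Exception hierarchy.

Everything raised deliberately by the library derives from :class:`FwstreamError`
so callers (and the CLI) can catch one base class.
"""


class FwstreamError(Exception):
    """Base class for all fwstream errors."""


class GeometryError(FwstreamError):
    """Grid geometries or shapes do not match, or a geometry is inconsistent."""


class InvalidSpecError(FwstreamError, ValueError):
    """A synthetic-fixture specification is out of its valid range."""


class InvalidParameterError(FwstreamError, ValueError):
    """A function parameter violates its contract (e.g. even smoothing window)."""


class EmptyInputError(FwstreamError):
    """An operation received an all-NoData raster."""


class FlowError(FwstreamError):
    """The flow-direction graph violates a precondition (cycle, undrainable flat)."""


class InvalidOutletError(FwstreamError, ValueError):
    """A pour point lies on a NoData cell or outside the grid."""


class RangeError(FwstreamError, OverflowError):
    """A scaled value does not fit the catalog storage type."""
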