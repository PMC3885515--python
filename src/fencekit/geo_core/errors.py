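"""Exception hierarchy for layer loading, validation and modeling."""


class FencekitError(Exception):
    """Base class for all package errors."""


class MissingFileError(FencekitError):
    """Input path does not exist."""


class UnsupportedFormatError(FencekitError):
    """File format not handled by this build."""


class UnknownCRSError(FencekitError):
    """Layer carries no usable coordinate reference system."""


class GeographicCRSError(FencekitError):
    """Layer is in a geographic (degree) CRS; a projected metric CRS is required."""


class MissingAttributeError(FencekitError):
    """A mapped attribute column is absent from the source layer."""


class EmptyLayerError(FencekitError):
    """Layer contains no features."""


class InvalidGeometryError(FencekitError):
    """Geometry could not be repaired."""


class ConfigError(FencekitError):
    """Model configuration violates an invariant."""


class CRSMismatchError(FencekitError):
    """Two layers that must share a CRS do not."""


class DegenerateMarginalsError(FencekitError):
    """Chance agreement equals 1; kappa is undefined."""


class RasterResolutionError(FencekitError):
    """Raster cell size too coarse for the smallest polygon."""
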