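"""Exception hierarchy shared across the package."""


class CropSuitError(Exception):
    """Base class for all package errors."""


class InputError(CropSuitError):
    """Invalid or missing user input (bad values, missing criteria, empty collections)."""


class FuzzySetError(InputError):
    """A fuzzy set violates its threshold ordering or contains non-finite values."""


class AlignmentError(InputError):
    """Raster layers do not share shape, transform, or CRS kind."""


class UndefinedStatisticError(CropSuitError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class RasterIOError(CropSuitError):
    """A raster file could not be read or lacks required georeferencing."""
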