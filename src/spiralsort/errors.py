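"""Exception hierarchy."""


class SpiralSortError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(SpiralSortError, ValueError):
    """Channel dimensions are non-positive or inconsistent."""


class DomainError(SpiralSortError, ValueError):
    """A numeric argument is outside its physical domain."""


class UnitError(SpiralSortError, ValueError):
    """Unknown unit tag or unparseable quantity string."""


class CalibrationError(SpiralSortError, ValueError):
    """Density-coefficient calibration input is unusable."""


class InsufficientReplicatesError(SpiralSortError, ValueError):
    """A statistical comparison needs at least two replicates per group."""


class InvalidBracketError(SpiralSortError, ValueError):
    """Bisection bracket has non-positive width."""


class SchemaError(SpiralSortError, ValueError):
    """A delimited input file violates its schema."""


class EmptySampleError(SpiralSortError, ValueError):
    """No particles were counted; rates are undefined."""
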