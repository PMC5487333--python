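"""Exception types shared across the package."""


class MalsfError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MalsfError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DegenerateMaskError(MalsfError, ValueError):
    """A binary mask is all-zero or all-one, so no boundary exists."""


class CongruenceError(MalsfError, ValueError):
    """Two grids that must share a shape (and spacing) do not."""


class DivergenceError(MalsfError, FloatingPointError):
    """The level-set update produced non-finite values (time step too large)."""


class FormatError(MalsfError, ValueError):
    """An input file does not match the expected on-disk format."""


class UndefinedMetricsError(MalsfError, ValueError):
    """Overlap metrics are undefined (e.g. both masks empty)."""
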