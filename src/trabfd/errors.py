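"""Exception types shared across the package."""


class TrabfdError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(TrabfdError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(InvalidArgumentError):
    """Landmark geometry does not admit the requested measurement."""


class EmptyObjectError(TrabfdError, ValueError):
    """A binary image contains no foreground; fractal dimension is undefined."""


class InsufficientDataError(TrabfdError, ValueError):
    """Too few usable points for a fit or a test."""
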