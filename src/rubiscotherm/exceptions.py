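"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`RubiscoThermError`, so callers (and the CLI) can catch one type.
"""


class RubiscoThermError(Exception):
    """Base class for all errors raised by rubiscotherm."""


class DomainError(RubiscoThermError, ValueError):
    """A value is outside its physically meaningful domain."""


class InputError(RubiscoThermError, ValueError):
    """An input dataset violates a precondition (too few points, bad shape)."""


class FitError(RubiscoThermError, RuntimeError):
    """A nonlinear fit failed to converge or was degenerate."""


class FitDomainError(FitError):
    """A fit encountered an inconsistent parameter region (e.g. negative
    discriminant in the finite-mesophyll-conductance quadratic)."""


class SchemaError(InputError):
    """A delimited file is missing a required column."""


class ParseError(InputError):
    """A delimited file contains a cell that cannot be parsed."""


class ConfigError(InputError):
    """A configuration file contains unknown keys or out-of-bounds values."""
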