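"""Exception hierarchy.

Domain errors subclass ValueError so that plain input checks behave the way
numpy/scipy users expect; the more operational failures get their own types so
the CLI can map them to distinct exit codes.
"""


class CardiomazeError(Exception):
    """Base class for package-specific failures."""


class ConfigurationError(CardiomazeError, ValueError):
    """Invalid configuration (schema violations, unsupported parameter values)."""


class DomainError(CardiomazeError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class GeometryError(CardiomazeError, ValueError):
    """Inconsistent or impossible tissue geometry."""


class NumericalInstabilityError(CardiomazeError, ArithmeticError):
    """The explicit integration diverged (|V| beyond the plausibility bound)."""


class NumericalStateError(CardiomazeError, ArithmeticError):
    """Non-finite values encountered in a cell state."""


class MeasurementError(CardiomazeError, RuntimeError):
    """A requested measurement is undefined on the given record/trace."""


class RangeError(CardiomazeError, ValueError):
    """A scan grid does not bracket the feature it is supposed to resolve."""
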