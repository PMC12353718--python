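"""Exception hierarchy shared across dietopt modules."""


class DietOptError(Exception):
    """Base class for all dietopt errors."""


class ValidationError(DietOptError):
    """A domain invariant was violated (bad value, bad unit, bad range)."""


class LoadError(DietOptError):
    """A delimited-text input could not be parsed or joined.

    Carries row provenance where available via the ``context`` attribute.
    """

    def __init__(self, message: str, context: dict | None = None):
        super().__init__(message)
        self.context = context or {}


class UnmatchedFoodError(DietOptError):
    """No composition match exists for a food."""


class UnpricedFoodError(DietOptError):
    """No price observation exists for a food."""


class ConfigError(DietOptError):
    """A scenario or run configuration is inconsistent."""


class SolverError(DietOptError):
    """The solver failed, timed out, or produced an unauditable solution."""


class EnumerationBudgetError(DietOptError):
    """A brute-force enumeration would exceed the configured budget."""
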