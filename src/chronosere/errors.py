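"""Exception hierarchy shared across the package."""


class ChronosereError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChronosereError, ValueError):
    """A delimited input file does not have the expected shape or header."""


class ValidationError(ChronosereError, ValueError):
    """Parsed data violate a domain invariant (category/age consistency,
    negative counts, unknown plot columns in strict mode, ...)."""


class UndefinedInputError(ChronosereError, ValueError):
    """A metric was requested on input for which it is mathematically
    undefined (all-zero abundance column, empty union, psiRef <= 0)."""


class FitError(ChronosereError, RuntimeError):
    """The recovery-trajectory fit cannot be performed (too few points)."""


class ConfigError(ChronosereError, ValueError):
    """A generator or pipeline configuration is infeasible or inconsistent."""
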