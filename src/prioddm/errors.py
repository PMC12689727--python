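"""Exception hierarchy.

All package errors derive from :class:`PrioDDMError` so callers can catch
one base class; the subclasses distinguish bad numeric arguments
(:class:`ParameterError`), inconsistent wiring between components
(:class:`ConfigurationError`), malformed input tables
(:class:`ValidationError`) and MCMC diagnostic failures
(:class:`DiagnosticError`).
"""


class PrioDDMError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PrioDDMError, ValueError):
    """A numeric argument is outside its valid domain."""


class ConfigurationError(PrioDDMError, ValueError):
    """Components are wired together inconsistently (e.g. unmapped condition)."""


class ValidationError(PrioDDMError, ValueError):
    """An input table violates the trial-table schema."""


class DiagnosticError(PrioDDMError, RuntimeError):
    """A convergence diagnostic cannot be computed or fails hard."""
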