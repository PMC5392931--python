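"""Exception hierarchy for ammoflux."""

from __future__ import annotations


class AmmofluxError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AmmofluxError, ValueError):
    """An input value lies outside its physical or mathematical domain."""


class ConfigurationError(AmmofluxError, ValueError):
    """A model/configuration object is inconsistent or incomplete."""


class UsageError(AmmofluxError, ValueError):
    """An unknown option or label was requested (e.g. mechanism name)."""


class ParseError(AmmofluxError, ValueError):
    """A tabular input file failed validation.

    ``problems`` lists every offending cell with its line number.
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        self.problems = list(problems or [])
        if self.problems:
            message = message + "\n  " + "\n  ".join(self.problems)
        super().__init__(message)


class EstimationError(AmmofluxError, RuntimeError):
    """A statistical estimate could not be produced.

    ``best`` optionally carries the best candidate found before failure.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class InfeasibleGradientError(EstimationError):
    """The NH3 concentration gradient is non-positive, so a permeability
    cannot be estimated directly; callers should use the steady-state
    solver's assumption-adjustment path instead."""


class GenerationError(AmmofluxError, RuntimeError):
    """A synthetic-data configuration is infeasible."""
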