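"""Exception hierarchy for the pipeline.

Validation errors (bad input data, unresolved references) are distinguished
from domain errors (mathematically undefined requests such as a zero
denominator) so the CLI can map them to distinct exit codes.
"""


class PigAmuError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PigAmuError):
    """Input data violates a schema or an invariant."""


class InputValidationError(ValidationError):
    """Collected row-level validation failures across input files."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            "input validation failed with %d error(s):\n  %s"
            % (len(self.errors), "\n  ".join(self.errors))
        )


class UnresolvedReferenceError(ValidationError):
    """A record refers to an ingredient, product or farm that does not exist."""


class MissingConversionError(PigAmuError):
    """An amount declared in I.U. but the ingredient has no iu_per_mg."""


class MissingDoseError(PigAmuError):
    """An ingredient has neither a DDDvet nor a long-acting dose standard."""


class UnimputableError(PigAmuError):
    """A missing pack count with no farmer estimate and no peer farms."""


class DomainError(PigAmuError):
    """A computation is undefined for the given inputs (e.g. zero denominator)."""


class ConfigError(PigAmuError):
    """An infeasible generator or run configuration."""
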