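"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`TriageError` so the
CLI can map any validation failure to a nonzero exit code.
"""


class TriageError(Exception):
    """Base class for all triagekit errors."""


class SchemaError(TriageError):
    """A rule file or casualty record violates its schema."""


class StructuralError(TriageError):
    """A decision tree is malformed: dangling reference, cycle, bad terminal."""


class CoverageError(TriageError):
    """The canonical map does not cover a predicate of a shipped system."""


class MissingFieldError(TriageError):
    """Tree evaluation hit an unknown/missing field with imputation disabled."""

    def __init__(self, field: str, criterion_id: str, system_id: str = ""):
        self.field = field
        self.criterion_id = criterion_id
        self.system_id = system_id
        where = f" in system '{system_id}'" if system_id else ""
        super().__init__(
            f"field '{field}' is unknown but required by criterion "
            f"'{criterion_id}'{where}"
        )


class DomainError(TriageError, ValueError):
    """An argument is outside its mathematical or clinical domain."""


class UsageError(TriageError):
    """An operation was invoked on inputs it is not defined for."""


class IdentifierError(TriageError, KeyError):
    """An unknown system / criterion identifier was referenced."""

    def __str__(self) -> str:  # KeyError quotes its payload; keep it readable
        return self.args[0] if self.args else ""


class ConfigurationError(TriageError):
    """A simulation or enumeration configuration is invalid."""
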