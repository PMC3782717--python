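"""Exception hierarchy shared across the package."""


class PsimiCoopError(Exception):
    """Base class for all package-specific errors."""


class UnknownTermError(PsimiCoopError, KeyError):
    """A controlled-vocabulary accession or name is not in the registry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class AmbiguityError(PsimiCoopError):
    """A lenient (case-insensitive) name lookup matched more than one term."""


class NotAnAttributeError(PsimiCoopError):
    """The term never names an interaction or feature attribute."""


class ParseError(PsimiCoopError):
    """Malformed OBO input.  Carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InvariantError(PsimiCoopError, ValueError):
    """A model object violates one of its structural invariants."""


class UnknownIdError(PsimiCoopError, KeyError):
    """An id does not resolve inside the entry."""

    def __str__(self) -> str:
        return Exception.__str__(self)


class FormatError(PsimiCoopError):
    """XML input is not a readable PSI-MI 2.5 document."""


class RefError(PsimiCoopError):
    """An entry with dangling references was handed to the writer."""


class ConfigurationError(PsimiCoopError):
    """Bundled package data (the XSD) is missing or unreadable."""


class ValueFormatError(PsimiCoopError, ValueError):
    """A cooperative-effect value is not a positive real number."""


class EffectExtractionError(PsimiCoopError):
    """A cooperative-effect record cannot be assembled into a valid effect."""


class GraphBuildError(PsimiCoopError):
    """Graph construction refused because semantic validation found errors."""

    def __init__(self, message: str, findings=()):
        self.findings = list(findings)
        super().__init__(message)


class CycleError(PsimiCoopError):
    """Assembly edges form a cycle.  Carries the offending node ids."""

    def __init__(self, message: str, cycle=()):
        self.cycle = list(cycle)
        super().__init__(message)


class UsageError(PsimiCoopError, ValueError):
    """Unknown enum-like argument (fixture name, export format, rule code)."""
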