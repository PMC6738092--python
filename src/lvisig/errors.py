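"""Exception hierarchy. Every error raised by lvisig derives from LvisigError."""


class LvisigError(Exception):
    """Base class for all lvisig errors."""


class FormatError(LvisigError):
    """A file could not be parsed (empty file, malformed line, non-numeric cell)."""


class SchemaError(LvisigError):
    """A table is missing mandatory columns."""


class DomainError(LvisigError):
    """A value lies outside its permitted domain."""


class CohortError(LvisigError):
    """Expression and clinical tables cannot be reconciled (e.g. disjoint samples)."""


class ValidationError(LvisigError):
    """A configuration object violates its invariants."""


class GroupSizeError(LvisigError):
    """A comparison group has too few samples."""


class BoundsError(LvisigError):
    """A parameter (e.g. top-K cutoff) is out of range."""


class CoverageError(LvisigError):
    """Too few signature genes are present in an expression matrix."""


class DegenerateTableError(LvisigError):
    """A contingency table has fewer than two observed levels on a margin."""


class StructuralZeroError(LvisigError):
    """A chi-squared test was requested on a table with an expected count of zero."""


class EmptyCohortError(LvisigError):
    """A prevalence or rate was requested on an empty denominator."""


class InputError(LvisigError):
    """Invalid analysis input (e.g. empty gene universe)."""


class FitError(LvisigError):
    """A model fit could not be carried out (e.g. no events)."""


class ConvergenceError(FitError):
    """Iterative model fitting failed to converge."""
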