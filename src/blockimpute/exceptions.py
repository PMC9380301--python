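"""Exception hierarchy for blockimpute.

All package errors derive from :class:`BlockImputeError` so callers can catch
one base class; the subclasses mirror the distinct failure modes of the
pipeline (file format, data validation, subset-design consistency, the
cascade's containment rule, configuration, and unimputable inputs).
"""


class BlockImputeError(Exception):
    """Base class for all blockimpute errors."""


class FormatError(BlockImputeError):
    """A file could not be parsed or its tables disagree (e.g. metadata
    lists a variable absent from the matrix header)."""


class ValidationError(BlockImputeError):
    """Data violates a declared constraint (e.g. an observed ordinal value
    outside its level set)."""


class DesignError(BlockImputeError):
    """A subset design is inconsistent with itself or with the matrix."""


class ContainmentError(BlockImputeError):
    """The cascade's admissibility rule is violated: a conditioning subset
    does not cover the target subset's participants."""


class ConfigError(BlockImputeError):
    """An invalid configuration value or combination."""


class UnimputableError(BlockImputeError):
    """Imputation is impossible (e.g. a variable with no observed values)."""


class DegenerateTestError(BlockImputeError):
    """A statistical test's assumptions fail degenerately (e.g. a paired
    t-test on differences with zero variance)."""
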