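"""Exception hierarchy.

All package errors derive from :class:`QuenchbindError` so callers (and the
CLI) can catch one base class and map it to a nonzero exit code.
"""


class QuenchbindError(Exception):
    """Base class for all quenchbind errors."""


class FormatError(QuenchbindError):
    """Malformed input file: missing column, bad header, unparsable field."""


class ValidationError(QuenchbindError):
    """Structurally valid input that violates a data invariant."""


class DomainError(QuenchbindError):
    """A value outside the mathematical domain of an operation."""


class AnalysisError(QuenchbindError):
    """The data cannot support the requested analysis (e.g. non-quencher)."""


class ConfigError(QuenchbindError):
    """Invalid or incomplete configuration."""


class IFEWarning(UserWarning):
    """Inner-filter-effect correction applied outside its reliable range."""


class DataWarning(UserWarning):
    """Points excluded or analyses degraded; results still produced."""
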