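"""Exception hierarchy.

Every user-facing failure raises a named subclass of :class:`ElmError` so
callers (and the CLI) can distinguish bad input from internal faults.
"""


class ElmError(Exception):
    """Base class for all errors raised by elmqsar."""


class MissingColumnError(ElmError):
    """A required column (ID, label, descriptor) is absent from the input."""


class DuplicateCompoundError(ElmError):
    """Two rows share the same compound identifier."""


class NonNumericCellError(ElmError):
    """A descriptor cell could not be parsed as a finite number (strict mode)."""


class UnknownLabelError(ElmError):
    """A label token is not one of 1/2, 'active'/'inactive' or a pIC50 real."""


class CurationError(ElmError):
    """Activity curation emptied the dataset or one of the classes."""


class StandardizationError(ElmError):
    """No descriptor column with nonzero variance remains."""


class ModelFormatError(ElmError):
    """A model file is truncated, corrupted, or has an unknown version."""


class DegenerateProblemError(ElmError):
    """A training operation received an empty or single-class problem."""


class ConfigError(ElmError):
    """An invalid configuration value."""
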