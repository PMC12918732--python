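"""Named exceptions shared across the package."""


class AcetomodError(Exception):
    """Base class for package errors."""


class HmmFormatError(AcetomodError):
    """Malformed HMMER3 profile text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SequenceAlphabetError(AcetomodError):
    """Residue outside the 20-letter amino alphabet (plus ambiguous X)."""


class DuplicateIdError(AcetomodError):
    """Duplicate protein or genome identifier where uniqueness is required."""


class TaxonomyFormatError(AcetomodError):
    """Taxonomy table row with wrong rank count or misplaced rank prefix."""


class TbloutFormatError(AcetomodError):
    """Malformed HMMER tabular (tblout) row; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ModelValidationError(AcetomodError):
    """Profile HMM violating its normalization invariants."""


class EngineUnavailableError(AcetomodError):
    """Requested external search engine is not on PATH."""


class ConfigurationError(AcetomodError):
    """Inconsistent module definitions or search configuration."""


class GrowthDataError(AcetomodError):
    """Invalid growth-curve data (non-positive OD, unsorted times, ...)."""
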