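"""Labeled exception types used across the package."""


class CidscopeError(Exception):
    """Base class for all package errors."""


class UnknownLabelError(CidscopeError):
    """An allele or variant label is absent from the registry."""


class LengthMismatchError(CidscopeError):
    """A sequence does not have the length required by its slot."""


class RegionError(CidscopeError):
    """A region interval is out of bounds, empty after exclusions, or malformed."""


class CoverageError(CidscopeError):
    """Coverage profile is unusable (all-zero, wrong length, zero marker)."""


class AmpliconError(CidscopeError):
    """In-silico PCR failed or was ambiguous."""


class EnzymeError(CidscopeError):
    """A restriction-enzyme definition is invalid."""


class TableError(CidscopeError):
    """A tabular input is missing required rows/columns."""


class AlignmentError(CidscopeError):
    """A sequence alignment is ragged or otherwise unusable."""


class TranslationError(CidscopeError):
    """A nucleotide region cannot be translated (frame or internal stop)."""
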