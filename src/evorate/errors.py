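"""Exception hierarchy.

All package-specific failures derive from :class:`EvorateError` so callers
can catch one base class at pipeline boundaries.
"""


class EvorateError(Exception):
    """Base class for all evorate errors."""


class AlignmentError(EvorateError):
    """Malformed alignment: length mismatch, broken frame, bad alphabet."""


class EmptyAlignmentError(AlignmentError):
    """Filtering removed every sequence or every column."""


class TableError(EvorateError):
    """Malformed delimited table: missing columns, duplicates, bad cells."""


class CodonError(EvorateError):
    """Invalid codon input (stop codon, ambiguity, wrong length)."""


class StopCodonError(CodonError):
    """Internal stop codon in a coding sequence — pseudogene signal."""


class SaturationError(EvorateError):
    """Observed difference proportion at or beyond the correction's domain
    (p >= 3/4); the pair is excluded and reported."""


class ZeroVarianceError(EvorateError):
    """A correlation/regression input has no variance."""


class InsufficientDataError(EvorateError):
    """Fewer usable points/records than the operation requires."""
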