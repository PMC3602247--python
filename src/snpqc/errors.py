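"""Exception hierarchy shared by all snpqc modules.

Every error raised on purpose derives from :class:`SnpQcError`, so callers
(and the CLI) can catch one base class. Parse-level errors carry the line
number or archive member that triggered them in the message.
"""


class SnpQcError(Exception):
    """Base class for all snpqc errors."""


class FormatError(SnpQcError):
    """Input file is not in any supported dialect."""


class EmptyInputError(FormatError):
    """A stream, archive or manifest contained no usable content."""


class MixedFormatError(FormatError):
    """A zip archive mixes plate files of different dialects."""


class ParseError(SnpQcError):
    """A data row could not be parsed (message names the line)."""


class DuplicateWellError(ParseError):
    """The same (well, assay) combination occurred twice in one plate."""


class ConfigurationError(SnpQcError):
    """Inconsistent study configuration (e.g. manifest ID equals a control token)."""


class AmbiguousAssayError(SnpQcError):
    """An allelic-discrimination assay did not expose exactly two detectors."""


class IncompleteMapError(SnpQcError):
    """A conversion map still has unmapped tokens at approval time."""


class CheckpointError(SnpQcError):
    """A mandatory confirmation checkpoint was not passed."""


class StaleMapError(SnpQcError):
    """A call token is missing from an approved conversion map."""


class InvalidAlleleError(SnpQcError):
    """An allele character outside {A, C, G, T} was supplied."""


class MultiAllelicError(SnpQcError):
    """More than two distinct alleles observed for one SNP."""


class NameCollisionError(SnpQcError):
    """Two results or columns would share the same SNP identifier."""


class EmptySelectionError(SnpQcError):
    """An export was requested for an empty SNP selection."""


class DuplicateKeyError(SnpQcError):
    """A keyed table (reference table, phenotype file) repeats a key."""


class ValidationError(SnpQcError):
    """A value failed a domain validity check (e.g. negative count)."""


class CodingError(SnpQcError):
    """A phenotype token is absent from the user-supplied sex coding."""


class StoreError(SnpQcError):
    """Project-store level failure."""


class NotFoundError(StoreError):
    """A study or result was not found in the project store."""
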