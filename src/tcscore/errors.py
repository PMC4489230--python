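"""Exception hierarchy.

Every error raised by the public API derives from :class:`TcsError` so the
CLI can map any failure to a one-line diagnostic and a nonzero exit code.
"""


class TcsError(Exception):
    """Base class for all tcscore errors."""


class AlignmentFormatError(TcsError):
    """The input could not be recognised or parsed as any supported format."""


class MalformedAlignmentError(TcsError):
    """Parsed content violates alignment invariants (row lengths, names...)."""


class AlphabetError(TcsError):
    """A sequence contains symbols the active parameter set cannot emit."""


class LibraryError(TcsError):
    """Invalid residue-pair library operation (mismatched sequence sets...)."""


class BackendIntegrityError(TcsError):
    """A proxy-MSA backend returned an alignment with mutated content."""


class EmptyAlignmentError(TcsError):
    """An operation removed every column and no empty-column fallback applies."""


class PairScoresUnavailableError(TcsError):
    """Pair-level scores were discarded; rerun with pair retention."""
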