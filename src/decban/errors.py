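"""Exception hierarchy shared across the package.

All errors raised by decban derive from :class:`DecbanError`, so callers
(including the CLI) can distinguish domain failures from programming bugs.
"""


class DecbanError(Exception):
    """Base class for all decban-specific errors."""


class InvalidSequenceError(DecbanError, ValueError):
    """A nucleotide sequence is empty or contains non-IUPAC characters."""


class SequenceTooShortError(DecbanError, ValueError):
    """A sequence is shorter than one k-mer word."""


class TranslationError(DecbanError, ValueError):
    """A word contains characters that cannot be translated as codons."""


class EmbeddingLookupError(DecbanError, KeyError):
    """A token is missing from an embedding table under a strict OOV policy."""


class EmbeddingFormatError(DecbanError, ValueError):
    """An embedding text file is malformed (ragged dimensions, empty, ...)."""


class CannotTrainError(DecbanError, ValueError):
    """Embedding training was requested on degenerate co-occurrence counts."""


class ConfigError(DecbanError, ValueError):
    """A configuration object is internally inconsistent."""


class ShapeError(DecbanError, ValueError):
    """Tensor shapes are incompatible with the requested operation."""


class TruncationError(DecbanError, ValueError):
    """A sequence exceeds the padding target and truncation was not allowed."""


class StratificationError(DecbanError, ValueError):
    """A class has too few members for a stratified split."""


class DivergenceError(DecbanError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


class DuplicateIdError(DecbanError, ValueError):
    """Two input records share the same identifier."""
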