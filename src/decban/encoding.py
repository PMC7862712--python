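"""Double-embedding encoding of circRNA sequences.

A sequence of length ``L`` is cut into ``m = floor(L / k)`` non-overlapping
k-mer "words" (``k = 7`` by default).  Each word is looked up in a pre-trained
RNA embedding table, and additionally translated — codon by codon, with the
codons overlapping at every offset — into a ``(k - 2)``-residue pseudo-peptide
that is looked up in a peptide embedding table.  The two vectors are
concatenated, RNA part first, giving one column of the ``(p + q) x m`` input
matrix fed to the network.

The pseudo-peptide alphabet has 21 symbols: the 20 standard amino acids plus
``*`` for the three stop codons, so translation is total over {A,C,G,U}^3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EmbeddingLookupError,
    InvalidSequenceError,
    SequenceTooShortError,
    TranslationError,
    TruncationError,
)

logger = logging.getLogger(__name__)

DEFAULT_K = 7

#: Minimum / maximum sequence length (nt) retained by default preprocessing.
DEFAULT_MIN_LEN = 500
DEFAULT_MAX_LEN = 7000

#: Default padding target: the word count of a maximum-length retained
#: sequence, floor(7000 / 7).
DEFAULT_MAX_WORDS = DEFAULT_MAX_LEN // DEFAULT_K

STOP_SYMBOL = "*"

# Standard genetic code over RNA codons; '*' marks the three stop codons.
STANDARD_GENETIC_CODE: Mapping[str, str] = {
    "UUU": "F", "UUC": "F", "UUA": "L", "UUG": "L",
    "CUU": "L", "CUC": "L", "CUA": "L", "CUG": "L",
    "AUU": "I", "AUC": "I", "AUA": "I", "AUG": "M",
    "GUU": "V", "GUC": "V", "GUA": "V", "GUG": "V",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S",
    "CCU": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCU": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "UAU": "Y", "UAC": "Y", "UAA": "*", "UAG": "*",
    "CAU": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAU": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAU": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "UGU": "C", "UGC": "C", "UGA": "*", "UGG": "W",
    "CGU": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGU": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGU": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# IUPAC nucleotide one-letter codes accepted on input (besides ACGTU).
_IUPAC_AMBIGUITY = set("RYSWKMBDHVN")
_CANONICAL = set("ACGU")


@dataclass
class EmbeddingTable:
    """A static token -> vector mapping of uniform dimension.

    ``oov_policy`` controls lookup of unseen tokens: ``"zero"`` returns the
    all-zero vector (and logs once per table), ``"error"`` raises
    :class:`EmbeddingLookupError`.
    """

    dimension: int
    vectors: dict[str, np.ndarray]
    oov_policy: str = "zero"
    _warned_oov: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.oov_policy not in ("zero", "error"):
            raise ValueError(f"unknown oov_policy: {self.oov_policy!r}")
        for tok, vec in self.vectors.items():
            if vec.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {tok!r} has shape {vec.shape}, "
                    f"expected ({self.dimension},)"
                )

    def __len__(self) -> int:
        return len(self.vectors)

    def lookup(self, token: str) -> np.ndarray:
        vec = self.vectors.get(token)
        if vec is not None:
            return vec
        if self.oov_policy == "error":
            raise EmbeddingLookupError(f"token not in embedding table: {token!r}")
        if not self._warned_oov:
            logger.warning(
                "token %r not in embedding table; using zero vector "
                "(further OOV lookups logged at DEBUG)", token,
            )
            self._warned_oov = True
        else:
            logger.debug("OOV token %r -> zero vector", token)
        return np.zeros(self.dimension, dtype=np.float32)


@dataclass
class EncodedSequence:
    """The (p+q) x m double-embedding matrix for one sequence."""

    matrix: np.ndarray  # shape (p + q, m)
    m: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.m:
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with m={self.m}"
            )


def normalize_sequence(raw: str, ambiguous: str = "replace") -> str:
    """Uppercase, convert DNA to RNA (T -> U), and resolve ambiguity codes.

    ``ambiguous="replace"`` substitutes every IUPAC ambiguity code with 'A'
    (deterministic, logged); ``ambiguous="strict"`` raises instead.  Empty
    input and non-IUPAC characters always raise :class:`InvalidSequenceError`.
    """
    if not raw:
        raise InvalidSequenceError("empty sequence")
    seq = raw.upper().replace("T", "U")
    out = []
    n_replaced = 0
    for pos, ch in enumerate(seq):
        if ch in _CANONICAL:
            out.append(ch)
        elif ch in _IUPAC_AMBIGUITY:
            if ambiguous == "strict":
                raise InvalidSequenceError(
                    f"ambiguous base {ch!r} at position {pos} (strict mode)"
                )
            out.append("A")
            n_replaced += 1
        else:
            raise InvalidSequenceError(
                f"invalid character {ch!r} at position {pos}"
            )
    if n_replaced:
        logger.warning(
            "replaced %d ambiguous base(s) with 'A' during normalization",
            n_replaced,
        )
    return "".join(out)


def filter_by_length(
    sequences: Sequence,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    length_of=len,
) -> tuple[list, int]:
    """Keep sequences with ``min_len <= L <= max_len`` (bounds inclusive).

    Order is preserved.  Returns ``(kept, n_removed)``; the removal count is
    also logged.  ``length_of`` extracts the length from an item, so the
    function works on raw strings as well as ``(id, seq)`` pairs.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = [s for s in sequences if min_len <= length_of(s) <= max_len]
    n_removed = len(sequences) - len(kept)
    if n_removed:
        logger.info(
            "length filter [%d, %d]: removed %d of %d sequences",
            min_len, max_len, n_removed, len(sequences),
        )
    return kept, n_removed


def segment_sequence(seq: str, k: int = DEFAULT_K) -> list[str]:
    """Cut ``seq`` into floor(L/k) non-overlapping k-mer words.

    The trailing remainder of fewer than k nucleotides is discarded: no
    partial-word token exists in the embedding vocabulary.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    if len(seq) < k:
        raise SequenceTooShortError(
            f"sequence of length {len(seq)} is shorter than one {k}-mer word"
        )
    m = len(seq) // k
    return [seq[i * k : (i + 1) * k] for i in range(m)]


def translate_word(
    word: str, code: Mapping[str, str] = STANDARD_GENETIC_CODE
) -> str:
    """Translate a k-mer into its (k-2)-residue pseudo-peptide.

    The k - 2 codons overlap: residue ``j`` is the translation of
    ``word[j:j+3]``.  Stop codons map to '*', so the output alphabet has 21
    symbols and translation never fails on {A,C,G,U} input.
    """
    if len(word) < 3:
        raise TranslationError(f"word {word!r} shorter than one codon")
    residues = []
    for j in range(len(word) - 2):
        codon = word[j : j + 3]
        try:
            residues.append(code[codon])
        except KeyError:
            raise TranslationError(
                f"cannot translate codon {codon!r} in word {word!r}"
            ) from None
    return "".join(residues)


def encode_sequence(
    seq: str,
    rna_table: EmbeddingTable,
    pep_table: EmbeddingTable,
    k: int = DEFAULT_K,
    source_id: str = "",
) -> EncodedSequence:
    """Build the (p+q) x m double-embedding matrix for one RNA sequence.

    Column i is the RNA embedding of word w_i concatenated with the peptide
    embedding of its pseudo-peptide translation, RNA part on top.
    """
    words = segment_sequence(seq, k)
    p, q = rna_table.dimension, pep_table.dimension
    mat = np.empty((p + q, len(words)), dtype=np.float32)
    for i, w in enumerate(words):
        mat[:p, i] = rna_table.lookup(w)
        mat[p:, i] = pep_table.lookup(translate_word(w))
    return EncodedSequence(matrix=mat, m=len(words), source_id=source_id)


def pad_batch(
    encoded: Iterable[EncodedSequence], target_m: int
) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad encoded sequences with zero columns into one batch tensor.

    Returns ``(batch, mask)`` with ``batch`` of shape ``(B, p+q, target_m)``
    and a boolean ``mask`` of shape ``(B, target_m)`` marking true-data
    columns.  A sequence longer than ``target_m`` raises
    :class:`TruncationError`; truncation is never silent.
    """
    encoded = list(encoded)
    if not encoded:
        raise ValueError("empty batch")
    dim = encoded[0].matrix.shape[0]
    for e in encoded:
        if e.m > target_m:
            raise TruncationError(
                f"sequence {e.source_id!r} has m={e.m} > target_m={target_m}"
            )
        if e.matrix.shape[0] != dim:
            raise ValueError("inconsistent embedding dimensions in batch")
    batch = np.zeros((len(encoded), dim, target_m), dtype=np.float32)
    mask = np.zeros((len(encoded), target_m), dtype=bool)
    for b, e in enumerate(encoded):
        batch[b, :, : e.m] = e.matrix
        mask[b, : e.m] = True
    return batch, mask
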