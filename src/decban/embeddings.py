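"""Desk-scale GloVe pre-training of k-mer and pseudo-peptide embeddings.

Embeddings of this kind are ideally pre-trained on genome-scale corpora;
this module trains the same weighted least-squares objective on whatever
corpus the user supplies, so the encoder is exercisable end to end without
downloads, and reads/writes the plain-text "token v1 v2 ..." embedding
dialect so externally pre-trained tables can be dropped in.

The objective is

    J = sum_ij f(X_ij) (w_i . w~_j + b_i + b~_j - log X_ij)^2

with f(x) = (x / x_max)^alpha clipped at 1, minimized by AdaGrad over
shuffled mini-chunks of the nonzero co-occurrence entries.  The returned
vector for token i is w_i + w~_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp

from .encoding import DEFAULT_K, EmbeddingTable, segment_sequence, translate_word
from .errors import CannotTrainError, EmbeddingFormatError

logger = logging.getLogger(__name__)

TOKEN_KINDS = ("rna_word", "pseudo_peptide")


@dataclass
class CooccurrenceCounts:
    """Symmetric, zero-diagonal weighted co-occurrence counts.

    ``counts`` is a sparse matrix over ``vocabulary`` indices; entry (i, j)
    accumulates 1/d for every ordered pair of tokens at sentence distance
    d <= window.
    """

    vocabulary: list[str]
    counts: sp.csr_matrix
    window: int

    @property
    def n_tokens(self) -> int:
        return len(self.vocabulary)


@dataclass
class GloveTrainConfig:
    dimension: int = 32
    epochs: int = 15
    learning_rate: float = 0.05
    x_max: float = 100.0
    alpha: float = 0.75
    seed: int = 0
    chunk_size: int = 200_000

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")


def tokenize_corpus(
    records: Iterable[tuple[str, str]] | Iterable[str],
    token_kind: str = "rna_word",
    k: int = DEFAULT_K,
) -> Iterator[list[str]]:
    """Yield one sentence of non-overlapping k-mer tokens per record.

    ``records`` may be raw sequences or ``(id, sequence)`` pairs, already
    normalized (uppercase RNA).  With ``token_kind="pseudo_peptide"`` each
    token is the (k-2)-residue translation of the corresponding k-mer, so
    sentence lengths are identical between the two kinds.
    """
    if token_kind not in TOKEN_KINDS:
        raise ValueError(f"token_kind must be one of {TOKEN_KINDS}")
    for rec in records:
        seq = rec[1] if isinstance(rec, tuple) else rec
        words = segment_sequence(seq, k)
        if token_kind == "pseudo_peptide":
            words = [translate_word(w) for w in words]
        yield words


def build_cooccurrence(
    sentences: Iterable[Sequence[str]], window: int = 10
) -> CooccurrenceCounts:
    """Accumulate distance-weighted co-occurrence counts X_ij.

    Tokens at sentence distance d <= window contribute 1/d to both X_ij and
    X_ji; pairs never cross sentence boundaries, and self co-occurrences
    (the diagonal) are dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    vocab: dict[str, int] = {}
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for sent in sentences:
        ids = np.fromiter(
            (vocab.setdefault(t, len(vocab)) for t in sent),
            dtype=np.int64,
            count=len(sent),
        )
        for d in range(1, min(window, len(ids) - 1) + 1):
            i, j = ids[:-d], ids[d:]
            keep = i != j
            if not keep.all():
                i, j = i[keep], j[keep]
            # canonicalize to the upper triangle so that mirroring below
            # yields exact (not merely floating-point) symmetry
            lo, hi = np.minimum(i, j), np.maximum(i, j)
            rows.append(lo)
            cols.append(hi)
            vals.append(np.full(len(lo), 1.0 / d))
    n = len(vocab)
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        v = np.concatenate(vals)
        upper = sp.coo_matrix((v, (r, c)), shape=(n, n)).tocsr()
        counts = upper + upper.T
    else:
        counts = sp.csr_matrix((n, n))
    return CooccurrenceCounts(
        vocabulary=list(vocab), counts=counts, window=window
    )


def train_glove(
    counts: CooccurrenceCounts, config: GloveTrainConfig | None = None
) -> EmbeddingTable:
    """Fit GloVe vectors to ``counts`` by AdaGrad; fully seed-deterministic.

    Raises :class:`CannotTrainError` when the counts are degenerate (fewer
    than two tokens or no nonzero entry).
    """
    config = config or GloveTrainConfig()
    coo = counts.counts.tocoo()
    if counts.n_tokens < 2 or coo.nnz == 0:
        raise CannotTrainError(
            "co-occurrence counts are degenerate (need >= 2 tokens "
            "and >= 1 nonzero entry)"
        )
    ii = coo.row.astype(np.int64)
    jj = coo.col.astype(np.int64)
    x = coo.data.astype(np.float64)
    logx = np.log(x)
    fx = np.minimum((x / config.x_max) ** config.alpha, 1.0)

    n, dim = counts.n_tokens, config.dimension
    rng = np.random.default_rng(config.seed)
    scale = 0.5 / dim
    w = rng.uniform(-scale, scale, size=(n, dim))
    wc = rng.uniform(-scale, scale, size=(n, dim))
    b = rng.uniform(-scale, scale, size=n)
    bc = rng.uniform(-scale, scale, size=n)
    # AdaGrad accumulators start at 1 so the first step size equals lr.
    gw, gwc = np.ones((n, dim)), np.ones((n, dim))
    gb, gbc = np.ones(n), np.ones(n)

    lr = config.learning_rate
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(coo.nnz)
        total = 0.0
        for start in range(0, coo.nnz, config.chunk_size):
            sel = order[start : start + config.chunk_size]
            i, j = ii[sel], jj[sel]
            wi, wj = w[i], wc[j]
            resid = (wi * wj).sum(axis=1) + b[i] + bc[j] - logx[sel]
            fsel = fx[sel]
            total += float(fsel @ resid**2)
            g = 2.0 * fsel * resid  # dJ/d(residual)
            grad_wi = g[:, None] * wj
            grad_wj = g[:, None] * wi
            np.add.at(w, i, -lr * grad_wi / np.sqrt(gw[i]))
            np.add.at(wc, j, -lr * grad_wj / np.sqrt(gwc[j]))
            np.add.at(b, i, -lr * g / np.sqrt(gb[i]))
            np.add.at(bc, j, -lr * g / np.sqrt(gbc[j]))
            np.add.at(gw, i, grad_wi**2)
            np.add.at(gwc, j, grad_wj**2)
            np.add.at(gb, i, g**2)
            np.add.at(gbc, j, g**2)
        history.append(total)
        logger.debug("glove epoch %d: loss %.6g", epoch + 1, total)
    logger.info(
        "glove: %d tokens, dim %d, %d epochs, loss %.6g -> %.6g",
        n, dim, config.epochs, history[0], history[-1],
    )

    merged = (w + wc).astype(np.float32)
    vectors = {tok: merged[idx] for idx, tok in enumerate(counts.vocabulary)}
    table = EmbeddingTable(dimension=dim, vectors=vectors)
    table.training_loss = history  # type: ignore[attr-defined]
    # raw factors kept for diagnostics: the objective is defined on
    # (w, w~, b, b~), not on the merged output vectors
    table.factors = (w, wc, b, bc)  # type: ignore[attr-defined]
    return table


def write_embeddings(table: EmbeddingTable, path) -> None:
    """Write a table in the plain-text dialect: token then reals, one per line."""
    if not table.vectors:
        raise ValueError("refusing to write an empty embedding table")
    with open(path, "w") as fh:
        for tok, vec in table.vectors.items():
            fh.write(tok + " " + " ".join(f"{v:.6f}" for v in vec) + "\n")


def read_embeddings(path, oov_policy: str = "zero") -> EmbeddingTable:
    """Read a plain-text embedding file, validating a uniform dimension."""
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            tok = parts[0]
            try:
                vec = np.array([float(v) for v in parts[1:]], dtype=np.float32)
            except ValueError as exc:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno}: non-numeric value ({exc})"
                ) from None
            if dim is None:
                dim = len(vec)
                if dim == 0:
                    raise EmbeddingFormatError(
                        f"{path}: line {lineno}: token without vector"
                    )
            elif len(vec) != dim:
                raise EmbeddingFormatError(
                    f"{path}: line {lineno}: dimension {len(vec)} != {dim}"
                )
            vectors[tok] = vec
    if dim is None:
        raise EmbeddingFormatError(f"{path}: empty embedding file")
    return EmbeddingTable(dimension=dim, vectors=vectors, oov_policy=oov_policy)
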