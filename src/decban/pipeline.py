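"""Training and evaluation pipeline.

Assembles labeled datasets, performs the stratified 7:3 train/test split,
trains the network with Adam (lr 0.001) under early stopping (patience 10,
monitored on a validation slice carved out of the training portion so the
test set stays untouched), and evaluates with F1 and ROC/AUC.

Batches are bucketed by word count: sequences are sorted by length, grouped,
and each batch is zero-padded only to its own longest member, which keeps the
valid-convolution cost proportional to the true sequence lengths.  Only the
batch visiting order is shuffled, so runs are seed-deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, f1_score, roc_curve, auc as sk_auc
from sklearn.model_selection import train_test_split

from . import network
from .encoding import (
    DEFAULT_K,
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    EmbeddingTable,
    EncodedSequence,
    encode_sequence,
    filter_by_length,
    normalize_sequence,
    pad_batch,
)
from .errors import (
    DivergenceError,
    DuplicateIdError,
    StratificationError,
    TruncationError,
)
from .network import Adam, CbanModel, backward, cross_entropy, forward

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    patience: int = 10
    max_epochs: int = 100
    batch_size: int = 32
    train_fraction: float = 0.7
    val_fraction: float = 0.1  # of the training portion, for early stopping
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class LabeledDataset:
    """Encoded sequences with binary labels and a train/test partition."""

    ids: list[str]
    encoded: list[EncodedSequence]
    labels: np.ndarray  # int, 0/1
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateIdError("dataset ids are not unique")
        self.labels = np.asarray(self.labels, dtype=int)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def class_balance(self) -> float:
        return float(self.labels.mean())

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class EvalReport:
    f1: float
    auc: float
    roc_points: list[tuple[float, float]]
    confusion: dict[str, int]  # TP / FP / TN / FN at threshold 0.5
    history: dict[str, list[float]] = field(default_factory=dict)


def split_dataset(
    dataset: LabeledDataset, train_fraction: float = 0.7, seed: int = 0
) -> LabeledDataset:
    """Stratified seeded split; sizes per class within 1 of the exact fractions."""
    if len(dataset) == 0:
        raise ValueError("cannot split an empty dataset")
    classes, counts = np.unique(dataset.labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise StratificationError(
            "stratified split needs >= 2 members in each class"
        )
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        shuffle=True,
        stratify=dataset.labels,
    )
    dataset.train_idx = np.sort(train_idx)
    dataset.test_idx = np.sort(test_idx)
    return dataset


def build_dataset(
    records: list[tuple[str, str]],
    labels: dict[str, int],
    rna_table: EmbeddingTable,
    pep_table: EmbeddingTable,
    k: int = DEFAULT_K,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    max_words: int | None = None,
) -> LabeledDataset:
    """Normalize, length-filter, and encode labeled FASTA records.

    ``max_words``, when given, truncates longer encodings to the first
    ``max_words`` words; the count of truncated sequences is logged (the
    padding layer itself never truncates silently).
    """
    kept, n_removed = filter_by_length(
        records, min_len, max_len, length_of=lambda r: len(r[1])
    )
    ids, encoded, y = [], [], []
    n_trunc = 0
    for rid, seq in kept:
        if rid not in labels:
            raise KeyError(f"no label for sequence {rid!r}")
        enc = encode_sequence(
            normalize_sequence(seq), rna_table, pep_table, k, source_id=rid
        )
        if max_words is not None and enc.m > max_words:
            enc = EncodedSequence(
                matrix=enc.matrix[:, :max_words], m=max_words, source_id=rid
            )
            n_trunc += 1
        ids.append(rid)
        encoded.append(enc)
        y.append(labels[rid])
    if n_trunc:
        logger.info("truncated %d sequence(s) to %d words", n_trunc, max_words)
    return LabeledDataset(ids=ids, encoded=encoded, labels=np.array(y))


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record an epoch's monitored loss; return True when training should stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _bucketed_batches(
    dataset: LabeledDataset, indices: np.ndarray, batch_size: int
) -> list[np.ndarray]:
    """Group indices into batches of similar word count (ascending)."""
    order = indices[np.argsort([dataset.encoded[i].m for i in indices],
                               kind="stable")]
    return [order[s : s + batch_size] for s in range(0, len(order), batch_size)]


def _forward_batch(model: CbanModel, dataset: LabeledDataset,
                   batch_idx: np.ndarray):
    enc = [dataset.encoded[i] for i in batch_idx]
    target = max(e.m for e in enc)
    batch, mask = pad_batch(enc, target)
    lengths = mask.sum(axis=1)
    trace = forward(model, batch, lengths=lengths)
    return trace, dataset.labels[batch_idx]


def _dataset_loss(model, dataset, indices, batch_size) -> float:
    total, n = 0.0, 0
    for b in _bucketed_batches(dataset, indices, batch_size):
        trace, y = _forward_batch(model, dataset, b)
        total += cross_entropy(trace.probs, y) * len(b)
        n += len(b)
    return total / max(n, 1)


def train(
    model: CbanModel,
    dataset: LabeledDataset,
    config: TrainConfig | None = None,
) -> tuple[CbanModel, dict[str, list[float]]]:
    """Train by Adam with early stopping; returns the best-scoring parameters.

    The monitored quantity is cross-entropy on a stratified validation slice
    (``val_fraction`` of the training portion).  Stops after ``patience``
    consecutive non-improving epochs or at ``max_epochs``; the parameters
    restored are those of the best monitored epoch, never the last.
    """
    config = config or TrainConfig()
    if dataset.train_idx is None:
        split_dataset(dataset, config.train_fraction, config.seed)
    rng = np.random.default_rng(config.seed)

    tr = dataset.train_idx
    y_tr = dataset.labels[tr]
    if config.val_fraction > 0 and np.unique(y_tr).size == 2:
        fit_idx, val_idx = train_test_split(
            tr, test_size=config.val_fraction,
            random_state=config.seed, stratify=y_tr,
        )
    else:
        fit_idx, val_idx = tr, tr  # degenerate fallback: monitor train loss

    opt = Adam(model.params, lr=config.learning_rate)
    stopper = EarlyStopper(config.patience)
    best_params = model.copy_params()
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    batches = _bucketed_batches(dataset, np.asarray(fit_idx), config.batch_size)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(batches))
        total, n = 0.0, 0
        for bi in order:
            b = batches[bi]
            trace, y = _forward_batch(model, dataset, b)
            loss = cross_entropy(trace.probs, y)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            grads = backward(model, trace, y)
            opt.step(model.params, grads)
            total += loss * len(b)
            n += len(b)
        train_loss = total / n
        val_loss = _dataset_loss(model, dataset, np.asarray(val_idx),
                                 config.batch_size)
        if not np.isfinite(val_loss):
            raise DivergenceError(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        improved = val_loss < stopper.best
        stop = stopper.update(val_loss, epoch)
        if improved:
            best_params = model.copy_params()
        logger.info(
            "epoch %d: train loss %.4f, monitored loss %.4f%s",
            epoch, train_loss, val_loss, " *" if improved else "",
        )
        if stop:
            logger.info(
                "early stopping at epoch %d (best epoch %d)",
                epoch, stopper.best_epoch,
            )
            break
    model.params = best_params
    return model, history


def predict_scores(
    model: CbanModel, dataset: LabeledDataset, indices: np.ndarray,
    batch_size: int = 32,
) -> np.ndarray:
    """Positive-class probability per requested sample, in `indices` order."""
    scores = np.empty(len(indices), dtype=float)
    pos = {int(i): n for n, i in enumerate(indices)}
    for b in _bucketed_batches(dataset, np.asarray(indices), batch_size):
        trace, _ = _forward_batch(model, dataset, b)
        for row, i in enumerate(b):
            scores[pos[int(i)]] = trace.probs[row, 1]
    return scores


def evaluate(
    model: CbanModel,
    dataset: LabeledDataset,
    part: str = "test",
    history: dict[str, list[float]] | None = None,
) -> EvalReport:
    """F1 (threshold 0.5) and trapezoidal ROC/AUC on the requested partition.

    On a single-class evaluation set the AUC is undefined and reported as
    NaN with a warning; F1 is still computed.
    """
    indices = {"train": dataset.train_idx, "test": dataset.test_idx}.get(
        part
    )
    if indices is None:
        raise ValueError(f"unknown or missing partition {part!r}")
    if len(indices) == 0:
        raise ValueError("empty evaluation set")
    y = dataset.labels[indices]
    scores = predict_scores(model, dataset, indices)
    pred = (scores >= 0.5).astype(int)
    f1 = float(f1_score(y, pred, zero_division=0))
    cm = confusion_matrix(y, pred, labels=[0, 1])
    confusion = {"TN": int(cm[0, 0]), "FP": int(cm[0, 1]),
                 "FN": int(cm[1, 0]), "TP": int(cm[1, 1])}
    if np.unique(y).size < 2:
        logger.warning("single-class evaluation set: AUC undefined (NaN)")
        auc_val, roc_points = float("nan"), []
    else:
        fpr, tpr, _ = roc_curve(y, scores)
        auc_val = float(sk_auc(fpr, tpr))
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
    return EvalReport(f1=f1, auc=auc_val, roc_points=roc_points,
                      confusion=confusion, history=history or {})


def predict(
    model: CbanModel,
    records: list[tuple[str, str]],
    rna_table: EmbeddingTable,
    pep_table: EmbeddingTable,
    k: int = DEFAULT_K,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score FASTA records; returns (predictions, rejects).

    Sequences failing the length policy or normalization are reported in the
    rejects table with a reason, never silently dropped.
    """
    seen: set[str] = set()
    rows, rejects = [], []
    for rid, seq in records:
        if rid in seen:
            raise DuplicateIdError(f"duplicate record id: {rid!r}")
        seen.add(rid)
        if not (min_len <= len(seq) <= max_len):
            rejects.append({"sequence_id": rid, "reason": "length",
                            "detail": f"L={len(seq)} outside "
                                      f"[{min_len}, {max_len}]"})
            continue
        try:
            enc = encode_sequence(normalize_sequence(seq), rna_table,
                                  pep_table, k, source_id=rid)
        except Exception as exc:  # invalid characters etc.
            rejects.append({"sequence_id": rid, "reason": "encoding",
                            "detail": str(exc)})
            continue
        m = min(enc.m, model.config.max_words)
        if m < enc.m:
            enc = EncodedSequence(enc.matrix[:, :m], m, rid)
        trace = forward(model, enc.matrix[None], lengths=np.array([enc.m]))
        prob = float(trace.probs[0, 1])
        rows.append({"sequence_id": rid, "m": enc.m,
                     "prob_bound": prob, "label": int(prob >= 0.5)})
    cols = ["sequence_id", "m", "prob_bound", "label"]
    rcols = ["sequence_id", "reason", "detail"]
    return (pd.DataFrame(rows, columns=cols),
            pd.DataFrame(rejects, columns=rcols))


# ---------------------------------------------------------------------------
# end-to-end synthetic benchmark
# ---------------------------------------------------------------------------

def run_synthetic_benchmark(
    seed: int = 0,
    n_sequences: int = 2000,
    max_words: int = 1000,
    embedding_dim: int = 32,
    glove_epochs: int = 6,
    glove_window: int = 3,
    max_epochs: int = 12,
    model_overrides: dict | None = None,
    train_overrides: dict | None = None,
):
    """Full pipeline on the default synthetic task, at desk scale.

    Generates the balanced motif-implant dataset, pre-trains GloVe tables
    for both token kinds on the *training-split* sequences (the desk-scale
    analogue of pre-training on a genome, which likewise contains the
    binding sites; the held-out 30% and all labels stay untouched), encodes,
    trains the network, and evaluates on the held-out 30%.  The embedding
    epoch count, context window, and Adam epoch cap are desk-scale defaults
    chosen to keep a full run within minutes on one CPU core; all are
    overridable.

    Returns ``(report, model, dataset)``.
    """
    from .embeddings import (
        GloveTrainConfig, build_cooccurrence, tokenize_corpus, train_glove,
    )
    from .synthetic_data import SyntheticTaskConfig, generate_dataset

    task = SyntheticTaskConfig(n_sequences=n_sequences, seed=seed)
    data = generate_dataset(task)

    # record-level stratified split up front so the embedding corpus can be
    # restricted to training-split sequences
    all_idx = np.arange(len(data.records))
    y_all = np.array([data.labels[rid] for rid, _ in data.records])
    train_idx, test_idx = train_test_split(
        all_idx, train_size=0.7, random_state=seed, stratify=y_all
    )
    corpus = [data.records[i] for i in np.sort(train_idx)]

    tables = {}
    for kind in ("rna_word", "pseudo_peptide"):
        counts = build_cooccurrence(
            tokenize_corpus(corpus, kind), window=glove_window
        )
        tables[kind] = train_glove(
            counts,
            GloveTrainConfig(dimension=embedding_dim, epochs=glove_epochs,
                             seed=seed + 2),
        )
    logger.info(
        "embeddings: %d RNA tokens, %d peptide tokens",
        len(tables["rna_word"]), len(tables["pseudo_peptide"]),
    )

    dataset = build_dataset(
        data.records, data.labels, tables["rna_word"],
        tables["pseudo_peptide"], max_words=max_words,
    )
    dataset.train_idx = np.sort(train_idx)
    dataset.test_idx = np.sort(test_idx)

    mcfg = dict(input_dim=2 * embedding_dim, max_words=max_words, seed=seed)
    mcfg.update(model_overrides or {})
    model = network.init_model(network.ModelConfig(**mcfg))
    tcfg = dict(seed=seed, max_epochs=max_epochs)
    tcfg.update(train_overrides or {})
    model, history = train(model, dataset, TrainConfig(**tcfg))
    report = evaluate(model, dataset, "test", history=history)
    logger.info("held-out AUC %.4f, F1 %.4f", report.auc, report.f1)
    return report, model, dataset
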