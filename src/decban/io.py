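"""FASTA and tab-separated file handling.

Record identifiers are preserved verbatim; duplicate ids are rejected early
because downstream label joins and prediction tables key on them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DuplicateIdError


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA into (id, sequence) pairs, ids verbatim."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA record id: {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq)))
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_labels(path) -> pd.DataFrame:
    """Read the two-column ``sequence_id <TAB> {0,1}`` label file.

    A header line is optional and detected by a non-binary second field.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     names=["sequence_id", "label"])
    if df.empty:
        return pd.DataFrame(columns=["sequence_id", "label"])
    if df.iloc[0]["label"] not in ("0", "1"):
        df = df.iloc[1:].reset_index(drop=True)
    bad = ~df["label"].isin(["0", "1"])
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"{path}: non-binary label {df.loc[row, 'label']!r} at data row {row}"
        )
    if df["sequence_id"].duplicated().any():
        dup = df.loc[df["sequence_id"].duplicated(), "sequence_id"].iloc[0]
        raise DuplicateIdError(f"duplicate sequence id in labels: {dup!r}")
    df["label"] = df["label"].astype(int)
    return df


def write_labels(labels: dict[str, int] | pd.DataFrame, path) -> None:
    if isinstance(labels, dict):
        labels = pd.DataFrame(
            {"sequence_id": list(labels), "label": list(labels.values())}
        )
    labels.to_csv(path, sep="\t", header=False, index=False)


def write_tsv(df: pd.DataFrame, path, header: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", header=header, index=False)
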