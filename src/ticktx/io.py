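"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA parsing is delegated to Biopython; this layer adds the strictness the
pipeline relies on (unique ids, uppercase sequences, an explicit error when
a file does not start with a header line) and a uniform lightweight record
type that carries the description separately from the id.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class SeqEntry:
    """One FASTA record: first token of the header, sequence, and the
    remainder of the header line (may be empty)."""

    id: str
    seq: str
    description: str = ""


def read_fasta(path: str | Path) -> list:
    """Read a FASTA file into a list of :class:`SeqEntry`.

    Sequences are uppercased. Raises on duplicate ids and on files whose
    first non-blank line is not a ``>`` header (naming the line number).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}, line {lineno}: expected a '>' header line"
                    )
                break
        else:
            return []
    entries = []
    seen = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        entries.append(SeqEntry(rec.id, str(rec.seq).upper(), desc))
    return entries


def write_fasta(entries, path: str | Path, width: int = 60) -> None:
    records = []
    for e in entries:
        records.append(
            SeqRecord(Seq(e.seq), id=e.id, description=e.description or "")
        )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_counts(path: str | Path, design) -> pd.DataFrame:
    """Read a counts TSV (rows: sequence ids; columns: library ids).

    Every column must be a library of ``design`` and every library of the
    design must be present; counts must be non-negative integers with no
    missing cells (no silent zero-fill).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    declared = list(design.library_ids)
    unknown = [c for c in df.columns if c not in set(declared)]
    if unknown:
        raise ValueError(f"{path}: unknown library id(s) {unknown}")
    missing = [c for c in declared if c not in set(df.columns)]
    if missing:
        raise ValueError(f"{path}: design libraries missing from header: {missing}")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"{path}: missing counts for {bad}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise ValueError(f"{path}: non-numeric count values")
    if (numeric < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    if ((numeric % 1) != 0).any().any():
        raise ValueError(f"{path}: non-integer counts")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate row ids")
    return numeric.astype("int64")[declared]


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="id")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
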