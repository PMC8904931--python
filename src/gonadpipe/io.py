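"""Plain-text readers and writers shared across the pipeline.

Sequence pools travel as FASTA/FASTQ (qualities are ignored), tabular
artifacts as headered TSV.  Everything here is deterministic: writing the
same objects twice produces byte-identical files.
"""

from __future__ import annotations

import os
from collections import OrderedDict
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_FASTA_SUFFIXES = {".fa", ".fasta", ".fna", ".faa"}
_FASTQ_SUFFIXES = {".fq", ".fastq"}


def _infer_format(path: str) -> str:
    suffix = os.path.splitext(str(path))[1].lower()
    if suffix in _FASTA_SUFFIXES:
        return "fasta"
    if suffix in _FASTQ_SUFFIXES:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from suffix {suffix!r}")


def read_sequences(path, fmt: str | None = None) -> "OrderedDict[str, str]":
    """Read a FASTA or FASTQ file into an ordered ``{read_id: sequence}`` map.

    FASTQ quality strings are discarded.  Duplicate record ids are rejected
    because every downstream structure keys on the read id.
    """
    fmt = fmt or _infer_format(path)
    pool: OrderedDict[str, str] = OrderedDict()
    for record in SeqIO.parse(str(path), fmt):
        if record.id in pool:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
        pool[record.id] = str(record.seq).upper()
    return pool


def write_fasta(path, records: Mapping[str, str] | Iterable[tuple[str, str]],
                descriptions: Mapping[str, str] | None = None) -> None:
    """Write ``{id: sequence}`` (or ``(id, sequence)`` pairs) as FASTA."""
    if isinstance(records, Mapping):
        records = records.items()
    seq_records = [
        SeqRecord(Seq(seq), id=name,
                  description=(descriptions or {}).get(name, ""))
        for name, seq in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def write_tsv(frame: pd.DataFrame, path) -> None:
    """Write a DataFrame as headered, index-free TSV."""
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
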