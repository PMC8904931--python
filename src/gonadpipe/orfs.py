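"""ORF calling on stranded reads and construction of the protein search database.

Reads from full-length cDNA sequencing are sense-stranded, so only the
three forward frames are scanned.  Every initiator ATG whose in-frame
extension reaches a stop codon on the read yields one candidate call; a
candidate must encode at least 30 residues (initiator Met included, stop
excluded).  Per read, candidates are then reduced to the longest possible
non-overlapping set by a greedy pass over descending protein length, with
overlap judged on nucleotide coordinates across frames.  Translations seen
on at least two distinct reads enter the protein search database used for
downstream proteomics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .clustering import ClusterAssignment
from .io import write_tsv

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)  # TAA, TAG, TGA
_ALPHABET = frozenset("ACGTN")

MIN_PROTEIN_LENGTH = 30


@dataclass(frozen=True)
class OrfCall:
    """One candidate coding region on a read.

    ``nt_start``/``nt_end`` are 0-based half-open nucleotide coordinates on
    the read; ``nt_end`` is just past the stop codon.  ``protein`` includes
    the initiator Met and excludes the stop.
    """

    read_id: str
    frame: int
    nt_start: int
    nt_end: int
    protein: str

    def __post_init__(self):
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if not self.protein.startswith("M"):
            raise ValueError("ORF protein must begin with Met")


@dataclass(frozen=True)
class ProteinDbEntry:
    """A database protein with its read support and source clusters."""

    entry_id: str
    protein: str
    support: int
    source_cluster_ids: frozenset


def _translate_codon(codon: str) -> str:
    # Codons containing N translate to X even when the ambiguity would
    # resolve; a codon like TAN is X, never a stop.
    return CODON_TO_AA.get(codon, "X")


def find_orfs(seq: str, read_id: str = "read",
              min_protein_length: int = MIN_PROTEIN_LENGTH) -> list[OrfCall]:
    """All Met-to-stop coding sequences of >= ``min_protein_length`` residues.

    Scans the three forward frames only (reads are stranded).  An ATG whose
    frame runs off the read without reaching a stop codon is not reported.
    Raises ``ValueError`` naming the position of any character outside
    {A,C,G,T,N}.
    """
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in _ALPHABET:
            raise ValueError(
                f"invalid nucleotide {ch!r} at position {pos} of {read_id}")
    calls: list[OrfCall] = []
    for frame in range(3):
        codons = [seq[i:i + 3] for i in range(frame, len(seq) - 2, 3)]
        stop_after: list[int | None] = [None] * len(codons)
        nxt: int | None = None
        for i in range(len(codons) - 1, -1, -1):
            if codons[i] in STOP_CODONS:
                nxt = i
            stop_after[i] = nxt
        for i, codon in enumerate(codons):
            if codon != "ATG":
                continue
            j = stop_after[i]
            if j is None or j - i < min_protein_length:
                continue
            protein = "".join(_translate_codon(c) for c in codons[i:j])
            calls.append(OrfCall(read_id=read_id, frame=frame,
                                 nt_start=frame + 3 * i,
                                 nt_end=frame + 3 * (j + 1),
                                 protein=protein))
    calls.sort(key=lambda c: (c.nt_start, c.frame))
    return calls


def select_nonoverlapping(orfs: Sequence[OrfCall]) -> list[OrfCall]:
    """Greedy longest-first selection of non-overlapping ORFs of one read.

    Candidates are taken in order of descending protein length, ties broken
    by smaller ``nt_start`` then smaller frame; a candidate is kept iff its
    nucleotide interval intersects no already-kept interval.  The result is
    maximal: no rejected candidate could be added back without overlap.
    """
    if len({c.read_id for c in orfs}) > 1:
        raise ValueError("select_nonoverlapping expects calls from a single read")
    ordered = sorted(orfs, key=lambda c: (-len(c.protein), c.nt_start, c.frame))
    kept: list[OrfCall] = []
    for cand in ordered:
        if all(cand.nt_end <= k.nt_start or cand.nt_start >= k.nt_end
               for k in kept):
            kept.append(cand)
    kept.sort(key=lambda c: c.nt_start)
    return kept


def call_reads(reads, min_protein_length: int = MIN_PROTEIN_LENGTH) -> list[OrfCall]:
    """Selected (non-overlapping) ORFs for every read in a pool.

    Identical sequences are scanned once and the calls re-labelled per
    read, which makes error-free pools (many identical copies per gene)
    cheap to process.
    """
    cache: dict[str, list[OrfCall]] = {}
    out: list[OrfCall] = []
    for read_id, seq in reads.items():
        seq = seq.upper()
        if seq not in cache:
            cache[seq] = select_nonoverlapping(
                find_orfs(seq, read_id=read_id,
                          min_protein_length=min_protein_length))
        for call in cache[seq]:
            out.append(OrfCall(read_id=read_id, frame=call.frame,
                               nt_start=call.nt_start, nt_end=call.nt_end,
                               protein=call.protein))
    return out


def build_protein_db(calls: Iterable[OrfCall], assignment: ClusterAssignment,
                     min_support: int = 2) -> list[ProteinDbEntry]:
    """Aggregate identical translations across reads into database entries.

    ``support`` counts distinct contributing reads; entries below
    ``min_support`` (default 2 reads) are dropped.  Entry ids are assigned
    deterministically by descending support then protein string.
    """
    by_protein: dict[str, set[str]] = {}
    for call in calls:
        if call.read_id not in assignment.read_to_cluster:
            raise ValueError(f"ORF call references unknown read {call.read_id!r}")
        by_protein.setdefault(call.protein, set()).add(call.read_id)
    surviving = sorted(
        ((protein, reads) for protein, reads in by_protein.items()
         if len(reads) >= min_support),
        key=lambda item: (-len(item[1]), item[0]))
    entries = []
    for i, (protein, reads) in enumerate(surviving):
        clusters = frozenset(assignment.read_to_cluster[r] for r in reads)
        entries.append(ProteinDbEntry(entry_id=f"db{i:05d}", protein=protein,
                                      support=len(reads),
                                      source_cluster_ids=clusters))
    return entries


def write_protein_fasta(entries: Iterable[ProteinDbEntry], path) -> None:
    """Protein database FASTA; headers carry support and source clusters."""
    with open(path, "w") as handle:
        for entry in entries:
            clusters = ";".join(sorted(entry.source_cluster_ids))
            handle.write(f">{entry.entry_id} support={entry.support} "
                         f"clusters={clusters}\n")
            for i in range(0, len(entry.protein), 60):
                handle.write(entry.protein[i:i + 60] + "\n")


def read_protein_fasta(path) -> list[ProteinDbEntry]:
    entries: list[ProteinDbEntry] = []
    header, chunks = None, []

    def flush():
        if header is None:
            return
        name, fields = header
        entries.append(ProteinDbEntry(
            entry_id=name, protein="".join(chunks),
            support=int(fields.get("support", 0)),
            source_cluster_ids=frozenset(
                c for c in fields.get("clusters", "").split(";") if c)))

    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                fields = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
                header, chunks = (parts[0], fields), []
            else:
                chunks.append(line)
        flush()
    return entries


def orf_calls_to_frame(calls: Iterable[OrfCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.read_id, c.frame, c.nt_start, c.nt_end, c.protein) for c in calls],
        columns=["read_id", "frame", "nt_start", "nt_end", "protein"])


def write_orf_tsv(calls: Iterable[OrfCall], path) -> None:
    write_tsv(orf_calls_to_frame(calls), path)
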