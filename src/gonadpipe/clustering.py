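"""Sample labels and gene-level clustering of stranded long reads.

Full-length cDNA long reads capture one transcript per molecule, so reads
can be grouped into gene-level clusters by raw sequence similarity with no
assembly step.  Two routes produce a :class:`ClusterAssignment`:

* :func:`import_clusters` ingests the two-column table emitted by an
  external greedy clustering tool, preserving its cluster boundaries; or
* :func:`greedy_cluster`, a deliberately simple built-in greedy
  k-mer-containment pass that lets the pipeline run self-contained on
  error-free or low-error pools.

The built-in algorithm sorts reads by descending length (ties by read id),
then each read joins the first existing cluster whose representative —
the cluster's founding, longest read — shares at least
``min_shared_fraction`` of the read's distinct k-mers; otherwise the read
founds a new cluster.  Representatives are never re-centred, which keeps
the pass deterministic and O(reads x clusters).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io import read_tsv, write_tsv

logger = logging.getLogger(__name__)

TISSUES = ("testis", "ovary")


@dataclass(frozen=True, order=True)
class SampleLabel:
    """Identity of one read pool: species, gonad tissue, biological replicate."""

    species: str
    tissue: str
    replicate: int

    def __post_init__(self):
        if self.tissue not in TISSUES:
            raise ValueError(
                f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")

    @property
    def tag(self) -> str:
        return f"{self.species}_{self.tissue}_{self.replicate}"


class ClusterAssignment:
    """A partition of reads into named clusters with one representative each.

    Invariants enforced on construction: every read belongs to exactly one
    cluster, every cluster is non-empty, and every cluster's representative
    is a member of that cluster.
    """

    def __init__(self, read_to_cluster: Mapping[str, str],
                 representatives: Mapping[str, str]):
        self.read_to_cluster: "OrderedDict[str, str]" = OrderedDict(read_to_cluster)
        self.representatives: "OrderedDict[str, str]" = OrderedDict(representatives)
        self._members: "OrderedDict[str, list[str]]" = OrderedDict(
            (c, []) for c in self.representatives)
        for read, cluster in self.read_to_cluster.items():
            if cluster not in self._members:
                raise ValueError(f"read {read!r} assigned to unknown cluster {cluster!r}")
            self._members[cluster].append(read)
        for cluster, reads in self._members.items():
            if not reads:
                raise ValueError(f"cluster {cluster!r} is empty")
            rep = self.representatives[cluster]
            if rep not in set(reads):
                raise ValueError(
                    f"representative {rep!r} is not a member of cluster {cluster!r}")

    @property
    def members(self) -> Mapping[str, list[str]]:
        return self._members

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def cluster_sizes(self) -> dict[str, int]:
        return {c: len(reads) for c, reads in self._members.items()}

    def to_frame(self) -> pd.DataFrame:
        """Two-column table, representative listed first within each cluster."""
        rows = []
        for cluster, reads in self._members.items():
            rep = self.representatives[cluster]
            ordered = [rep] + [r for r in reads if r != rep]
            rows.extend((r, cluster) for r in ordered)
        return pd.DataFrame(rows, columns=["read_id", "cluster_id"])

    def write_tsv(self, path) -> None:
        write_tsv(self.to_frame(), path)


def import_clusters(table) -> ClusterAssignment:
    """Build a :class:`ClusterAssignment` from a read_id/cluster_id table.

    ``table`` may be a DataFrame or a path to a headered TSV.  The
    representative of each cluster is its first-listed read, so tables
    written by :meth:`ClusterAssignment.write_tsv` round-trip exactly.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_tsv(table, dtype=str)
    missing = {"read_id", "cluster_id"} - set(table.columns)
    if missing:
        raise ValueError(f"assignment table lacks column(s): {sorted(missing)}")
    read_to_cluster: "OrderedDict[str, str]" = OrderedDict()
    representatives: "OrderedDict[str, str]" = OrderedDict()
    for read, cluster in zip(table["read_id"].astype(str),
                             table["cluster_id"].astype(str)):
        if read in read_to_cluster:
            raise ValueError(f"read id {read!r} listed more than once")
        read_to_cluster[read] = cluster
        representatives.setdefault(cluster, read)
    return ClusterAssignment(read_to_cluster, representatives)


def _kmers(seq: str, k: int) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def greedy_cluster(reads: Mapping[str, str], k: int = 15,
                   min_shared_fraction: float = 0.5) -> ClusterAssignment:
    """Greedy k-mer-containment clustering of a ``{read_id: sequence}`` pool.

    Deterministic for any input order of ``reads``: reads are processed in
    descending length order with ties broken by read id.  A read shorter
    than ``k`` carries no k-mers and becomes a singleton cluster (logged).
    """
    if k < 5:
        raise ValueError(f"k must be >= 5, got {k}")
    if not (0 < min_shared_fraction <= 1):
        raise ValueError(
            f"min_shared_fraction must be in (0, 1], got {min_shared_fraction}")

    order = sorted(reads, key=lambda r: (-len(reads[r]), r))
    kmer_cache: dict[str, frozenset] = {}
    # Valid because clusters are append-only and representatives fixed:
    # identical sequences always hit the same first matching cluster.
    decision_cache: dict[str, str] = {}

    read_to_cluster: "OrderedDict[str, str]" = OrderedDict()
    representatives: "OrderedDict[str, str]" = OrderedDict()
    rep_kmers: list[tuple[str, frozenset]] = []  # founding order

    def new_cluster(read: str, km: frozenset) -> str:
        cluster = f"c{len(representatives):06d}"
        representatives[cluster] = read
        rep_kmers.append((cluster, km))
        return cluster

    for read in order:
        seq = reads[read]
        if len(seq) < k:
            logger.info("read %s shorter than k=%d; singleton cluster", read, k)
            read_to_cluster[read] = new_cluster(read, frozenset())
            continue
        if seq in decision_cache:
            read_to_cluster[read] = decision_cache[seq]
            continue
        km = kmer_cache.get(seq)
        if km is None:
            km = kmer_cache[seq] = _kmers(seq, k)
        chosen = None
        need = min_shared_fraction * len(km)
        for cluster, rk in rep_kmers:
            if len(km & rk) >= need:
                chosen = cluster
                break
        if chosen is None:
            chosen = new_cluster(read, km)
        read_to_cluster[read] = chosen
        decision_cache[seq] = chosen

    return ClusterAssignment(read_to_cluster, representatives)
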