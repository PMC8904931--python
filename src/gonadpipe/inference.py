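"""Peptide-to-protein assignment, shared-peptide grouping, top-3 quantification.

Detected peptides rarely distinguish every database entry: transcript
clusters with similar coding sequences yield proteins that share tryptic
peptides.  The parsimonious reading used here consolidates sequence
clusters into protein groups: two clusters are linked when at least two
distinct observed peptide sequences map to entries of both, and groups are
the connected components of that graph.  A group with at least three
distinct observed peptides is quantified as the mean intensity of its
three most intense peptides (top-3); group abundances are then normalized
to the most abundant group and ranked.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .digest import IonIndex
from .io import read_tsv, write_tsv

logger = logging.getLogger(__name__)

MIN_SHARED_PEPTIDES = 2
TOP_N = 3


@dataclass(frozen=True)
class PeptideObservation:
    """One detected peptide with its ion intensity (arbitrary units)."""

    sequence: str
    intensity: float

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


@dataclass
class ProteinGroup:
    """A consolidated set of database entries sharing detected peptides."""

    group_id: str
    member_cluster_ids: frozenset
    member_entry_ids: frozenset
    peptide_set: frozenset
    abundance: float | None = None
    normalized_abundance: float | None = None
    rank: int | None = None


def read_observations(table) -> list[PeptideObservation]:
    """Load a detection table (TSV or DataFrame with peptide, intensity)."""
    if not isinstance(table, pd.DataFrame):
        table = read_tsv(table)
    missing = {"peptide", "intensity"} - set(table.columns)
    if missing:
        raise ValueError(f"detection table lacks column(s): {sorted(missing)}")
    return [PeptideObservation(sequence=str(p), intensity=float(i))
            for p, i in zip(table["peptide"], table["intensity"])]


def aggregate_intensities(observations: Iterable[PeptideObservation],
                          ) -> dict[str, float]:
    """Sum duplicate observations of one peptide into a single intensity."""
    totals: dict[str, float] = defaultdict(float)
    for obs in observations:
        totals[obs.sequence] += obs.intensity
    return dict(totals)


def assign_peptides(observations: Sequence[PeptideObservation],
                    ion_index: IonIndex,
                    ) -> tuple[dict[str, frozenset], list[str]]:
    """Map each observed peptide sequence to its source database entries.

    Matching is exact on the peptide string and charge-independent.
    Returns ``(assignment, unassigned)``; peptides absent from the index
    are collected in ``unassigned`` (counted, logged, never fatal) so they
    can be surfaced in QC output.
    """
    assignment: dict[str, frozenset] = {}
    unassigned: list[str] = []
    for sequence in sorted({obs.sequence for obs in observations}):
        entries = ion_index.sources.get(sequence)
        if entries:
            assignment[sequence] = entries
        else:
            unassigned.append(sequence)
    if unassigned:
        logger.info("%d observed peptides not in the ion index", len(unassigned))
    return assignment, unassigned


def build_groups(assignment: Mapping[str, frozenset],
                 entry_to_cluster: Mapping[str, str],
                 min_shared: int = MIN_SHARED_PEPTIDES) -> list[ProteinGroup]:
    """Consolidate clusters into protein groups on shared observed peptides.

    Nodes are clusters that received at least one assigned peptide; an
    edge joins two clusters when >= ``min_shared`` distinct observed
    peptide sequences are assigned to entries of both.  Groups are the
    connected components, so consolidation is transitive and invariant to
    input ordering.
    """
    peptides_of_cluster: dict[str, set[str]] = defaultdict(set)
    entries_of_cluster: dict[str, set[str]] = defaultdict(set)
    for peptide, entries in assignment.items():
        for entry in entries:
            try:
                cluster = entry_to_cluster[entry]
            except KeyError:
                raise ValueError(f"entry {entry!r} has no cluster") from None
            peptides_of_cluster[cluster].add(peptide)
            entries_of_cluster[cluster].add(entry)

    graph = nx.Graph()
    graph.add_nodes_from(peptides_of_cluster)
    shared: dict[tuple[str, str], int] = defaultdict(int)
    for peptide, entries in assignment.items():
        clusters = sorted({entry_to_cluster[e] for e in entries})
        for pair in combinations(clusters, 2):
            shared[pair] += 1
    for (a, b), n in shared.items():
        if n >= min_shared:
            graph.add_edge(a, b)

    groups = []
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for component in components:
        members = frozenset(component)
        entries = frozenset().union(*(entries_of_cluster[c] for c in members))
        peptides = frozenset().union(*(peptides_of_cluster[c] for c in members))
        groups.append(ProteinGroup(
            group_id=f"grp_{min(members)}",
            member_cluster_ids=members,
            member_entry_ids=entries,
            peptide_set=peptides))
    return groups


def quantify_top3(group: ProteinGroup,
                  intensities: Mapping[str, float],
                  top_n: int = TOP_N) -> float | None:
    """Mean intensity of the group's ``top_n`` most intense peptides.

    Returns ``None`` (group detected but unquantified) when fewer than
    ``top_n`` distinct peptides were observed.  Intensities must be the
    per-peptide totals from :func:`aggregate_intensities`.
    """
    values = []
    for peptide in group.peptide_set:
        value = intensities.get(peptide)
        if value is None:
            continue
        if value < 0:
            raise ValueError(f"negative intensity for peptide {peptide!r}")
        values.append(value)
    if len(values) < top_n:
        return None
    values.sort(reverse=True)
    return sum(values[:top_n]) / top_n


def normalize_and_rank(groups: Sequence[ProteinGroup],
                       intensities: Mapping[str, float],
                       top_n: int = TOP_N) -> list[ProteinGroup]:
    """Attach abundance, normalized abundance and rank to every group.

    Abundances are top-``top_n`` means; normalization divides by the
    maximum group abundance so the most abundant protein sits at 1.0.
    Ranks are 1-based by descending abundance, ties broken by group id;
    unquantified groups keep ``None`` for all three fields.  Raises if no
    group is quantifiable.
    """
    out = []
    for group in groups:
        abundance = quantify_top3(group, intensities, top_n)
        out.append(ProteinGroup(
            group_id=group.group_id,
            member_cluster_ids=group.member_cluster_ids,
            member_entry_ids=group.member_entry_ids,
            peptide_set=group.peptide_set,
            abundance=abundance))
    quantified = [g for g in out if g.abundance is not None]
    if not quantified:
        raise ValueError("no protein group has >= 3 detected peptides")
    top = max(g.abundance for g in quantified)
    quantified.sort(key=lambda g: (-g.abundance, g.group_id))
    for rank, group in enumerate(quantified, start=1):
        group.normalized_abundance = group.abundance / top
        group.rank = rank
    return out


def groups_to_frame(groups: Iterable[ProteinGroup]) -> pd.DataFrame:
    rows = [(g.group_id,
             ";".join(sorted(g.member_cluster_ids)),
             ";".join(sorted(g.member_entry_ids)),
             len(g.peptide_set),
             g.abundance, g.normalized_abundance, g.rank)
            for g in groups]
    return pd.DataFrame(rows, columns=[
        "group_id", "member_cluster_ids", "member_entry_ids", "n_peptides",
        "abundance", "normalized_abundance", "rank"])


def write_groups_tsv(groups: Iterable[ProteinGroup], path) -> None:
    write_tsv(groups_to_frame(groups), path)
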