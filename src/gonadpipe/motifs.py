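"""Cysteine-spacing motif scanning and sequence-composition descriptors.

Three-finger proteins (TFPs) are defined by a conserved scaffold of eight
core cysteines whose only strictly conserved sequence feature is the
C-terminal CCXXXXCN block; the spacing of the earlier cysteines varies
within bounded ranges.  Divergent TFP-like candidates that escape homology
search can still be flagged by scanning protein databases with a
gap-bounded cysteine-spacing pattern.  The default pattern encodes the
8-cysteine scaffold:

    .{2}C.{5,30}C.{2,20}C.{5,30}C.{2,20}C.{5,30}CC.{4}CN

Composition descriptors (residue counts and a simple integer net-charge
estimate) help characterize hits, e.g. unusually lysine-rich candidates.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .io import write_tsv

TFP_8C_PATTERN = r".{2}C.{5,30}C.{2,20}C.{5,30}C.{2,20}C.{5,30}CC.{4}CN"

#: Named patterns; extend via :func:`load_patterns` without code changes.
PATTERNS: dict[str, str] = {"tfp_8c": TFP_8C_PATTERN}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MotifHit:
    """One motif match: 0-based half-open residue span on the protein."""

    entry_id: str
    start: int
    end: int
    matched_subsequence: str
    pattern_name: str


@dataclass(frozen=True)
class CompositionReport:
    """Residue counts and a simple integer net-charge estimate.

    ``net_charge_estimate = (K + R) - (D + E)``; His, termini and pKa
    effects are deliberately ignored — the descriptor flags strongly basic
    or acidic sequences, it is not a pH-dependent charge model.  'X'
    residues are counted but excluded from the charge estimate.
    """

    entry_id: str
    length: int
    counts: Mapping[str, int]
    n_lys: int
    n_arg: int
    net_charge_estimate: int


def compile_pattern(pattern: str) -> "re.Pattern[str]":
    try:
        return re.compile(pattern)
    except re.error as exc:
        raise ValueError(
            f"malformed pattern at position {exc.pos}: {exc.msg}") from exc


def scan_motif(protein: str, pattern: str = TFP_8C_PATTERN,
               pattern_name: str = "tfp_8c",
               entry_id: str = "protein") -> list[MotifHit]:
    """All leftmost non-overlapping matches of a gap-bounded motif.

    Matching uses greedy bounded quantifiers scanning left to right;
    overlapping alternate matches are not enumerated.  The search is
    unanchored — a hit may sit anywhere in the protein.
    """
    compiled = compile_pattern(pattern)
    return [MotifHit(entry_id=entry_id, start=m.start(), end=m.end(),
                     matched_subsequence=m.group(0), pattern_name=pattern_name)
            for m in compiled.finditer(protein)]


def scan_database(proteins: Mapping[str, str],
                  patterns: Mapping[str, str] | None = None) -> list[MotifHit]:
    """Scan every protein in ``{entry_id: protein}`` with every named pattern."""
    patterns = dict(patterns or PATTERNS)
    hits: list[MotifHit] = []
    for entry_id in sorted(proteins):
        for name in sorted(patterns):
            hits.extend(scan_motif(proteins[entry_id], patterns[name],
                                   pattern_name=name, entry_id=entry_id))
    return hits


def composition(protein: str, entry_id: str = "protein") -> CompositionReport:
    """Per-residue counts plus lysine/arginine and net-charge descriptors."""
    allowed = set(AMINO_ACIDS) | {"X"}
    bad = set(protein) - allowed
    if bad:
        raise ValueError(f"unexpected residue(s) {sorted(bad)} in {entry_id}")
    counts = Counter(protein)
    full = {aa: counts.get(aa, 0) for aa in AMINO_ACIDS}
    if counts.get("X"):
        full["X"] = counts["X"]
    return CompositionReport(
        entry_id=entry_id, length=len(protein), counts=full,
        n_lys=full["K"], n_arg=full["R"],
        net_charge_estimate=(full["K"] + full["R"]) - (full["D"] + full["E"]))


def load_patterns(path) -> dict[str, str]:
    """Read a flat ``name: pattern`` YAML file, validating each pattern."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValueError("pattern file must be a flat name: pattern mapping")
    patterns = {}
    for name, pattern in raw.items():
        compile_pattern(str(pattern))
        patterns[str(name)] = str(pattern)
    return patterns


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.entry_id, h.start, h.end, h.pattern_name) for h in hits],
        columns=["entry_id", "start", "end", "pattern_name"])


def write_hits_tsv(hits: Iterable[MotifHit], path) -> None:
    write_tsv(hits_to_frame(hits), path)


def compositions_to_frame(reports: Iterable[CompositionReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {"entry_id": r.entry_id, "length": r.length,
               "n_lys": r.n_lys, "n_arg": r.n_arg,
               "net_charge_estimate": r.net_charge_estimate}
        row.update({f"n_{aa}": r.counts.get(aa, 0) for aa in AMINO_ACIDS})
        rows.append(row)
    return pd.DataFrame(rows)
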