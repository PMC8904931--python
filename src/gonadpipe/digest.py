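"""In-silico tryptic digestion with length, charge and precursor-m/z filters.

The search space for a gas-phase-fractionated DIA experiment is built by
digesting every database protein with trypsin (cleavage after K/R except
before P), allowing up to one missed cleavage, and keeping peptides of
7-30 residues whose +2H or +3H precursor m/z falls inside the instrument's
acquired window of 396.43-1,002.70 Th (bounds inclusive).  Cysteines carry
the fixed carbamidomethyl modification (+57.021464 Da) reflecting
iodoacetamide alkylation during sample preparation.  Identical peptide
strings arising from multiple proteins are emitted once per charge state,
with the full set of source entries recorded as provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io import write_tsv
from .orfs import ProteinDbEntry

logger = logging.getLogger(__name__)

WATER_MONO = 18.010565
PROTON_MASS = 1.0072765
CARBAMIDOMETHYL = 57.021464

# Monoisotopic residue masses, Da.
RESIDUE_MASS = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047678, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

MIN_PEPTIDE_LENGTH = 7
MAX_PEPTIDE_LENGTH = 30
CHARGES = (2, 3)
MZ_WINDOW = (396.43, 1002.70)
MAX_MISSED_CLEAVAGES = 1


@dataclass(frozen=True)
class PeptideIon:
    """A digested peptide at one charge state with its precursor m/z."""

    sequence: str
    missed_cleavages: int
    charge: int
    monoisotopic_mass: float
    mz: float


@dataclass
class IonIndex:
    """Deduplicated ion list with peptide -> source-entry provenance."""

    ions: list[PeptideIon] = field(default_factory=list)
    sources: dict[str, frozenset] = field(default_factory=dict)

    @property
    def peptides(self) -> set[str]:
        return set(self.sources)

    def to_frame(self) -> pd.DataFrame:
        rows = [(i.sequence, i.charge, i.missed_cleavages,
                 i.monoisotopic_mass, i.mz,
                 ";".join(sorted(self.sources[i.sequence])))
                for i in self.ions]
        return pd.DataFrame(rows, columns=[
            "peptide", "charge", "missed_cleavages", "mass", "mz",
            "source_entry_ids"])

    def write_tsv(self, path) -> None:
        write_tsv(self.to_frame(), path)


def cleave_tryptic(protein: str,
                   max_missed: int = MAX_MISSED_CLEAVAGES,
                   ) -> list[tuple[str, int]]:
    """All tryptic products of ``protein`` with 0..``max_missed`` missed sites.

    Trypsin cleaves C-terminal to K or R unless the next residue is P.
    N- and C-terminal peptides are included; an empty protein yields an
    empty list.
    """
    if not protein:
        return []
    boundaries = [0]
    for i, residue in enumerate(protein[:-1]):
        if residue in "KR" and protein[i + 1] != "P":
            boundaries.append(i + 1)
    boundaries.append(len(protein))
    products = []
    for a in range(len(boundaries) - 1):
        for missed in range(max_missed + 1):
            b = a + 1 + missed
            if b >= len(boundaries):
                break
            products.append((protein[boundaries[a]:boundaries[b]], missed))
    return products


def monoisotopic_mass(peptide: str,
                      fixed_cys_mod: float = CARBAMIDOMETHYL) -> float:
    """Monoisotopic peptide mass: residues + water + fixed Cys modification.

    Peptides containing 'X' (unknown residue, e.g. from an ambiguous codon)
    have no defined mass and are rejected; callers skip them upstream.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    mass = WATER_MONO
    for residue in peptide:
        try:
            mass += RESIDUE_MASS[residue]
        except KeyError:
            raise ValueError(f"residue {residue!r} has no defined mass") from None
        if residue == "C":
            mass += fixed_cys_mod
    return mass


def mz_from_mass(mass: float, charge: int) -> float:
    return (mass + charge * PROTON_MASS) / charge


def enumerate_ions(proteins: Mapping[str, str] | Iterable[ProteinDbEntry],
                   min_length: int = MIN_PEPTIDE_LENGTH,
                   max_length: int = MAX_PEPTIDE_LENGTH,
                   charges: tuple[int, ...] = CHARGES,
                   mz_window: tuple[float, float] = MZ_WINDOW,
                   max_missed: int = MAX_MISSED_CLEAVAGES) -> IonIndex:
    """Every peptide ion passing all digestion filters, with provenance.

    ``proteins`` is either a ``{entry_id: protein}`` mapping or an iterable
    of :class:`~gonadpipe.orfs.ProteinDbEntry`.  Each distinct peptide
    string is emitted at most once per charge state; its ``sources`` entry
    accumulates every database entry containing it.  Peptides with 'X'
    residues are skipped (logged).
    """
    if not isinstance(proteins, Mapping):
        proteins = {entry.entry_id: entry.protein for entry in proteins}
    if not proteins:
        raise ValueError("protein database is empty")
    lo, hi = mz_window
    # peptide -> (missed, {charge: ion})
    seen: dict[str, tuple[int, dict[int, PeptideIon]]] = {}
    sources: dict[str, set] = {}
    n_skipped = 0
    for entry_id in sorted(proteins):
        for peptide, missed in cleave_tryptic(proteins[entry_id], max_missed):
            if not (min_length <= len(peptide) <= max_length):
                continue
            if peptide in seen:
                if seen[peptide][1]:
                    sources[peptide].add(entry_id)
                continue
            if "X" in peptide:
                n_skipped += 1
                seen[peptide] = (missed, {})
                continue
            mass = monoisotopic_mass(peptide)
            ions = {}
            for charge in charges:
                mz = mz_from_mass(mass, charge)
                if lo <= mz <= hi:
                    ions[charge] = PeptideIon(
                        sequence=peptide, missed_cleavages=missed,
                        charge=charge, monoisotopic_mass=mass, mz=mz)
            seen[peptide] = (missed, ions)
            if ions:
                sources[peptide] = {entry_id}
    if n_skipped:
        logger.info("skipped %d peptides containing 'X'", n_skipped)
    index = IonIndex()
    for peptide in sorted(sources):
        _, ions = seen[peptide]
        index.ions.extend(ions[c] for c in sorted(ions))
        index.sources[peptide] = frozenset(sources[peptide])
    return index
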