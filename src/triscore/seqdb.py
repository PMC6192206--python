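"""Protein database handling: FASTA input, reversed decoys, tryptic digestion,
peptide masses, and precursor-mass candidate lookup.

The search space is the set of fully tryptic peptides (with up to a configured
number of missed cleavages) of all target proteins plus one reversed-sequence
decoy per target.  Peptides are indexed by monoisotopic neutral mass so that a
spectrum's precursor window can be resolved to candidates in O(log n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .constants import AA_MONO, CARBAMIDOMETHYL, WATER

DEFAULT_DECOY_PREFIX = "Rev_"

#: Default fixed modifications: carbamidomethyl cysteine.
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL}


class DecoySplit(Enum):
    """Train/test assignment of a decoy protein (targets are NOT_APPLICABLE)."""

    TRAIN = "train"
    TEST = "test"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class ProteinEntry:
    """One target or reversed-decoy protein."""

    identifier: str
    description: str
    sequence: str
    is_decoy: bool = False
    decoy_split: DecoySplit = DecoySplit.NOT_APPLICABLE

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.identifier!r} has an empty sequence")


@dataclass
class PeptideCandidate:
    """A digested peptide with its mass and parent proteins.

    A peptide shared between target and decoy proteins counts as target:
    ``is_decoy`` is true only when every parent is a decoy.
    """

    sequence: str
    neutral_mass: float
    missed_cleavages: int
    parent_protein_ids: set[str] = field(default_factory=set)
    is_decoy: bool = False


def read_fasta(path) -> list[ProteinEntry]:
    """Read a FASTA file into protein entries.

    The identifier is the first whitespace-delimited token of the header;
    sequences are uppercased and ``*`` (stop codons) stripped.
    """
    entries: list[ProteinEntry] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ident = record.id
        desc = record.description[len(ident):].strip()
        seq = str(record.seq).upper().replace("*", "")
        if not seq:
            raise ValueError(f"FASTA record {ident!r} has an empty sequence")
        entries.append(ProteinEntry(ident, desc, seq))
    if not entries:
        raise ValueError(f"FASTA file {path} contains no records")
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            header = f"{e.identifier} {e.description}".strip()
            fh.write(f">{header}\n")
            for i in range(0, len(e.sequence), 60):
                fh.write(e.sequence[i : i + 60] + "\n")


def generate_decoys(
    targets: Sequence[ProteinEntry], prefix: str = DEFAULT_DECOY_PREFIX
) -> list[ProteinEntry]:
    """Append one reversed-sequence decoy per target protein.

    Returns targets + decoys (twice the input length).  Decoy identifiers are
    ``prefix`` + the target identifier.
    """
    for t in targets:
        if t.identifier.startswith(prefix):
            raise ValueError(
                f"target identifier {t.identifier!r} collides with decoy prefix {prefix!r}"
            )
    decoys = [
        ProteinEntry(
            identifier=prefix + t.identifier,
            description=t.description,
            sequence=t.sequence[::-1],
            is_decoy=True,
        )
        for t in targets
    ]
    return list(targets) + decoys


def _cleavage_sites(sequence: str) -> list[int]:
    """Positions after which trypsin cuts: C-terminal to K/R, not before P."""
    n = len(sequence)
    return [
        i + 1
        for i in range(n - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinEntry,
    max_missed: int = 3,
    length_range: tuple[int, int] = (6, 60),
) -> list[PeptideCandidate]:
    """Fully tryptic digestion of one protein.

    Yields every peptide delimited by cleavage sites (or the protein termini)
    spanning 0..``max_missed`` internal missed cleavages, filtered to
    ``length_range``.  A protein with no cleavage site yields itself.
    """
    seq = protein.sequence
    bounds = [0] + _cleavage_sites(seq) + [len(seq)]
    lo, hi = length_range
    out: list[PeptideCandidate] = []
    for i in range(len(bounds) - 1):
        for skip in range(max_missed + 1):
            j = i + 1 + skip
            if j >= len(bounds):
                break
            pep = seq[bounds[i] : bounds[j]]
            if lo <= len(pep) <= hi:
                out.append(
                    PeptideCandidate(
                        sequence=pep,
                        neutral_mass=peptide_mass(pep),
                        missed_cleavages=skip,
                        parent_protein_ids={protein.identifier},
                        is_decoy=protein.is_decoy,
                    )
                )
    return out


def peptide_mass(sequence: str, fixed_mods: dict[str, float] | None = None) -> float:
    """Monoisotopic neutral mass: residue masses + water + fixed-mod deltas."""
    if not sequence:
        raise ValueError("cannot compute the mass of an empty peptide")
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    total = WATER
    for aa in sequence:
        try:
            total += AA_MONO[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in peptide {sequence!r}") from None
        total += fixed_mods.get(aa, 0.0)
    return total


class MassIndex:
    """Sorted peptide-mass index for precursor-window candidate lookup.

    Duplicate sequences arising from different proteins are merged into a
    single candidate holding the union of parents; such a merged candidate is
    a decoy only if every parent is a decoy.
    """

    def __init__(self, peptides: Iterable[PeptideCandidate]):
        merged: dict[str, PeptideCandidate] = {}
        for p in peptides:
            cur = merged.get(p.sequence)
            if cur is None:
                merged[p.sequence] = PeptideCandidate(
                    p.sequence,
                    p.neutral_mass,
                    p.missed_cleavages,
                    set(p.parent_protein_ids),
                    p.is_decoy,
                )
            else:
                cur.parent_protein_ids |= p.parent_protein_ids
                cur.is_decoy = cur.is_decoy and p.is_decoy
                cur.missed_cleavages = min(cur.missed_cleavages, p.missed_cleavages)
        self.peptides = sorted(merged.values(), key=lambda p: (p.neutral_mass, p.sequence))
        self._masses = np.array([p.neutral_mass for p in self.peptides])

    def __len__(self) -> int:
        return len(self.peptides)

    def query(
        self,
        precursor_neutral_mass: float,
        tolerance: float,
        unit: str = "ppm",
    ) -> list[PeptideCandidate]:
        """All candidates with |mass - precursor| within the tolerance window."""
        if tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if unit == "ppm":
            half = precursor_neutral_mass * tolerance * 1e-6
        elif unit == "Da":
            half = tolerance
        else:
            raise ValueError(f"unknown tolerance unit {unit!r}")
        lo = np.searchsorted(self._masses, precursor_neutral_mass - half, side="left")
        hi = np.searchsorted(self._masses, precursor_neutral_mass + half, side="right")
        return self.peptides[lo:hi]


def build_mass_index(peptides: Iterable[PeptideCandidate]) -> MassIndex:
    return MassIndex(peptides)


def digest_database(
    entries: Sequence[ProteinEntry],
    max_missed: int = 3,
    length_range: tuple[int, int] = (6, 60),
) -> MassIndex:
    """Digest every protein and build the merged mass index."""
    all_peps: list[PeptideCandidate] = []
    for e in entries:
        all_peps.extend(digest(e, max_missed=max_missed, length_range=length_range))
    return build_mass_index(all_peps)
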