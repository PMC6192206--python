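"""Assembly of accepted PSMs into peptide and protein identifications.

A peptide is identified if any of its PSMs is accepted.  Proteins whose
accepted-peptide sets are identical are indistinguishable and merged into one
protein group; a peptide is *unique* if it maps to exactly one group, and a
group is identified when it holds at least the configured minimum of unique
peptides (default 1).  Peptide- and protein-level FDRs reuse the held-out
decoy estimator with identification counts in place of PSM counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .filtering import CandidatePSM, FdrEstimate, estimate_fdr
from .seqdb import DecoySplit


@dataclass
class PeptideIdentification:
    sequence: str
    supporting_scans: list[str]
    parent_protein_ids: frozenset[str]
    is_decoy: bool
    decoy_split: DecoySplit = DecoySplit.NOT_APPLICABLE

    @property
    def spectrum_count(self) -> int:
        return len(self.supporting_scans)


@dataclass
class ProteinGroup:
    member_ids: tuple[str, ...]
    peptides: frozenset[str]
    unique_peptides: frozenset[str] = frozenset()
    is_decoy: bool = False
    decoy_split: DecoySplit = DecoySplit.NOT_APPLICABLE


def assemble_peptides(accepted: list[CandidatePSM]) -> list[PeptideIdentification]:
    """Group accepted PSMs by peptide sequence (charge states and
    modification forms collapse onto one sequence)."""
    by_seq: dict[str, list[CandidatePSM]] = {}
    for c in accepted:
        by_seq.setdefault(c.psm.sequence, []).append(c)
    out = []
    for seq in sorted(by_seq):
        cands = by_seq[seq]
        first = cands[0]
        out.append(
            PeptideIdentification(
                sequence=seq,
                supporting_scans=sorted(c.psm.scan_id for c in cands),
                parent_protein_ids=frozenset(first.psm.peptide.parent_protein_ids),
                is_decoy=first.is_decoy,
                decoy_split=first.decoy_split,
            )
        )
    return out


def infer_proteins(
    peptides: list[PeptideIdentification],
    split_assignment: dict[str, DecoySplit] | None = None,
    min_unique: int = 1,
) -> list[ProteinGroup]:
    """Group indistinguishable proteins and keep groups with enough unique
    peptides.

    Uniqueness is evaluated after grouping: a peptide shared only among the
    members of one group still counts as unique to that group.  Subset
    proteins (peptide set strictly contained in another's) are kept as their
    own group.
    """
    pep_of_protein: dict[str, set[str]] = {}
    for p in peptides:
        for prot in p.parent_protein_ids:
            pep_of_protein.setdefault(prot, set()).add(p.sequence)
    # merge proteins with identical accepted-peptide sets
    by_pepset: dict[frozenset[str], list[str]] = {}
    for prot, peps in pep_of_protein.items():
        by_pepset.setdefault(frozenset(peps), []).append(prot)
    groups = [
        ProteinGroup(member_ids=tuple(sorted(members)), peptides=pepset)
        for pepset, members in by_pepset.items()
    ]
    groups.sort(key=lambda g: g.member_ids)
    # a peptide is unique if exactly one group contains it
    n_groups_of_pep: dict[str, int] = {}
    for g in groups:
        for s in g.peptides:
            n_groups_of_pep[s] = n_groups_of_pep.get(s, 0) + 1
    decoy_of_pep = {p.sequence: p.is_decoy for p in peptides}
    split_of_pep = {p.sequence: p.decoy_split for p in peptides}
    out: list[ProteinGroup] = []
    for g in groups:
        unique = frozenset(s for s in g.peptides if n_groups_of_pep[s] == 1)
        if len(unique) < min_unique:
            continue
        is_decoy = all(decoy_of_pep[s] for s in g.peptides)
        if is_decoy:
            if split_assignment is not None:
                splits = {split_assignment.get(m) for m in g.member_ids}
            else:
                splits = {split_of_pep[s] for s in g.peptides}
            split = (
                DecoySplit.TEST if DecoySplit.TEST in splits else DecoySplit.TRAIN
            )
        else:
            split = DecoySplit.NOT_APPLICABLE
        out.append(
            ProteinGroup(
                member_ids=g.member_ids,
                peptides=g.peptides,
                unique_peptides=unique,
                is_decoy=is_decoy,
                decoy_split=split,
            )
        )
    return out


def level_fdr_counts(
    identifications: list[PeptideIdentification] | list[ProteinGroup],
    alpha: float,
) -> FdrEstimate:
    """Held-out decoy FDR over assembled identifications; training-split
    decoys count in neither the numerator nor the denominator."""
    n_target = sum(1 for i in identifications if not i.is_decoy)
    n_test = sum(
        1
        for i in identifications
        if i.is_decoy and i.decoy_split is DecoySplit.TEST
    )
    return estimate_fdr(n_target, n_test, alpha)
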