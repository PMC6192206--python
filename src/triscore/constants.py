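"""Physical constants and residue masses (monoisotopic throughout)."""

from pyteomics import mass as _pmass

#: Mass of a proton, Da (used for every m/z <-> neutral-mass conversion).
PROTON = 1.00727646677

#: Mass of water, Da (added to the residue-mass sum of a peptide).
WATER = 18.010565

#: Monoisotopic residue masses for the 20 standard amino acids, Da.
AA_MONO: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

#: Carbamidomethylation of cysteine, the conventional fixed modification.
CARBAMIDOMETHYL = 57.02146
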