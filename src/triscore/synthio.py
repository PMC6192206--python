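"""Synthetic FASTA+MGF fixture generation with ground-truth labels.

The generator emulates the conditions that make community (metaproteomic)
searches hard: a protein database that is an *incomplete* picture of the
sample, so a sizeable fraction of spectra come from peptides absent from the
database and can only produce false matches.  Foreign peptides copy the
length of a database peptide and are required to land near its mass, so
their spectra fall into precursor windows as populated as any other — the
adversarial kind of unmatchable spectrum — while remaining unrelated to any
specific target sequence.

Fragment m/z values are jittered and log-normally sized, and uniform noise
peaks are added.  Peptides are sampled uniformly from the tryptic pool; no
protein-abundance skew is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import PROTON
from .seqdb import PeptideCandidate, ProteinEntry, digest, write_fasta
from .scoring import theoretical_fragments

#: Residue alphabet with elevated K/R frequency so tryptic sites are common.
_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_WEIGHTS = np.array(
    [5, 2, 5, 6, 4, 7, 2, 5, 7, 9, 2, 4, 5, 4, 7, 7, 5, 6, 1, 3], dtype=float
)
_WEIGHTS /= _WEIGHTS.sum()

FOREIGN_LABEL = "foreign"


@dataclass
class SyntheticConfig:
    n_proteins: int = 500
    protein_length_range: tuple[int, int] = (100, 400)
    n_spectra: int = 1000
    fraction_foreign: float = 0.3
    noise_peaks_per_spectrum: int = 20
    fragment_mz_jitter: float = 0.05  # Da, s.d. of fragment m/z noise
    precursor_mz_jitter: float = 0.002  # Da, s.d. of precursor m/z noise
    #: probability that a theoretical fragment appears in the spectrum at all;
    #: real spectra carry partial b/y ladders, which produces the continuum of
    #: marginal true matches that filtering has to recover
    fragment_detect_prob: float = 0.6
    intensity_mu: float = 2.0  # log-normal fragment intensity parameters
    intensity_sigma: float = 0.8
    noise_intensity_mu: float = 0.5
    noise_intensity_sigma: float = 0.8
    #: instrument scan range: only peptides whose precursor m/z (at the charge
    #: the generator assigns) falls in this window are sampled for spectra
    precursor_mz_range: tuple[float, float] = (300.0, 1500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_foreign <= 1.0:
            raise ValueError("fraction_foreign must lie in [0, 1]")
        if self.n_proteins < 1 or self.n_spectra < 0:
            raise ValueError("counts must be non-negative (and >=1 protein)")


@dataclass
class TruthRecord:
    scan_id: str
    peptide: str  # true peptide sequence, or FOREIGN_LABEL origin marker
    origin: str  # source protein id, or FOREIGN_LABEL


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_RESIDUES, size=length, p=_WEIGHTS))


def generate_proteins(cfg: SyntheticConfig, rng: np.random.Generator) -> list[ProteinEntry]:
    lo, hi = cfg.protein_length_range
    return [
        ProteinEntry(
            identifier=f"syn{i:04d}",
            description="synthetic protein",
            sequence=_random_protein(rng, int(rng.integers(lo, hi + 1))),
        )
        for i in range(cfg.n_proteins)
    ]


def _assign_charge(neutral_mass: float) -> int:
    return 2 if neutral_mass < 2400.0 else 3


def _sample_peptide_pool(
    proteins: list[ProteinEntry], cfg: SyntheticConfig
) -> tuple[list[PeptideCandidate], set[str]]:
    """Digest all proteins (<=1 missed cleavage) into the samplable pool.

    Only peptides whose precursor m/z falls inside the instrument scan range
    are samplable (mass outliers would sit in near-empty precursor windows no
    real acquisition would select).  Peptides are drawn uniformly: no
    protein-abundance model is imposed, so the peptide/protein spectrum-count
    features carry only the weak signal of repeated draws and protein size.
    (An abundance-skewed sample would couple the protein-count feature to
    targets only — decoy proteins never accumulate true spectra — and bias
    the held-out decoy FDR estimate.)
    """
    mz_lo, mz_hi = cfg.precursor_mz_range
    pool: list[PeptideCandidate] = []
    seqs: set[str] = set()
    for prot in proteins:
        for pep in digest(prot, max_missed=1):
            z = _assign_charge(pep.neutral_mass)
            mz = (pep.neutral_mass + z * PROTON) / z
            if mz_lo <= mz <= mz_hi:
                pool.append(pep)
                seqs.add(pep.sequence)
    if not pool:
        raise ValueError("the synthetic database yields no samplable peptides")
    return pool, seqs


def _random_foreign(
    template: PeptideCandidate,
    db_sequences: set[str],
    rng: np.random.Generator,
    mass_window: float = 25.0,
) -> str:
    """A random tryptic-looking peptide absent from the database.

    Length is copied from a database peptide and the mass is required to land
    within ``mass_window`` of it, so the foreign spectrum's precursor window
    is as populated as a typical database peptide's — without the foreign
    peptide resembling any specific target, which keeps its false matches
    unbiased between targets and decoys.
    """
    from .seqdb import peptide_mass

    n = len(template.sequence)
    last = template.sequence[-1] if template.sequence[-1] in "KR" else "K"
    window = mass_window
    for attempt in range(2000):
        body = "".join(rng.choice(_RESIDUES, size=n - 1, p=_WEIGHTS))
        cand = body + last
        if cand in db_sequences or cand == template.sequence:
            continue
        if abs(peptide_mass(cand) - template.neutral_mass) <= window:
            return cand
        if attempt % 200 == 199:  # composition bias: relax gradually
            window *= 2.0
    raise ValueError(
        f"could not derive a foreign peptide near {template.sequence!r}"
    )


def _synthesize_spectrum(
    scan_id: str,
    sequence: str,
    neutral_mass: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> dict:
    charge = _assign_charge(neutral_mass)
    frags = theoretical_fragments(sequence, charge)
    mzs: list[float] = []
    intens: list[float] = []
    for f in frags:
        if rng.random() > cfg.fragment_detect_prob:
            continue
        mzs.append(f.mz + rng.normal(0.0, cfg.fragment_mz_jitter))
        intens.append(rng.lognormal(cfg.intensity_mu, cfg.intensity_sigma))
    mz_hi = (neutral_mass + charge * PROTON) / charge * charge  # spectrum span
    for _ in range(cfg.noise_peaks_per_spectrum):
        mzs.append(float(rng.uniform(100.0, max(300.0, mz_hi))))
        intens.append(rng.lognormal(cfg.noise_intensity_mu, cfg.noise_intensity_sigma))
    order = np.argsort(mzs)
    precursor_mz = (neutral_mass + charge * PROTON) / charge + rng.normal(
        0.0, cfg.precursor_mz_jitter
    )
    return {
        "scan_id": scan_id,
        "precursor_mz": precursor_mz,
        "charge": charge,
        "mz": np.asarray(mzs)[order],
        "intensity": np.asarray(intens)[order],
    }


def generate_dataset(
    cfg: SyntheticConfig, out_dir
) -> tuple[Path, Path, list[TruthRecord]]:
    """Write FASTA, MGF and a truth TSV under ``out_dir``; return their paths
    and the in-memory truth table.  Identical seeds give identical bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    proteins = generate_proteins(cfg, rng)
    pool, db_seqs = _sample_peptide_pool(proteins, cfg)

    n_foreign = int(round(cfg.n_spectra * cfg.fraction_foreign))
    is_foreign = np.zeros(cfg.n_spectra, dtype=bool)
    if cfg.n_spectra:
        is_foreign[rng.choice(cfg.n_spectra, size=n_foreign, replace=False)] = True

    truth: list[TruthRecord] = []
    blocks: list[dict] = []
    for i in range(cfg.n_spectra):
        scan = f"scan={i:05d}"
        j = int(rng.integers(len(pool)))
        src = pool[j]
        if is_foreign[i]:
            seq = _random_foreign(src, db_seqs, rng)
            truth.append(TruthRecord(scan, FOREIGN_LABEL, FOREIGN_LABEL))
        else:
            seq = src.sequence
            truth.append(
                TruthRecord(scan, seq, sorted(src.parent_protein_ids)[0])
            )
        from .seqdb import peptide_mass

        blocks.append(_synthesize_spectrum(scan, seq, peptide_mass(seq), cfg, rng))

    fasta_path = out / "database.fasta"
    mgf_path = out / "spectra.mgf"
    truth_path = out / "truth.tsv"
    write_fasta(proteins, fasta_path)
    with open(mgf_path, "w") as fh:
        for b in blocks:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={b['scan_id']}\n")
            fh.write(f"PEPMASS={b['precursor_mz']:.6f}\n")
            fh.write(f"CHARGE={b['charge']}+\n")
            for mz, it in zip(b["mz"], b["intensity"]):
                fh.write(f"{mz:.5f} {it:.4f}\n")
            fh.write("END IONS\n")
    with open(truth_path, "w") as fh:
        fh.write("scan_id\tpeptide\torigin\n")
        for t in truth:
            fh.write(f"{t.scan_id}\t{t.peptide}\t{t.origin}\n")
    return fasta_path, mgf_path, truth


def read_truth(path) -> list[TruthRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            scan, pep, origin = line.rstrip("\n").split("\t")
            records.append(TruthRecord(scan, pep, origin))
    return records


@dataclass
class TruthEvaluation:
    n_accepted: int
    n_correct: int
    n_in_database: int
    true_fdr: float
    recall: float
    empty: bool = False


def evaluate_against_truth(
    accepted: list, truth: list[TruthRecord]
) -> TruthEvaluation:
    """True FDR and recall of an accepted PSM set against the truth table.

    ``accepted`` holds objects with ``psm`` (scan_id, sequence) attributes or
    (scan_id, sequence) pairs; decoy PSMs carried along for FDR bookkeeping
    are ignored, since the evaluation concerns the reported target
    identifications.  An accepted PSM is correct when its peptide equals the
    spectrum's true peptide; every foreign spectrum's PSM is false by
    construction.
    """
    by_scan = {t.scan_id: t for t in truth}
    n_in_db = sum(1 for t in truth if t.peptide != FOREIGN_LABEL)
    n_correct = 0
    n_accepted = 0
    for item in accepted:
        if hasattr(item, "psm"):
            if item.is_decoy:
                continue
            scan, seq = item.psm.scan_id, item.psm.sequence
        else:
            scan, seq = item
        if scan not in by_scan:
            raise ValueError(f"accepted PSM references unknown scan {scan!r}")
        n_accepted += 1
        if by_scan[scan].peptide == seq:
            n_correct += 1
    if n_accepted == 0:
        return TruthEvaluation(0, 0, n_in_db, 0.0, 0.0, empty=True)
    return TruthEvaluation(
        n_accepted,
        n_correct,
        n_in_db,
        (n_accepted - n_correct) / n_accepted,
        n_correct / n_in_db if n_in_db else 0.0,
    )
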