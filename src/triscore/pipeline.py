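"""End-to-end orchestration: database preparation, ensemble search,
supervised filtering and assembly."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import assembly, filtering, scoring, seqdb, spectra
from .config import RunConfig

logger = logging.getLogger(__name__)


def prepare_database(fasta_path, cfg: RunConfig):
    """Read targets, append reversed decoys, digest, and index by mass."""
    targets = seqdb.read_fasta(fasta_path)
    entries = seqdb.generate_decoys(targets, cfg.decoy_prefix)
    index = seqdb.digest_database(
        entries, max_missed=cfg.max_missed_cleavages, length_range=cfg.length_range
    )
    logger.info(
        "database: %d targets, %d entries with decoys, %d indexed peptides",
        len(targets), len(entries), len(index),
    )
    return entries, index


def run_search(fasta_path, mgf_path, cfg: RunConfig):
    """Search an MGF against a FASTA; returns (per-scan PSMs, entries, index)."""
    entries, index = prepare_database(fasta_path, cfg)
    specs = spectra.read_mgf(mgf_path, assumed_charges=cfg.assumed_charge_list)
    logger.info("read %d spectra", len(specs))
    by_scan = scoring.search(
        specs,
        index,
        precursor_tol=cfg.precursor_tolerance,
        precursor_unit=cfg.precursor_unit,
        fragment_tol=cfg.fragment_tolerance,
        tier2_depth=cfg.tier2_depth,
        output_depth=cfg.output_depth,
        batch_size=cfg.batch_size,
        n_workers=cfg.n_workers,
    )
    logger.info("spectra with PSMs: %d", len(by_scan))
    return by_scan, entries, index


@dataclass
class FilterOutput:
    candidates: dict
    selected: dict
    result: filtering.FilterResult
    peptides: list
    protein_groups: list
    peptide_fdr: object
    protein_fdr: object
    split_assignment: dict
    trained: filtering.TrainedFilter


def run_filter(by_scan, decoy_protein_ids, cfg: RunConfig) -> FilterOutput:
    """Filter search results: features, agreement, training, selection and
    FDR-controlled thresholding, then peptide/protein assembly."""
    candidates = filtering.rank1_candidates(by_scan)
    filtering.extract_features(candidates, by_scan, cfg.spectrum_count_depth)
    split = filtering.split_decoy_proteins(
        sorted(decoy_protein_ids), alpha=cfg.alpha, seed=cfg.split_seed
    )
    alpha = filtering.realized_alpha(split)
    logger.info("decoy split: realized alpha %.4f (seed %d)", alpha, cfg.split_seed)
    filtering.annotate_splits(candidates, split)
    positives, negatives = filtering.build_training_data(candidates)
    n_una = sum(
        1 for cs in candidates.values() for c in cs
        if c.agreement is filtering.AgreementClass.UNANIMOUS
    )
    logger.info(
        "training data: %d positives (of %d unanimous), %d negatives",
        len(positives), n_una, len(negatives),
    )
    trained = filtering.train_filter(
        positives, negatives, model_kind=cfg.model_kind, alpha=alpha,
        seed=cfg.split_seed,
    )
    filtering.score_candidates(candidates, trained)
    selected = filtering.select_psm_per_spectrum(candidates)
    result = filtering.filter_at_fdr(
        selected,
        target_fdr=cfg.target_fdr,
        level=cfg.fdr_level,
        alpha=alpha,
        split_assignment=split,
    )
    peptides = assembly.assemble_peptides(result.accepted)
    groups = assembly.infer_proteins(
        peptides, split_assignment=split, min_unique=cfg.min_unique_peptides
    )
    peptide_fdr = assembly.level_fdr_counts(peptides, alpha)
    protein_fdr = assembly.level_fdr_counts(groups, alpha)
    logger.info(
        "accepted %d PSMs at threshold %.4g (estimated %s FDR %.4g); "
        "%d peptides, %d protein groups",
        len(result.accepted), result.threshold, result.level, result.fdr.fdr,
        len(peptides), len(groups),
    )
    return FilterOutput(
        candidates, selected, result, peptides, groups,
        peptide_fdr, protein_fdr, split, trained,
    )


def decoy_ids_from_entries(entries) -> list[str]:
    return [e.identifier for e in entries if e.is_decoy]


def decoy_ids_from_psms(by_scan, decoy_prefix: str) -> list[str]:
    """Decoy protein ids referenced by any PSM (used when filtering starts
    from a search report rather than the FASTA)."""
    ids = set()
    for psms in by_scan.values():
        for p in psms:
            for prot in p.peptide.parent_protein_ids:
                if prot.startswith(decoy_prefix):
                    ids.add(prot)
    return sorted(ids)
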