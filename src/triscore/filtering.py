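"""Supervised PSM filtering.

Every spectrum's rank-1 PSMs (one per scoring function, 1-3 distinct
peptides) are classified by agreement: *unanimous* when all three scorers
rank the same peptide first, *majority*/*minority* when exactly two agree,
*discordant* when all three disagree.  Unanimous target PSMs form the
positive training data; decoy PSMs from a randomly chosen training split of
the decoy proteins form the negative training data.  A classifier trained on
10 PSM features scores every rank-1 PSM, one PSM per spectrum is kept (the
highest classification score), and a score threshold is chosen to meet a
user-defined FDR estimated from the held-out test split of decoy proteins:

    FDR = #TestDecoy / (alpha * #Target)

where alpha is the fraction of decoy proteins assigned to the test split.
Because training-split decoys are never counted, #TestDecoy / alpha estimates
the total number of decoy PSMs without training bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .scoring import PSM
from .seqdb import DecoySplit

logger = logging.getLogger(__name__)

EPS_DENOM = 1e-6
SINGLE_PSM_DIFFERENTIAL = 1.0
DEFAULT_SPLIT_SEED = 20170922
DEFAULT_ALPHA = 0.5

FEATURE_NAMES = [
    "mvh", "xcorr", "wdp",
    "d_mvh", "d_xcorr", "d_wdp",
    "delta_mass", "n_missed_cleavages",
    "pep_spectrum_count", "pro_spectrum_count",
]


class AgreementClass(Enum):
    UNANIMOUS = "unanimous"
    MAJORITY = "majority"
    MINORITY = "minority"
    DISCORDANT = "discordant"


def score_differential(sc: float, sb: float) -> float:
    """Relative score margin (sc - sb) / sb against the best *other* PSM.

    Positive for the top-ranking PSM, negative below it.  When |sb| is tiny
    the denominator is clamped to +-eps to keep the differential finite.
    """
    if not (math.isfinite(sc) and math.isfinite(sb)):
        raise ValueError("scores must be finite")
    if abs(sb) >= EPS_DENOM:
        return (sc - sb) / sb
    denom = EPS_DENOM if sb >= 0 else -EPS_DENOM
    return (sc - sb) / denom


def classify_agreement(
    rank1_by_scorer: dict[str, str],
) -> dict[str, tuple[AgreementClass, str | None]]:
    """Classify the rank-1 peptides of the three scorers.

    Returns a map from peptide sequence to (class, dissenting scorer).  The
    dissenting scorer is recorded on the minority peptide only.
    """
    for scorer in ("mvh", "xcorr", "wdp"):
        if scorer not in rank1_by_scorer:
            raise ValueError(f"missing rank-1 peptide for scorer {scorer!r}")
    peptides = list(rank1_by_scorer.values())
    distinct = set(peptides)
    if len(distinct) == 1:
        return {peptides[0]: (AgreementClass.UNANIMOUS, None)}
    if len(distinct) == 2:
        counts = {p: peptides.count(p) for p in distinct}
        majority_pep = max(counts, key=counts.get)
        minority_pep = min(counts, key=counts.get)
        dissenter = next(
            s for s, p in rank1_by_scorer.items() if p == minority_pep
        )
        return {
            majority_pep: (AgreementClass.MAJORITY, None),
            minority_pep: (AgreementClass.MINORITY, dissenter),
        }
    return {p: (AgreementClass.DISCORDANT, None) for p in distinct}


@dataclass
class CandidatePSM:
    """A rank-1 PSM entering filtering, with its features and labels."""

    psm: PSM
    agreement: AgreementClass
    dissenting_scorer: str | None = None
    features: np.ndarray | None = None
    classification_score: float = math.nan
    decoy_split: DecoySplit = DecoySplit.NOT_APPLICABLE
    assigned_protein: str | None = None  # highest-spectrum-count parent

    @property
    def is_decoy(self) -> bool:
        return self.psm.is_decoy


def rank1_candidates(by_scan: dict[str, list[PSM]]) -> dict[str, list[CandidatePSM]]:
    """Collect, per scan, the distinct rank-1 PSMs of the three scorers with
    their agreement classes."""
    out: dict[str, list[CandidatePSM]] = {}
    for scan, psms in by_scan.items():
        rank1: dict[str, PSM] = {}
        for p in psms:
            if p.rank_mvh == 1:
                rank1["mvh"] = p
            if p.rank_xcorr == 1:
                rank1["xcorr"] = p
            if p.rank_wdp == 1:
                rank1["wdp"] = p
        if len(rank1) < 3:
            continue  # defensive: a scorer's rank-1 missing from the report
        classes = classify_agreement({s: p.sequence for s, p in rank1.items()})
        seen: dict[str, CandidatePSM] = {}
        for p in rank1.values():
            if p.sequence in seen:
                continue
            cls, dissent = classes[p.sequence]
            seen[p.sequence] = CandidatePSM(p, cls, dissent)
        out[scan] = sorted(seen.values(), key=lambda c: c.psm.sequence)
    return out


def _spectrum_counts(
    candidates: dict[str, list[CandidatePSM]],
    by_scan: dict[str, list[PSM]],
    count_depth: str = "all_reported",
) -> tuple[dict[str, int], dict[str, int]]:
    """Pre-filtering spectrum counts per peptide (#PEP) and per protein (#PRO).

    A peptide's count is the number of pre-filtering PSMs bearing it, across
    all charge states; a protein's count sums the counts of all its peptides
    (unique and shared alike).  ``count_depth`` selects which PSMs count:

    * ``"all_reported"`` (default) — every PSM in the search report.  Random
      matches at every rank then contribute counts to target and decoy
      proteins alike, which keeps the null distribution of the protein-count
      feature target/decoy-symmetric and the held-out FDR estimate unbiased.
    * ``"rank1"`` — only the per-scorer rank-1 PSMs.
    """
    pep_counts: dict[str, int] = {}
    pro_counts: dict[str, int] = {}
    if count_depth == "all_reported":
        pool = [p for psms in by_scan.values() for p in psms]
    elif count_depth == "rank1":
        pool = [c.psm for cands in candidates.values() for c in cands]
    else:
        raise ValueError(f"unknown spectrum-count depth {count_depth!r}")
    for p in pool:
        pep_counts[p.sequence] = pep_counts.get(p.sequence, 0) + 1
        for prot in p.peptide.parent_protein_ids:
            pro_counts[prot] = pro_counts.get(prot, 0) + 1
    return pep_counts, pro_counts


def extract_features(
    candidates: dict[str, list[CandidatePSM]],
    by_scan: dict[str, list[PSM]],
    count_depth: str = "all_reported",
) -> None:
    """Fill the 10-feature vector of every candidate PSM in place.

    The three score differentials compare each PSM against the best *other*
    PSM reported for its spectrum under the same scorer; a spectrum whose
    report holds a single PSM gets the configured cap.
    """
    pep_counts, pro_counts = _spectrum_counts(candidates, by_scan, count_depth)
    for scan, cands in candidates.items():
        reported = by_scan[scan]
        for c in cands:
            p = c.psm
            parents = sorted(p.peptide.parent_protein_ids)
            best_prot = max(parents, key=lambda pr: (pro_counts.get(pr, 0), pr))
            c.assigned_protein = best_prot
            diffs = []
            for scorer in ("mvh", "xcorr", "wdp"):
                sc = getattr(p, scorer)
                others = [
                    getattr(o, scorer)
                    for o in reported
                    if o.sequence != p.sequence and math.isfinite(getattr(o, scorer))
                ]
                if others:
                    diffs.append(score_differential(sc, max(others)))
                else:
                    diffs.append(SINGLE_PSM_DIFFERENTIAL)
            c.features = np.array(
                [
                    p.mvh, p.xcorr, p.wdp,
                    *diffs,
                    p.delta_mass,
                    p.peptide.missed_cleavages,
                    pep_counts[p.sequence],
                    pro_counts[best_prot],
                ]
            )


def split_decoy_proteins(
    decoy_ids: list[str],
    alpha: float = DEFAULT_ALPHA,
    seed: int = DEFAULT_SPLIT_SEED,
) -> dict[str, DecoySplit]:
    """Randomly assign each decoy protein to the test split with probability
    alpha, the rest to the training split.  Deterministic under a fixed seed."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    draws = rng.random(len(decoy_ids))
    assignment = {
        d: (DecoySplit.TEST if u < alpha else DecoySplit.TRAIN)
        for d, u in zip(sorted(decoy_ids), draws)
    }
    kinds = set(assignment.values())
    if len(decoy_ids) > 0 and kinds != {DecoySplit.TRAIN, DecoySplit.TEST}:
        raise ValueError(
            "all decoy proteins fell into one split; cannot both train and estimate FDR"
        )
    return assignment


def realized_alpha(assignment: dict[str, DecoySplit]) -> float:
    n_test = sum(1 for s in assignment.values() if s is DecoySplit.TEST)
    return n_test / len(assignment)


def annotate_splits(
    candidates: dict[str, list[CandidatePSM]],
    assignment: dict[str, DecoySplit],
) -> None:
    """Attach the train/test split of each decoy PSM's assigned parent."""
    for cands in candidates.values():
        for c in cands:
            if c.is_decoy:
                c.decoy_split = assignment[c.assigned_protein]


def build_training_data(
    candidates: dict[str, list[CandidatePSM]],
) -> tuple[list[CandidatePSM], list[CandidatePSM]]:
    """Positives: unanimous target PSMs.  Negatives: decoy PSMs whose assigned
    parent decoy protein is in the training split.  Test-split decoy PSMs
    enter neither set."""
    positives = [
        c
        for cands in candidates.values()
        for c in cands
        if c.agreement is AgreementClass.UNANIMOUS and not c.is_decoy
    ]
    negatives = [
        c
        for cands in candidates.values()
        for c in cands
        if c.is_decoy and c.decoy_split is DecoySplit.TRAIN
    ]
    if not positives or not negatives:
        raise ValueError(
            "empty positive or negative training data; provide a larger search "
            f"(got {len(positives)} positives, {len(negatives)} negatives)"
        )
    return positives, negatives


@dataclass
class TrainedFilter:
    """A fitted PSM classifier with its standardization constants."""

    model_kind: str
    model: object
    feature_mean: np.ndarray
    feature_std: np.ndarray
    kept_features: np.ndarray  # boolean mask over the 10 features
    alpha: float

    def classification_scores(self, X: np.ndarray) -> np.ndarray:
        Z = (X[:, self.kept_features] - self.feature_mean) / self.feature_std
        return self.model.predict_proba(Z)[:, 1]


def _make_model(model_kind: str, seed: int):
    if model_kind == "logistic_regression":
        # default penalty is the L2 norm; C is the inverse regularization strength
        return LogisticRegression(C=1.0, max_iter=2000)
    if model_kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=200,
            criterion="gini",
            min_samples_split=800,
            min_samples_leaf=50,
            random_state=seed,
        )
    if model_kind == "adaboost":
        return AdaBoostClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown model kind {model_kind!r}")


def train_filter(
    positives: list[CandidatePSM],
    negatives: list[CandidatePSM],
    model_kind: str = "logistic_regression",
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> TrainedFilter:
    """Standardize features on the training set and fit the classifier.

    Constant features are dropped with a warning (they carry no signal and
    break standardization)."""
    X = np.array([c.features for c in positives + negatives])
    y = np.array([1] * len(positives) + [0] * len(negatives))
    std = X.std(axis=0)
    kept = std > 0
    for i in np.flatnonzero(~kept):
        logger.warning("dropping constant feature %s", FEATURE_NAMES[i])
    mean = X[:, kept].mean(axis=0)
    sd = X[:, kept].std(axis=0)
    model = _make_model(model_kind, seed)
    model.fit((X[:, kept] - mean) / sd, y)
    return TrainedFilter(model_kind, model, mean, sd, kept, alpha)


def score_candidates(
    candidates: dict[str, list[CandidatePSM]], filt: TrainedFilter
) -> None:
    flat = [c for cands in candidates.values() for c in cands]
    if not flat:
        return
    X = np.array([c.features for c in flat])
    scores = filt.classification_scores(X)
    for c, s in zip(flat, scores):
        c.classification_score = float(s)


def select_psm_per_spectrum(
    candidates: dict[str, list[CandidatePSM]],
) -> dict[str, CandidatePSM]:
    """Keep, per spectrum, the candidate with the highest classification
    score (ties: target over decoy, then lexicographically smaller peptide)."""
    selected: dict[str, CandidatePSM] = {}
    for scan, cands in candidates.items():
        selected[scan] = min(
            cands,
            key=lambda c: (-c.classification_score, c.is_decoy, c.psm.sequence),
        )
    return selected


@dataclass
class FdrEstimate:
    n_target: int
    n_test_decoy: int
    alpha: float
    fdr: float
    undefined: bool = False  # decoys present but no targets


def estimate_fdr(n_target: int, n_test_decoy: int, alpha: float) -> FdrEstimate:
    """Held-out decoy FDR: #TestDecoy / (alpha * #Target)."""
    if n_target < 0 or n_test_decoy < 0:
        raise ValueError("counts must be non-negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if n_target == 0:
        return FdrEstimate(0, n_test_decoy, alpha, 0.0, undefined=n_test_decoy > 0)
    return FdrEstimate(n_target, n_test_decoy, alpha, n_test_decoy / (alpha * n_target))


def _counts_at_threshold(
    accepted: list[CandidatePSM],
    level: str,
    split_assignment=None,
) -> tuple[int, int]:
    """(#Target, #TestDecoy) among accepted identifications at the requested
    level.  Training-split decoys count in neither."""
    from . import assembly  # local import to avoid a cycle

    if level == "psm":
        n_target = sum(1 for c in accepted if not c.is_decoy)
        n_test = sum(1 for c in accepted if c.decoy_split is DecoySplit.TEST)
        return n_target, n_test
    peptides = assembly.assemble_peptides(accepted)
    if level == "peptide":
        n_target = sum(1 for p in peptides if not p.is_decoy)
        n_test = sum(1 for p in peptides if p.decoy_split is DecoySplit.TEST)
        return n_target, n_test
    if level == "protein":
        groups = assembly.infer_proteins(peptides, split_assignment)
        n_target = sum(1 for g in groups if not g.is_decoy)
        n_test = sum(1 for g in groups if g.decoy_split is DecoySplit.TEST)
        return n_target, n_test
    raise ValueError(f"unknown FDR level {level!r}")


@dataclass
class FilterResult:
    threshold: float
    accepted: list[CandidatePSM]
    fdr: FdrEstimate
    level: str
    reached_target: bool


def filter_at_fdr(
    selected: dict[str, CandidatePSM],
    target_fdr: float = 0.01,
    level: str = "psm",
    alpha: float = DEFAULT_ALPHA,
    split_assignment=None,
) -> FilterResult:
    """Choose the smallest classification-score threshold whose estimated FDR
    at the requested level stays within ``target_fdr``.

    The sweep walks the distinct classification scores from high to low,
    re-estimating the level FDR at each cut; training-split decoy PSMs are
    excluded from the accepted set and from the FDR numerator.  If no cut
    meets the target, the empty set is returned with the best achievable FDR.
    """
    pool = sorted(
        (c for c in selected.values() if c.decoy_split is not DecoySplit.TRAIN),
        key=lambda c: (-c.classification_score, c.is_decoy, c.psm.sequence),
    )
    thresholds = sorted({c.classification_score for c in pool}, reverse=True)
    best: FilterResult | None = None
    best_fdr = math.inf
    for t in thresholds:
        accepted = [c for c in pool if c.classification_score >= t]
        n_target, n_test = _counts_at_threshold(accepted, level, split_assignment)
        est = estimate_fdr(n_target, n_test, alpha)
        effective = math.inf if est.undefined else est.fdr
        if effective <= target_fdr:
            best = FilterResult(t, accepted, est, level, True)  # keep widening
        elif best is None and effective < best_fdr:
            best_fdr = effective
    if best is not None:
        return best
    # nothing met the target: report an empty set with the best achievable FDR
    est = FdrEstimate(0, 0, alpha, best_fdr if math.isfinite(best_fdr) else 0.0,
                      undefined=not math.isfinite(best_fdr))
    return FilterResult(math.inf, [], est, level, False)
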