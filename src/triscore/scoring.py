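"""Theoretical b/y fragmentation, the three scoring functions, and the
two-tier ensemble search.

For each spectrum every precursor-window candidate is scored with the
multivariate-hypergeometric score (MVH, cheap), the top candidates by MVH are
rescored with the cross-correlation score (Xcorr) and the weighted dot
product (WDP), and the union of the top-5 peptides per scorer is reported
with all three scores and per-scorer ranks.

Scores increase with match quality for all three functions.  Ties are broken
deterministically everywhere: higher score first, then lexicographically
smaller peptide sequence, then target before decoy.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .constants import PROTON, WATER
from .seqdb import DEFAULT_FIXED_MODS, MassIndex, PeptideCandidate
from .spectra import (
    MvhClassedPeaks,
    Spectrum,
    XcorrArray,
    XCORR_SCALE,
    preprocess_mvh,
    preprocess_xcorr,
    xcorr_bin,
)

TIER2_DEPTH = 50
OUTPUT_DEPTH = 5
FRAGMENT_TOL_DA = 0.5
WDP_ION_WEIGHTS = {"b": 1.0, "y": 1.0}


@dataclass(frozen=True)
class Fragment:
    ion_type: str  # 'b' or 'y'
    index: int
    charge: int
    mz: float


def theoretical_fragments(
    sequence: str,
    precursor_charge: int,
    fixed_mods: dict[str, float] | None = None,
) -> list[Fragment]:
    """Singly charged b/y ions for indices 1..n-1; doubly charged added for
    precursor charge >= 3."""
    if len(sequence) < 2:
        raise ValueError("peptide must have at least two residues")
    if fixed_mods is None:
        fixed_mods = DEFAULT_FIXED_MODS
    from .constants import AA_MONO

    res = np.array([AA_MONO[a] + fixed_mods.get(a, 0.0) for a in sequence])
    b_neutral = np.cumsum(res)[:-1]  # b_i = sum of first i residues
    y_neutral = np.cumsum(res[::-1])[:-1] + WATER  # y_i = last i residues + water
    charges = (1, 2) if precursor_charge >= 3 else (1,)
    frags: list[Fragment] = []
    for z in charges:
        for i, m in enumerate(b_neutral, start=1):
            frags.append(Fragment("b", i, z, (m + z * PROTON) / z))
        for i, m in enumerate(y_neutral, start=1):
            frags.append(Fragment("y", i, z, (m + z * PROTON) / z))
    return frags


def _ln_choose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def score_mvh(
    classed: MvhClassedPeaks,
    fragments: list[Fragment],
    fragment_tol: float = FRAGMENT_TOL_DA,
) -> float:
    """Multivariate-hypergeometric score.

    Each predicted fragment is a draw from the candidate-bin universe; a draw
    lands in the intensity class of the occupied 1-Da bin it matches (each bin
    matched at most once), otherwise in the implicit empty class.  The score
    is -ln of the multivariate hypergeometric probability of the observed
    per-class draw counts, so rarer (higher-intensity) classes reward matches
    more.
    """
    if not fragments:
        raise ValueError("no predicted fragments to score")
    matched_bins: set[int] = set()
    n_draws = 0
    for f in fragments:
        if not (classed.mz_lo <= f.mz < classed.mz_hi):
            continue
        n_draws += 1
        lo_bin = int(f.mz - fragment_tol)
        hi_bin = int(f.mz + fragment_tol)
        best: tuple[float, int] | None = None
        for b in range(lo_bin, hi_bin + 1):
            if b in classed.class_of_bin and b not in matched_bins:
                center = b + 0.5
                d = abs(f.mz - center)
                if d <= fragment_tol and (best is None or d < best[0]):
                    best = (d, b)
        if best is not None:
            matched_bins.add(best[1])
    if n_draws == 0:
        return 0.0
    k = [0] * classed.n_classes
    for b in matched_bins:
        k[classed.class_of_bin[b]] += 1
    n_empty_bins = classed.n_bins - sum(classed.class_counts)
    k_empty = n_draws - len(matched_bins)
    ln_p = (
        sum(_ln_choose(N, kk) for N, kk in zip(classed.class_counts, k))
        + _ln_choose(n_empty_bins, k_empty)
        - _ln_choose(classed.n_bins, n_draws)
    )
    return -ln_p


def score_xcorr(arr: XcorrArray, fragments: list[Fragment]) -> float:
    """Scaled dot product of the unit-intensity theoretical bins with the
    fast-transformed observed vector."""
    bins = {xcorr_bin(f.mz, arr.bin_width) for f in fragments}
    total = sum(arr.binned[b] for b in bins if 0 <= b < arr.n_bins)
    return XCORR_SCALE * total


def score_wdp(
    spectrum: Spectrum,
    fragments: list[Fragment],
    fragment_tol: float = FRAGMENT_TOL_DA,
    ion_weights: dict[str, float] | None = None,
) -> float:
    """Weighted dot product: matched fragments contribute
    w_type * sqrt(I_obs / I_total) * (1 - |dmz| / tol)."""
    if ion_weights is None:
        ion_weights = WDP_ION_WEIGHTS
    if spectrum.is_empty:
        return 0.0
    mz = spectrum.peaks_mz
    inten = spectrum.peaks_intensity
    total_i = float(inten.sum())
    if total_i <= 0:
        return 0.0
    score = 0.0
    for f in fragments:
        j = np.searchsorted(mz, f.mz)
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(mz):
                d = abs(mz[cand] - f.mz)
                if d <= fragment_tol and (best is None or d < best[0]):
                    best = (d, cand)
        if best is not None:
            d, cand = best
            w = ion_weights.get(f.ion_type, 1.0)
            score += w * math.sqrt(inten[cand] / total_i) * (1.0 - d / fragment_tol)
    return score


@dataclass
class PSM:
    """One scored peptide-spectrum match."""

    scan_id: str
    peptide: PeptideCandidate
    charge: int
    mvh: float = math.nan
    xcorr: float = math.nan
    wdp: float = math.nan
    rank_mvh: int = 0
    rank_xcorr: int = 0
    rank_wdp: int = 0
    delta_mass: float = math.nan  # |calculated - measured| precursor mass, Da

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy

    @property
    def sequence(self) -> str:
        return self.peptide.sequence


def _tie_key(score: float, psm: PSM) -> tuple:
    return (-score, psm.sequence, psm.is_decoy)


def score_spectrum(
    spectrum: Spectrum,
    index: MassIndex,
    precursor_tol: float = 10.0,
    precursor_unit: str = "ppm",
    fragment_tol: float = FRAGMENT_TOL_DA,
    tier2_depth: int = TIER2_DEPTH,
    output_depth: int = OUTPUT_DEPTH,
) -> list[PSM]:
    """Two-tier scoring of one spectrum.

    All precursor-window candidates are scored by MVH; the top ``tier2_depth``
    by MVH are rescored by Xcorr and WDP; the union of the top ``output_depth``
    peptides per scorer is returned, every reported PSM carrying all three
    scores and per-scorer ranks.
    """
    neutral = spectrum.precursor_neutral_mass
    candidates = index.query(neutral, precursor_tol, precursor_unit)
    if not candidates or spectrum.is_empty:
        return []
    classed = preprocess_mvh(spectrum)
    psms: list[PSM] = []
    for cand in candidates:
        frags = theoretical_fragments(cand.sequence, spectrum.precursor_charge)
        psm = PSM(
            scan_id=spectrum.scan_id,
            peptide=cand,
            charge=spectrum.precursor_charge,
            delta_mass=abs(cand.neutral_mass - neutral),
        )
        psm.mvh = score_mvh(classed, frags, fragment_tol)
        psms.append(psm)
    psms.sort(key=lambda p: _tie_key(p.mvh, p))
    for r, p in enumerate(psms, start=1):
        p.rank_mvh = r
    top = psms[:tier2_depth]
    arr = preprocess_xcorr(spectrum)
    for p in top:
        frags = theoretical_fragments(p.sequence, spectrum.precursor_charge)
        p.xcorr = score_xcorr(arr, frags)
        p.wdp = score_wdp(spectrum, frags, fragment_tol)
    by_xcorr = sorted(top, key=lambda p: _tie_key(p.xcorr, p))
    by_wdp = sorted(top, key=lambda p: _tie_key(p.wdp, p))
    for r, p in enumerate(by_xcorr, start=1):
        p.rank_xcorr = r
    for r, p in enumerate(by_wdp, start=1):
        p.rank_wdp = r
    keep: dict[str, PSM] = {}
    for pool in (psms[:output_depth], by_xcorr[:output_depth], by_wdp[:output_depth]):
        for p in pool:
            keep.setdefault(p.sequence, p)
    return sorted(keep.values(), key=lambda p: p.rank_mvh)


def search(
    spectra: list[Spectrum],
    index: MassIndex,
    precursor_tol: float = 10.0,
    precursor_unit: str = "ppm",
    fragment_tol: float = FRAGMENT_TOL_DA,
    tier2_depth: int = TIER2_DEPTH,
    output_depth: int = OUTPUT_DEPTH,
    batch_size: int = 20_000,
    n_workers: int = 1,
) -> dict[str, list[PSM]]:
    """Search all spectra, returning reported PSMs keyed by scan id.

    When a scan appears at several assumed precursor charges, each charge is
    scored independently and the charge whose best MVH score is highest is
    kept for the scan.  Work is split into fixed-size batches whose results
    are merged in input order, so output is invariant to batch size and
    worker count.
    """

    def _one(spectrum: Spectrum) -> list[PSM]:
        return score_spectrum(
            spectrum, index, precursor_tol, precursor_unit,
            fragment_tol, tier2_depth, output_depth,
        )

    batches = [spectra[i : i + batch_size] for i in range(0, len(spectra), batch_size)]
    results: list[list[PSM]] = []
    if n_workers > 1 and len(batches) > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            for batch_out in pool.map(lambda b: [_one(s) for s in b], batches):
                results.extend(batch_out)
    else:
        for batch in batches:
            results.extend(_one(s) for s in batch)

    by_scan: dict[str, list[PSM]] = {}
    for psms in results:
        if not psms:
            continue
        scan = psms[0].scan_id
        prev = by_scan.get(scan)
        if prev is None:
            by_scan[scan] = psms
        else:
            # keep the assumed charge with the better best-MVH (deterministic ties)
            best_new = min(_tie_key(p.mvh, p) for p in psms)
            best_old = min(_tie_key(p.mvh, p) for p in prev)
            if best_new < best_old:
                by_scan[scan] = psms
    return by_scan
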