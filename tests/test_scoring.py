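"""Theoretical fragmentation, the three scorers (each against an independent
oracle), and the two-tier ensemble search."""

import itertools
import math

import numpy as np
import pytest

from triscore import scoring, seqdb
from triscore.constants import PROTON
from triscore.scoring import (
    Fragment,
    score_mvh,
    score_spectrum,
    score_wdp,
    score_xcorr,
    search,
    theoretical_fragments,
)
from triscore.seqdb import PeptideCandidate, build_mass_index, peptide_mass
from triscore.spectra import (
    MvhClassedPeaks,
    Spectrum,
    XCORR_SCALE,
    preprocess_xcorr,
    xcorr_bin,
)


def _spectrum(mz, inten, pepmass=500.0, charge=2, scan="s"):
    return Spectrum(scan, pepmass, charge, np.asarray(mz, float), np.asarray(inten, float))


class TestTheoreticalFragments:
    def test_b2_and_y1_of_peptide(self):
        frags = {(f.ion_type, f.index, f.charge): f.mz
                 for f in theoretical_fragments("PEPTIDE", 2, fixed_mods={})}
        assert frags[("b", 2, 1)] == pytest.approx(227.10262, abs=1e-4)
        assert frags[("y", 1, 1)] == pytest.approx(148.06043, abs=1e-4)

    def test_doubly_charged_only_for_high_precursor_charge(self):
        z2 = {f.charge for f in theoretical_fragments("PEPTIDEK", 2)}
        z3 = {f.charge for f in theoretical_fragments("PEPTIDEK", 3)}
        assert z2 == {1} and z3 == {1, 2}

    def test_by_complementarity(self):
        seq = "ACDEFGHIK"
        n = len(seq)
        frags = {(f.ion_type, f.index): f.mz
                 for f in theoretical_fragments(seq, 2, fixed_mods={})}
        total = peptide_mass(seq, fixed_mods={})
        for i in range(1, n):
            b, y = frags[("b", i)], frags[("y", n - i)]
            # neutral(b_i) + neutral(y_{n-i}) = precursor neutral mass
            assert (b - PROTON) + (y - PROTON) == pytest.approx(total, abs=1e-6)

    def test_too_short_peptide_rejected(self):
        with pytest.raises(ValueError):
            theoretical_fragments("A", 2)


def mvh_enumeration_oracle(classed: MvhClassedPeaks, fragments) -> float:
    """Exhaustive oracle: enumerate every way of drawing n bins from the
    universe and sum the probability of those reproducing the observed
    per-class counts."""
    # reproduce the matcher to obtain the observed configuration
    matched = set()
    n_draws = 0
    for f in fragments:
        if not (classed.mz_lo <= f.mz < classed.mz_hi):
            continue
        n_draws += 1
        best = None
        for b in range(int(f.mz - 0.5), int(f.mz + 0.5) + 1):
            if b in classed.class_of_bin and b not in matched:
                d = abs(f.mz - (b + 0.5))
                if d <= 0.5 and (best is None or d < best[0]):
                    best = (d, b)
        if best:
            matched.add(best[1])
    observed = [0] * classed.n_classes
    for b in matched:
        observed[classed.class_of_bin[b]] += 1
    observed.append(n_draws - len(matched))  # empty class
    # enumerate all draws of n bins out of the universe
    bins = []
    for b, cls in classed.class_of_bin.items():
        bins.append(cls)
    bins += [classed.n_classes] * (classed.n_bins - len(classed.class_of_bin))
    hits = 0
    total = 0
    for combo in itertools.combinations(range(len(bins)), n_draws):
        total += 1
        counts = [0] * (classed.n_classes + 1)
        for i in combo:
            counts[bins[i]] += 1
        if counts == observed:
            hits += 1
    return -math.log(hits / total)


class TestScoreMvh:
    def _tiny_classed(self, class_of_bin, n_bins):
        counts = [0, 0, 0]
        for cls in class_of_bin.values():
            counts[cls] += 1
        return MvhClassedPeaks(class_of_bin, counts, n_bins, 3, 0.0, float(n_bins))

    def test_matches_exhaustive_enumeration_on_tiny_instances(self, rng):
        for trial in range(20):
            n_bins = int(rng.integers(8, 16))
            n_occ = int(rng.integers(2, min(7, n_bins)))
            occupied = rng.choice(n_bins, size=n_occ, replace=False)
            class_of_bin = {int(b): int(rng.integers(0, 3)) for b in occupied}
            classed = self._tiny_classed(class_of_bin, n_bins)
            n_frags = int(rng.integers(1, 4))
            frag_bins = rng.choice(n_bins, size=n_frags, replace=False)
            frags = [Fragment("b", i + 1, 1, float(b) + 0.5)
                     for i, b in enumerate(frag_bins)]
            got = score_mvh(classed, frags)
            expected = mvh_enumeration_oracle(classed, frags)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_zero_matches_equals_all_empty_draw_probability(self):
        classed = self._tiny_classed({0: 0, 1: 1, 2: 2}, 10)
        frags = [Fragment("b", 1, 1, 5.5), Fragment("b", 2, 1, 7.5)]
        got = score_mvh(classed, frags)
        # both draws from the 7 empty bins out of 10
        expected = -math.log(math.comb(7, 2) / math.comb(10, 2))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_match_in_rarer_class_scores_strictly_higher(self):
        # class occupancies 1 (top) vs 3 (bottom): hitting the rarer class is
        # less probable, hence a larger -ln probability
        base = {0: 0, 2: 2, 3: 2, 4: 2}
        classed = self._tiny_classed(base, 12)
        hit_top = score_mvh(classed, [Fragment("b", 1, 1, 0.5)])
        hit_bottom = score_mvh(classed, [Fragment("b", 1, 1, 2.5)])
        assert hit_top > hit_bottom

    def test_no_fragments_is_an_error(self):
        classed = self._tiny_classed({0: 0}, 5)
        with pytest.raises(ValueError):
            score_mvh(classed, [])


def xcorr_naive_oracle(spectrum: Spectrum, fragments, halfwidth=75) -> float:
    """Direct cross-correlation: dot(theo, binned) minus the mean of
    dot(theo, binned shifted by tau) over tau = -75..75 excluding 0."""
    from triscore.spectra import bin_spectrum_xcorr

    raw = bin_spectrum_xcorr(spectrum)
    theo = np.zeros_like(raw)
    for b in {xcorr_bin(f.mz) for f in fragments}:
        if 0 <= b < len(theo):
            theo[b] = 1.0
    dot0 = float(theo @ raw)
    shifted_sum = 0.0
    for tau in range(-halfwidth, halfwidth + 1):
        if tau == 0:
            continue
        shifted = np.zeros_like(raw)
        if tau > 0:
            shifted[tau:] = raw[:-tau]
        else:
            shifted[:tau] = raw[-tau:]
        shifted_sum += float(theo @ shifted)
    return XCORR_SCALE * (dot0 - shifted_sum / (2 * halfwidth))


class TestScoreXcorr:
    def test_matches_naive_cross_correlation(self, rng):
        for _ in range(10):
            n = 60
            mz = np.sort(rng.uniform(150, 900, n))
            inten = rng.random(n) * 100
            s = _spectrum(mz, inten, pepmass=600.0, charge=2)
            frags = [Fragment("b", i + 1, 1, float(m))
                     for i, m in enumerate(rng.uniform(150, 900, 12))]
            fast = score_xcorr(preprocess_xcorr(s), frags)
            naive = xcorr_naive_oracle(s, frags)
            assert fast == pytest.approx(naive, abs=1e-6)

    def test_zero_spectrum_scores_zero(self):
        s = _spectrum([], [])
        frags = theoretical_fragments("PEPTIDEK", 2)
        assert score_xcorr(preprocess_xcorr(s), frags) == 0.0

    def test_own_fragments_beat_random_same_mass_peptides(self, rng):
        seq = "ACDEFGHIKLNK"
        frags = theoretical_fragments(seq, 2)
        mz = np.array(sorted(f.mz for f in frags))
        s = _spectrum(mz, np.full(len(mz), 100.0),
                      pepmass=(peptide_mass(seq) + 2 * PROTON) / 2, charge=2)
        arr = preprocess_xcorr(s)
        own = score_xcorr(arr, frags)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(100):
            other = "".join(rng.choice(alphabet, len(seq)))
            if other == seq:
                continue
            assert score_xcorr(arr, theoretical_fragments(other, 2)) < own


class TestScoreWdp:
    def test_no_matches_scores_zero(self):
        s = _spectrum([1000.0], [5.0])
        frags = [Fragment("b", 1, 1, 200.0)]
        assert score_wdp(s, frags) == 0.0

    def test_perfect_match_closed_form(self):
        frags = theoretical_fragments("PEPTIDEK", 2)
        mz = np.array(sorted(f.mz for f in frags))
        s = _spectrum(mz, np.full(len(mz), 7.0))
        # every fragment matched at dmz=0 with equal intensities
        expected = len(frags) * math.sqrt(1.0 / len(mz))
        assert score_wdp(s, frags) == pytest.approx(expected, abs=1e-9)

    def test_direct_formula_recomputation(self, rng):
        seq = "LMNPQRSTVK"
        frags = theoretical_fragments(seq, 2)
        mz = np.sort(rng.uniform(150, 900, 40))
        inten = rng.random(40) * 50
        s = _spectrum(mz, inten)
        got = score_wdp(s, frags)
        total = inten.sum()
        expected = 0.0
        for f in frags:
            dmz = np.abs(mz - f.mz)
            j = int(np.argmin(dmz))
            if dmz[j] <= 0.5:
                expected += math.sqrt(inten[j] / total) * (1 - dmz[j] / 0.5)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_halving_matched_intensity_decreases_score(self):
        frags = [Fragment("y", 1, 1, 300.0)]
        s_full = _spectrum([300.0, 500.0], [8.0, 2.0])
        s_half = _spectrum([300.0, 500.0], [4.0, 2.0])
        assert score_wdp(s_half, frags) < score_wdp(s_full, frags)


def _planted_database_and_spectrum(rng, n_peptides=30):
    """A database of tryptic-like peptides and a clean spectrum synthesized
    from one of them."""
    alphabet = list("ACDEFGHILMNPQSTV")
    peps = []
    for i in range(n_peptides):
        seq = "".join(rng.choice(alphabet, int(rng.integers(7, 13)))) + "K"
        peps.append(PeptideCandidate(seq, peptide_mass(seq), 0, {f"p{i}"}))
    target = peps[0]
    frags = theoretical_fragments(target.sequence, 2)
    mz = np.array(sorted(f.mz for f in frags))
    spectrum = Spectrum(
        "planted",
        (target.neutral_mass + 2 * PROTON) / 2,
        2,
        mz,
        np.full(len(mz), 100.0),
    )
    return peps, target, spectrum


class TestSearch:
    def test_planted_peptide_ranks_first_under_all_scorers(self, rng):
        peps, target, spectrum = _planted_database_and_spectrum(rng)
        index = build_mass_index(peps)
        psms = score_spectrum(spectrum, index, precursor_tol=3000.0, precursor_unit="Da")
        best = next(p for p in psms if p.sequence == target.sequence)
        assert (best.rank_mvh, best.rank_xcorr, best.rank_wdp) == (1, 1, 1)

    def test_no_candidates_yields_empty_output(self, rng):
        peps, _, spectrum = _planted_database_and_spectrum(rng)
        index = build_mass_index(peps)
        far = Spectrum("far", 3000.0, 2, spectrum.peaks_mz, spectrum.peaks_intensity)
        assert score_spectrum(far, index, precursor_tol=0.01, precursor_unit="Da") == []

    def test_two_tier_equals_exhaustive_for_small_candidate_sets(self, rng):
        # with <= 50 candidates tier 2 rescans everything, so a run with a
        # huge tier-2 depth must give the identical report
        peps, _, spectrum = _planted_database_and_spectrum(rng, n_peptides=40)
        index = build_mass_index(peps)
        kw = dict(precursor_tol=3000.0, precursor_unit="Da")
        two_tier = score_spectrum(spectrum, index, tier2_depth=50, **kw)
        exhaustive = score_spectrum(spectrum, index, tier2_depth=10**6, **kw)
        assert [(p.sequence, p.mvh, p.xcorr, p.wdp,
                 p.rank_mvh, p.rank_xcorr, p.rank_wdp) for p in two_tier] == \
               [(p.sequence, p.mvh, p.xcorr, p.wdp,
                 p.rank_mvh, p.rank_xcorr, p.rank_wdp) for p in exhaustive]

    def test_rank1_attains_the_maximum_per_scorer(self, searched):
        _, by_scan, _, _, _ = searched
        for scan, psms in by_scan.items():
            for scorer, rank_attr in (("mvh", "rank_mvh"), ("xcorr", "rank_xcorr"),
                                      ("wdp", "rank_wdp")):
                r1 = [p for p in psms if getattr(p, rank_attr) == 1]
                if r1:
                    top = max(getattr(p, scorer) for p in psms)
                    assert getattr(r1[0], scorer) == top

    def test_results_invariant_to_batch_size_and_workers(self, rng):
        peps, _, spectrum = _planted_database_and_spectrum(rng)
        index = build_mass_index(peps)
        spectra_list = []
        for i in range(8):
            s = Spectrum(f"s{i}", spectrum.precursor_mz, 2,
                         spectrum.peaks_mz, spectrum.peaks_intensity)
            spectra_list.append(s)
        kw = dict(precursor_tol=3000.0, precursor_unit="Da")
        runs = [
            search(spectra_list, index, batch_size=10, n_workers=1, **kw),
            search(spectra_list, index, batch_size=3, n_workers=1, **kw),
            search(spectra_list, index, batch_size=3, n_workers=4, **kw),
        ]
        snap = [
            {scan: [(p.sequence, p.mvh, p.xcorr, p.wdp) for p in psms]
             for scan, psms in r.items()}
            for r in runs
        ]
        assert snap[0] == snap[1] == snap[2]
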