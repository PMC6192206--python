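"""MS2 spectrum input and per-scorer preprocessing.

Each scoring function sees the spectrum through its own representation:

* Xcorr scores against a dense binned vector whose intensities are
  square-rooted, regionally max-normalized, and mean-subtracted over a sliding
  offset window (the "fast" transform, which makes the cross-correlation a
  single dot product).
* MVH scores against intensity-classed peaks: the retained peaks are split by
  descending intensity into geometrically sized classes, and all unoccupied
  1-Da bins of the scored range form an implicit "empty" class.
* WDP reads the raw peak list directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pyteomics import mgf as _mgf

from .constants import PROTON

#: Comet-convention Xcorr binning constants.
XCORR_BIN_WIDTH = 1.0005079
XCORR_BIN_OFFSET = 0.4
XCORR_N_REGIONS = 10
XCORR_NORM_MAX = 50.0
XCORR_OFFSET_HALFWIDTH = 75
XCORR_SCALE = 0.005

MVH_N_CLASSES = 3


@dataclass
class Spectrum:
    """One MS2 spectrum: precursor and a peak list sorted by m/z."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray

    @property
    def precursor_neutral_mass(self) -> float:
        return (self.precursor_mz - PROTON) * self.precursor_charge

    @property
    def is_empty(self) -> bool:
        return len(self.peaks_mz) == 0


def read_mgf(path, assumed_charges: tuple[int, ...] = (2, 3)) -> list[Spectrum]:
    """Read an MGF file into spectra (one per BEGIN/END IONS block).

    A block without a CHARGE line is expanded into one spectrum per assumed
    charge state, sharing the scan id.
    """
    spectra: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, block in enumerate(reader):
            try:
                params = block["params"]
                scan = str(params.get("title", f"scan={i}"))
                pepmass = params["pepmass"][0]
                mz = np.asarray(block["m/z array"], dtype=float)
                inten = np.asarray(block["intensity array"], dtype=float)
            except (KeyError, TypeError, IndexError) as exc:
                raise ValueError(f"malformed MGF block {i}: {exc}") from exc
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
            charges = params.get("charge")
            charge_list = [int(c) for c in charges] if charges else list(assumed_charges)
            for z in charge_list:
                spectra.append(Spectrum(scan, float(pepmass), z, mz, inten))
    return spectra


@dataclass
class XcorrArray:
    """Fast-transformed binned spectrum for Xcorr scoring."""

    bin_width: float
    binned: np.ndarray  # transformed intensities, index = bin number
    n_bins: int


def xcorr_bin(mz: float, bin_width: float = XCORR_BIN_WIDTH,
              offset: float = XCORR_BIN_OFFSET) -> int:
    return int(mz / bin_width + 1.0 - offset)


def bin_spectrum_xcorr(
    spectrum: Spectrum,
    bin_width: float = XCORR_BIN_WIDTH,
    n_regions: int = XCORR_N_REGIONS,
    norm_max: float = XCORR_NORM_MAX,
) -> np.ndarray:
    """Square-root, bin and regionally normalize intensities (no transform yet)."""
    max_mass = spectrum.precursor_neutral_mass + 2 * PROTON + 50.0
    n_bins = xcorr_bin(max_mass, bin_width) + XCORR_OFFSET_HALFWIDTH + 2
    binned = np.zeros(n_bins)
    if spectrum.is_empty:
        return binned
    for mz, inten in zip(spectrum.peaks_mz, spectrum.peaks_intensity):
        if inten <= 0:
            continue
        b = xcorr_bin(mz, bin_width)
        if 0 <= b < n_bins:
            binned[b] = max(binned[b], np.sqrt(inten))
    # split the occupied range into regions, each max-normalized to norm_max
    top = xcorr_bin(float(spectrum.peaks_mz[-1]), bin_width) + 1
    region_size = max(1, int(np.ceil(top / n_regions)))
    for r in range(n_regions):
        sl = slice(r * region_size, min((r + 1) * region_size, n_bins))
        peak = binned[sl].max() if sl.start < n_bins and binned[sl].size else 0.0
        if peak > 0:
            binned[sl] *= norm_max / peak
    return binned


def fast_xcorr_transform(
    binned: np.ndarray, halfwidth: int = XCORR_OFFSET_HALFWIDTH
) -> np.ndarray:
    """Subtract from each bin the mean of its +-halfwidth neighbours (self excluded).

    y'[i] = y[i] - (1 / 2w) * sum_{j=i-w..i+w, j != i} y[j], computed with a
    cumulative sum so the whole array costs O(n).
    """
    n = len(binned)
    csum = np.concatenate([[0.0], np.cumsum(binned)])
    idx = np.arange(n)
    lo = np.maximum(idx - halfwidth, 0)
    hi = np.minimum(idx + halfwidth, n - 1)
    window_sum = csum[hi + 1] - csum[lo] - binned
    return binned - window_sum / (2 * halfwidth)


def preprocess_xcorr(
    spectrum: Spectrum,
    bin_width: float = XCORR_BIN_WIDTH,
    n_regions: int = XCORR_N_REGIONS,
    norm_max: float = XCORR_NORM_MAX,
    offset_halfwidth: int = XCORR_OFFSET_HALFWIDTH,
) -> XcorrArray:
    binned = bin_spectrum_xcorr(spectrum, bin_width, n_regions, norm_max)
    transformed = fast_xcorr_transform(binned, offset_halfwidth)
    return XcorrArray(bin_width=bin_width, binned=transformed, n_bins=len(binned))


@dataclass
class MvhClassedPeaks:
    """Intensity-classed peaks for multivariate-hypergeometric scoring.

    ``class_of_bin`` maps each occupied 1-Da bin to its intensity class
    (0 = most intense class); ``class_counts`` are the per-class occupancies
    and ``n_bins`` the candidate-bin universe of the scored m/z range, so the
    empty class holds ``n_bins - sum(class_counts)`` bins.
    """

    class_of_bin: dict[int, int]
    class_counts: list[int]
    n_bins: int
    n_classes: int
    mz_lo: float
    mz_hi: float


def geometric_partition(n_peaks: int, n_classes: int) -> list[int]:
    """Split n peaks into classes sized 1:2:4:... with the remainder in the last.

    Class i (i < C-1) gets floor(n * 2^i / (2^C - 1)); the last class takes
    whatever remains.
    """
    denom = 2**n_classes - 1
    sizes = [(n_peaks * 2**i) // denom for i in range(n_classes - 1)]
    sizes.append(n_peaks - sum(sizes))
    return sizes


def preprocess_mvh(
    spectrum: Spectrum, n_classes: int = MVH_N_CLASSES
) -> MvhClassedPeaks:
    """Filter to the most intense peak per 1-Da bin, then class by intensity.

    Ties in intensity are broken by ascending m/z.  The candidate-bin universe
    is the number of 1-Da bins spanning the scored m/z range (up to the
    precursor neutral mass + a small margin, so all b/y fragments fit).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    mz_lo = 0.0
    mz_hi = spectrum.precursor_neutral_mass + 2 * PROTON + 1.0
    n_bins = int(mz_hi - mz_lo) + 1
    if spectrum.is_empty:
        return MvhClassedPeaks({}, [0] * n_classes, n_bins, n_classes, mz_lo, mz_hi)
    # retain the most intense peak per 1-Da window
    best_in_bin: dict[int, tuple[float, float]] = {}
    for mz, inten in zip(spectrum.peaks_mz, spectrum.peaks_intensity):
        if not (mz_lo <= mz < mz_hi):
            continue
        b = int(mz - mz_lo)
        cur = best_in_bin.get(b)
        if cur is None or inten > cur[1]:
            best_in_bin[b] = (mz, inten)
    # sort by descending intensity, ascending m/z on ties
    retained = sorted(best_in_bin.items(), key=lambda kv: (-kv[1][1], kv[1][0]))
    sizes = geometric_partition(len(retained), n_classes)
    class_of_bin: dict[int, int] = {}
    pos = 0
    for cls, size in enumerate(sizes):
        for b, _ in retained[pos : pos + size]:
            class_of_bin[b] = cls
        pos += size
    return MvhClassedPeaks(class_of_bin, sizes, n_bins, n_classes, mz_lo, mz_hi)
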