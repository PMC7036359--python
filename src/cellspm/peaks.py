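"""Centroided peak lists and the preprocessing rules applied to them.

A :class:`PeakList` is one cell's centroided spectrum: an m/z array and a
parallel intensity array. The preprocessing chain applied before any
similarity scoring is fixed:

    denoise -> blank subtraction -> (optional integer-mass conversion)
            -> base-peak normalization

Each step is a pure function returning a new :class:`PeakList`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PeakList",
    "PreprocessParams",
    "denoise",
    "subtract_blank",
    "normalize_basepeak",
    "to_integer_spectrum",
    "mad_noise_level",
    "preprocess",
]

#: nominal acquisition window; informational only, never enforced
ACQUISITION_RANGE = (100.0, 1000.0)


@dataclass(frozen=True)
class PeakList:
    """An immutable centroided spectrum.

    ``mz`` is strictly ascending and positive; ``intensity`` is positive
    (zero-intensity peaks are dropped on construction, duplicate m/z values
    are merged by summing their intensities). Both arrays always have the
    same length, :attr:`n_peaks`.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64).ravel()
        inten = np.asarray(self.intensity, dtype=np.float64).ravel()
        if mz.shape != inten.shape:
            raise ValueError(
                f"mz and intensity must have equal length, got {mz.size} != {inten.size}"
            )
        if np.any(~np.isfinite(mz)) or np.any(~np.isfinite(inten)):
            raise ValueError("mz and intensity must be finite")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        # drop zero-intensity peaks: they cannot contribute to any score
        keep = inten > 0
        mz, inten = mz[keep], inten[keep]
        if np.any(mz <= 0):
            raise ValueError("m/z values must be positive")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        # merge exact duplicate m/z by summing intensity
        if mz.size > 1 and np.any(np.diff(mz) == 0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            inten = np.bincount(inverse, weights=inten)
            mz = uniq
        if mz.size and (mz[0] < ACQUISITION_RANGE[0] or mz[-1] > ACQUISITION_RANGE[1]):
            warnings.warn(
                "peaks outside the nominal m/z 100-1000 acquisition window",
                stacklevel=2,
            )
        mz.setflags(write=False)
        inten.setflags(write=False)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def __len__(self) -> int:
        return self.n_peaks

    @property
    def base_peak_intensity(self) -> float:
        if self.n_peaks == 0:
            raise ValueError("empty peak list has no base peak")
        return float(self.intensity.max())

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakList):
            return NotImplemented
        return (
            self.mz.shape == other.mz.shape
            and bool(np.all(self.mz == other.mz))
            and bool(np.all(self.intensity == other.intensity))
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PeakList(n_peaks={self.n_peaks})"


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the fixed preprocessing chain.

    snr
        signal-to-noise threshold used by :func:`denoise` (default 5).
    blank_tol_ppm
        relative tolerance for blank-peak removal; by default the same
        5 ppm window used for high-resolution spectral matching.
    min_peaks
        minimum number of peaks a spectrum must retain to stay in a
        database (default 2; a one-peak spectrum carries no pattern).
    """

    snr: float = 5.0
    blank_tol_ppm: float = 5.0
    min_peaks: int = 2

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be > 0")
        if not self.blank_tol_ppm > 0:
            raise ValueError("blank_tol_ppm must be > 0")
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")


def mad_noise_level(intensity: np.ndarray) -> float:
    """Robust noise level of a centroid intensity vector.

    Returns ``1.4826 * MAD`` (median absolute deviation scaled to be
    consistent with a Gaussian sigma). If the MAD is zero (more than half
    of the intensities identical) falls back to 20% of the median; if that
    is also zero the noise level is 0, i.e. nothing is removed.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.size == 0:
        return 0.0
    med = float(np.median(intensity))
    mad = float(np.median(np.abs(intensity - med)))
    noise = 1.4826 * mad
    if noise == 0.0:
        noise = 0.2 * med
    return noise


def denoise(p: PeakList, snr: float) -> PeakList:
    """Remove peaks below ``snr`` times the spectrum's noise level.

    The noise level is estimated by :func:`mad_noise_level`; a noise level
    of zero keeps every peak. May return an empty peak list.
    """
    if not snr > 0:
        raise ValueError("snr must be > 0")
    if p.n_peaks == 0:
        raise ValueError("cannot denoise an empty peak list")
    noise = mad_noise_level(p.intensity)
    if noise == 0.0:
        return p
    keep = p.intensity >= snr * noise
    return PeakList(p.mz[keep], p.intensity[keep])


def _covered_by_windows(mz: np.ndarray, centers: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Boolean mask of ``mz`` values lying within +/- tol_ppm of any center.

    Window half-widths are relative to the *center* (reference) m/z. Both
    inputs must be ascending; the windows lo/hi are then ascending too,
    which allows a two-searchsorted sweep instead of a pairwise scan.
    """
    if centers.size == 0 or mz.size == 0:
        return np.zeros(mz.size, dtype=bool)
    half = tol_ppm * 1e-6 * centers
    lo = centers - half
    hi = centers + half
    # rightmost window starting at or before each mz
    j = np.searchsorted(lo, mz, side="right") - 1
    mask = j >= 0
    mask[mask] = hi[j[mask]] >= mz[mask]
    return mask


def subtract_blank(p: PeakList, blank: PeakList, tol_ppm: float) -> PeakList:
    """Remove peaks co-occurring (within ``tol_ppm``) with a medium blank.

    The tolerance half-width is computed from the blank peak m/z.
    Intensities of surviving peaks are unchanged. An empty blank removes
    nothing.
    """
    if not tol_ppm > 0:
        raise ValueError("tol_ppm must be > 0")
    hit = _covered_by_windows(p.mz, blank.mz, tol_ppm)
    return PeakList(p.mz[~hit], p.intensity[~hit])


def normalize_basepeak(p: PeakList) -> PeakList:
    """Divide intensities by the base-peak (maximum) intensity.

    The output's maximum intensity is exactly 1.0.
    """
    if p.n_peaks == 0:
        raise ValueError("cannot base-peak normalize an empty peak list")
    return PeakList(p.mz, p.intensity / p.base_peak_intensity)


def to_integer_spectrum(p: PeakList) -> PeakList:
    """Round m/z to integers and merge coincident peaks by summing intensity.

    Rounding is half-to-even (numpy's default), centralized here so the
    rule can be swapped in one place. Total intensity is conserved.
    """
    if p.n_peaks == 0:
        raise ValueError("cannot convert an empty peak list")
    rounded = np.rint(p.mz)
    uniq, inverse = np.unique(rounded, return_inverse=True)
    inten = np.bincount(inverse, weights=p.intensity)
    return PeakList(uniq, inten)


def preprocess(
    p: PeakList,
    blank: PeakList | None,
    params: PreprocessParams = PreprocessParams(),
    integer: bool = False,
) -> PeakList | None:
    """Apply the full chain: denoise, blank subtraction, optional integer
    conversion, base-peak normalization.

    Returns ``None`` if the spectrum is emptied along the way (the caller
    decides whether to drop or report the record).
    """
    if p.n_peaks == 0:
        return None
    q = denoise(p, params.snr)
    if blank is not None and blank.n_peaks and q.n_peaks:
        q = subtract_blank(q, blank, params.blank_tol_ppm)
    if q.n_peaks == 0:
        return None
    if integer:
        q = to_integer_spectrum(q)
    return normalize_basepeak(q)
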