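"""Quadratic B-spline discrete wavelet transform.

The P300 component lives in the delta band (0-4 Hz).  A five-level dyadic
decomposition of a 250 Hz signal puts the deepest approximation band at
0 - 250/2**6 = 3.90625 Hz, i.e. the delta band, and the approximation
coefficients at that depth are the wavelet features used downstream.

The mother wavelet is the quadratic B-spline, realised as a biorthogonal
spline filter pair.  The analysis low-pass carries the quadratic B-spline
scaling coefficients from its two-scale relation,

    dec_lo = sqrt(2)/8 * [1, 3, 3, 1]   (sums to sqrt(2)),

zero-padded to the length of its dual; the analysis high-pass is the
standard spline dual with ``dual_moments`` vanishing moments (7 by
default) and sums to 0.  The short duals (1 or 3 moments) reconstruct
perfectly but smear octave bands badly; 7 dual moments give a clean
delta-band/detail energy split while keeping the same B-spline analysis
low-pass.  All four tap vectors are frozen in the returned
:class:`FilterBank` so results are bit-comparable across implementations.

Boundary handling is half-point symmetric extension throughout; analysis
filters convolve and then downsample keeping odd output indices (the
convention of :mod:`pywt`, which performs the actual filtering).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "FilterBank",
    "WaveletDecomposition",
    "build_bspline_bank",
    "dwt_multilevel",
    "idwt_multilevel",
    "delta_coefficients",
]

_SQRT2 = math.sqrt(2.0)

# Quadratic B-spline scaling coefficients (two-scale relation of the
# degree-2 B-spline), normalised so the low-pass sums to sqrt(2).
BSPLINE2_SCALING = tuple(_SQRT2 / 8.0 * np.array([1.0, 3.0, 3.0, 1.0]))


@dataclass(frozen=True)
class FilterBank:
    """A biorthogonal analysis/synthesis filter quadruple."""

    dec_lo: tuple[float, ...]
    dec_hi: tuple[float, ...]
    rec_lo: tuple[float, ...]
    rec_hi: tuple[float, ...]
    name: str = "bspline2"

    def to_pywt(self) -> pywt.Wavelet:
        return pywt.Wavelet(
            self.name,
            filter_bank=[list(self.dec_lo), list(self.dec_hi), list(self.rec_lo), list(self.rec_hi)],
        )


@dataclass
class WaveletDecomposition:
    """Multilevel DWT output with band-edge bookkeeping.

    ``approx`` holds the deepest-level approximation coefficients (the "A"
    output, scale-function side); ``details[j-1]`` holds the level-``j``
    detail coefficients (the "D" output, wavelet-function side) covering
    the octave band [fs/2**(j+1), fs/2**j] Hz.
    """

    approx: np.ndarray
    details: list[np.ndarray]
    levels: int
    fs: float
    n_samples: int
    band_edges: dict = field(default_factory=dict)

    @property
    def approx_band(self) -> tuple[float, float]:
        return (0.0, self.fs / 2 ** (self.levels + 1))

    def detail_band(self, level: int) -> tuple[float, float]:
        if not 1 <= level <= self.levels:
            raise ValueError(f"level must be in 1..{self.levels}")
        return (self.fs / 2 ** (level + 1), self.fs / 2 ** level)


def build_bspline_bank(spline_order: int = 2, dual_moments: int = 7) -> FilterBank:
    """Return the quadratic B-spline biorthogonal filter bank.

    Only ``spline_order=2`` (quadratic) is provided.  The analysis
    low-pass holds the B-spline scaling coefficients (1, 3, 3, 1)/8
    normalised to sum to sqrt(2) (zero-padded to the dual's length); the
    dual high-pass has ``dual_moments`` vanishing moments (odd, 1..9).
    """
    if spline_order != 2:
        raise ValueError(f"unsupported spline order {spline_order}; only 2 (quadratic) is built")
    if dual_moments not in (1, 3, 5, 7, 9):
        raise ValueError("dual_moments must be one of 1, 3, 5, 7, 9")
    w = pywt.Wavelet(f"rbio3.{dual_moments}")
    bank = FilterBank(
        tuple(w.dec_lo), tuple(w.dec_hi), tuple(w.rec_lo), tuple(w.rec_hi),
        name=f"bspline2-d{dual_moments}",
    )
    # the nonzero analysis low-pass taps are exactly the B-spline ones
    nz = np.array(bank.dec_lo)[np.array(bank.dec_lo) != 0.0]
    assert np.allclose(nz, BSPLINE2_SCALING)
    return bank


def dwt_multilevel(
    x: np.ndarray,
    bank: FilterBank,
    levels: int = 5,
    fs: float = 250.0,
    mode: str = "symmetric",
    axis: int = -1,
) -> WaveletDecomposition:
    """Cascade filter-and-downsample decomposition of ``x`` to ``levels`` depth.

    ``x`` may be any array; the transform runs along ``axis``.  Requires
    at least ``2**levels`` samples along that axis.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 2**levels:
        raise ValueError(
            f"signal too short for {levels}-level decomposition: "
            f"need at least {2**levels} samples, got {n}"
        )
    with warnings.catch_warnings():
        # pywt warns when the filter length suggests fewer levels; the
        # 2**levels minimum above is the contract we enforce
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, bank.to_pywt(), mode=mode, level=levels, axis=axis)
    approx = coeffs[0]
    # wavedec orders detail arrays deepest first; store them level 1..levels.
    details = list(coeffs[:0:-1])
    dec = WaveletDecomposition(approx=approx, details=details, levels=levels, fs=fs, n_samples=n)
    dec.band_edges = {
        "approx": dec.approx_band,
        **{f"d{j}": dec.detail_band(j) for j in range(1, levels + 1)},
    }
    dec._mode = mode  # kept so reconstruction matches the analysis
    dec._axis = axis
    return dec


def idwt_multilevel(dec: WaveletDecomposition, bank: FilterBank) -> np.ndarray:
    """Invert :func:`dwt_multilevel`; exact to ~1e-10 relative for this bank."""
    coeffs = [dec.approx] + dec.details[::-1]
    axis = getattr(dec, "_axis", -1)
    mode = getattr(dec, "_mode", "symmetric")
    # each synthesis step roughly doubles the length; the paired detail may
    # differ from the running approximation length by at most one sample
    L = len(bank.rec_lo)
    n = dec.approx.shape[axis]
    for d in coeffs[1:]:
        if abs(d.shape[axis] - n) > 1:
            raise ValueError(
                f"inconsistent coefficient lengths: detail of {d.shape[axis]} "
                f"against running length {n}"
            )
        n = 2 * d.shape[axis] if mode == "periodization" else 2 * d.shape[axis] - L + 2
    x = pywt.waverec(coeffs, bank.to_pywt(), mode=getattr(dec, "_mode", "symmetric"), axis=axis)
    # waverec can overshoot the original length by one sample per level
    return np.take(x, np.arange(dec.n_samples), axis=axis)


def delta_coefficients(dec: WaveletDecomposition, target_len: int = 23) -> np.ndarray:
    """Fixed-length delta-band feature vector from the deepest approximation.

    The approximation coefficients are right-zero-padded (or centre
    truncated) to exactly ``target_len`` entries, preserving order, so the
    per-channel feature count is independent of the epoch window length.
    Raises if the approximation band extends above 4 Hz (decomposition too
    shallow to isolate the delta band).
    """
    lo, hi = dec.approx_band
    if hi > 4.0 + 1e-12:
        raise ValueError(
            f"decomposition too shallow for delta band: approximation band "
            f"[0, {hi:g}] Hz exceeds 4 Hz"
        )
    a = np.asarray(dec.approx, dtype=float)
    n = a.shape[-1]
    if n == target_len:
        return a.copy()
    if n < target_len:
        pad = [(0, 0)] * (a.ndim - 1) + [(0, target_len - n)]
        return np.pad(a, pad)
    start = (n - target_len) // 2
    return a[..., start : start + target_len].copy()
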