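"""Stationary wavelet transform denoising of the cardiac artifact.

The signal is decomposed with the undecimated (stationary, shift-invariant)
wavelet transform using the 4-tap Daubechies wavelet db2 and at least three
levels.  Coefficients whose magnitude exceeds ``4.5 * sigma_k`` are zeroed:
the roles of classical wavelet denoising are reversed here, because the
large-coefficient component IS the artifact (the cardiac complexes) while
the sub-threshold coefficients carry the background of interest.  Hard
thresholding (zeroing, not shrinking) reproduces R-peak-scale transients
without bias in what is kept.

``sigma_k`` is a level-dependent, time-varying noise scale: a moving median
of the coefficient magnitudes over a 2 s window, divided by 0.6745 (the
half-normal median), with all samples within +/-200 ms of an R peak
excluded so the artifact does not inflate its own removal threshold; the
estimate is interpolated across the excluded spans.  The final
approximation band is thresholded by the same rule, since leaving it
untouched would retain the low-frequency tail of the cardiac waveform.

Default decomposition depth is 4 at 2 kHz sampling (detail bands roughly
500-250, 250-125, 125-62.5 and 62.5-31.25 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .rpeaks import BeatAnnotations

__all__ = [
    "SwtConfig",
    "SwtDecomposition",
    "NoiseProfile",
    "swt_decompose",
    "swt_reconstruct",
    "estimate_level_noise",
    "swt_denoise",
]

_HALF_NORMAL_MEDIAN = 0.6745  # median(|N(0,1)|)


@dataclass(frozen=True)
class SwtConfig:
    wavelet: str = "db2"
    levels: int = 4
    k_thresh: float = 4.5
    median_window_s: float = 2.0
    r_exclusion_ms: float = 200.0


@dataclass
class SwtDecomposition:
    """Per-level detail coefficients (finest first) plus final approximation.

    Coefficient vectors live on the padded time axis; ``n_orig`` records the
    unpadded signal length (padding is appended symmetrically at the end).
    """

    details: list[np.ndarray]
    approx: np.ndarray
    wavelet: str
    levels: int
    n_orig: int


@dataclass(frozen=True)
class NoiseProfile:
    """Per-level local noise sd estimates, one vector per detail level
    (finest first) plus one for the approximation band."""

    sigma_details: list[np.ndarray]
    sigma_approx: np.ndarray


def _pad_length(n: int, levels: int) -> int:
    block = 1 << levels
    return ((n + block - 1) // block) * block


def swt_decompose(x: np.ndarray, wavelet: str = "db2",
                  levels: int = 4) -> SwtDecomposition:
    """Stationary wavelet decomposition with symmetric end-padding."""
    if levels < 3:
        raise ValueError("at least three levels of decomposition are required")
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    n_pad = _pad_length(n, levels)
    if n_pad > 2 * n:
        raise ValueError(f"signal too short for {levels} levels")
    xp = np.pad(x, (0, n_pad - n), mode="symmetric")
    coeffs = pywt.swt(xp, wavelet, level=levels, trim_approx=True,
                      norm=False)
    approx = coeffs[0]
    details_coarse_first = coeffs[1:]
    details = list(reversed(details_coarse_first))  # finest first
    return SwtDecomposition(details=details, approx=approx, wavelet=wavelet,
                            levels=levels, n_orig=n)


def swt_reconstruct(dec: SwtDecomposition) -> np.ndarray:
    """Inverse transform; returns the unpadded signal."""
    coeffs = [dec.approx] + list(reversed(dec.details))
    y = pywt.iswt(coeffs, dec.wavelet, norm=False)
    return np.asarray(y)[: dec.n_orig]


def _excluded_mask(n: int, ann: BeatAnnotations | None, fs: float,
                   excl_ms: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    if ann is None:
        return mask
    half = int(round(excl_ms / 1000.0 * fs))
    for r in ann.r_indices:
        mask[max(0, r - half):min(n, r + half + 1)] = True
    return mask


def _moving_median_excluding(absc: np.ndarray, excluded: np.ndarray,
                             window: int, hop: int) -> np.ndarray:
    """Moving median of |coefficients| over *window* samples, evaluated on a
    *hop* grid using only non-excluded samples, linearly interpolated back
    to the full axis (which also bridges fully excluded spans)."""
    n = absc.size
    centers = np.arange(0, n, hop)
    vals = np.full(centers.size, np.nan)
    half = window // 2
    for k, c in enumerate(centers):
        a, b = max(0, c - half), min(n, c + half)
        seg = absc[a:b][~excluded[a:b]]
        if seg.size:
            vals[k] = np.median(seg)
    good = np.isfinite(vals)
    if not np.any(good):
        return np.zeros(n)
    full = np.interp(np.arange(n), centers[good], vals[good])
    return full


def estimate_level_noise(dec: SwtDecomposition, ann: BeatAnnotations | None,
                         fs: float, cfg: SwtConfig | None = None) -> NoiseProfile:
    """Level-dependent moving-median noise scale, excluding R-peak windows."""
    cfg = cfg or SwtConfig()
    window = int(round(cfg.median_window_s * fs))
    n = dec.approx.size
    if window > n:
        raise ValueError("median window longer than the signal")
    hop = max(1, window // 8)
    excluded = _excluded_mask(n, ann, fs, cfg.r_exclusion_ms)
    sigmas = [
        _moving_median_excluding(np.abs(d), excluded, window, hop)
        / _HALF_NORMAL_MEDIAN
        for d in dec.details
    ]
    sigma_a = _moving_median_excluding(np.abs(dec.approx), excluded, window,
                                       hop) / _HALF_NORMAL_MEDIAN
    return NoiseProfile(sigma_details=sigmas, sigma_approx=sigma_a)


def swt_denoise(x: np.ndarray, ann: BeatAnnotations | None, fs: float,
                cfg: SwtConfig | None = None) -> np.ndarray:
    """Zero supra-threshold (artifact) coefficients and invert the transform."""
    cfg = cfg or SwtConfig()
    dec = swt_decompose(x, cfg.wavelet, cfg.levels)
    prof = estimate_level_noise(dec, ann, fs, cfg)
    for d, sig in zip(dec.details, prof.sigma_details):
        d[np.abs(d) > cfg.k_thresh * sig] = 0.0
    dec.approx[np.abs(dec.approx) > cfg.k_thresh * prof.sigma_approx] = 0.0
    return swt_reconstruct(dec)
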