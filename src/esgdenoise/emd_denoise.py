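"""Empirical mode decomposition and IMF-based artifact separation.

EMD decomposes a signal, data-driven and in the time domain, into intrinsic
mode functions (IMFs) ordered fine to coarse.  For cardiac-contaminated
surface recordings the broadband background concentrates in the first IMF
while the slow, large cardiac complexes fall into the later ones, so the
denoised output keeps the first ``k`` IMFs (default ``k = 1``) and discards
the rest.  This is deliberately aggressive: the retained signal can sound
and look quite unlike the input, which is the documented character of this
method, not a defect to tune away.

Sifting uses cubic-spline upper/lower envelopes through the local extrema
with mirror extension of the edge extrema, Huang's standard-deviation stop
criterion (threshold 0.2, normalised by the energy of the previous
iterate), at most 10 siftings per IMF and at most 12 IMFs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["EmdConfig", "ImfSet", "emd_decompose", "emd_denoise"]


@dataclass(frozen=True)
class EmdConfig:
    max_imfs: int = 12
    sd_stop: float = 0.2
    max_siftings: int = 10
    keep_imfs: int = 1


@dataclass
class ImfSet:
    """Ordered IMFs (finest first) and the final residue/trend."""

    imfs: list[np.ndarray]
    residue: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateau midpoints count once)."""
    dx = np.diff(x)
    # collapse exact plateaus by treating zero slope as the previous sign
    sign = np.sign(dx)
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.nonzero(np.diff(sign))[0] + 1
    maxima = flips[sign[flips - 1] > 0]
    minima = flips[sign[flips - 1] < 0]
    return maxima, minima


def _envelope(t_ext: np.ndarray, v_ext: np.ndarray, n: int) -> np.ndarray:
    """Cubic-spline envelope through extrema with mirror boundary extension."""
    # mirror up to two edge extrema about each end of the record
    k = min(2, t_ext.size)
    t_pre = -t_ext[:k][::-1]
    v_pre = v_ext[:k][::-1]
    t_post = 2 * (n - 1) - t_ext[-k:][::-1]
    v_post = v_ext[-k:][::-1]
    t_all = np.concatenate([t_pre, t_ext, t_post])
    v_all = np.concatenate([v_pre, v_ext, v_post])
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    spline = CubicSpline(t_all[keep], v_all[keep])
    return spline(np.arange(n))


def emd_decompose(x: np.ndarray, cfg: EmdConfig | None = None) -> ImfSet:
    """Sift out IMFs until the residual is monotone-ish or limits are hit."""
    cfg = cfg or EmdConfig()
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    maxima, minima = _local_extrema(x)
    if maxima.size + minima.size < 4:
        raise ValueError("signal has fewer than 4 extrema; cannot decompose")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < cfg.max_imfs:
        maxima, minima = _local_extrema(residual)
        if maxima.size < 2 or minima.size < 2:
            break
        h = residual.copy()
        for _ in range(cfg.max_siftings):
            maxima, minima = _local_extrema(h)
            if maxima.size < 2 or minima.size < 2:
                break
            upper = _envelope(maxima, h[maxima], n)
            lower = _envelope(minima, h[minima], n)
            mean_env = 0.5 * (upper + lower)
            h_new = h - mean_env
            denom = float(np.dot(h, h))
            if denom < 1e-300:
                h = h_new
                break
            sd = float(np.dot(mean_env, mean_env)) / denom
            h = h_new
            if sd < cfg.sd_stop:
                break
        imfs.append(h)
        residual = residual - h
    return ImfSet(imfs=imfs, residue=residual)


def emd_denoise(x: np.ndarray, cfg: EmdConfig | None = None,
                k: int | None = None) -> np.ndarray:
    """Keep the first *k* IMFs (background); drop the rest (artifact).

    When *k* meets or exceeds the number of IMFs the input is returned
    unchanged (residue included).
    """
    cfg = cfg or EmdConfig()
    k = cfg.keep_imfs if k is None else k
    dec = emd_decompose(x, cfg)
    if k >= dec.n_imfs:
        return np.asarray(x, dtype=np.float64).copy()
    out = np.zeros_like(dec.residue)
    for imf in dec.imfs[:k]:
        out += imf
    return out
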