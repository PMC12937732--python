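"""Quality metrics, the convergence-error screen and result aggregation.

Each denoiser output ``y1`` is scored against the preprocessed reference
``y0`` of the same channel with six metrics:

* ``RE``  -- relative error between power spectral densities,
  ``sum(PSD(y0) - PSD(y1))^2 / sum PSD(y0)^2`` (no square root, as printed;
  a sqrt variant is available via ``sqrt_re=True``);
* ``SNR`` -- ``10 log10(var(y0) / var(y1 - y0))`` in dB;
* ``CC``  -- zero-lag normalised cross-correlation, percent;
* ``SD``  -- band-integrated PSD ratio ``100 * P1(band)/P0(band)`` for the
  0-20 Hz and 20-200 Hz bands, percent;
* ``KR2`` -- robust quantile-based kurtosis,
  ``(q(.975) - q(.025)) / (q(.75) - q(.25)) - 2.91``; the constant centres
  the statistic so Gaussian data score ~0, and higher |KR2| means heavier
  tails, i.e. more cardiac contamination;
* ``dKR2`` -- relative change of |KR2| from reference to denoised
  (-1 = complete suppression, > 0 = amplification).

An identity "denoiser" scores RE = 0, CC = 100 and SD = 100 in both bands
while leaving KR2 unchanged -- optimal values on those metrics therefore
never by themselves demonstrate artifact removal, and the metrics must be
read jointly.

The convergence screen flags channel/algorithm cases whose denoised KR2
falls outside reference-population bounds: upper bound = mean reference
KR2, lower bound = the 15th percentile of the reference population with
its sign inverted.  Flagged cases correspond to filters that diverged
(millivolt-scale output) rather than merely denoised poorly.

PSDs use an averaged periodogram (2 s Hann segments, 50 % overlap).
Empirical quantiles interpolate linearly at index ``p * (n - 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SpectralEstimate",
    "MetricSet",
    "ScreenThresholds",
    "welch_psd",
    "relative_error",
    "snr",
    "cross_correlation",
    "spectral_distortion",
    "kr2",
    "delta_kr2",
    "compute_metric_set",
    "screen_convergence",
    "aggregate_metrics",
]

KR2_GAUSSIAN_CONSTANT = 2.91
LOW_BAND = (0.0, 20.0)
HIGH_BAND = (20.0, 200.0)


@dataclass(frozen=True)
class SpectralEstimate:
    freqs: np.ndarray
    psd: np.ndarray


@dataclass(frozen=True)
class MetricSet:
    re: float
    snr_db: float
    cc_pct: float
    sd_low_pct: float
    sd_high_pct: float
    kr2: float
    delta_kr2: float

    def as_dict(self) -> dict[str, float]:
        return {"RE": self.re, "SNR": self.snr_db, "CC": self.cc_pct,
                "SD_low": self.sd_low_pct, "SD_high": self.sd_high_pct,
                "KR2": self.kr2, "dKR2": self.delta_kr2}


@dataclass(frozen=True)
class ScreenThresholds:
    upper: float
    lower: float


def welch_psd(y: np.ndarray, fs: float, segment_s: float = 2.0) -> SpectralEstimate:
    """Averaged periodogram: Hann segments of *segment_s*, 50 % overlap."""
    y = np.asarray(y, dtype=np.float64)
    nperseg = int(round(segment_s * fs))
    if y.size < nperseg:
        raise ValueError("signal shorter than one PSD segment")
    f, p = signal.welch(y, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2, detrend=False)
    return SpectralEstimate(freqs=f, psd=p)


def _pair_psds(y0, y1, fs):
    p0 = welch_psd(y0, fs)
    p1 = welch_psd(y1, fs)
    return p0, p1


def relative_error(y0: np.ndarray, y1: np.ndarray, fs: float,
                   sqrt_re: bool = False) -> float:
    """PSD discrepancy; 0 for identical spectra, 1 for a nulled signal."""
    p0, p1 = _pair_psds(y0, y1, fs)
    denom = float(np.sum(p0.psd ** 2))
    if denom <= 0:
        raise ValueError("reference signal has zero spectral power")
    re = float(np.sum((p0.psd - p1.psd) ** 2)) / denom
    return float(np.sqrt(re)) if sqrt_re else re


def snr(y0: np.ndarray, y1: np.ndarray, cap_db: float = 120.0) -> float:
    """10 log10(var(y0)/var(y1-y0)); capped when the residual vanishes."""
    y0 = np.asarray(y0, dtype=np.float64)
    y1 = np.asarray(y1, dtype=np.float64)
    v0 = float(np.var(y0))
    vd = float(np.var(y1 - y0))
    if vd < 1e-12 * max(v0, 1e-300):
        return cap_db
    return 10.0 * np.log10(v0 / vd)


def cross_correlation(y0: np.ndarray, y1: np.ndarray) -> float:
    """Zero-lag normalised correlation in percent, in [-100, 100]."""
    y0 = np.asarray(y0, dtype=np.float64)
    y1 = np.asarray(y1, dtype=np.float64)
    n0 = float(np.dot(y0, y0))
    n1 = float(np.dot(y1, y1))
    if n0 <= 0 or n1 <= 0:
        raise ValueError("cross-correlation undefined for an all-zero signal")
    return 100.0 * float(np.dot(y0, y1)) / np.sqrt(n0 * n1)


def band_power(est: SpectralEstimate, band: tuple[float, float]) -> float:
    """PSD integrated over [band[0], band[1]] by the trapezoidal rule."""
    lo, hi = band
    m = (est.freqs >= lo) & (est.freqs <= hi)
    if m.sum() < 2:
        raise ValueError(f"band {band} covers fewer than two PSD bins")
    return float(np.trapezoid(est.psd[m], est.freqs[m]))


def spectral_distortion(y0: np.ndarray, y1: np.ndarray, fs: float,
                        band: tuple[float, float]) -> float:
    """100 * band power of y1 / band power of y0 (percent)."""
    p0, p1 = _pair_psds(y0, y1, fs)
    ref = band_power(p0, band)
    if ref <= 0:
        raise ValueError(f"reference has zero power in band {band}")
    return 100.0 * band_power(p1, band) / ref


def kr2(y: np.ndarray) -> float:
    """Robust kurtosis: quantile-width ratio centred to 0 for Gaussian data."""
    y = np.asarray(y, dtype=np.float64)
    if y.size < 100:
        raise ValueError("KR2 requires at least 100 samples")
    q025, q25, q75, q975 = np.quantile(y, [0.025, 0.25, 0.75, 0.975])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("KR2 undefined: zero interquartile range")
    return float((q975 - q025) / iqr - KR2_GAUSSIAN_CONSTANT)


def delta_kr2(kr2_y0: float, kr2_y1: float) -> float:
    """(|KR2(y1)| - |KR2(y0)|) / |KR2(y0)|."""
    if abs(kr2_y0) <= 1e-9:
        raise ValueError("delta KR2 undefined: reference KR2 is (near) zero")
    return (abs(kr2_y1) - abs(kr2_y0)) / abs(kr2_y0)


def compute_metric_set(y0: np.ndarray, y1: np.ndarray, fs: float,
                       low_band: tuple[float, float] = LOW_BAND,
                       high_band: tuple[float, float] = HIGH_BAND) -> MetricSet:
    """All six metrics for one (reference, denoised) channel pair."""
    k0 = kr2(y0)
    k1 = kr2(y1)
    return MetricSet(
        re=relative_error(y0, y1, fs),
        snr_db=snr(y0, y1),
        cc_pct=cross_correlation(y0, y1),
        sd_low_pct=spectral_distortion(y0, y1, fs, low_band),
        sd_high_pct=spectral_distortion(y0, y1, fs, high_band),
        kr2=k1,
        delta_kr2=delta_kr2(k0, k1),
    )


def screen_convergence(kr2_denoised: np.ndarray,
                       kr2_reference: np.ndarray) -> tuple[np.ndarray, ScreenThresholds]:
    """Flag convergence errors from the reference KR2 population.

    upper = mean(reference); lower = -(15th percentile of reference).
    A case is flagged iff its denoised KR2 exceeds the upper bound or
    falls below the lower bound.
    """
    kr2_denoised = np.asarray(kr2_denoised, dtype=np.float64)
    kr2_reference = np.asarray(kr2_reference, dtype=np.float64)
    if kr2_denoised.size == 0 or kr2_reference.size == 0:
        raise ValueError("screen populations must be non-empty")
    upper = float(np.mean(kr2_reference))
    lower = float(-np.quantile(kr2_reference, 0.15))
    if lower > upper:
        import warnings
        warnings.warn("screen lower threshold exceeds upper threshold; "
                      "reference population is unusually clean")
    flags = (kr2_denoised > upper) | (kr2_denoised < lower)
    return flags, ScreenThresholds(upper=upper, lower=lower)


_METRIC_COLUMNS = ["RE", "SNR", "CC", "SD_low", "SD_high", "KR2", "dKR2"]


def aggregate_metrics(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise per-case metrics into benchmark tables.

    *results* must hold one row per (matrix, algorithm, subject, trial,
    channel) with the seven metric columns plus boolean ``null`` and
    ``flagged`` columns.  Returns ``(summary, counts)``:

    * ``summary``: per (matrix, algorithm, metric) mean and sd across all
      non-null cases, both before and after excluding flagged cases;
    * ``counts``: convergence-error counts and percentages per
      (matrix, algorithm), with per-matrix case totals and a ``Total`` row.
    """
    df = results[~results["null"]].copy()
    rows = []
    for (matrix, alg), grp in df.groupby(["matrix", "algorithm"], sort=True):
        kept = grp[~grp["flagged"]]
        for metric in _METRIC_COLUMNS:
            rows.append({
                "matrix": matrix, "algorithm": alg, "metric": metric,
                "mean_before": grp[metric].mean(),
                "sd_before": grp[metric].std(ddof=1),
                "mean_after": kept[metric].mean(),
                "sd_after": kept[metric].std(ddof=1),
                "n_before": len(grp), "n_after": len(kept),
            })
    summary = pd.DataFrame(rows)

    crows = []
    for (matrix, alg), grp in df.groupby(["matrix", "algorithm"], sort=True):
        n = len(grp)
        k = int(grp["flagged"].sum())
        crows.append({"matrix": matrix, "algorithm": alg,
                      "errors": k, "cases": n,
                      "percent": 100.0 * k / n if n else 0.0})
    counts = pd.DataFrame(crows)
    if not counts.empty:
        totals = (counts.groupby("algorithm")[["errors", "cases"]].sum()
                  .reset_index())
        totals.insert(0, "matrix", "Total")
        totals["percent"] = 100.0 * totals["errors"] / totals["cases"]
        counts = pd.concat([counts, totals], ignore_index=True)
    return summary, counts


def format_count(errors: int, cases: int) -> str:
    """Render a Table-3-style cell, e.g. ``12 (0.67%)``."""
    pct = 100.0 * errors / cases if cases else 0.0
    return f"{errors} ({pct:.2f}%)"
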