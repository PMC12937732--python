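"""HP200 high-pass denoising and the ATS + HP200 composition.

A fourth-order Butterworth high-pass with a 200 Hz cutoff removes the
cardiac artifact's energy wholesale (ECG content lies almost entirely below
100 Hz) at the cost of discarding all low-frequency signal content.  The
composition runs adaptive template subtraction first, then the high-pass.
Filters are applied zero-phase, consistent with the preprocessing stage,
so the magnitude response is squared (about -6 dB at the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .rpeaks import BeatAnnotations
from .template_denoise import TemplateConfig, ats_denoise

__all__ = ["HighpassConfig", "hp200_denoise", "ats_hp200_denoise"]


@dataclass(frozen=True)
class HighpassConfig:
    cutoff: float = 200.0
    order: int = 4


def hp200_denoise(x: np.ndarray, fs: float,
                  cfg: HighpassConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth high-pass; same length as the input."""
    cfg = cfg or HighpassConfig()
    if not 0 < cfg.cutoff < fs / 2:
        raise ValueError(f"cutoff {cfg.cutoff} Hz not below Nyquist ({fs / 2} Hz)")
    sos = signal.butter(cfg.order, cfg.cutoff, btype="highpass", fs=fs,
                       output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=np.float64))


def ats_hp200_denoise(x: np.ndarray, ann: BeatAnnotations, fs: float,
                      hp_cfg: HighpassConfig | None = None,
                      tpl_cfg: TemplateConfig | None = None) -> np.ndarray:
    """ATS followed by HP200; the order is fixed (template stage first)."""
    return hp200_denoise(ats_denoise(x, ann, tpl_cfg), fs, hp_cfg)
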