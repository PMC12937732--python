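"""Template Subtraction (TS) and Adaptive Template Subtraction (ATS).

TS estimates the cardiac waveform of each beat by averaging the 40 nearest
beats in a +/-200 ms window around the R peak, aligns that template to the
current beat by cross-correlation (+/-50 ms search), fits gain and offset by
linear regression, and subtracts the fitted template inside the window.

ATS refines TS for beat-to-beat morphology changes: the template is split
into P / QRS / T segments, 21 time-scaled versions of the QRS segment are
generated by stretching or shrinking about the R peak, each segment is
gain- and offset-fitted independently, and the candidate with the lowest
sum of squared differences from the current beat is subtracted.

Both denoisers leave the signal untouched outside subtraction windows.
Windows are not cross-faded at their edges; the per-segment offset term
absorbs most of the step, but small discontinuities at window boundaries
are possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rpeaks import BeatAnnotations

__all__ = [
    "TemplateConfig",
    "BeatTemplate",
    "SegmentedTemplate",
    "build_beat_template",
    "segment_template",
    "ts_denoise",
    "ats_denoise",
]


def _default_scale_grid() -> tuple[float, ...]:
    # 21 factors, 0.80 .. 1.20 in steps of 0.02; contains 1.0 exactly
    return tuple(np.round(np.linspace(0.8, 1.2, 21), 10))


@dataclass(frozen=True)
class TemplateConfig:
    n_beats: int = 40          # beats averaged per template
    window_ms: float = 200.0   # template half-width around R
    search_ms: float = 50.0    # alignment search half-span
    qrs_ms: float = 60.0       # QRS segment half-width (P/QRS/T boundaries)
    scale_grid: tuple[float, ...] = field(default_factory=_default_scale_grid)

    def __post_init__(self) -> None:
        grid = np.asarray(self.scale_grid, dtype=float)
        if grid.size != 21 or np.any(np.diff(grid) <= 0):
            raise ValueError("scale_grid must hold 21 strictly increasing factors")
        if not np.any(np.isclose(grid, 1.0)):
            raise ValueError("scale_grid must contain 1.0")


@dataclass(frozen=True)
class BeatTemplate:
    """Per-beat subtraction template covering +/-200 ms around the R peak."""

    samples: np.ndarray
    n_averaged: int
    fs: float

    @property
    def half(self) -> int:
        return (self.samples.size - 1) // 2


@dataclass(frozen=True)
class SegmentedTemplate:
    """P / QRS / T partition of a beat template with the QRS scale grid."""

    p_seg: np.ndarray
    qrs_seg: np.ndarray
    t_seg: np.ndarray
    boundaries_ms: tuple[float, float]
    scale_grid: tuple[float, ...]

    def concatenate(self) -> np.ndarray:
        return np.concatenate([self.p_seg, self.qrs_seg, self.t_seg])


def _beat_window_indices(ann: BeatAnnotations, n_samples: int,
                         half: int) -> np.ndarray:
    """Indices of beats whose full +/-half window lies inside the signal."""
    r = ann.r_indices
    ok = (r - half >= 0) & (r + half + 1 <= n_samples)
    return np.nonzero(ok)[0]


def _neighbour_beats(i: int, usable: np.ndarray, n_beats: int) -> np.ndarray:
    """The ``n_beats`` usable beats nearest to beat *i* (including *i*),
    symmetric where possible and shifted at record edges."""
    pos = int(np.searchsorted(usable, i))
    n = min(n_beats, usable.size)
    lo = max(0, min(pos - n // 2, usable.size - n))
    return usable[lo:lo + n]


def build_beat_template(x: np.ndarray, ann: BeatAnnotations, i: int,
                        cfg: TemplateConfig | None = None) -> BeatTemplate:
    """Average the nearest ``n_beats`` beat windows around beat *i*."""
    cfg = cfg or TemplateConfig()
    x = np.asarray(x, dtype=np.float64)
    half = int(round(cfg.window_ms / 1000.0 * ann.fs))
    usable = _beat_window_indices(ann, x.size, half)
    if usable.size == 0:
        raise ValueError("no beat window fits inside the signal")
    members = _neighbour_beats(i, usable, cfg.n_beats)
    windows = np.stack([x[ann.r_indices[j] - half:ann.r_indices[j] + half + 1]
                        for j in members])
    return BeatTemplate(samples=windows.mean(axis=0),
                        n_averaged=int(members.size), fs=ann.fs)


def segment_template(tpl: BeatTemplate,
                     boundaries_ms: tuple[float, float] = (-60.0, 60.0),
                     scale_grid: tuple[float, ...] | None = None) -> SegmentedTemplate:
    """Split a template into P / QRS / T; concatenation reproduces it exactly.

    Default partition: P = [-200, -60) ms, QRS = [-60, +60] ms,
    T = (+60, +200] ms relative to the R peak.
    """
    lo_ms, hi_ms = boundaries_ms
    half = tpl.half
    half_ms = half / tpl.fs * 1000.0
    if not (-half_ms <= lo_ms < hi_ms <= half_ms):
        raise ValueError(f"boundaries {boundaries_ms} outside +/-{half_ms:.0f} ms")
    i0 = half + int(round(lo_ms / 1000.0 * tpl.fs))
    i1 = half + int(round(hi_ms / 1000.0 * tpl.fs))
    s = tpl.samples
    return SegmentedTemplate(
        p_seg=s[:i0], qrs_seg=s[i0:i1 + 1], t_seg=s[i1 + 1:],
        boundaries_ms=(lo_ms, hi_ms),
        scale_grid=tuple(scale_grid) if scale_grid is not None
        else _default_scale_grid())


def _best_lag(segment_span: np.ndarray, template: np.ndarray,
              search: int) -> int:
    """Lag in [-search, +search] maximizing cross-correlation."""
    corr = np.correlate(segment_span, template, mode="valid")
    return int(np.argmax(corr)) - search


def _fit_gain_offset(target: np.ndarray, template: np.ndarray):
    """Least-squares target ~ g*template + c; returns (g, c) or None when
    the template segment has (near-)zero variance."""
    tm = template.mean()
    var = float(np.dot(template - tm, template - tm))
    if var < 1e-300:
        return None
    g = float(np.dot(template - tm, target - target.mean())) / var
    c = float(target.mean() - g * tm)
    return g, c


def ts_denoise(x: np.ndarray, ann: BeatAnnotations,
               cfg: TemplateConfig | None = None,
               return_details: bool = False):
    """Template subtraction over every beat with a full window in the signal."""
    cfg = cfg or TemplateConfig()
    x = np.asarray(x, dtype=np.float64)
    if ann.n_beats < 3:
        raise ValueError("at least 3 beats are required")
    y = x.copy()
    half = int(round(cfg.window_ms / 1000.0 * ann.fs))
    search = int(round(cfg.search_ms / 1000.0 * ann.fs))
    usable = _beat_window_indices(ann, x.size, half)
    details = []
    for i in usable:
        tpl = build_beat_template(x, ann, int(i), cfg)
        r = int(ann.r_indices[i])
        a, b = r - half - search, r + half + search + 1
        lag = 0
        if a >= 0 and b <= x.size:
            lag = _best_lag(x[a:b], tpl.samples, search)
        w0, w1 = r + lag - half, r + lag + half + 1
        if w0 < 0 or w1 > x.size:
            lag, w0, w1 = 0, r - half, r + half + 1
        fit = _fit_gain_offset(x[w0:w1], tpl.samples)
        if fit is None:
            details.append({"beat": int(i), "lag": lag, "gain": 0.0,
                            "offset": 0.0, "window": (w0, w1)})
            continue
        g, c = fit
        y[w0:w1] -= g * tpl.samples + c
        details.append({"beat": int(i), "lag": lag, "gain": g, "offset": c,
                        "window": (w0, w1)})
    return (y, details) if return_details else y


def _scaled_qrs(tpl: BeatTemplate, seg: SegmentedTemplate, scale: float) -> np.ndarray:
    """QRS segment time-scaled about the R peak by *scale* (width x scale).

    Sampled from the full template by linear interpolation, so a shrunken
    QRS (scale < 1) draws its edges from the adjacent P/T ends.
    """
    half = tpl.half
    n_p = seg.p_seg.size
    n_q = seg.qrs_seg.size
    offsets = np.arange(n_p, n_p + n_q) - half  # sample offsets relative to R
    src = half + offsets / scale
    return np.interp(src, np.arange(tpl.samples.size), tpl.samples)


def ats_denoise(x: np.ndarray, ann: BeatAnnotations,
                cfg: TemplateConfig | None = None,
                return_details: bool = False):
    """Adaptive template subtraction with per-segment fits and QRS scaling."""
    cfg = cfg or TemplateConfig()
    x = np.asarray(x, dtype=np.float64)
    if ann.n_beats < 3:
        raise ValueError("at least 3 beats are required")
    y = x.copy()
    half = int(round(cfg.window_ms / 1000.0 * ann.fs))
    search = int(round(cfg.search_ms / 1000.0 * ann.fs))
    usable = _beat_window_indices(ann, x.size, half)
    grid = np.asarray(cfg.scale_grid, dtype=float)
    details = []
    for i in usable:
        tpl = build_beat_template(x, ann, int(i), cfg)
        seg = segment_template(tpl, (-cfg.qrs_ms, cfg.qrs_ms), cfg.scale_grid)
        r = int(ann.r_indices[i])
        a, b = r - half - search, r + half + search + 1
        lag = 0
        if a >= 0 and b <= x.size:
            lag = _best_lag(x[a:b], tpl.samples, search)
        w0, w1 = r + lag - half, r + lag + half + 1
        if w0 < 0 or w1 > x.size:
            lag, w0, w1 = 0, r - half, r + half + 1
        beat = x[w0:w1]
        n_p, n_q = seg.p_seg.size, seg.qrs_seg.size
        beat_p, beat_q, beat_t = beat[:n_p], beat[n_p:n_p + n_q], beat[n_p + n_q:]
        best = None  # (ssd, |scale-1|, candidate, scale)
        for s in grid:
            qrs_s = _scaled_qrs(tpl, seg, float(s))
            cand = np.empty_like(beat)
            ssd = 0.0
            for sl, tseg, btgt in (
                    (slice(0, n_p), seg.p_seg, beat_p),
                    (slice(n_p, n_p + n_q), qrs_s, beat_q),
                    (slice(n_p + n_q, beat.size), seg.t_seg, beat_t)):
                fit = _fit_gain_offset(btgt, tseg)
                if fit is None:
                    cand[sl] = 0.0
                    continue
                g, c = fit
                fitted = g * tseg + c
                cand[sl] = fitted
                res = btgt - fitted
                ssd += float(np.dot(res, res))
            key = (ssd, abs(float(s) - 1.0))  # ties prefer scale nearest 1
            if best is None or key < best[0]:
                best = (key, cand, float(s))
        _, cand, scale = best
        y[w0:w1] -= cand
        details.append({"beat": int(i), "lag": lag, "scale": scale,
                        "ssd": best[0][0], "window": (w0, w1)})
    return (y, details) if return_details else y
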