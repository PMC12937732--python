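"""Algorithm registry.

Every denoiser is registered under a short name with the uniform signature

    fn(x, ann, fs, config) -> (cleaned_signal, info_dict)

where ``ann`` is the channel's :class:`~esgdenoise.rpeaks.BeatAnnotations`
and ``config`` an optional per-algorithm mapping.  The orchestration layer
iterates the registry, so adding an algorithm requires no pipeline changes.
An ``identity`` entry exists as the no-op control: it scores the optimal
RE/CC/SD values while removing nothing, the standing caveat against reading
any single metric in isolation.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .emd_denoise import EmdConfig, emd_denoise
from .highpass_denoise import HighpassConfig, ats_hp200_denoise, hp200_denoise
from .kalman_denoise import KalmanConfig, eks2_denoise
from .template_denoise import TemplateConfig, ats_denoise, ts_denoise
from .wavelet_denoise import SwtConfig, swt_denoise

__all__ = ["ALGORITHMS", "BENCHMARK_ALGORITHMS", "register", "get_algorithm"]

ALGORITHMS: dict[str, Callable] = {}

#: The seven benchmarked denoisers, in reporting order.
BENCHMARK_ALGORITHMS = ("ts", "ats", "hp200", "ats+hp200", "eks2", "swt", "emd")


def register(name: str):
    def deco(fn):
        ALGORITHMS[name] = fn
        return fn
    return deco


def get_algorithm(name: str) -> Callable:
    try:
        return ALGORITHMS[name]
    except KeyError:
        raise KeyError(f"unknown algorithm {name!r}; "
                       f"registered: {sorted(ALGORITHMS)}") from None


def _build(cfg_cls, config):
    if config is None:
        return cfg_cls()
    if isinstance(config, cfg_cls):
        return config
    fields = {f.name for f in dataclasses.fields(cfg_cls)}
    return cfg_cls(**{k: v for k, v in dict(config).items() if k in fields})


@register("identity")
def _identity(x, ann, fs, config=None):
    return np.asarray(x, dtype=float).copy(), {}


@register("ts")
def _ts(x, ann, fs, config=None):
    return ts_denoise(x, ann, _build(TemplateConfig, config)), {}


@register("ats")
def _ats(x, ann, fs, config=None):
    return ats_denoise(x, ann, _build(TemplateConfig, config)), {}


@register("hp200")
def _hp200(x, ann, fs, config=None):
    return hp200_denoise(x, fs, _build(HighpassConfig, config)), {}


@register("ats+hp200")
def _ats_hp200(x, ann, fs, config=None):
    config = dict(config or {})
    hp_cfg = _build(HighpassConfig, config.get("hp"))
    tpl_cfg = _build(TemplateConfig, config.get("template"))
    return ats_hp200_denoise(x, ann, fs, hp_cfg, tpl_cfg), {}


@register("eks2")
def _eks2(x, ann, fs, config=None):
    y, diag = eks2_denoise(x, ann, fs, _build(KalmanConfig, config))
    return y, {"diverged": diag.diverged,
               "max_abs_estimate": diag.max_abs_estimate,
               "fit_rms": diag.fit_rms}


@register("swt")
def _swt(x, ann, fs, config=None):
    return swt_denoise(x, ann, fs, _build(SwtConfig, config)), {}


@register("emd")
def _emd(x, ann, fs, config=None):
    return emd_denoise(x, _build(EmdConfig, config)), {}
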