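"""Recording data model and file round-tripping.

A :class:`Recording` holds a channels x samples matrix of surface-electrode
potentials in microvolts together with its sampling rate and the electrode
grid geometry.  Three interchange formats are supported:

* ``delimited`` -- CSV with one column per channel, optional header row of
  channel names, plus a small JSON sidecar carrying the sampling rate and
  labels;
* ``binary`` -- a raw little-endian numeric matrix with the same JSON
  sidecar (exact round trip);
* ``edf`` -- European Data Format, read-only, via :mod:`mne`.

Sample indexing is 0-based; time ``t = index / fs`` seconds; all windows in
this package are half-open ``[start, end)`` in samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ChannelGrid",
    "Recording",
    "read_recording",
    "write_recording",
    "detect_null_channels",
]

_SIDE_SUFFIX = ".json"


@dataclass(frozen=True)
class ChannelGrid:
    """Electrode grid geometry: rows x cols with inter-electrode distance in cm."""

    rows: int
    cols: int
    ied_cm: float = 0.8

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.ied_cm <= 0:
            raise ValueError("inter-electrode distance must be positive")

    @property
    def n_sites(self) -> int:
        return self.rows * self.cols


@dataclass
class Recording:
    """Multichannel surface-electrophysiology recording in microvolts.

    ``data`` is channels x samples.  ``grid`` is optional geometry; labels
    identify subject / trial / matrix (e.g. ``"64-BP"``, ``"32-LP"``).
    """

    data: np.ndarray
    fs: float
    grid: ChannelGrid | None = None
    channel_names: list[str] | None = None
    subject: str = ""
    trial: str = ""
    matrix: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.grid is not None and self.grid.n_sites < self.n_channels:
            raise ValueError("grid has fewer sites than channels")
        if self.channel_names is not None and len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data, dtype=np.float64))


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDE_SUFFIX)


def _grid_to_dict(grid: ChannelGrid | None):
    if grid is None:
        return None
    return {"rows": grid.rows, "cols": grid.cols, "ied_cm": grid.ied_cm}


def _grid_from_dict(d) -> ChannelGrid | None:
    if d is None:
        return None
    return ChannelGrid(rows=d["rows"], cols=d["cols"], ied_cm=d.get("ied_cm", 0.8))


def write_recording(rec: Recording, path, format: str = "binary") -> None:
    """Write a recording to *path* in ``binary`` or ``delimited`` format.

    Binary round-trips bit-exactly; delimited round-trips to <= 1e-6 uV.
    A JSON sidecar ``<name>.json`` stores fs, shape, dtype and labels.
    """
    if rec.n_channels == 0 or rec.n_samples == 0:
        raise ValueError("cannot write an empty recording")
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "float64",
        "channel_names": rec.channel_names,
        "subject": rec.subject,
        "trial": rec.trial,
        "matrix": rec.matrix,
        "grid": _grid_to_dict(rec.grid),
        "format": format,
    }
    if format == "binary":
        rec.data.astype("<f8").tofile(path)
    elif format == "delimited":
        names = rec.channel_names or [f"ch{i}" for i in range(rec.n_channels)]
        header = ",".join(names)
        np.savetxt(path, rec.data.T, delimiter=",", header=header,
                   comments="", fmt="%.8f")
    else:
        raise ValueError(f"unsupported write format: {format!r}")
    _sidecar_path(path).write_text(json.dumps(meta))


def _read_delimited(path: Path, fs, n_channels, has_header):
    import csv

    with open(path, newline="") as fh:
        first = fh.readline()
    if has_header is None:
        # header if the first row is not fully numeric
        tokens = next(csv.reader([first]))
        try:
            [float(t) for t in tokens]
            has_header = False
        except ValueError:
            has_header = True
    names = None
    if has_header:
        names = [t.strip() for t in next(csv.reader([first]))]
    data = np.loadtxt(path, delimiter=",", skiprows=1 if has_header else 0,
                      ndmin=2)
    if n_channels is not None and data.shape[1] != n_channels:
        raise ValueError(
            f"file has {data.shape[1]} channels but {n_channels} were declared")
    return data.T, names


def read_recording(path, format: str | None = None, fs: float | None = None,
                   n_channels: int | None = None,
                   has_header: bool | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`, or an EDF file.

    *format* is inferred from the sidecar / extension when omitted.  For
    sidecar-less delimited files *fs* must be given.  If *n_channels* is
    declared it is validated against the file contents.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = {}
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
    if format is None:
        format = meta.get("format") or ("edf" if path.suffix.lower() == ".edf" else None)
    if format is None:
        raise ValueError("format not given and no sidecar present")

    if format == "edf":
        return _read_edf(path)

    fs = fs if fs is not None else meta.get("fs")
    if fs is None:
        raise ValueError("sampling rate missing: pass fs= or provide a sidecar")

    if format == "binary":
        nch = n_channels if n_channels is not None else meta.get("n_channels")
        if nch is None:
            raise ValueError("binary format requires channel count (sidecar or n_channels=)")
        raw = np.fromfile(path, dtype="<f8")
        if raw.size % nch:
            raise ValueError(
                f"file size {raw.size} not divisible by {nch} channels")
        data = raw.reshape(nch, -1)
        names = meta.get("channel_names")
    elif format == "delimited":
        data, names = _read_delimited(path, fs, n_channels, has_header)
        names = meta.get("channel_names") or names
    else:
        raise ValueError(f"unsupported read format: {format!r}")

    return Recording(
        data=data, fs=float(fs), grid=_grid_from_dict(meta.get("grid")),
        channel_names=names, subject=meta.get("subject", ""),
        trial=meta.get("trial", ""), matrix=meta.get("matrix", ""),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    # MNE returns volts; canonical internal unit is microvolts.
    data = raw.get_data() * 1e6
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     channel_names=list(raw.ch_names))


def detect_null_channels(rec: Recording) -> np.ndarray:
    """Boolean mask of channels that recorded exactly zero throughout.

    Disconnected electrodes register a flat zero trace for the whole
    session; the rule is strict -- a single non-zero sample keeps the
    channel.
    """
    if rec.n_channels == 0 or rec.n_samples == 0:
        raise ValueError("recording is empty")
    return ~np.any(rec.data != 0.0, axis=1)
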