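"""Epoched multichannel recordings: the in-memory container and its on-disk format.

An :class:`EpochSet` holds a ``trials x channels x samples`` array together with
the sampling rate, a millisecond time axis relative to a named event (``frame1``
or ``frame2`` of the two-frame apparent-motion stimulus), channel labels, and a
per-trial table (percept report, condition, interframe interval, reaction time,
and — for synthetic data — the generating alpha frequency).

On disk an epoch container is a directory of three plain files:

``data.bin``
    little-endian float32, trial-major ``trials x channels x samples``
``meta.json``
    sampling rate, time axis origin/step, channel labels, units, shape
``trials.csv``
    one row per trial

The three files are cross-validated on read; any shape mismatch is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "read_epochs", "write_epochs"]


@dataclass
class EpochSet:
    """Trials x channels x samples data with metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
    fs : float
        Sampling rate in Hz.
    times : ndarray
        Time axis in ms, strictly increasing, uniform at ``1000/fs``.
    channels : list of str
        Channel labels, one per channel.
    trials : pandas.DataFrame
        Per-trial table, one row per trial.
    time_origin : str
        Name of the event that defines time 0 (``"frame1"`` or ``"frame2"``).
    attrs : dict
        Free-form provenance (e.g. mirror-padding bookkeeping, filter band).
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    channels: list[str]
    trials: pd.DataFrame
    time_origin: str = "frame1"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channels = list(self.channels)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be trials x channels x samples, got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_trials, n_channels, n_samples = self.data.shape
        if len(self.times) != n_samples:
            raise ValueError(
                f"time axis length {len(self.times)} != n_samples {n_samples}"
            )
        step = 1000.0 / self.fs
        if n_samples > 1:
            d = np.diff(self.times)
            if np.any(d <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(d, step, rtol=0, atol=1e-6 * step):
                raise ValueError("time axis must be uniform at 1000/fs ms")
        if len(self.channels) != n_channels:
            raise ValueError(
                f"{len(self.channels)} channel labels for {n_channels} channels"
            )
        if len(self.trials) != n_trials:
            raise ValueError(
                f"trial table has {len(self.trials)} rows for {n_trials} trials"
            )

    # -- basic introspection ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.fs,
            self.times.copy(),
            list(self.channels),
            self.trials.copy().reset_index(drop=True),
            self.time_origin,
            dict(self.attrs),
        )

    # -- selection ----------------------------------------------------------
    def pick_channels(self, labels) -> "EpochSet":
        """Return a copy restricted to ``labels`` (kept in the given order)."""
        labels = [labels] if isinstance(labels, str) else list(labels)
        missing = [c for c in labels if c not in self.channels]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        idx = [self.channels.index(c) for c in labels]
        out = self.copy()
        out.data = self.data[:, idx, :].copy()
        out.channels = labels
        return out

    def pick_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool and len(mask) != self.n_trials:
            raise ValueError("boolean trial mask length mismatch")
        out = self.copy()
        out.data = self.data[mask].copy()
        out.trials = self.trials.iloc[mask].reset_index(drop=True)
        return out

    def crop(self, tmin: float, tmax: float) -> "EpochSet":
        """Restrict the time axis to ``[tmin, tmax]`` ms (inclusive)."""
        if tmin > tmax:
            raise ValueError("tmin > tmax")
        if tmax < self.times[0] or tmin > self.times[-1]:
            raise ValueError(
                f"window [{tmin}, {tmax}] ms outside epoch "
                f"[{self.times[0]:.1f}, {self.times[-1]:.1f}] ms"
            )
        keep = (self.times >= tmin - 1e-9) & (self.times <= tmax + 1e-9)
        out = self.copy()
        out.data = self.data[:, :, keep].copy()
        out.times = self.times[keep]
        return out

    def shift_times(self, delta_ms: float, origin: str | None = None) -> "EpochSet":
        """Shift the time axis by ``delta_ms`` (new time = old + delta)."""
        out = self.copy()
        out.times = self.times + delta_ms
        if origin is not None:
            out.time_origin = origin
        return out

    def sample_index(self, t_ms: float) -> int:
        """Index of the sample nearest ``t_ms``; errors outside the epoch."""
        if t_ms < self.times[0] - 1e-9 or t_ms > self.times[-1] + 1e-9:
            raise ValueError(
                f"time {t_ms} ms outside epoch "
                f"[{self.times[0]:.1f}, {self.times[-1]:.1f}] ms"
            )
        return int(np.argmin(np.abs(self.times - t_ms)))


# -- container i/o ----------------------------------------------------------

_DATA, _META, _TRIALS = "data.bin", "meta.json", "trials.csv"


def write_epochs(path, epochs: EpochSet) -> Path:
    """Write ``epochs`` as a flat-file container directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(epochs.data, dtype="<f4")
    arr.tofile(path / _DATA)
    meta = {
        "shape": list(epochs.data.shape),
        "dtype": "<f4",
        "fs": float(epochs.fs),
        "time_start_ms": float(epochs.times[0]),
        "time_step_ms": 1000.0 / epochs.fs,
        "time_origin": epochs.time_origin,
        "channels": list(epochs.channels),
        "units": "a.u.",
        "attrs": _jsonable(epochs.attrs),
    }
    (path / _META).write_text(json.dumps(meta, indent=1))
    epochs.trials.to_csv(path / _TRIALS, index=False)
    return path


def read_epochs(path) -> EpochSet:
    """Read an epoch container directory written by :func:`write_epochs`."""
    path = Path(path)
    for name in (_DATA, _META, _TRIALS):
        if not (path / name).exists():
            raise FileNotFoundError(f"epoch container missing {name} in {path}")
    meta = json.loads((path / _META).read_text())
    shape = tuple(meta["shape"])
    expected = int(np.prod(shape)) * 4
    found = (path / _DATA).stat().st_size
    if found != expected:
        raise ValueError(
            f"data.bin size mismatch: expected {expected} bytes for shape "
            f"{shape}, found {found}"
        )
    data = np.fromfile(path / _DATA, dtype="<f4").reshape(shape).astype(float)
    trials = pd.read_csv(path / _TRIALS)
    if len(trials) != shape[0]:
        raise ValueError(
            f"trials.csv has {len(trials)} rows for {shape[0]} trials"
        )
    times = meta["time_start_ms"] + meta["time_step_ms"] * np.arange(shape[2])
    return EpochSet(
        data,
        meta["fs"],
        times,
        meta["channels"],
        trials,
        meta.get("time_origin", "frame1"),
        meta.get("attrs", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
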