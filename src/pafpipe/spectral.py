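"""Spectrum estimation, alpha peak/channel selection, and instantaneous frequency.

The instantaneous-frequency estimator is the phase-derivative ("frequency
sliding") method: the prestimulus signal is mirror-padded to push filter edge
artifacts outside the data, band-passed with a zero-phase plateau-shaped filter
(flat over the alpha band, 15% raised-cosine transition zones), the analytic
signal is taken by Hilbert transform, and the unwrapped phase is differenced and
scaled by ``fs / 2*pi`` to Hz. Because noise in the phase series produces sharp
nonphysiological spikes in the derivative, the raw estimate is median filtered
with 10 window lengths from 10 to 400 ms and the pointwise median of the 10
versions is taken. The estimate depends only on the phase, so it is
mathematically independent of oscillation amplitude (except where the amplitude
is exactly zero and phase is undefined, which is flagged as missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import hilbert

from .epochs import EpochSet

__all__ = [
    "Spectrum",
    "amplitude_spectrum",
    "peak_alpha",
    "select_channels_by_alpha",
    "mirror_pad",
    "trim_mirror",
    "plateau_gain",
    "bandpass_plateau",
    "InstFreqSeries",
    "instantaneous_frequency",
    "ContrastSeries",
    "condition_contrast_series",
]


# ---------------------------------------------------------------------------
# spectrum & selection
# ---------------------------------------------------------------------------

@dataclass
class Spectrum:
    """Trial-averaged amplitude spectrum per channel."""

    amplitude: np.ndarray  # channels x freqs
    freqs: np.ndarray  # Hz
    channels: list[str]
    window_ms: tuple[float, float]

    def band_mean(self, band: tuple[float, float]) -> np.ndarray:
        """Mean amplitude per channel within ``band`` (inclusive)."""
        sel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        if not sel.any():
            raise ValueError(f"band {band} outside spectrum range")
        return self.amplitude[:, sel].mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.channels):
            for fi, f in enumerate(self.freqs):
                rows.append((ch, f, self.amplitude[ci, fi]))
        return pd.DataFrame(rows, columns=["channel", "frequency_hz", "amplitude"])


def amplitude_spectrum(
    epochs: EpochSet,
    window_ms: tuple[float, float] = (-800.0, 0.0),
    freq_range: tuple[float, float] = (5.0, 30.0),
) -> Spectrum:
    """FFT amplitude spectrum per channel, averaged over trials.

    The window must lie inside the epoch and span at least two cycles of the
    lowest requested frequency.
    """
    t0, t1 = window_ms
    step = 1000.0 / epochs.fs  # a window edge may fall within one sample step
    if t0 < epochs.times[0] - step or t1 > epochs.times[-1] + step:
        raise ValueError(
            f"window {window_ms} outside epoch "
            f"[{epochs.times[0]:.1f}, {epochs.times[-1]:.1f}] ms"
        )
    if (t1 - t0) < 2 * 1000.0 / freq_range[0]:
        raise ValueError(
            f"window of {t1 - t0:.0f} ms shorter than two cycles of "
            f"{freq_range[0]} Hz"
        )
    sub = epochs.crop(t0, t1)
    n = sub.n_samples
    amp = np.abs(np.fft.rfft(sub.data, axis=-1)) / n
    freqs = np.fft.rfftfreq(n, 1.0 / epochs.fs)
    sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    return Spectrum(amp.mean(axis=0)[:, sel], freqs[sel], list(epochs.channels),
                    (float(t0), float(t1)))


def peak_alpha(
    spectrum: Spectrum,
    band: tuple[float, float] = (8.0, 13.0),
    channel_subset=None,
) -> float:
    """Frequency of the maximum subset-averaged amplitude within ``band``.

    Ties go to the lowest frequency. If the in-band spectrum is monotone
    (no interior peak) the argmax is still returned, with a warning.
    """
    if band[0] < spectrum.freqs[0] or band[1] > spectrum.freqs[-1]:
        raise ValueError(f"band {band} outside spectrum range")
    if channel_subset is not None:
        channel_subset = [c for c in channel_subset if c in spectrum.channels]
        if not channel_subset:
            raise ValueError("channel subset shares no channels with spectrum")
        idx = [spectrum.channels.index(c) for c in channel_subset]
        mean_amp = spectrum.amplitude[idx].mean(axis=0)
    else:
        mean_amp = spectrum.amplitude.mean(axis=0)
    sel = np.flatnonzero((spectrum.freqs >= band[0]) & (spectrum.freqs <= band[1]))
    in_band = mean_amp[sel]
    i = int(np.argmax(in_band))  # first occurrence = lowest-frequency tie winner
    if i in (0, len(sel) - 1):
        d = np.diff(in_band)
        if np.all(d >= 0) or np.all(d <= 0):
            warnings.warn("no interior alpha peak; returning in-band argmax")
    return float(spectrum.freqs[sel[i]])


def select_channels_by_alpha(
    spectrum: Spectrum,
    k: int,
    band: tuple[float, float] = (8.0, 13.0),
    candidates=None,
) -> list[str]:
    """Top-``k`` channels by band-mean alpha amplitude, strongest first.

    ``candidates`` restricts the ranking (e.g. the posterior scalp set for
    EEG; ``None`` ranks all channels, as for intracranial contacts).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if candidates is None:
        labels = list(spectrum.channels)
    else:
        labels = [c for c in candidates if c in spectrum.channels]
        if not labels:
            raise ValueError("no candidate channels present in spectrum")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds {len(labels)} candidate channels")
    idx = [spectrum.channels.index(c) for c in labels]
    amps = spectrum.band_mean(band)[idx]
    order = np.argsort(-amps, kind="stable")
    return [labels[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# mirror padding & plateau band-pass
# ---------------------------------------------------------------------------

def mirror_pad(epochs: EpochSet) -> EpochSet:
    """Append the time-reversed epoch to its right (prestimulus data only).

    Pushes filter edge artifacts at the stimulus-onset edge into the padded
    region, which :func:`trim_mirror` removes again. The input must contain
    only prestimulus samples (time axis entirely <= 0).
    """
    if epochs.times[-1] > 1e-9:
        raise ValueError("mirror_pad expects prestimulus-only epochs (times <= 0)")
    n = epochs.n_samples
    out = epochs.copy()
    out.data = np.concatenate([epochs.data, epochs.data[:, :, ::-1]], axis=-1)
    step = 1000.0 / epochs.fs
    out.times = epochs.times[0] + step * np.arange(2 * n)
    out.attrs["mirror_n_original"] = n
    return out


def trim_mirror(epochs: EpochSet) -> EpochSet:
    """Undo :func:`mirror_pad`: keep the original (first) half."""
    n = epochs.attrs.get("mirror_n_original")
    if n is None:
        raise ValueError("epochs carry no mirror-padding metadata")
    out = epochs.copy()
    out.data = epochs.data[:, :, :n].copy()
    out.times = epochs.times[:n]
    del out.attrs["mirror_n_original"]
    return out


def plateau_gain(
    freqs: np.ndarray,
    band: tuple[float, float] = (8.0, 13.0),
    transition_frac: float = 0.15,
) -> np.ndarray:
    """Plateau-shaped amplitude response: 1 over the band, raised-cosine
    transition zones of ``transition_frac`` of each band edge, 0 beyond."""
    lo, hi = band
    f1, f2 = lo * (1 - transition_frac), hi * (1 + transition_frac)
    g = np.zeros_like(np.asarray(freqs, float))
    g[(freqs >= lo) & (freqs <= hi)] = 1.0
    up = (freqs >= f1) & (freqs < lo)
    g[up] = 0.5 * (1 - np.cos(np.pi * (freqs[up] - f1) / (lo - f1)))
    dn = (freqs > hi) & (freqs <= f2)
    g[dn] = 0.5 * (1 + np.cos(np.pi * (freqs[dn] - hi) / (f2 - hi)))
    return g


def bandpass_plateau(
    epochs: EpochSet,
    band: tuple[float, float] = (8.0, 13.0),
    transition_frac: float = 0.15,
) -> EpochSet:
    """Zero-phase plateau band-pass.

    Realized by multiplying the discrete Fourier transform with the real,
    symmetric plateau response — the impulse response is time-symmetric, so
    the filter is exactly zero-phase, with unit passband gain and total
    stopband rejection on the DFT grid.
    """
    if band[1] * (1 + transition_frac) >= epochs.fs / 2:
        raise ValueError(
            f"band {band} (with transitions) reaches Nyquist {epochs.fs / 2} Hz"
        )
    n = epochs.n_samples
    gain = plateau_gain(np.fft.rfftfreq(n, 1.0 / epochs.fs), band, transition_frac)
    out = epochs.copy()
    out.data = np.fft.irfft(np.fft.rfft(epochs.data, axis=-1) * gain, n=n, axis=-1)
    out.attrs["bandpass"] = {"band": list(band), "transition_frac": transition_frac}
    return out


# ---------------------------------------------------------------------------
# instantaneous frequency
# ---------------------------------------------------------------------------

@dataclass
class InstFreqSeries:
    """Per-trial instantaneous frequency with companion amplitude/power."""

    frequency: np.ndarray  # trials x samples, Hz (NaN where phase undefined)
    amplitude: np.ndarray  # trials x samples, analytic magnitude
    times: np.ndarray  # ms
    fs: float
    band: tuple[float, float]
    channel: str
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def power(self) -> np.ndarray:
        return self.amplitude**2

    def interior_mask(self, margin_ms: float = 400.0) -> np.ndarray:
        """Samples further than ``margin_ms`` from either epoch edge —
        the region where median-filter edge effects are excluded."""
        return ((self.times >= self.times[0] + margin_ms)
                & (self.times <= self.times[-1] - margin_ms))


def median_window_samples(
    fs: float,
    window_range_ms: tuple[float, float] = (10.0, 400.0),
    n_windows: int = 10,
) -> list[int]:
    """Odd sample counts (>= 3) for linearly spaced median-filter windows."""
    out = []
    for w in np.linspace(window_range_ms[0], window_range_ms[1], n_windows):
        k = int(round(w * fs / 1000.0))
        k += (k + 1) % 2
        out.append(max(k, 3))
    return out


def instantaneous_frequency(
    filtered: EpochSet,
    channel: str | None = None,
    median_window_range_ms: tuple[float, float] = (10.0, 400.0),
    n_windows: int = 10,
) -> InstFreqSeries:
    """Phase-derivative instantaneous frequency with a median-filter consensus.

    ``filtered`` must be band-limited (output of :func:`bandpass_plateau`);
    a single channel is analyzed (pass ``channel`` when several are present).
    The raw estimate is the unwrapped phase first difference times
    ``fs / 2*pi`` (last sample repeated to preserve length); ``n_windows``
    median-filtered versions with windows spanning ``median_window_range_ms``
    are combined by pointwise median. Samples with exactly zero amplitude
    have undefined phase and are returned as NaN.
    """
    bp = filtered.attrs.get("bandpass")
    band = tuple(bp["band"]) if bp else (8.0, 13.0)
    if channel is None:
        if filtered.n_channels != 1:
            raise ValueError("multiple channels present; pass channel=...")
        channel = filtered.channels[0]
    x = filtered.pick_channels([channel]).data[:, 0, :]  # trials x samples

    analytic = hilbert(x, axis=-1)
    amp = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic), axis=-1)
    raw = np.diff(phase, axis=-1) * filtered.fs / (2 * np.pi)
    raw = np.concatenate([raw, raw[:, -1:]], axis=-1)

    versions = [
        median_filter(raw, size=(1, k), mode="nearest")
        for k in median_window_samples(filtered.fs, median_window_range_ms, n_windows)
    ]
    est = np.median(np.stack(versions), axis=0)
    est = np.where(amp == 0, np.nan, est)
    return InstFreqSeries(est, amp, filtered.times.copy(), filtered.fs,
                          band, channel, filtered.trials.copy())


# ---------------------------------------------------------------------------
# condition contrast
# ---------------------------------------------------------------------------

@dataclass
class ContrastSeries:
    """Trial-averaged time courses for two percept labels and their difference."""

    mean_a: np.ndarray
    mean_b: np.ndarray
    labels: tuple[str, str]
    times: np.ndarray
    measure: str

    @property
    def difference(self) -> np.ndarray:
        return self.mean_a - self.mean_b


def condition_contrast_series(
    instfreq: InstFreqSeries,
    percepts,
    labels: tuple[str, str] = ("GM", "EM"),
    measure: str = "frequency",
) -> ContrastSeries:
    """Per-label mean series (frequency or power) and their paired difference.

    The difference (``labels[0] - labels[1]``) is the subject-level series
    entered into the group cluster test.
    """
    percepts = np.asarray(percepts)
    if measure == "frequency":
        data = instfreq.frequency
    elif measure == "power":
        data = instfreq.power
    else:
        raise ValueError("measure must be 'frequency' or 'power'")
    means = []
    for lab in labels:
        sel = percepts == lab
        if not sel.any():
            raise ValueError(f"label {lab!r} absent")
        means.append(np.nanmean(data[sel], axis=0))
    return ContrastSeries(means[0], means[1], tuple(labels),
                          instfreq.times.copy(), measure)
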