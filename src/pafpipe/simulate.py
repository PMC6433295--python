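"""Synthetic behavioral and electrophysiological cohorts with known ground truth.

The generator emulates the study design that the analysis pipeline targets:
64-channel EEG at 160 Hz (or an intracranial variant at 500 Hz), epochs from
-800 ms before the first stimulus frame to +1000 ms after it, posterior-weighted
alpha (8-13 Hz) whose per-trial frequency is coupled to the reported percept
(group motion trials run faster by ``freq_offset_gm``), 1/f background noise,
percept-specific evoked spatial patterns after the second frame, and 2AFC
responses from a logistic observer over seven interframe intervals.

Every quantity the downstream estimators are supposed to recover (per-trial
generating frequency, subject peak frequency, transition threshold) is stored
in the trial table or the cohort record, so recovery is testable without any
recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = [
    "POSTERIOR_CHANNELS",
    "STANDARD_IFIS",
    "SimConfig",
    "SubjectRecord",
    "Cohort",
    "generate_psychometric_responses",
    "generate_main_behavior",
    "generate_subject_epochs",
    "generate_cohort",
]

#: Posterior scalp electrodes used as the alpha region of interest.
POSTERIOR_CHANNELS = ("Oz", "O1", "O2", "POz", "PO1", "PO2", "PO3", "PO4")

#: Interframe intervals (ms) of the psychophysical pretest.
STANDARD_IFIS = (50, 80, 110, 140, 170, 200, 230)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of a synthetic cohort.

    Attributes
    ----------
    n_subjects : int
        Cohort size (the EEG study has 17 subjects).
    n_trials_per_condition : int
        Bistable trials per percept (EM and GM each); must be even.
    n_channels, fs : int, float
        Channel count and sampling rate (64 ch / 160 Hz scalp EEG;
        the intracranial variant uses 500 Hz).
    epoch_start, epoch_end : float
        Epoch limits in ms relative to frame 1.
    alpha_band : (float, float)
        Alpha band in Hz.
    subject_peak_freq : float or None
        Fixed subject peak alpha; ``None`` draws one per subject uniformly
        inside the band (1 Hz in from each edge so percept offsets and
        jitter stay within band).
    freq_offset_gm : float
        Per-trial increment of the generating alpha frequency on GM trials.
    freq_jitter_sd : float
        Trial-to-trial SD of the generating frequency, Hz.
    freq_drift_hz : float
        Optional linear within-epoch frequency drift (total Hz over the
        epoch); off by default — the default trials are stationary.
    threshold_coupling : (slope, intercept_ms, noise_sd_ms)
        Links each subject's transition threshold to their alpha cycle
        length: ``threshold = slope * (1000/peak) + intercept + N(0, sd)``.
    snr : float
        Ratio of posterior alpha RMS amplitude to 1/f-noise SD.
    evoked_effect : float
        Per-channel RMS amplitude of the percept-specific spatial pattern
        added after frame 2, in units of the alpha oscillation amplitude.
    preactivation : {"none", "efficient_only", "all"}
        Whether the percept pattern is also present (weakly) before frame 2;
        ``efficient_only`` adds it only on trials whose generating frequency
        is on the percept-consistent side of the subject median. The
        amplitude is graded by the distance of the trial's frequency from
        the median (no evidence at the median, full strength at the extreme).
    preactivation_effect : float
        Peak per-channel amplitude of the prestimulus pattern when enabled,
        in units of the alpha oscillation amplitude.
    frame_duration_ms : float
        Stimulus frame duration; frame 2 starts at IFI + frame duration.
    seed : int
        Master seed; all randomness derives from it.
    """

    n_subjects: int = 17
    n_trials_per_condition: int = 80
    n_channels: int = 64
    fs: float = 160.0
    epoch_start: float = -800.0
    epoch_end: float = 1000.0
    alpha_band: tuple[float, float] = (8.0, 13.0)
    subject_peak_freq: float | None = None
    freq_offset_gm: float = 0.3
    freq_jitter_sd: float = 0.15
    freq_drift_hz: float = 0.0
    threshold_coupling: tuple[float, float, float] = (1.0, 10.0, 5.0)
    snr: float = 1.0
    evoked_effect: float = 1.0
    preactivation: str = "none"
    preactivation_effect: float = 0.5
    frame_duration_ms: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (self.epoch_start < 0 < self.epoch_end):
            raise ValueError("epoch must bracket frame 1: epoch_start < 0 < epoch_end")
        lo, hi = self.alpha_band
        if not (0 < lo < hi):
            raise ValueError("alpha_band must satisfy 0 < low < high")
        if self.n_trials_per_condition % 2 or self.n_trials_per_condition < 2:
            raise ValueError("n_trials_per_condition must be even and >= 2")
        if self.n_channels < 1 or self.n_subjects < 1:
            raise ValueError("n_channels and n_subjects must be >= 1")
        if self.preactivation not in ("none", "efficient_only", "all"):
            raise ValueError(f"unknown preactivation mode {self.preactivation!r}")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.epoch_end - self.epoch_start < 1000.0 / lo:
            raise ValueError("epoch shorter than one alpha cycle")


@dataclass
class SubjectRecord:
    subject: int
    epochs: EpochSet
    behavior: pd.DataFrame  # pretest + main-experiment trials
    true_threshold_ms: float
    true_peak_freq_hz: float


@dataclass
class Cohort:
    config: SimConfig
    subjects: list[SubjectRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_psychometric_responses(
    threshold_ms: float,
    slope_per_ms: float,
    ifis: Sequence[float] = STANDARD_IFIS,
    n_per_ifi: int = 20,
    lapse_rate: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    subject: int = 0,
) -> pd.DataFrame:
    """Simulate a 2AFC logistic observer over the pretest interframe intervals.

    Each trial's GM report is a Bernoulli draw with
    ``p = lapse + (1 - 2*lapse) * logistic((IFI - threshold) * slope)``.
    Returns a trial table with columns ``subject, condition, ifi_ms,
    response, rt_ms``.
    """
    if not np.isfinite(threshold_ms) or not np.isfinite(slope_per_ms):
        raise ValueError("threshold and slope must be finite")
    if slope_per_ms <= 0:
        raise ValueError("slope_per_ms must be > 0")
    if not (0 <= lapse_rate < 0.5):
        raise ValueError("lapse_rate must lie in [0, 0.5)")
    if n_per_ifi < 1:
        raise ValueError("n_per_ifi must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    for ifi in ifis:
        p_gm = lapse_rate + (1 - 2 * lapse_rate) * _logistic(
            (ifi - threshold_ms) * slope_per_ms
        )
        gm = rng.random(n_per_ifi) < p_gm
        rt = rng.lognormal(mean=np.log(600.0), sigma=0.25, size=n_per_ifi)
        for g, r in zip(gm, rt):
            rows.append(
                dict(
                    subject=subject,
                    condition="pretest",
                    ifi_ms=float(ifi),
                    response="GM" if g else "EM",
                    rt_ms=float(r),
                )
            )
    return pd.DataFrame(rows)


def generate_main_behavior(
    threshold_ms: float,
    bistable_percepts: Sequence[str],
    rng: np.random.Generator,
    subject: int = 0,
    n_explicit: int = 40,
    explicit_accuracy: float = 0.95,
    omission_rate: float = 0.01,
    short_ifi: float = 50.0,
    long_ifi: float = 230.0,
) -> pd.DataFrame:
    """Main-experiment trial table: explicit EM/GM blocks plus bistable trials.

    Explicit short-IFI trials are EM stimuli and long-IFI trials GM stimuli;
    reports are correct with probability ``explicit_accuracy``. Bistable
    trials replay the epoch percept labels at the subject's threshold IFI.
    A small fraction of trials are omissions (no response, no RT).
    """
    rows = []

    def _rt(mean):
        return float(rng.lognormal(np.log(mean), 0.25))

    for cond, ifi, truth in (
        ("explicit-EM", short_ifi, "EM"),
        ("explicit-GM", long_ifi, "GM"),
    ):
        for _ in range(n_explicit):
            if rng.random() < omission_rate:
                rows.append(dict(subject=subject, condition=cond, ifi_ms=ifi,
                                 response="omission", rt_ms=np.nan))
                continue
            correct = rng.random() < explicit_accuracy
            resp = truth if correct else ("GM" if truth == "EM" else "EM")
            # explicit EM responses are a bit slower, as in the recorded cohorts
            rows.append(dict(subject=subject, condition=cond, ifi_ms=ifi,
                             response=resp,
                             rt_ms=_rt(640.0 if truth == "EM" else 600.0)))
    for percept in bistable_percepts:
        if rng.random() < omission_rate:
            rows.append(dict(subject=subject, condition="bistable",
                             ifi_ms=float(threshold_ms), response="omission",
                             rt_ms=np.nan))
            continue
        rows.append(dict(subject=subject, condition="bistable",
                         ifi_ms=float(threshold_ms), response=percept,
                         rt_ms=_rt(620.0)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# electrophysiology
# ---------------------------------------------------------------------------

def channel_labels(n_channels: int) -> list[str]:
    """Posterior ROI labels first, generic labels for the remainder."""
    labels = list(POSTERIOR_CHANNELS[: min(n_channels, len(POSTERIOR_CHANNELS))])
    labels += [f"E{i:02d}" for i in range(len(labels) + 1, n_channels + 1)]
    return labels[:n_channels]


def alpha_topography(n_channels: int, posterior_weight: float = 1.0,
                     far_weight: float = 0.2, falloff: float = 6.0) -> np.ndarray:
    """Smoothly decaying posterior-dominant weights (posterior channels first)."""
    n_post = min(n_channels, len(POSTERIOR_CHANNELS))
    idx = np.arange(n_channels, dtype=float)
    dist = np.clip(idx - (n_post - 1), 0, None)
    return far_weight + (posterior_weight - far_weight) * np.exp(
        -((dist / falloff) ** 2)
    )


def one_over_f_noise(shape: tuple[int, ...], fs: float,
                     rng: np.random.Generator, exponent: float = 1.0) -> np.ndarray:
    """Gaussian noise with 1/f^exponent amplitude spectrum, unit SD, last axis=time."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent)
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * amp
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _evoked_envelope(times_ms: np.ndarray, onset_ms: float,
                     duration_ms: float = 300.0) -> np.ndarray:
    """Raised-cosine bump starting at ``onset_ms``, zero elsewhere."""
    u = (times_ms - onset_ms) / duration_ms
    env = np.where((u >= 0) & (u <= 1), 0.5 * (1 - np.cos(2 * np.pi * np.clip(u, 0, 1))), 0.0)
    return env


def _subject_rng(cfg: SimConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, subject_index]))


def generate_subject_epochs(
    cfg: SimConfig,
    subject_index: int,
    peak_freq: float | None = None,
    threshold_ms: float | None = None,
    rng: np.random.Generator | None = None,
) -> EpochSet:
    """Simulate one subject's bistable epochs.

    The signal per trial is a posterior-weighted alpha oscillator at the
    trial's generating frequency (subject peak + GM offset + jitter, random
    initial phase) plus 1/f noise, plus — after frame-2 onset — a
    percept-specific spatial pattern scaled by ``evoked_effect``. The trial
    table stores the percept label and the generating frequency.
    """
    cfg.validate()
    rng = rng if rng is not None else _subject_rng(cfg, subject_index)
    lo, hi = cfg.alpha_band
    if peak_freq is None:
        peak_freq = (cfg.subject_peak_freq
                     if cfg.subject_peak_freq is not None
                     else float(rng.uniform(lo + 1.0, hi - 1.0)))
    if threshold_ms is None:
        slope, intercept, sd = cfg.threshold_coupling
        threshold_ms = slope * 1000.0 / peak_freq + intercept
        if sd > 0:
            threshold_ms += float(rng.normal(0, sd))

    n_cond = cfg.n_trials_per_condition
    n_trials = 2 * n_cond
    percepts = np.array(["EM"] * n_cond + ["GM"] * n_cond)
    rng.shuffle(percepts)
    is_gm = percepts == "GM"

    f_trial = peak_freq + cfg.freq_offset_gm * is_gm
    f_trial = f_trial + rng.normal(0, cfg.freq_jitter_sd, n_trials)
    f_trial = np.clip(f_trial, lo, hi)

    step = 1000.0 / cfg.fs
    times = np.arange(cfg.epoch_start, cfg.epoch_end + step / 2, step)
    t_s = times / 1000.0
    phase0 = rng.uniform(0, 2 * np.pi, n_trials)

    # per-trial oscillator phase; optional linear drift over the epoch
    if cfg.freq_drift_hz:
        dur = t_s[-1] - t_s[0]
        inst_f = f_trial[:, None] + cfg.freq_drift_hz * (t_s - t_s[0])[None, :] / dur
        phase = phase0[:, None] + 2 * np.pi * np.cumsum(inst_f, axis=1) / cfg.fs
    else:
        phase = phase0[:, None] + 2 * np.pi * f_trial[:, None] * t_s[None, :]
    alpha = np.sin(phase)  # trials x samples, unit amplitude

    topo = alpha_topography(cfg.n_channels)
    data = alpha[:, None, :] * topo[None, :, None]

    noise_sd = (1.0 / np.sqrt(2.0)) / cfg.snr  # alpha RMS at posterior / snr
    data += noise_sd * one_over_f_noise(
        (n_trials, cfg.n_channels, len(times)), cfg.fs, rng
    )

    ifi = float(threshold_ms)
    frame2_onset = ifi + cfg.frame_duration_ms
    # percept patterns scaled to unit per-channel RMS, so evoked_effect is the
    # per-channel response amplitude relative to alpha, whatever the montage
    pattern = {
        p: _unit(rng.standard_normal(cfg.n_channels)) * np.sqrt(cfg.n_channels)
        for p in ("EM", "GM")
    }
    if cfg.evoked_effect:
        env = _evoked_envelope(times, frame2_onset)
        for p in ("EM", "GM"):
            sel = percepts == p
            data[sel] += cfg.evoked_effect * pattern[p][None, :, None] * env[None, None, :]

    if cfg.preactivation != "none" and cfg.preactivation_effect:
        pre_env = _evoked_envelope(times, frame2_onset - 400.0, 400.0)
        pre_env[times >= frame2_onset] = 0.0
        med = np.median(f_trial)
        # inference strength grows with the evidence: trials whose frequency
        # sits at the median carry no prediction, extreme trials a full one
        dev = np.abs(f_trial - med)
        grade = dev / dev.max() if dev.max() > 0 else np.zeros(n_trials)
        consistent = (is_gm & (f_trial > med)) | (~is_gm & (f_trial <= med))
        if cfg.preactivation == "efficient_only":
            grade = np.where(consistent, grade, 0.0)
        for p in ("EM", "GM"):
            sel = percepts == p
            data[sel] += (cfg.preactivation_effect * grade[sel, None, None]
                          * pattern[p][None, :, None] * pre_env[None, None, :])

    trials = pd.DataFrame(
        dict(
            subject=subject_index,
            condition="bistable",
            percept=percepts,
            response=percepts,
            ifi_ms=ifi,
            gen_freq_hz=f_trial,
        )
    )
    attrs = dict(
        true_peak_freq_hz=float(peak_freq),
        true_threshold_ms=float(threshold_ms),
        frame2_onset_ms=float(frame2_onset),
        seed=int(cfg.seed),
        subject=int(subject_index),
    )
    return EpochSet(data, cfg.fs, times, channel_labels(cfg.n_channels),
                    trials, "frame1", attrs)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_cohort(cfg: SimConfig, out_dir=None) -> Cohort:
    """Simulate a full cohort: epochs, pretest + main behavior, ground truth.

    Subject thresholds follow ``threshold_coupling`` applied to each
    subject's alpha cycle length. If ``out_dir`` is given, each subject's
    epochs are written as an epoch container under ``out_dir/sub-XX``.
    """
    cfg.validate()
    if cfg.n_subjects < 2:
        raise ValueError("a cohort needs n_subjects >= 2")
    subjects = []
    for s in range(cfg.n_subjects):
        rng = _subject_rng(cfg, s)
        lo, hi = cfg.alpha_band
        peak = (cfg.subject_peak_freq
                if cfg.subject_peak_freq is not None
                else float(rng.uniform(lo + 1.0, hi - 1.0)))
        slope, intercept, sd = cfg.threshold_coupling
        thr = slope * 1000.0 / peak + intercept
        if sd > 0:
            thr += float(rng.normal(0, sd))
        epochs = generate_subject_epochs(cfg, s, peak_freq=peak,
                                         threshold_ms=thr, rng=rng)
        pretest = generate_psychometric_responses(
            thr, 0.06, n_per_ifi=40, rng=rng, subject=s
        )
        main = generate_main_behavior(
            thr, epochs.trials["percept"].to_numpy(), rng, subject=s
        )
        behavior = pd.concat([pretest, main], ignore_index=True)
        subjects.append(SubjectRecord(s, epochs, behavior, thr, peak))
    cohort = Cohort(cfg, subjects)
    if out_dir is not None:
        from .epochs import write_epochs
        from pathlib import Path

        out_dir = Path(out_dir)
        for rec in cohort:
            sub = out_dir / f"sub-{rec.subject:02d}"
            write_epochs(sub / "epochs", rec.epochs)
            rec.behavior.to_csv(sub / "behavior.csv", index=False)
    return cohort


def null_config(**overrides) -> SimConfig:
    """A cohort with no percept coupling anywhere (exchangeable EM/GM trials)."""
    base = dict(freq_offset_gm=0.0, evoked_effect=0.0, preactivation="none",
                threshold_coupling=(0.0, 110.0, 5.0))
    base.update(overrides)
    return SimConfig(**base)
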