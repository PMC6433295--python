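"""End-to-end orchestration: simulate -> behavior -> alpha -> sorting -> decoding -> stats.

``run_pipeline`` sequences the full analysis on a cohort (synthetic by default,
or epoch containers on disk) and emits a machine-readable report: psychometric
thresholds, the peak-alpha/threshold correlation with the cycle-length slope
test, the group GM-vs-EM instantaneous-frequency cluster test, and the
efficient/inefficient temporal-generalization decoding with its cluster tests.
Every output embeds a hash of the configuration so runs are auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, psychometrics, sorting, spectral, stats
from .epochs import EpochSet, read_epochs
from .simulate import POSTERIOR_CHANNELS, Cohort, SimConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_cohort_dir"]


@dataclass
class PipelineConfig:
    """Flat, namespaced parameters of every pipeline stage.

    Unknown keys in a config file are rejected; every random operation takes
    its seed from ``seed`` so a report is reproducible end to end.
    """

    seed: int = 0
    # simulation (see SimConfig for meanings)
    sim_n_subjects: int = 17
    sim_n_trials_per_condition: int = 80
    sim_n_channels: int = 64
    sim_fs: float = 160.0
    sim_alpha_band: tuple[float, float] = (8.0, 13.0)
    sim_freq_offset_gm: float = 0.3
    sim_snr: float = 1.0
    sim_evoked_effect: float = 1.0
    sim_preactivation: str = "none"
    sim_preactivation_effect: float = 0.5
    sim_threshold_coupling: tuple[float, float, float] = (1.0, 10.0, 5.0)
    # spectral
    spec_window_ms: tuple[float, float] = (-800.0, 0.0)
    spec_freq_range: tuple[float, float] = (5.0, 30.0)
    alpha_band: tuple[float, float] = (8.0, 13.0)
    n_channels_select: int = 1
    posterior_only: bool = True
    # trial sorting
    paf_window_mode: str = "cluster"  # "cluster" (data-driven) or "fixed"
    paf_window_fixed_ms: tuple[float, float] = (-570.0, -350.0)  # rel. frame 2
    # decoding
    decode_lambda: float = 0.1
    decode_step_ms: float = 10.0
    decode_window_ms: float = 50.0
    decode_epoch_ms: tuple[float, float] = (-400.0, 400.0)  # rel. frame 2
    # statistics
    n_perm_series: int = 1000
    n_perm_decoding: int = 500
    cluster_alpha: float = 0.05

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a flat key-value config file (YAML or JSON)."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            import yaml

            data = yaml.safe_load(text)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        tupled = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(**tupled)

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self).items()}

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_subjects=self.sim_n_subjects,
            n_trials_per_condition=self.sim_n_trials_per_condition,
            n_channels=self.sim_n_channels,
            fs=self.sim_fs,
            alpha_band=self.sim_alpha_band,
            freq_offset_gm=self.sim_freq_offset_gm,
            snr=self.sim_snr,
            evoked_effect=self.sim_evoked_effect,
            preactivation=self.sim_preactivation,
            preactivation_effect=self.sim_preactivation_effect,
            threshold_coupling=self.sim_threshold_coupling,
            seed=self.seed,
        )


def load_cohort_dir(path) -> list[tuple[EpochSet, pd.DataFrame]]:
    """Load ``sub-*/epochs`` containers and ``behavior.csv`` tables."""
    path = Path(path)
    out = []
    for sub in sorted(path.glob("sub-*")):
        epochs = read_epochs(sub / "epochs")
        behavior = pd.read_csv(sub / "behavior.csv")
        out.append((epochs, behavior))
    if not out:
        raise FileNotFoundError(f"no sub-* containers under {path}")
    return out


def _subject_alpha(epochs: EpochSet, cfg: PipelineConfig):
    """Spectrum, peak alpha, selected channel, and instantaneous frequency."""
    spec = spectral.amplitude_spectrum(epochs, cfg.spec_window_ms,
                                       cfg.spec_freq_range)
    candidates = POSTERIOR_CHANNELS if cfg.posterior_only else None
    chans = spectral.select_channels_by_alpha(
        spec, cfg.n_channels_select, cfg.alpha_band, candidates
    )
    peak = spectral.peak_alpha(spec, cfg.alpha_band, candidates)
    prestim = epochs.crop(epochs.times[0], 0.0).pick_channels(chans)
    padded = spectral.mirror_pad(prestim)
    filtered = spectral.bandpass_plateau(padded, cfg.alpha_band)
    instf = spectral.instantaneous_frequency(filtered, channel=chans[0])
    instf = _trim_instfreq(instf, prestim.n_samples)
    return spec, peak, chans, instf


def _trim_instfreq(instf: spectral.InstFreqSeries, n: int) -> spectral.InstFreqSeries:
    instf.frequency = instf.frequency[:, :n]
    instf.amplitude = instf.amplitude[:, :n]
    instf.times = instf.times[:n]
    return instf


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
    fixture_dir=None,
    out_dir=None,
) -> dict:
    """Execute the full pipeline; returns (and optionally writes) the report.

    Stages: simulate/load cohort -> clean behavior & fit psychometric curves
    -> spectrum, peak alpha & channel selection -> mirror-pad, band-pass &
    instantaneous frequency -> group GM-EM frequency cluster test ->
    peak-alpha/threshold correlation -> per-trial PAF, median split, matched
    inference conditions -> temporal-generalization decoding -> decoding
    cluster tests. A stage failure aborts with the stage named; partial
    results accumulated so far are kept in the raised error's report.
    """
    report: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "stages": {},
    }
    stage = "simulate"
    try:
        if cohort is None and fixture_dir is not None:
            loaded = load_cohort_dir(fixture_dir)
            subjects = [(ep, beh, np.nan, np.nan) for ep, beh in loaded]
        else:
            cohort = cohort or generate_cohort(config.sim_config())
            subjects = [(r.epochs, r.behavior, r.true_threshold_ms,
                         r.true_peak_freq_hz) for r in cohort]
        report["stages"]["simulate"] = {"n_subjects": len(subjects)}

        stage = "behavior"
        thresholds, clean_counts = [], []
        for epochs, behavior, _, _ in subjects:
            clean, rep = psychometrics.clean_behavior(behavior)
            fit = psychometrics.fit_logistic(clean)
            thresholds.append(fit.threshold_ms)
            clean_counts.append(
                dict(n_input=rep.n_input, n_omissions=rep.n_omissions,
                     n_rt_outliers=rep.n_rt_outliers,
                     n_incorrect_explicit=rep.n_incorrect_explicit,
                     threshold_ms=fit.threshold_ms, r_squared=fit.r_squared,
                     identifiable=fit.identifiable)
            )
        report["stages"]["behavior"] = clean_counts

        stage = "alpha"
        peaks, instfs, frame2 = [], [], []
        for epochs, _, _, _ in subjects:
            _, peak, chans, instf = _subject_alpha(epochs, config)
            peaks.append(peak)
            instfs.append(instf)
            frame2.append(epochs.attrs.get(
                "frame2_onset_ms",
                float(epochs.trials["ifi_ms"].iloc[0]) + 30.0,
            ))
        report["stages"]["alpha"] = {"peak_freqs_hz": peaks}

        stage = "frequency-contrast"
        diffs = []
        for (epochs, *_), instf in zip(subjects, instfs):
            con = spectral.condition_contrast_series(
                instf, epochs.trials["percept"].to_numpy()
            )
            diffs.append(con.difference)
        diffs = np.asarray(diffs)
        interior = instfs[0].interior_mask(200.0)
        freq_cluster = stats.cluster_permutation(
            diffs[:, interior], n_perm=config.n_perm_series,
            cluster_alpha=config.cluster_alpha, seed=config.seed,
        )
        contrast_times = instfs[0].times[interior]
        report["stages"]["frequency_contrast"] = _cluster_report(
            freq_cluster, contrast_times
        )

        stage = "correlate"
        corr = stats.pearson_alpha_threshold(peaks, thresholds)
        report["stages"]["correlation"] = dict(
            r=corr.r, p=corr.p, n=corr.n, slope=corr.slope,
            intercept=corr.intercept, slope_vs1_t=corr.slope_vs1_t,
            slope_vs1_p=corr.slope_vs1_p,
        )

        stage = "sort-trials"
        window_used = []
        cats = []
        for (epochs, *_), instf, f2 in zip(subjects, instfs, frame2):
            if config.paf_window_mode == "cluster" and freq_cluster.significant_clusters:
                cl = freq_cluster.significant_clusters[0]
                w = (float(contrast_times[cl["elements"][0].min()]),
                     float(contrast_times[cl["elements"][0].max()]))
            else:
                w0, w1 = config.paf_window_fixed_ms
                w = (w0 + f2, w1 + f2)  # frame-2-relative -> frame-1 axis
                w = (max(w[0], instf.times[0]), min(w[1], instf.times[-1]))
            window_used.append(w)
            paf = sorting.per_trial_paf(instf, w)
            ok = ~np.isnan(paf)
            split = sorting.median_split(paf[ok])
            cat = sorting.categorize_inference(
                split, epochs.trials["percept"].to_numpy()[ok]
            )
            cat.table["trial"] = np.flatnonzero(ok)
            cat.table["paf_hz"] = paf[ok]
            sorting.match_trial_counts(cat, seed=config.seed)
            cats.append(cat)
        report["stages"]["sorting"] = [
            dict(window_ms=list(w), counts={f"{s}/{p}": c[(s, p)]
                                            for s, p in sorting.CELLS})
            for w, c in zip(window_used, (c.counts for c in cats))
        ]

        stage = "decode-tg"
        tg = {"efficient": [], "inefficient": []}
        for (epochs, *_), cat, f2 in zip(subjects, cats, frame2):
            ep2 = epochs.shift_times(-f2, origin="frame2").crop(
                *config.decode_epoch_ms
            )
            for condition in ("efficient", "inefficient"):
                t = cat.trials_of(condition)
                sub = ep2.pick_trials(t["trial"].to_numpy())
                m = decoding.temporal_generalization(
                    sub, sub.trials["percept"].to_numpy(),
                    lam=config.decode_lambda, step_ms=config.decode_step_ms,
                    window_ms=config.decode_window_ms, seed=config.seed,
                    condition=condition,
                )
                tg[condition].append(m.auc)
        centers = np.arange(config.decode_epoch_ms[0],
                            config.decode_epoch_ms[1] + 1e-9,
                            config.decode_step_ms)

        stage = "cluster-test"
        decode_report = {}
        for condition in ("efficient", "inefficient"):
            mats = np.asarray(tg[condition])
            # above-chance decoding is a directional hypothesis -> positive tail
            res = stats.cluster_permutation(
                mats - 0.5, n_perm=config.n_perm_decoding,
                cluster_alpha=config.cluster_alpha, seed=config.seed,
                tail="pos",
            )
            decode_report[condition] = _cluster_report_2d(res, centers)
        res_diff = stats.cluster_permutation(
            np.asarray(tg["efficient"]) - np.asarray(tg["inefficient"]),
            n_perm=config.n_perm_decoding, cluster_alpha=config.cluster_alpha,
            seed=config.seed,
        )
        decode_report["efficient_vs_inefficient"] = _cluster_report_2d(
            res_diff, centers
        )
        decode_report["mean_auc"] = {
            c: float(np.mean(tg[c])) for c in ("efficient", "inefficient")
        }
        report["stages"]["decoding"] = decode_report
    except Exception as err:
        raise PipelineError(stage, report) from err

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    return report


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the partial report."""

    def __init__(self, stage: str, report: dict):
        super().__init__(f"pipeline failed at stage {stage!r}")
        self.stage = stage
        self.report = report


def _cluster_report(res: stats.ClusterTestResult, times: np.ndarray) -> dict:
    out = dict(
        size_threshold=res.size_threshold,
        n_clusters=len(res.clusters),
        significant=[],
    )
    for c in res.significant_clusters:
        idx = c["elements"][0]
        out["significant"].append(
            dict(size=c["size"], sign=c["sign"], p=c["p"],
                 t_start_ms=float(times[idx.min()]),
                 t_end_ms=float(times[idx.max()]))
        )
    return out


def _cluster_report_2d(res: stats.ClusterTestResult, centers: np.ndarray) -> dict:
    out = dict(
        size_threshold=res.size_threshold,
        n_clusters=len(res.clusters),
        significant=[],
    )
    for c in res.significant_clusters:
        tr, te = c["elements"]
        out["significant"].append(
            dict(size=c["size"], sign=c["sign"], p=c["p"],
                 train_start_ms=float(centers[tr.min()]),
                 train_end_ms=float(centers[tr.max()]),
                 test_start_ms=float(centers[te.min()]),
                 test_end_ms=float(centers[te.max()]))
        )
    return out
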