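"""Per-trial alpha frequency, median split, and inference-condition sorting.

Each bistable trial gets a scalar prestimulus alpha frequency (PAF): the mean
of its instantaneous-frequency series over a scoring window. Trials are split
at the PAF of the rank-``n/2`` trial into high and low sets; crossing the split
with the reported percept yields the efficient (high & GM, low & EM) and
inefficient (high & EM, low & GM) inference conditions. Because the four
split x percept cells generally differ in size, a seeded subsample matches
their counts before decoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import InstFreqSeries

__all__ = [
    "TrialCategorization",
    "per_trial_paf",
    "median_split",
    "categorize_inference",
    "match_trial_counts",
]

CELLS = [("high", "GM"), ("low", "EM"), ("low", "GM"), ("high", "EM")]


def per_trial_paf(instfreq: InstFreqSeries, window_ms: tuple[float, float]
                  ) -> np.ndarray:
    """Mean instantaneous frequency per trial over ``window_ms``.

    Missing samples (undefined phase) are excluded from the mean; a trial
    with no valid sample in the window is returned as NaN (unusable) with a
    warning.
    """
    t0, t1 = window_ms
    if t0 < instfreq.times[0] - 1e-9 or t1 > instfreq.times[-1] + 1e-9:
        raise ValueError(
            f"scoring window {window_ms} outside series "
            f"[{instfreq.times[0]:.1f}, {instfreq.times[-1]:.1f}] ms"
        )
    sel = (instfreq.times >= t0 - 1e-9) & (instfreq.times <= t1 + 1e-9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        paf = np.nanmean(instfreq.frequency[:, sel], axis=1)
    if np.isnan(paf).any():
        warnings.warn(f"{int(np.isnan(paf).sum())} trial(s) unusable "
                      "(no valid samples in scoring window)")
    return paf


def median_split(pafs) -> np.ndarray:
    """Split trials at the PAF of the rank-``n/2`` trial.

    The boundary is the value of the trial at rank ``max(1, n//2)``
    (1-indexed, ascending). Trials strictly above it are ``"high"``;
    the boundary trial and any tie at its value are ``"low"``.
    """
    pafs = np.asarray(pafs, dtype=float)
    if len(pafs) < 4:
        raise ValueError("median split needs >= 4 trials")
    if np.isnan(pafs).any():
        raise ValueError("NaN PAFs; drop unusable trials before splitting")
    boundary = np.sort(pafs)[max(1, len(pafs) // 2) - 1]
    if np.all(pafs == pafs[0]):
        warnings.warn("all PAFs equal; every trial assigned 'low'")
    return np.where(pafs > boundary, "high", "low")


@dataclass
class TrialCategorization:
    """Per-trial PAF, split, percept, inference label and matched mask."""

    table: pd.DataFrame  # columns: trial, paf_hz, split, percept, inference, matched

    @property
    def counts(self) -> dict:
        """Trial counts of the four split x percept cells."""
        return {
            (s, p): int(((self.table["split"] == s)
                         & (self.table["percept"] == p)).sum())
            for s, p in CELLS
        }

    @property
    def matched_counts(self) -> dict:
        m = self.table[self.table["matched"]]
        return {
            (s, p): int(((m["split"] == s) & (m["percept"] == p)).sum())
            for s, p in CELLS
        }

    def trials_of(self, inference: str, matched_only: bool = True) -> pd.DataFrame:
        t = self.table[self.table["inference"] == inference]
        return t[t["matched"]] if matched_only else t

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def categorize_inference(split_labels, percepts) -> TrialCategorization:
    """Cross split with percept into efficient/inefficient inference labels.

    efficient = (high & GM) | (low & EM); inefficient = the other two cells.
    Errors if any split x percept cell is empty (the conditions would be
    degenerate downstream).
    """
    split_labels = np.asarray(split_labels)
    percepts = np.asarray(percepts)
    if split_labels.shape != percepts.shape:
        raise ValueError("split and percept arrays must align")
    for s, p in CELLS:
        if not ((split_labels == s) & (percepts == p)).any():
            raise ValueError(f"empty cell: ({s} PAF, {p})")
    efficient = ((split_labels == "high") & (percepts == "GM")) | (
        (split_labels == "low") & (percepts == "EM")
    )
    table = pd.DataFrame(
        dict(
            trial=np.arange(len(percepts)),
            split=split_labels,
            percept=percepts,
            inference=np.where(efficient, "efficient", "inefficient"),
            matched=True,
        )
    )
    return TrialCategorization(table)


def match_trial_counts(cat: TrialCategorization, seed: int | None = None
                       ) -> np.ndarray:
    """Equalize the four cell counts by seeded subsampling without replacement.

    The target is the minimum cell count; larger cells are subsampled
    uniformly. Updates ``cat.table['matched']`` in place and returns the mask.
    """
    rng = np.random.default_rng(seed)
    counts = cat.counts
    target = min(counts.values())
    mask = np.zeros(len(cat.table), dtype=bool)
    for s, p in CELLS:
        idx = np.flatnonzero(
            (cat.table["split"] == s).to_numpy()
            & (cat.table["percept"] == p).to_numpy()
        )
        if len(idx) > target:
            idx = rng.choice(idx, size=target, replace=False)
        mask[idx] = True
    cat.table["matched"] = mask
    return mask
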