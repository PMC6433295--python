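"""Regularized LDA temporal-generalization decoding with LOOCV and AUC scoring.

The decoder is a linear projection y = sum_i w_i x_i + c over channels, with

    w  proportional to  (Sigma_pooled + lambda * diag-mean * I)^-1 (mu_1 - mu_0)

and the offset placing the boundary midway between projected class means.
Features at each time point are channel amplitudes averaged within a 50-ms
window. A classifier trained at one time is tested at every other time, giving
a (training time) x (testing time) matrix of AUC values; decision values are
pooled over leave-one-out folds before computing each cell's AUC (per-fold AUC
is undefined when each fold holds a single trial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .epochs import EpochSet

__all__ = [
    "DecoderModel",
    "windowed_features",
    "train_lda",
    "auc",
    "TGMatrix",
    "temporal_generalization",
]


@dataclass
class DecoderModel:
    """One linear discriminant: channel weights, offset, regularization."""

    weights: np.ndarray
    offset: float
    lam: float

    def decision_values(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.weights + self.offset

    def predict(self, X) -> np.ndarray:
        return (self.decision_values(X) > 0).astype(int)


def windowed_features(
    epochs: EpochSet, center_ms: float, width_ms: float = 50.0
) -> np.ndarray:
    """Trials x channels mean amplitude in a window centered at ``center_ms``.

    The window holds ``round(width * fs / 1000)`` samples centered on the
    sample nearest the requested time; at the epoch edges it is clipped,
    not padded.
    """
    c = epochs.sample_index(center_ms)  # errors if center outside epoch
    n_win = max(1, int(round(width_ms * epochs.fs / 1000.0)))
    start = max(0, c - n_win // 2)
    stop = min(epochs.n_samples, start + n_win)
    start = max(0, stop - n_win) if stop == epochs.n_samples else start
    return epochs.data[:, :, start:stop].mean(axis=-1)


def train_lda(features, labels, lam: float = 0.1) -> DecoderModel:
    """Fit the regularized linear discriminant.

    The pooled within-class covariance is shrunk toward a scaled identity,
    ``Sigma + lam * mean(diag(Sigma)) * I``; ``lam = 0`` with collinear
    features is rejected with advice to regularize.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("need >= 2 trials per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    W = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    cov = W / (n0 + n1 - 2)
    reg = cov + lam * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    try:
        w = np.linalg.solve(reg, mu1 - mu0)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular regularized covariance; use lam > 0 with collinear features"
        ) from err
    if not np.all(np.isfinite(w)):
        raise ValueError(
            "non-finite weights; use lam > 0 with collinear features"
        )
    c = -float(w @ (mu0 + mu1) / 2.0)
    return DecoderModel(w, c, lam)


def auc(decision_values, labels) -> float:
    """Mann-Whitney AUC: P(random positive's value > random negative's),
    ties counted 1/2. ``labels`` may be any two-class coding; the larger
    label (sorted order) is the positive class."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score((y == classes[1]).astype(int),
                               np.asarray(decision_values, dtype=float)))


@dataclass
class TGMatrix:
    """Training-time x testing-time AUC matrix."""

    auc: np.ndarray
    train_times_ms: np.ndarray
    test_times_ms: np.ndarray
    n_folds: int
    lam: float
    condition: str | None = None
    params: dict = field(default_factory=dict)

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.auc)

    def to_frame(self) -> pd.DataFrame:
        tr, te = np.meshgrid(self.train_times_ms, self.test_times_ms, indexing="ij")
        return pd.DataFrame(
            dict(train_ms=tr.ravel(), test_ms=te.ravel(), auc=self.auc.ravel())
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ext = [self.test_times_ms[0], self.test_times_ms[-1],
               self.train_times_ms[0], self.train_times_ms[-1]]
        im = ax.imshow(self.auc, origin="lower", extent=ext, aspect="auto",
                       cmap=kwargs.pop("cmap", "RdBu_r"),
                       vmin=kwargs.pop("vmin", 0.3), vmax=kwargs.pop("vmax", 0.7))
        ax.set(xlabel="testing time (ms)", ylabel="training time (ms)")
        plt.colorbar(im, ax=ax, label="AUC")
        return ax


def temporal_generalization(
    epochs: EpochSet,
    labels,
    lam: float = 0.1,
    step_ms: float = 10.0,
    window_ms: float = 50.0,
    tmin_ms: float | None = None,
    tmax_ms: float | None = None,
    rebalance: bool = False,
    seed: int | None = None,
    block_average: int | None = None,
    condition: str | None = None,
) -> TGMatrix:
    """Leave-one-out temporal-generalization decoding.

    For every left-out trial a discriminant is trained on the remaining
    trials at each training time and applied to the left-out trial's
    features at every testing time; decision values are pooled across folds
    and one AUC is computed per (train, test) cell. ``block_average``
    instead partitions folds into that many blocks and averages per-block
    AUCs. ``rebalance`` drops one seeded opposite-class trial per fold so
    training class counts stay equal after the leave-out.
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    n = len(y)
    if n < 8:
        raise ValueError("need >= 8 trials for temporal generalization")
    counts = [(y == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("need >= 2 trials per class (match counts upstream)")
    if counts[0] != counts[1]:
        warnings.warn("unmatched class counts; consider match_trial_counts")

    t0 = epochs.times[0] if tmin_ms is None else tmin_ms
    t1 = epochs.times[-1] if tmax_ms is None else tmax_ms
    centers = np.arange(t0, t1 + 1e-9, step_ms)
    T = len(centers)
    feats = np.stack([windowed_features(epochs, c, window_ms) for c in centers])
    # feats: T x trials x channels
    n_ch = feats.shape[2]
    ybin = (y == classes[1]).astype(int)

    # per-center, per-class sufficient statistics for fast LOO downdating
    sums = np.zeros((T, 2, n_ch))
    scat = np.zeros((T, 2, n_ch, n_ch))
    for k in (0, 1):
        Xk = feats[:, ybin == k, :]
        sums[:, k] = Xk.sum(axis=1)
        scat[:, k] = np.einsum("tic,tid->tcd", Xk, Xk)
    n_k = np.array([(ybin == 0).sum(), (ybin == 1).sum()])

    rng = np.random.default_rng(seed)
    eye = np.eye(n_ch)
    dv = np.full((T, T, n) if block_average is None else (T, T, n), np.nan)
    for i in range(n):
        ki = ybin[i]
        drop_j = None
        if rebalance:
            others = np.flatnonzero((ybin == 1 - ki))
            drop_j = int(rng.choice(others))
        for tr in range(T):
            s = sums[tr].copy()
            S = scat[tr].copy()
            nk = n_k.copy()
            xi = feats[tr, i]
            s[ki] -= xi
            S[ki] -= np.outer(xi, xi)
            nk[ki] -= 1
            if drop_j is not None:
                xj = feats[tr, drop_j]
                s[1 - ki] -= xj
                S[1 - ki] -= np.outer(xj, xj)
                nk[1 - ki] -= 1
            if nk.min() < 1:
                raise ValueError("a class vanished from a training fold")
            mu0, mu1 = s[0] / nk[0], s[1] / nk[1]
            W = (S[0] - nk[0] * np.outer(mu0, mu0)
                 + S[1] - nk[1] * np.outer(mu1, mu1))
            cov = W / max(nk.sum() - 2, 1)
            reg = cov + lam * np.trace(cov) / n_ch * eye
            w = np.linalg.solve(reg, mu1 - mu0)
            c = -float(w @ (mu0 + mu1) / 2.0)
            dv[tr, :, i] = feats[:, i, :] @ w + c

    if block_average is None:
        # pooled Mann-Whitney AUC per cell, vectorized via midranks
        from scipy.stats import rankdata

        r = rankdata(dv, axis=-1, method="average")
        pos = ybin.astype(bool)
        n1, n0 = int(pos.sum()), int((~pos).sum())
        mat = (r[..., pos].sum(axis=-1) - n1 * (n1 + 1) / 2) / (n1 * n0)
    else:
        order = rng.permutation(n)
        blocks = np.array_split(order, block_average)
        mat = np.zeros((T, T))
        for blk in blocks:
            for tr in range(T):
                for te in range(T):
                    mat[tr, te] += auc(dv[tr, te, blk], ybin[blk]) / len(blocks)
    return TGMatrix(
        mat, centers.copy(), centers.copy(), n, lam, condition,
        dict(step_ms=step_ms, window_ms=window_ms, rebalance=rebalance,
             seed=seed, block_average=block_average,
             classes=[str(c) for c in classes]),
    )
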