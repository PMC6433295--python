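"""Discriminant training, AUC semantics and temporal generalization."""

import numpy as np
import pandas as pd
import pytest

from pafpipe import auc, temporal_generalization, train_lda, windowed_features
from conftest import make_epochs, sinusoid_epochs

FS = 160.0


def _two_gaussians(n_per_class=50, n_ch=8, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n_per_class, n_ch))
    X1 = rng.standard_normal((n_per_class, n_ch))
    X1[:, 0] += sep
    X = np.vstack([X0, X1])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y


class TestWindowedFeatures:
    def test_constant_channel(self):
        ep = make_epochs(np.full((2, 3, 128), 7.5), t0=-400)
        for center in (-300, -100, 0):
            assert np.allclose(windowed_features(ep, center), 7.5)

    def test_full_cycle_zero_mean(self):
        # one full 10 Hz cycle averages to ~0
        ep = sinusoid_epochs(10.0, t0=-400, dur_s=0.8)
        f = windowed_features(ep, -200.0, width_ms=100.0)
        assert abs(f[0, 0]) < 1e-9

    def test_window_sample_count(self):
        ep = make_epochs(np.zeros((1, 1, 128)), t0=-400)
        ep.data[0, 0, :] = np.arange(128.0)
        c = ep.sample_index(-200.0)
        expected = ep.data[0, 0, c - 4:c + 4].mean()  # 8 samples at 160 Hz
        assert windowed_features(ep, -200.0, 50.0)[0, 0] == expected

    def test_edge_windows_clipped(self):
        ep = make_epochs(np.tile(np.arange(128.0), (1, 1, 1)), t0=-400)
        f = windowed_features(ep, ep.times[0], 50.0)
        assert f[0, 0] == ep.data[0, 0, :8].mean() or f[0, 0] == \
            ep.data[0, 0, :4].mean()

    def test_center_outside_epoch(self):
        ep = make_epochs(np.zeros((1, 1, 128)), t0=-400)
        with pytest.raises(ValueError, match="outside epoch"):
            windowed_features(ep, 1000.0)


class TestTrainLda:
    def test_separated_classes_high_accuracy(self):
        X, y = _two_gaussians(seed=1)
        Xt, yt = _two_gaussians(seed=2)
        model = train_lda(X, y, lam=0.1)
        acc = (model.predict(Xt) == yt).mean()
        assert acc > 0.9

    def test_identical_distributions_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 6))
        y = np.array([0, 1] * 40)
        model = train_lda(X, y, lam=0.1)
        a = auc(model.decision_values(X), y)
        # training-set AUC on pure noise stays in a generous chance band
        assert 0.35 < a < 0.75

    def test_duplicated_channels_regularized(self):
        X, y = _two_gaussians(seed=4)
        Xd = np.hstack([X, X[:, :1]])
        m = train_lda(X, y, lam=0.1)
        md = train_lda(Xd, y, lam=0.1)
        assert np.all(np.isfinite(md.weights))
        d1, d2 = m.decision_values(X), md.decision_values(Xd)
        assert np.corrcoef(d1, d2)[0, 1] > 0.99
        assert auc(d2, y) == pytest.approx(auc(d1, y), abs=0.02)

    def test_collinear_without_regularization_rejected(self):
        X, y = _two_gaussians(n_ch=3, seed=5)
        Xd = np.hstack([X, X[:, :1]])  # exact collinearity
        with pytest.raises(ValueError, match="lam > 0"):
            train_lda(Xd, y, lam=0.0)

    def test_matches_sklearn_shrinkage_direction(self):
        # our lam maps to sklearn's convex shrinkage up to scale:
        # Sigma + lam*(tr/p) I  proportional to  (1-a)Sigma + a*(tr/p) I
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, y = _two_gaussians(sep=1.5, seed=6)
        lam = 0.3
        ours = train_lda(X, y, lam=lam).weights
        sk = LinearDiscriminantAnalysis(solver="lsqr",
                                        shrinkage=lam / (1 + lam)).fit(X, y)
        theirs = sk.coef_.ravel()
        cos = ours @ theirs / np.linalg.norm(ours) / np.linalg.norm(theirs)
        assert cos > 0.999

    def test_needs_two_trials_per_class(self):
        with pytest.raises(ValueError, match=">= 2 trials"):
            train_lda(np.zeros((3, 2)), np.array([0, 1, 1]))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(30)
        y = rng.integers(0, 2, 30)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, 30)
        assert auc(v, y) == pytest.approx(1 - auc(v, 1 - y))

    def test_tie_counted_half(self):
        # pairs: (.9,.8)=1 (.9,.1)=1 (.8,.8)=tie (.8,.1)=1 -> 3.5/4
        assert auc([0.9, 0.8, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal(40)
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        a = auc(v, y)
        assert auc(np.exp(v), y) == a
        assert auc(3 * v + 10, y) == a

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2, 3], [1, 1, 1])


def _evoked_epochs(n=40, ch=8, pre_effect=0.0, post_effect=1.5, seed=0,
                   shared_pattern=True):
    """Two-class epochs with a post-onset pattern and optional preactivation."""
    rng = np.random.default_rng(seed)
    times = np.arange(-400, 401, 1000 / FS)
    y = np.array(["EM"] * (n // 2) + ["GM"] * (n // 2))
    rng.shuffle(y)
    pats = {p: rng.standard_normal(ch) / np.sqrt(ch) for p in ("EM", "GM")}
    pre_pats = pats if shared_pattern else {
        p: rng.standard_normal(ch) / np.sqrt(ch) for p in ("EM", "GM")}
    data = rng.standard_normal((n, ch, len(times)))
    post = (times >= 0) & (times <= 300)
    pre = (times >= -300) & (times < 0)
    for i in range(n):
        data[i, :, post] += post_effect * pats[y[i]]
        data[i, :, pre] += pre_effect * pre_pats[y[i]]
    ep = make_epochs(data, t0=-400, trials=pd.DataFrame({"percept": y}))
    return ep, y


class TestTemporalGeneralization:
    def test_observed_within_permutation_null_band(self):
        # with no class signal the observed mean AUC is an ordinary draw
        # from the label-permutation null distribution
        ep, y = _evoked_epochs(n=16, ch=4, post_effect=0.0, seed=2)
        rng = np.random.default_rng(7)
        obs = temporal_generalization(ep, y, step_ms=100).auc.mean()
        null = []
        for _ in range(100):
            null.append(temporal_generalization(
                ep, rng.permutation(y), step_ms=100).auc.mean())
        lo, hi = np.percentile(null, [2.5, 97.5])
        assert lo <= obs <= hi

    def test_signal_confined_to_post_stimulus_quadrant(self):
        ep, y = _evoked_epochs(n=40, ch=8, post_effect=1.5, seed=3)
        m = temporal_generalization(ep, y, step_ms=50)
        post = m.train_times_ms >= 0
        pre = m.train_times_ms < -50
        post_block = m.auc[np.ix_(post, post)]
        pre_block = m.auc[np.ix_(pre, pre)]
        assert post_block.mean() > 0.75
        assert abs(pre_block.mean() - 0.5) < 0.12

    def test_preactivation_generalizes_across_onset(self):
        # prestimulus pattern sharing the post-stimulus topography ->
        # above-chance off-diagonal (train post, test pre) generalization
        ep, y = _evoked_epochs(n=40, ch=8, pre_effect=1.0, post_effect=1.5,
                               seed=4, shared_pattern=True)
        m = temporal_generalization(ep, y, step_ms=50)
        post = m.train_times_ms >= 0
        pre = m.train_times_ms <= -100
        cross = m.auc[np.ix_(post, pre)]
        assert cross.mean() > 0.6

    def test_amplitude_scaling_invariance(self):
        ep, y = _evoked_epochs(n=24, ch=4, post_effect=1.0, seed=5)
        doubled = make_epochs(2.0 * ep.data, t0=-400, trials=ep.trials)
        m1 = temporal_generalization(ep, y, step_ms=100)
        m2 = temporal_generalization(doubled, y, step_ms=100)
        assert np.allclose(m1.auc, m2.auc)

    def test_rebalance_mode_runs_and_is_seeded(self):
        ep, y = _evoked_epochs(n=24, ch=4, post_effect=1.0, seed=6)
        a = temporal_generalization(ep, y, step_ms=200, rebalance=True, seed=1)
        b = temporal_generalization(ep, y, step_ms=200, rebalance=True, seed=1)
        assert np.array_equal(a.auc, b.auc)

    def test_block_average_close_to_pooled(self):
        ep, y = _evoked_epochs(n=32, ch=4, post_effect=2.0, seed=8)
        pooled = temporal_generalization(ep, y, step_ms=200)
        blocked = temporal_generalization(ep, y, step_ms=200, block_average=4,
                                          seed=0)
        post = pooled.train_times_ms >= 0
        assert blocked.auc[np.ix_(post, post)].mean() == pytest.approx(
            pooled.auc[np.ix_(post, post)].mean(), abs=0.1)

    def test_too_few_trials_rejected(self):
        ep, y = _evoked_epochs(n=40, ch=4)
        with pytest.raises(ValueError, match=">= 8 trials"):
            temporal_generalization(ep.pick_trials(np.arange(6)), y[:6])
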