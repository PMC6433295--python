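"""Cluster-based permutation inference and group-level correlation analyses.

The cluster test controls family-wise error over time points (1D) or
train x test cells (2D) nonparametrically: element-wise paired t statistics
are thresholded at the cluster-forming alpha, neighboring suprathreshold
elements form clusters whose size is their element count, and the observed
sizes are referred to the null distribution of the *maximum* cluster size
obtained by randomly sign-flipping each subject's difference (the exact
paired-design null). A cluster is significant only if its size strictly
exceeds the 95th percentile of that null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "paired_t_map",
    "ClusterTestResult",
    "cluster_permutation",
    "CohortCorrelation",
    "pearson_alpha_threshold",
]


def paired_t_map(cond_a, cond_b):
    """Element-wise paired t (and two-tailed p) over the subject axis.

    ``cond_a``/``cond_b``: subjects x elements (any trailing shape).
    Zero-variance elements are undefined and returned as NaN with a warning.
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must share a shape")
    if a.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    t, p = _t_one_sample(a - b)
    return t, p


def _t_one_sample(d: np.ndarray):
    """One-sample t of subject x elements differences, NaN where var = 0."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance element(s) masked")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[bad] = np.nan
    p = 2 * stats.t.sf(np.abs(t), n - 1)
    return t, p


@dataclass
class ClusterTestResult:
    """Observed clusters, the max-size permutation null, and significance."""

    t_map: np.ndarray
    mask: np.ndarray  # suprathreshold elements (either sign)
    clusters: list[dict]  # elements (index array), size, sign, p, significant
    null_max_sizes: np.ndarray
    size_threshold: float  # 95th-percentile order statistic of the null
    params: dict = field(default_factory=dict)

    @property
    def significant_mask(self) -> np.ndarray:
        out = np.zeros_like(self.mask)
        for cl in self.clusters:
            if cl["significant"]:
                out[cl["elements"]] = True
        return out

    @property
    def significant_clusters(self) -> list[dict]:
        return [c for c in self.clusters if c["significant"]]

    def summary(self) -> str:
        p = self.params
        lines = [
            "Cluster-based permutation test",
            "=" * 40,
            f"elements {self.t_map.shape}, subjects n={p.get('n_subjects')}",
            f"cluster-forming alpha {p.get('cluster_alpha')}, "
            f"{p.get('n_perm')} sign-flip permutations, tail={p.get('tail')}",
            f"null 95th-percentile max size: {self.size_threshold:.0f}",
        ]
        if not self.clusters:
            lines.append("no suprathreshold clusters")
        for i, c in enumerate(self.clusters):
            star = "*" if c["significant"] else " "
            lines.append(
                f"{star} cluster {i}: sign {c['sign']:+d}, size {c['size']}, "
                f"p = {c['p']:.4f}"
            )
        return "\n".join(lines)


def _label_clusters(mask: np.ndarray):
    """Connected components under grid adjacency (4-connectivity in 2D)."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    labels, n = ndimage.label(mask, structure=structure)
    return [np.nonzero(labels == i) for i in range(1, n + 1)]


def _signed_clusters(t_map, t_crit, tail):
    out = []
    if tail in ("two", "pos"):
        for el in _label_clusters(t_map > t_crit):
            out.append((el, +1))
    if tail in ("two", "neg"):
        for el in _label_clusters(t_map < -t_crit):
            out.append((el, -1))
    return out


def cluster_permutation(
    diff_data,
    n_perm: int = 1000,
    cluster_alpha: float = 0.05,
    tail: str = "two",
    seed: int | None = None,
    adjacency: str = "grid",
) -> ClusterTestResult:
    """Max-cluster-size permutation test on paired differences.

    Parameters
    ----------
    diff_data : ndarray, subjects x elements
        Per-subject condition differences; elements may be a 1D series
        (time) or a 2D matrix (training x testing time).
    n_perm : int
        Number of per-subject random sign flips (>= 100).
    cluster_alpha : float
        Element-wise cluster-forming threshold (p-value).
    tail : {"two", "pos", "neg"}
        Two-tailed forms positive and negative clusters separately.
    adjacency : str
        Only grid adjacency (1D runs / 2D 4-connectivity) is supported.

    A cluster is significant iff its size strictly exceeds the empirical
    95th-percentile order statistic (at ``ceil(0.95 * n_perm)``) of the null
    max-size distribution; its Monte-Carlo p is
    ``(1 + #{null >= size}) / (1 + n_perm)``.
    """
    d = np.asarray(diff_data, float)
    if d.ndim not in (2, 3):
        raise ValueError("diff_data must be subjects x elements (1D or 2D)")
    if adjacency != "grid":
        raise ValueError("only grid adjacency is supported")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if tail not in ("two", "pos", "neg"):
        raise ValueError("tail must be 'two', 'pos' or 'neg'")
    n_sub = d.shape[0]
    elem_shape = d.shape[1:]
    df = n_sub - 1
    if tail == "two":
        t_crit = stats.t.ppf(1 - cluster_alpha / 2, df)
    else:
        t_crit = stats.t.ppf(1 - cluster_alpha, df)

    t_obs, _ = _t_one_sample(d)
    t_for_mask = np.nan_to_num(t_obs)
    observed = _signed_clusters(t_for_mask, t_crit, tail)
    mask = np.zeros(elem_shape, bool)
    for el, _sign in observed:
        mask[el] = True

    # vectorized sign-flip t-maps: squares are flip-invariant
    flat = d.reshape(n_sub, -1)
    ss = (flat**2).sum(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    m = signs @ flat / n_sub
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ss - n_sub * m**2) / (n_sub - 1)
        t_null = m / np.sqrt(var / n_sub)
    t_null = np.nan_to_num(t_null)

    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        tm = t_null[i].reshape(elem_shape)
        sizes = [len(el[0]) for el, _s in _signed_clusters(tm, t_crit, tail)]
        null_max[i] = max(sizes) if sizes else 0
    size_threshold = float(np.sort(null_max)[int(np.ceil(0.95 * n_perm)) - 1])

    clusters = []
    for el, sign in observed:
        size = len(el[0])
        p = (1 + (null_max >= size).sum()) / (1 + n_perm)
        clusters.append(
            dict(elements=el, size=size, sign=sign, p=float(p),
                 significant=size > size_threshold)
        )
    clusters.sort(key=lambda c: -c["size"])
    return ClusterTestResult(
        t_obs, mask, clusters, null_max, size_threshold,
        dict(n_subjects=n_sub, n_perm=n_perm, cluster_alpha=cluster_alpha,
             tail=tail, seed=seed, t_crit=float(t_crit)),
    )


@dataclass
class CohortCorrelation:
    """Between-subject correlation with the cycle-length slope analysis."""

    r: float
    p: float
    n: int
    slope: float
    intercept: float
    slope_stderr: float
    slope_vs1_t: float
    slope_vs1_p: float
    x: np.ndarray  # alpha cycle length, ms
    y: np.ndarray  # transition threshold, ms
    peak_freqs: np.ndarray

    def summary(self) -> str:
        return "\n".join([
            "Peak alpha frequency vs transition threshold",
            "=" * 46,
            f"n = {self.n}, Pearson r = {self.r:.4f}, p = {self.p:.4g}",
            "threshold ~ alpha cycle length (1000/f):",
            f"  slope = {self.slope:.4f} +- {self.slope_stderr:.4f} ms/ms, "
            f"intercept = {self.intercept:.1f} ms",
            f"  H0 slope=1: t({self.n - 2}) = {self.slope_vs1_t:.3f}, "
            f"p = {self.slope_vs1_p:.4g}",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x, self.y, "o")
        grid = np.linspace(self.x.min(), self.x.max(), 2)
        ax.plot(grid, self.intercept + self.slope * grid, "-")
        ax.set(xlabel="alpha cycle length (ms)", ylabel="transition IFI threshold (ms)")
        return ax


def pearson_alpha_threshold(peak_freqs, thresholds) -> CohortCorrelation:
    """Pearson r between peak alpha frequency and transition threshold, plus
    the regression of threshold on alpha cycle length with a slope-vs-1 test.

    A frequency-gated integration window predicts the cycle-length slope to
    be 1: one extra ms of alpha cycle shifts the transition by one ms.
    """
    f = np.asarray(peak_freqs, float)
    y = np.asarray(thresholds, float)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("peak_freqs and thresholds must be equal-length 1D")
    if len(f) < 3:
        raise ValueError("need >= 3 subjects")
    if f.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(f, y)
    cycle = 1000.0 / f
    reg = stats.linregress(cycle, y)
    t1 = (reg.slope - 1.0) / reg.stderr
    p1 = 2 * stats.t.sf(abs(t1), len(f) - 2)
    return CohortCorrelation(
        float(r), float(p), len(f), float(reg.slope), float(reg.intercept),
        float(reg.stderr), float(t1), float(p1), cycle, y, f,
    )
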