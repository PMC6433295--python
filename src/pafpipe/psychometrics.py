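"""Behavioral cleaning and logistic psychometric fitting.

The transition threshold of the bistable two-frame stimulus is the interframe
interval (IFI) at which element-motion and group-motion reports are equally
likely. It is estimated per subject by fitting a logistic psychometric curve

    P(GM | IFI) = 1 / (1 + exp(-(IFI - a) / b))

to the 2AFC pretest responses by binomial maximum likelihood; the threshold is
then ``a`` exactly (the 50% point of the fitted curve) and the per-ms steepness
is ``1/b``. Goodness of fit is an R^2 over the per-IFI observed proportions.

Cleaning follows the recorded-cohort rules: omissions are removed first, then
trials whose RT lies more than 3 SD from the per-condition mean, and explicit
trials with percept-incongruent reports are flagged incorrect and excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CleaningReport",
    "clean_behavior",
    "LogisticPsychometric",
    "PsychometricResults",
    "fit_logistic",
    "BehaviorSummary",
    "summarize_behavior",
]


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    n_input: int
    n_omissions: int
    n_rt_outliers: int
    n_incorrect_explicit: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return (self.n_input - self.n_omissions - self.n_rt_outliers
                - self.n_incorrect_explicit)


_EXPLICIT_TRUTH = {"explicit-EM": "EM", "explicit-GM": "GM"}


def clean_behavior(table: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the behavioral exclusion rules; returns (clean table, report).

    Rule order: (1) omissions removed; (2) per-condition RT mean/SD computed
    on the remaining trials and trials with ``|RT - mean| > 3*SD`` removed
    (strict, so a zero-SD condition removes nothing); (3) explicit trials
    whose report contradicts the stimulus are flagged incorrect and removed.
    """
    if "rt_ms" not in table or "response" not in table:
        raise ValueError("table needs 'rt_ms' and 'response' columns")
    report = CleaningReport(len(table), 0, 0, 0)
    omitted = table["response"].eq("omission") | table["rt_ms"].isna()
    report.n_omissions = int(omitted.sum())
    kept = table.loc[~omitted].copy()

    cond = kept["condition"] if "condition" in kept else pd.Series("all", index=kept.index)
    outlier = pd.Series(False, index=kept.index)
    for c, grp in kept.groupby(cond):
        if len(grp) == 0:
            continue
        mu, sd = grp["rt_ms"].mean(), grp["rt_ms"].std(ddof=1)
        if not np.isfinite(sd):
            sd = 0.0
        outlier.loc[grp.index] = (grp["rt_ms"] - mu).abs() > 3 * sd
    report.n_rt_outliers = int(outlier.sum())
    kept = kept.loc[~outlier]

    if "condition" in kept:
        truth = kept["condition"].map(_EXPLICIT_TRUTH)
        incorrect = truth.notna() & (kept["response"] != truth)
        report.n_incorrect_explicit = int(incorrect.sum())
        kept = kept.loc[~incorrect]
        for c in table["condition"].unique():
            if not (kept["condition"] == c).any():
                msg = f"condition {c!r} empty after cleaning"
                report.warnings.append(msg)
                warnings.warn(msg)
    return kept.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# logistic psychometric model
# ---------------------------------------------------------------------------

class LogisticPsychometric:
    """Binomial-ML logistic model of P(GM) as a function of IFI.

    Parameters
    ----------
    gm : array-like of bool/int
        1 for a GM report, 0 for EM, one entry per trial.
    ifi_ms : array-like
        Interframe interval of each trial, ms.
    """

    def __init__(self, gm, ifi_ms):
        self.gm = np.asarray(gm, dtype=float)
        self.ifi_ms = np.asarray(ifi_ms, dtype=float)
        if self.gm.shape != self.ifi_ms.shape:
            raise ValueError("gm and ifi_ms must have equal length")
        if len(np.unique(self.ifi_ms)) < 2:
            raise ValueError("need >= 2 distinct IFIs to fit a psychometric curve")

    @classmethod
    def from_table(cls, table: pd.DataFrame, condition: str | None = "pretest"):
        """Build from a trial table with ``ifi_ms`` and ``response`` columns."""
        t = table
        if condition is not None and "condition" in t:
            t = t[t["condition"] == condition]
        t = t[t["response"].isin(["EM", "GM"])]
        return cls((t["response"] == "GM").to_numpy(), t["ifi_ms"].to_numpy())

    def fit(self) -> "PsychometricResults":
        ifis = np.unique(self.ifi_ms)
        k = np.array([self.gm[self.ifi_ms == x].sum() for x in ifis])
        n = np.array([(self.ifi_ms == x).sum() for x in ifis])
        props = k / n

        identifiable = True
        diagnostics: list[str] = []
        if self.gm.min() == self.gm.max():
            # all-GM or all-EM: the likelihood is maximized at infinite offset
            identifiable = False
            diagnostics.append("all responses identical; threshold not identifiable")
            sign = -np.inf if self.gm.min() == 1 else np.inf
            return PsychometricResults(
                threshold_ms=float(sign), slope_per_ms=np.nan, r_squared=np.nan,
                ifis=ifis, per_ifi_props=props, n_per_ifi=n,
                params=(np.nan, np.nan), identifiable=False,
                diagnostics=diagnostics, model=self,
            )

        exog = sm.add_constant(self.ifi_ms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(self.gm, exog, family=sm.families.Binomial())
            res = glm.fit(maxiter=200)
        b0, b1 = res.params
        if abs(b1) < 1e-12:
            slope = 0.0
            threshold = np.inf
            identifiable = False
            diagnostics.append("flat psychometric curve; threshold not identifiable")
        else:
            slope = float(b1)
            threshold = float(-b0 / b1)
        fitted = 1.0 / (1.0 + np.exp(-(b0 + b1 * ifis)))
        ss_res = float(np.sum((props - fitted) ** 2))
        ss_tot = float(np.sum((props - props.mean()) ** 2))
        if ss_tot > 0:
            r2 = max(0.0, 1.0 - ss_res / ss_tot)
        else:
            r2 = 1.0 if ss_res < 1e-12 else 0.0
        if identifiable and not (ifis.min() <= threshold <= ifis.max()):
            identifiable = False
            diagnostics.append(
                f"threshold {threshold:.1f} ms outside tested IFI range "
                f"[{ifis.min():.0f}, {ifis.max():.0f}] ms"
            )
        return PsychometricResults(
            threshold_ms=threshold, slope_per_ms=slope, r_squared=r2,
            ifis=ifis, per_ifi_props=props, n_per_ifi=n,
            params=(float(b0), float(b1)), identifiable=identifiable,
            diagnostics=diagnostics, model=self,
        )


@dataclass
class PsychometricResults:
    """Fitted psychometric curve: threshold, slope, fit quality, raw proportions."""

    threshold_ms: float
    slope_per_ms: float
    r_squared: float
    ifis: np.ndarray
    per_ifi_props: np.ndarray
    n_per_ifi: np.ndarray
    params: tuple[float, float]  # (intercept, slope) on the logit scale
    identifiable: bool
    diagnostics: list[str]
    model: LogisticPsychometric | None = None

    def predict(self, ifi_ms) -> np.ndarray:
        """Fitted P(GM) at the given interframe interval(s)."""
        b0, b1 = self.params
        x = np.asarray(ifi_ms, dtype=float)
        return 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))

    def summary(self) -> str:
        lines = [
            "Logistic psychometric fit (binomial ML)",
            "=" * 42,
            f"threshold (50% point)  {self.threshold_ms:10.2f} ms",
            f"slope                  {self.slope_per_ms:10.4f} /ms",
            f"R^2 (per-IFI props)    {self.r_squared:10.4f}",
            f"identifiable           {str(self.identifiable):>10}",
            "",
            "  IFI(ms)   n    P(GM) obs   P(GM) fit",
        ]
        for x, n, p in zip(self.ifis, self.n_per_ifi, self.per_ifi_props):
            lines.append(f"  {x:7.0f} {n:4d}   {p:9.3f}   {self.predict(x):9.3f}")
        for d in self.diagnostics:
            lines.append(f"note: {d}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid = np.linspace(self.ifis.min(), self.ifis.max(), 200)
        ax.plot(grid, self.predict(grid), "-", label="fit")
        ax.plot(self.ifis, self.per_ifi_props, "o", label="observed")
        if self.identifiable:
            ax.axvline(self.threshold_ms, ls="--", c="gray")
            ax.axhline(0.5, ls=":", c="gray")
        ax.set(xlabel="IFI (ms)", ylabel="P(GM)", ylim=(-0.02, 1.02))
        ax.legend()
        return ax


def fit_logistic(table: pd.DataFrame, condition: str | None = "pretest"
                 ) -> PsychometricResults:
    """Convenience: build and fit :class:`LogisticPsychometric` from a table."""
    return LogisticPsychometric.from_table(table, condition).fit()


# ---------------------------------------------------------------------------
# group summary
# ---------------------------------------------------------------------------

def _paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t with explicit zero-variance handling (t=0/p=1 or t=+-inf/p=0)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    sd = d.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        if np.allclose(d.mean(), 0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class BehaviorSummary:
    per_condition: pd.DataFrame  # condition x (accuracy, choice rate, RT mean, sem)
    tests: dict
    n_subjects: int

    def summary(self) -> str:
        lines = ["Group behavioral summary", "=" * 40,
                 self.per_condition.to_string(), ""]
        if not self.tests:
            lines.append("t-tests suppressed (single subject)")
        for name, (t, p) in self.tests.items():
            lines.append(f"{name:40s} t={t:8.3f}  p={p:.4g}")
        return "\n".join(lines)


def summarize_behavior(table: pd.DataFrame) -> BehaviorSummary:
    """Per-condition accuracies, choice rates and RTs with paired t contrasts.

    Expects a cleaned multi-subject table (``subject`` column). Explicit-trial
    accuracy is judged against the stimulus (short IFI = EM, long = GM);
    bistable rows contribute EM/GM choice rates. With a single subject the
    t-tests are suppressed.
    """
    if "subject" not in table:
        raise ValueError("table needs a 'subject' column")
    subjects = sorted(table["subject"].unique())
    per_subj = {}
    for s in subjects:
        t = table[table["subject"] == s]
        row = {}
        for cond, truth in _EXPLICIT_TRUTH.items():
            sel = t[t["condition"] == cond]
            resp = sel[sel["response"].isin(["EM", "GM"])]
            row[f"acc_{cond}"] = (resp["response"] == truth).mean() if len(resp) else np.nan
            row[f"rt_{cond}"] = resp["rt_ms"].mean() if len(resp) else np.nan
        bi = t[(t["condition"] == "bistable") & t["response"].isin(["EM", "GM"])]
        row["rate_bistable_EM"] = (bi["response"] == "EM").mean() if len(bi) else np.nan
        row["rate_bistable_GM"] = (bi["response"] == "GM").mean() if len(bi) else np.nan
        row["rt_bistable_EM"] = bi.loc[bi["response"] == "EM", "rt_ms"].mean()
        row["rt_bistable_GM"] = bi.loc[bi["response"] == "GM", "rt_ms"].mean()
        per_subj[s] = row
    df = pd.DataFrame(per_subj).T
    agg = pd.DataFrame({"mean": df.mean(), "sem": df.sem()})

    tests = {}
    if len(subjects) >= 2:
        pairs = {
            "accuracy explicit-EM vs explicit-GM": ("acc_explicit-EM", "acc_explicit-GM"),
            "bistable EM vs GM choice rate": ("rate_bistable_EM", "rate_bistable_GM"),
            "RT explicit-EM vs explicit-GM": ("rt_explicit-EM", "rt_explicit-GM"),
            "RT bistable-EM vs bistable-GM": ("rt_bistable_EM", "rt_bistable_GM"),
        }
        for name, (a, b) in pairs.items():
            ok = df[[a, b]].dropna()
            if len(ok) >= 2:
                tests[name] = _paired_t(ok[a].to_numpy(), ok[b].to_numpy())
    return BehaviorSummary(agg, tests, len(subjects))
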