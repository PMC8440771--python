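"""Paired statistical battery for two-condition (manual vs self-driving)
within-subject designs.

Endpoints and their test families:

* SREM counts and PVT lapses — over-dispersed counts, compared with a
  negative-binomial regression adjusted for the within-subject correlation
  (GEE with an exchangeable working correlation and robust errors).
* SREM counts vs habitual sleep duration — per-condition negative-binomial
  regression; the slope log b is the per-hour log rate change.
* Time to first SREM — log-rank test stratified by subject, with censoring
  at (possibly premature) drive end.
* KSS — Wilcoxon signed-rank on paired ratings (ordinal, non-normal).
* PVT mean RT and band synchrony — linear mixed model with a per-subject
  random intercept (REML); on balanced complete data the fixed-effect test
  coincides exactly with the paired t-test.
* Effect sizes — Hedge's g with a multiplicative small-sample bias
  correction and RMS-pooled SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "EffectSizeInput", "CountModelResult", "PairedTestResult",
    "hedges_g_adj", "nb_repeated_condition", "nb_sleep_slope",
    "wilcoxon_signed_rank", "paired_logrank", "mixed_random_intercept",
    "paired_ttest", "sample_size_mean_change",
    "CONDITIONS",
]

#: canonical condition labels; the second is the "treatment" level whose
#: contrast against the first is reported by every model
CONDITIONS = ("manual", "self-driving")


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSizeInput:
    """Condition summary moments for a paired comparison."""

    m1: float
    sd1: float
    m2: float
    sd2: float
    n: int


def hedges_g_adj(inp: EffectSizeInput) -> float:
    """Small-sample-corrected Hedge's g from condition moments.

    ``g = (M1 − M2) / SD_pooled × (N−3)/(N−2.25) × sqrt((N−2)/N)`` with
    ``SD_pooled = sqrt((SD1² + SD2²)/2)`` (root-mean-square of the two
    condition SDs) and ``N`` the number of paired participants.
    """
    if inp.n < 4:
        raise ValueError("correction factor undefined for N < 4")
    if inp.sd1 < 0 or inp.sd2 < 0:
        raise ValueError("SDs must be nonnegative")
    sd_pooled = math.sqrt((inp.sd1 ** 2 + inp.sd2 ** 2) / 2.0)
    if sd_pooled == 0:
        raise ValueError("both condition SDs are zero; g undefined")
    correction = (inp.n - 3) / (inp.n - 2.25) * math.sqrt((inp.n - 2) / inp.n)
    return (inp.m1 - inp.m2) / sd_pooled * correction


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, matching printed-table conventions."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class CountModelResult:
    """Negative-binomial model summary on the log-rate scale."""

    estimate: float          # log rate ratio, or slope log b
    ci_low: float
    ci_high: float
    wald_chi2: float
    p: float
    dispersion_alpha: float  # NB2 alpha: Var = mu + alpha * mu^2
    label: str = ""

    @property
    def rate_ratio(self) -> float:
        return math.exp(self.estimate)


@dataclass
class PairedTestResult:
    """Generic paired-test summary."""

    statistic: float
    p: float
    statistic_name: str
    df: float | None = None
    estimate: float | None = None
    note: str = ""


# ---------------------------------------------------------------------------
# negative-binomial models
# ---------------------------------------------------------------------------

def _estimate_nb_alpha(y: np.ndarray, mu: np.ndarray) -> float:
    """Moment estimate of the NB2 dispersion alpha (Var = mu + alpha mu²)."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu ** 2)
    return float(max(num / den, 1e-8)) if den > 0 else 1e-8


def _prepare_paired_counts(counts: pd.DataFrame) -> pd.DataFrame:
    df = counts.copy()
    required = {"subject", "condition", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts frame needs columns {sorted(required)}")
    unknown = set(df["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    per_subject = df.groupby("subject")["condition"].nunique()
    if (per_subject != 2).any():
        raise ValueError("each subject needs exactly one count per condition")
    df["treat"] = (df["condition"] == CONDITIONS[1]).astype(float)
    return df.sort_values(["subject", "treat"]).reset_index(drop=True)


def nb_repeated_condition(counts: pd.DataFrame) -> CountModelResult:
    """Condition effect on over-dispersed paired counts.

    Fits a negative-binomial regression of count on condition with the
    within-subject correlation handled by generalized estimating equations
    (exchangeable working correlation, robust covariance).  The NB2
    dispersion is fixed at a moment estimate from a preliminary Poisson fit.
    Reports the log rate ratio (self-driving vs manual), a robust Wald
    χ²(1) and its p-value.
    """
    df = _prepare_paired_counts(counts)
    cond_sums = df.groupby("condition")["count"].sum()
    if (cond_sums == 0).any():
        warnings.warn(
            "a condition has all-zero counts; the NB fit may be degenerate"
        )
    X = sm.add_constant(df["treat"].to_numpy())
    y = df["count"].to_numpy(dtype=float)
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    alpha = _estimate_nb_alpha(y, pois.fittedvalues)
    family = sm.families.NegativeBinomial(alpha=alpha)
    model = sm.GEE(y, X, groups=df["subject"].to_numpy(), family=family,
                   cov_struct=sm.cov_struct.Exchangeable())
    with warnings.catch_warnings():
        # a degenerate robust covariance (e.g. identical paired counts)
        # surfaces as sqrt-of-negative noise; handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = model.fit()
        beta, se = res.params[1], res.bse[1]
    if not np.isfinite(se) or se == 0:
        if abs(beta) < 1e-8:   # no effect and no sampling variability
            return CountModelResult(float(beta), 0.0, 0.0, 0.0, 1.0, alpha,
                                    label="condition log rate ratio "
                                          "(degenerate covariance)")
        raise ValueError("robust covariance degenerate; Wald test undefined")
    chi2 = (beta / se) ** 2
    p = float(sps.chi2.sf(chi2, 1))
    z = sps.norm.ppf(0.975)
    return CountModelResult(float(beta), float(beta - z * se),
                            float(beta + z * se), float(chi2), p, alpha,
                            label="condition log rate ratio")


def nb_sleep_slope(counts, sleep_hours) -> CountModelResult:
    """Per-condition NB regression of SREM count on habitual sleep (hours).

    The slope log b is the change in log rate per additional hour of
    habitual sleep; its 95% CI and Wald test come from the NB2 maximum
    likelihood fit.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(sleep_hours, dtype=float)
    if y.shape != x.shape:
        raise ValueError("counts and sleep durations must align")
    if np.ptp(x) == 0:
        raise ValueError("sleep durations are constant; slope undefined")
    if np.ptp(y) == 0:
        raise ValueError("counts have zero variance; slope undefined")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = sm.NegativeBinomial(y, X)
        res = mod.fit(disp=False, maxiter=200)
    beta, se = res.params[1], res.bse[1]
    ci = res.conf_int()
    alpha = float(res.params[-1])
    chi2 = (beta / se) ** 2
    return CountModelResult(float(beta), float(ci[1, 0]), float(ci[1, 1]),
                            float(chi2), float(sps.chi2.sf(chi2, 1)), alpha,
                            label="sleep slope log b")


# ---------------------------------------------------------------------------
# nonparametric and survival comparisons
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(x, y=None) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired values (or on differences).

    Reports V — the sum of the ranks of the positive differences — with an
    exact two-sided p-value for ≤ 25 informative pairs without ties and the
    tie-corrected normal approximation otherwise.  Zero differences are
    dropped.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    if d.size < 5:
        warnings.warn("fewer than 5 informative pairs; p-value is coarse")
    ranks = sps.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       method=method, correction=(method == "approx"))
    return PairedTestResult(v, float(res.pvalue), "V",
                            note=f"method={method}")


def _logrank_terms(times: np.ndarray, events: np.ndarray,
                   in_group1: np.ndarray) -> tuple[float, float]:
    """Observed-minus-expected and hypergeometric variance for group 1."""
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_group1).sum()
        dead = (times == t) & (events == 1)
        d = dead.sum()
        d1 = (dead & in_group1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
    return o_minus_e, var


def paired_logrank(records) -> PairedTestResult:
    """Log-rank test of time-to-first-SREM stratified by subject.

    ``records`` is an iterable of :class:`~sleepdrive.oculomotor.SurvivalRecord`
    (or any object with ``subject``, ``condition``, ``time_s``, ``event``),
    one per drive.  Within-subject correlation is absorbed by stratifying on
    subject; when every stratum is uninformative (zero variance) the test
    falls back to the unstratified statistic with a warning.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no survival records")
    if sum(r.event for r in recs) == 0:
        raise ValueError("no events observed; log-rank undefined")
    subjects = sorted({r.subject for r in recs})
    total_oe = 0.0
    total_var = 0.0
    for subj in subjects:
        sub = [r for r in recs if r.subject == subj]
        times = np.array([r.time_s for r in sub])
        events = np.array([r.event for r in sub])
        grp1 = np.array([r.condition == CONDITIONS[1] for r in sub])
        oe, v = _logrank_terms(times, events, grp1)
        total_oe += oe
        total_var += v
    stratified = True
    if total_var == 0.0:
        warnings.warn(
            "all subject strata uninformative; falling back to the "
            "unstratified log-rank test"
        )
        stratified = False
        times = np.array([r.time_s for r in recs])
        events = np.array([r.event for r in recs])
        grp1 = np.array([r.condition == CONDITIONS[1] for r in recs])
        total_oe, total_var = _logrank_terms(times, events, grp1)
        if total_var == 0.0:
            raise ValueError("log-rank variance is zero; test undefined")
    chi2 = total_oe ** 2 / total_var
    return PairedTestResult(float(chi2), float(sps.chi2.sf(chi2, 1)),
                            "logrank_chi2", df=1,
                            note="stratified" if stratified else "unstratified")


# ---------------------------------------------------------------------------
# mixed / paired mean comparisons
# ---------------------------------------------------------------------------

def paired_ttest(x, y) -> PairedTestResult:
    """Two-sided paired-samples t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equally long samples of size >= 2")
    d = x - y
    if np.ptp(d) == 0:
        raise ValueError("paired differences have zero variance")
    res = sps.ttest_rel(x, y)
    return PairedTestResult(float(res.statistic), float(res.pvalue), "t",
                            df=float(x.size - 1), estimate=float(d.mean()))


def mixed_random_intercept(values: pd.DataFrame) -> PairedTestResult:
    """Condition effect from a random-intercept linear mixed model (REML).

    ``values`` needs columns ``subject``, ``condition``, ``value``.  The
    fixed condition effect b (self-driving minus manual) is tested against
    a t reference with ``n_subjects − 1`` degrees of freedom, which on
    balanced complete data coincides exactly with the paired t-test.  When
    the random-intercept fit is singular or fails, the paired t-test is
    used directly (with a warning).
    """
    df = values.copy()
    required = {"subject", "condition", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"values frame needs columns {sorted(required)}")
    if df["condition"].nunique() != 2:
        raise ValueError("need exactly two conditions")
    df["treat"] = (df["condition"] == CONDITIONS[1]).astype(float)
    n_subjects = df["subject"].nunique()
    if n_subjects < 2:
        raise ValueError("need at least two subjects")

    def _paired_fallback(note: str) -> PairedTestResult:
        warnings.warn(f"mixed model {note}; using the paired t-test")
        wide = df.pivot_table(index="subject", columns="condition",
                              values="value")
        res = paired_ttest(wide[CONDITIONS[1]], wide[CONDITIONS[0]])
        res.note = f"paired-t fallback ({note})"
        return res

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df["value"].to_numpy(),
                               sm.add_constant(df["treat"].to_numpy()),
                               groups=df["subject"].to_numpy())
            fit = model.fit(reml=True)
    except Exception as exc:  # singular / nonconvergent fits
        return _paired_fallback(f"failed ({exc})")
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    bse = np.asarray(fit.bse, dtype=float)
    if not fit.converged or not np.isfinite(bse[1]) or re_var <= 1e-10:
        return _paired_fallback("is singular or did not converge")
    b = float(np.asarray(fit.params, dtype=float)[1])
    se = float(bse[1])
    dof = n_subjects - 1
    t = b / se
    p = 2 * float(sps.t.sf(abs(t), dof))
    return PairedTestResult(t, p, "t", df=float(dof), estimate=b,
                            note="random-intercept REML")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def sample_size_mean_change(delta_ms: float, sd_ms: float,
                            power: float = 0.80,
                            alpha: float = 0.05) -> int:
    """Participants needed to detect a mean change (normal approximation).

    ``n = ceil((z_{1−α/2} + z_power)² σ² / δ²)``.
    """
    if delta_ms <= 0 or sd_ms <= 0:
        raise ValueError("delta and sd must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if power <= alpha / 2:
        raise ValueError("power must exceed alpha/2")
    z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
    return int(math.ceil(z ** 2 * sd_ms ** 2 / delta_ms ** 2))
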