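"""Associations between signature scores, clonal expansion and outcome.

Least-squares regression with a two-sided Wald test and bootstrap CIs for
score-vs-expansion scatter analyses; Kruskal-Wallis group comparisons with
optional Bonferroni correction; Kaplan-Meier estimation and the Mantel-Cox
log-rank test (delegated to lifelines) for median-split survival
stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .io import ClonetrackError


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int
    n: int


def regress(
    x,
    y,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    reference: str = "normal",
) -> RegressionResult:
    """Least-squares fit of y on x with Wald slope test and bootstrap CI.

    The Wald p uses the normal reference by default (``reference='t'``
    switches to the t distribution with n-2 df).  The CI is a percentile
    bootstrap over case resampling of (x, y) pairs; ``n_boot=1`` degenerates
    to the point estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ClonetrackError("regression needs at least 3 finite pairs")
    if np.ptp(x) == 0:
        raise ClonetrackError("zero variance in x")

    def fit(xv, yv):
        slope, intercept = np.polyfit(xv, yv, 1)
        return slope, intercept

    slope, intercept = fit(x, y)
    resid = y - (slope * x + intercept)
    sxx = np.sum((x - x.mean()) ** 2)
    dof = n - 2
    sigma2 = np.sum(resid**2) / max(dof, 1)
    se = np.sqrt(sigma2 / sxx)
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        z = slope / se
        if reference == "t":
            p = float(2 * stats.t.sf(abs(z), dof))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
    r = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    if n_boot <= 1:
        ci_low = ci_high = slope
    else:
        boots = np.empty(n_boot)
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            xv = x[idx]
            if np.ptp(xv) == 0:
                boots[i] = np.nan
                continue
            boots[i], _ = fit(xv, y[idx])
        boots = boots[np.isfinite(boots)]
        lo = (1 - level) / 2
        ci_low, ci_high = np.quantile(boots, [lo, 1 - lo])
    return RegressionResult(
        slope=float(slope), intercept=float(intercept), r=r, p_value=p,
        ci_low=float(min(ci_low, slope)), ci_high=float(max(ci_high, slope)),
        level=level, n_boot=n_boot, seed=seed, n=n,
    )


@dataclass
class EnrichmentComparison:
    groups: list[str]
    statistic: float
    p_value: float
    p_corrected: float
    correction: str | None
    n_per_group: dict[str, int] = field(default_factory=dict)


def compare_groups(
    scores_by_group: dict[str, np.ndarray],
    correction: str | None = None,
    n_comparisons: int | None = None,
) -> EnrichmentComparison:
    """Kruskal-Wallis H test across score distributions.

    ``correction='bonferroni'`` multiplies p by ``n_comparisons`` (the size
    of the family of tests it belongs to), capped at 1.
    """
    if len(scores_by_group) < 2:
        raise ClonetrackError("need at least 2 groups")
    arrays = []
    for name, vals in scores_by_group.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ClonetrackError(f"group {name!r} is empty")
        arrays.append(vals)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        h, p = 0.0, 1.0  # every observation tied: no evidence of a shift
    else:
        h, p = stats.kruskal(*arrays)
    p_corr = p
    if correction == "bonferroni":
        m = n_comparisons if n_comparisons else len(scores_by_group)
        p_corr = min(1.0, p * m)
    elif correction is not None:
        raise ValueError(f"unknown correction: {correction}")
    return EnrichmentComparison(
        groups=list(scores_by_group),
        statistic=float(h),
        p_value=float(p),
        p_corrected=float(p_corr),
        correction=correction,
        n_per_group={k: len(np.asarray(v)) for k, v in scores_by_group.items()},
    )


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate as a step function."""

    event_times: np.ndarray  # distinct times with >=1 observed event
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    censor_times: np.ndarray


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimate; censored subjects leave the risk set after
    their time.  S(0) = 1 and the curve is non-increasing by construction."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ClonetrackError("empty survival input")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    ev = ev[ev.index > 0]
    surv = kmf.survival_function_["KM_estimate"]
    return SurvivalCurve(
        event_times=ev.index.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        n_events=ev["observed"].to_numpy(dtype=float),
        survival=surv.reindex(ev.index).to_numpy(dtype=float),
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sided Mantel-Cox log-rank test; chi-square statistic with 1 df."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ClonetrackError("both groups need at least one subject")
    res = _ll_logrank(times_a, times_b, event_observed_A=np.asarray(events_a),
                      event_observed_B=np.asarray(events_b))
    return float(res.test_statistic), float(res.p_value)


def median_split(scores: pd.Series) -> pd.Series:
    """Label subjects High (score above the median) or Low (at or below).

    Scores exactly at the median go to Low.  Errors if a side would be
    empty (all scores identical).
    """
    scores = pd.Series(scores).astype(float)
    if len(scores) < 2:
        raise ClonetrackError("need at least 2 subjects to split")
    if not np.isfinite(scores).all():
        raise ClonetrackError("non-finite scores")
    med = scores.median()
    labels = pd.Series(np.where(scores > med, "High", "Low"), index=scores.index)
    if labels.nunique() < 2:
        raise ClonetrackError("degenerate split: all scores identical")
    return labels


def logrank_rejection_rate(
    hazard_beta: float,
    n_subjects: int = 100,
    n_replicates: int = 500,
    seed: int = 0,
    censor_rate: float = 0.2,
    alpha: float = 0.05,
) -> float:
    """Fraction of simulated cohorts where the median-split log-rank rejects.

    Each replicate draws standard-normal subject scores, simulates
    exponential survival with log-hazard ``hazard_beta`` per unit score,
    median-splits on the scores and tests High vs Low.  With
    ``hazard_beta=0`` this measures type-I error; with a protective effect
    it measures power.
    """
    from .simulate import SimConfig, gen_survival

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        scores = pd.Series(
            rng.normal(0, 1, n_subjects),
            index=[f"s{j}" for j in range(n_subjects)],
        )
        config = SimConfig(hazard_beta=hazard_beta, censor_rate=censor_rate,
                           seed=int(rng.integers(2**31)))
        table = gen_survival(scores, config, rng)
        labels = median_split(scores)
        grp = labels.reindex(table["subject_id"]).to_numpy()
        hi, lo = table[grp == "High"], table[grp == "Low"]
        _, p = logrank_test(hi["time"], hi["event"], lo["time"], lo["event"])
        rejections += p < alpha
    return rejections / n_replicates


def survival_by_split(table: pd.DataFrame, scores: pd.Series) -> dict:
    """Median-split a cohort on scores and compare survival of the halves."""
    labels = median_split(scores.reindex(table["subject_id"]))
    table = table.assign(group=labels.to_numpy())
    hi = table[table["group"] == "High"]
    lo = table[table["group"] == "Low"]
    chi2, p = logrank_test(hi["time"], hi["event"], lo["time"], lo["event"])
    return {
        "chi2": chi2,
        "p_value": p,
        "n_high": int(len(hi)),
        "n_low": int(len(lo)),
        "curve_high": km_estimate(hi["time"], hi["event"]),
        "curve_low": km_estimate(lo["time"], lo["event"]),
    }
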