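"""Clone expansion/contraction calling and cohort-level dynamics summaries.

The differential-abundance test models a clone's read count in a repertoire
of N reads as beta-binomial with mean f (the clone's latent frequency) and
overdispersion rho(f), where log rho is linear in log f.  The dispersion
curve is fitted on same-timepoint replicate repertoires (e.g. bilateral
tumors excised together), which share a latent frequency per clone, so any
excess variance between them is overdispersion.  A clone's change between
two timepoints is then scored with a likelihood-ratio test against a common
latent frequency, chi-square with 1 df, followed by Benjamini-Hochberg
correction across the subject's testable clones.

Single-cell cohorts without replicate repertoires use a >1.5-fold
cell-count rule instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .clones import CloneKey, CloneSet, clone_day_counts, phenotype_compositions
from .io import ClonetrackError


class InsufficientTrainingError(ClonetrackError):
    """Too few clones in the replicate pairs to fit a dispersion curve."""


# ---------------------------------------------------------------------------
# beta-binomial likelihood

def _bb_loglik(x, n, f, rho, rho_min=1e-8):
    """Beta-binomial log-pmf (without the constant binomial coefficient term
    cancelling in likelihood ratios kept — it is included for exactness).

    Parametrized by mean f and overdispersion rho; rho <= rho_min falls back
    to the binomial limit.  Degenerate means (f=0 or f=1) give a point mass.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    f = np.asarray(f, dtype=float)
    rho = np.asarray(rho, dtype=float)
    x, n, f, rho = np.broadcast_arrays(x, n, f, rho)
    out = np.full(x.shape, -np.inf)

    at_zero = f <= 0
    at_one = f >= 1
    interior = ~(at_zero | at_one)
    out[at_zero & (x == 0)] = 0.0
    out[at_one & (x == n)] = 0.0

    binom_like = interior & (rho <= rho_min)
    if binom_like.any():
        out[binom_like] = stats.binom.logpmf(x[binom_like], n[binom_like], f[binom_like])

    bb = interior & (rho > rho_min)
    if bb.any():
        conc = (1.0 - rho[bb]) / rho[bb]
        a = f[bb] * conc
        b = (1.0 - f[bb]) * conc
        out[bb] = (
            special.gammaln(n[bb] + 1)
            - special.gammaln(x[bb] + 1)
            - special.gammaln(n[bb] - x[bb] + 1)
            + special.betaln(x[bb] + a, n[bb] - x[bb] + b)
            - special.betaln(a, b)
        )
    return out if out.shape else float(out)


@dataclass
class DispersionModel:
    """Fitted overdispersion curve log rho = a + b log f, floored at rho_min.

    ``a`` and ``b`` come from a clone-count-weighted regression of per-bin
    maximum-likelihood rho estimates on bin frequency; the curve is clipped
    to [rho_min, rho_max] so it stays a valid overdispersion on any input.
    """

    a: float
    b: float
    rho_min: float = 1e-8
    rho_max: float = 0.5
    n_pairs: int = 0
    n_clones: int = 0
    freq_range: tuple[float, float] = (0.0, 1.0)
    bin_table: pd.DataFrame | None = None

    def rho(self, f):
        f = np.asarray(f, dtype=float)
        with np.errstate(divide="ignore"):
            r = np.exp(self.a + self.b * np.log(np.maximum(f, 1e-300)))
        r = np.clip(r, self.rho_min, self.rho_max)
        return r if r.shape else float(r)

    @classmethod
    def fixed(cls, rho: float) -> "DispersionModel":
        """Constant-dispersion model (useful for limits and nulls)."""
        rho = max(rho, 1e-300)
        return cls(a=float(np.log(rho)), b=0.0, rho_min=min(rho, 1e-8))


def fit_dispersion(
    replicate_pairs: Sequence[tuple[np.ndarray, int, np.ndarray, int]],
    n_bins: int = 10,
    rho_min: float = 1e-8,
    min_clones_per_bin: int = 20,
    min_clones_total: int = 50,
) -> DispersionModel:
    """Fit rho(f) on same-timepoint replicate repertoire pairs.

    Each pair is ``(x1, N1, x2, N2)``: aligned per-clone counts from two
    repertoires sharing a latent frequency.  Clones are pooled across
    pairs, the pooled frequency estimate f = (x1+x2)/(N1+N2) bins them into
    ``n_bins`` log-spaced bins, a scalar rho maximises the joint
    beta-binomial likelihood within each bin, and the per-bin estimates are
    regressed (log-log, weighted by clone count) to give the curve.
    """
    xs1, ns1, xs2, ns2 = [], [], [], []
    for x1, n1, x2, n2 in replicate_pairs:
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        keep = (x1 + x2) > 0
        xs1.append(x1[keep])
        xs2.append(x2[keep])
        ns1.append(np.full(keep.sum(), float(n1)))
        ns2.append(np.full(keep.sum(), float(n2)))
    if not xs1:
        raise InsufficientTrainingError("no replicate pairs supplied")
    x1 = np.concatenate(xs1)
    x2 = np.concatenate(xs2)
    n1 = np.concatenate(ns1)
    n2 = np.concatenate(ns2)
    if len(x1) < min_clones_total:
        raise InsufficientTrainingError(
            f"only {len(x1)} clones across pairs; need >= {min_clones_total}"
        )
    f_hat = (x1 + x2) / (n1 + n2)

    edges = np.logspace(np.log10(f_hat.min()), np.log10(f_hat.max()), n_bins + 1)
    edges[-1] *= 1 + 1e-9
    which = np.clip(np.digitize(f_hat, edges) - 1, 0, n_bins - 1)

    log_rho_lo, log_rho_hi = np.log(rho_min), np.log(0.5)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() < min_clones_per_bin:
            continue
        xb1, xb2, nb1, nb2, fb = x1[sel], x2[sel], n1[sel], n2[sel], f_hat[sel]

        def nll(log_rho):
            r = np.exp(log_rho)
            return -np.sum(
                _bb_loglik(xb1, nb1, fb, r, rho_min=0.0)
                + _bb_loglik(xb2, nb2, fb, r, rho_min=0.0)
            )

        res = optimize.minimize_scalar(
            nll, bounds=(log_rho_lo, log_rho_hi), method="bounded",
            options={"xatol": 1e-4},
        )
        rho_b = float(np.exp(res.x))
        rows.append({"bin": b, "f_mid": float(np.exp(np.mean(np.log(fb)))),
                     "rho": max(rho_b, rho_min), "n_clones": int(sel.sum())})
    if not rows:
        raise InsufficientTrainingError("no frequency bin had enough clones")
    table = pd.DataFrame(rows)
    logf = np.log(table["f_mid"].to_numpy())
    logr = np.log(table["rho"].to_numpy())
    w = table["n_clones"].to_numpy(dtype=float)
    if len(table) == 1 or np.ptp(logf) < 1e-12:
        a, b_slope = float(np.average(logr, weights=w)), 0.0
    else:
        b_slope, a = np.polyfit(logf, logr, 1, w=np.sqrt(w))
        a, b_slope = float(a), float(b_slope)
    return DispersionModel(
        a=a, b=b_slope, rho_min=rho_min,
        n_pairs=len(replicate_pairs), n_clones=int(len(x1)),
        freq_range=(float(f_hat.min()), float(f_hat.max())),
        bin_table=table,
    )


def test_clone_abundance(x1, n1, x2, n2, model: DispersionModel):
    """Likelihood-ratio test of a change in latent clone frequency.

    Compares the beta-binomial likelihood at free per-sample frequencies
    (x1/N1, x2/N2) against a common frequency (x1+x2)/(N1+N2), with
    rho = model.rho(common frequency); the statistic is chi-square with
    1 df, two-sided.  Clones with x1 = x2 = 0 are untestable (p = nan).
    Accepts scalars or aligned arrays.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1a = np.broadcast_to(np.asarray(n1, dtype=float), x1.shape)
    n2a = np.broadcast_to(np.asarray(n2, dtype=float), x2.shape)
    if np.any(x1 < 0) or np.any(x1 > n1a) or np.any(x2 < 0) or np.any(x2 > n2a):
        raise ValueError("counts must satisfy 0 <= x <= N")
    f1 = np.divide(x1, n1a)
    f2 = np.divide(x2, n2a)
    fc = (x1 + x2) / (n1a + n2a)
    rho = model.rho(fc)
    ll_free = _bb_loglik(x1, n1a, f1, rho, model.rho_min) + _bb_loglik(
        x2, n2a, f2, rho, model.rho_min
    )
    ll_common = _bb_loglik(x1, n1a, fc, rho, model.rho_min) + _bb_loglik(
        x2, n2a, fc, rho, model.rho_min
    )
    lam = np.maximum(2.0 * (ll_free - ll_common), 0.0)
    p = stats.chi2.sf(lam, df=1)
    untestable = (x1 == 0) & (x2 == 0)
    lam = np.where(untestable, np.nan, lam)
    p = np.where(untestable, np.nan, p)
    if lam.shape == ():
        return float(lam), float(p)
    return lam, p


def dynamics_calls(
    cloneset: CloneSet,
    day1: int,
    day2: int,
    model: DispersionModel,
) -> pd.DataFrame:
    """Per-clone test inputs and p-values for a day1 -> day2 comparison.

    Corrected counts are pooled across that day's datasets and rounded
    half-to-even to integers (as are the totals) before testing.  Run
    :func:`classify_dynamics` on the result to add q-values and labels.
    """
    c1 = clone_day_counts(cloneset, day1)
    c2 = clone_day_counts(cloneset, day2)
    x1 = np.round(c1.to_numpy())
    x2 = np.round(c2.to_numpy())
    n1 = float(np.round(c1.sum()))
    n2 = float(np.round(c2.sum()))
    x1 = np.minimum(x1, n1)
    x2 = np.minimum(x2, n2)
    lam, p = test_clone_abundance(x1, n1, x2, n2, model)
    f1 = x1 / n1
    f2 = x2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where((f1 > 0) & (f2 > 0), np.log2(f2 / f1), np.nan)
    return pd.DataFrame(
        {
            "x1": x1.astype(np.int64), "N1": int(n1),
            "x2": x2.astype(np.int64), "N2": int(n2),
            "statistic": lam, "p_value": p, "E": e,
        },
        index=c1.index,
    )


def classify_dynamics(calls: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH-correct p-values across one subject-comparison and label each clone.

    q <= alpha with a higher later frequency means ``expanding``, with a
    lower one ``contracting``; otherwise ``stable``.  Clones without a
    p-value stay ``untestable``.  Labels do not depend on row order.
    """
    out = calls.copy()
    testable = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable.to_numpy()] = multipletests(
            out.loc[testable, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["q_value"] = q
    f1 = out["x1"] / out["N1"]
    f2 = out["x2"] / out["N2"]
    call = np.where(
        ~testable, "untestable",
        np.where((q <= alpha) & (f2 > f1), "expanding",
                 np.where((q <= alpha) & (f2 < f1), "contracting", "stable")),
    )
    out["call"] = call
    return out


def expansion_log2fc(f1: float, f2: float) -> float:
    """Expansion E = log2(f2/f1); defined only for co-detected clones."""
    if f1 <= 0 or f2 <= 0:
        raise ClonetrackError(
            "expansion undefined at zero frequency; use classify_dynamics for detection changes"
        )
    return float(np.log2(f2 / f1))


def composition_velocity(comp_day1: pd.Series, comp_day2: pd.Series) -> tuple[float, float]:
    """Change in (precursor, terminal) fractions between two days."""
    for comp in (comp_day1, comp_day2):
        if comp is None or "precursor" not in comp or "terminal" not in comp:
            raise ClonetrackError("composition missing on one of the days")
    return (
        float(comp_day2["precursor"] - comp_day1["precursor"]),
        float(comp_day2["terminal"] - comp_day1["terminal"]),
    )


def state_count_change(
    freqs: dict[int, float],
    comps: dict[int, pd.Series],
    total_cd8_counts: dict[int, float],
    day1: int,
    day2: int,
) -> tuple[float, float]:
    """Change in absolute precursor/terminal cell numbers for one clone.

    n_state(day) = f_day * frac_state(day) * total CD8 count(day), the
    latter from flow-cytometry bead counts.
    """
    for day in (day1, day2):
        if day not in total_cd8_counts:
            raise ClonetrackError(f"missing total CD8 count for day {day}")
        if day not in freqs or day not in comps:
            raise ClonetrackError(f"missing frequency or composition for day {day}")

    def n_state(day, state):
        return freqs[day] * float(comps[day][state]) * total_cd8_counts[day]

    return (
        n_state(day2, "precursor") - n_state(day1, "precursor"),
        n_state(day2, "terminal") - n_state(day1, "terminal"),
    )


def fold_change_classify(count1: float, count2: float, threshold: float = 1.5) -> str:
    """>threshold-fold rule for cohorts without replicate repertoires.

    Expanding iff count2 > threshold*count1 (strict); contracting
    symmetrically; otherwise stable.  A clone absent at one timepoint is an
    infinite fold change in the direction of its appearance.
    """
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be nonnegative")
    if count1 == 0 and count2 == 0:
        raise ClonetrackError("fold change undefined for a clone absent at both timepoints")
    if count2 > threshold * count1:
        return "expanding"
    if count1 > threshold * count2:
        return "contracting"
    return "stable"


def top_clones(frequencies: pd.Series, n: int) -> list:
    """The n largest clones by frequency; ties broken by lexicographic key."""
    if n <= 0:
        raise ValueError("n must be positive")
    df = frequencies.rename("f").reset_index()
    key_cols = [c for c in df.columns if c != "f"]
    df = df.sort_values(by=["f", *key_cols], ascending=[False] + [True] * len(key_cols),
                        kind="mergesort")
    head = df.head(n)
    if len(key_cols) == 1:
        return head[key_cols[0]].tolist()
    return [tuple(r) for r in head[key_cols].itertuples(index=False, name=None)]


@dataclass
class SubjectDynamics:
    """Three-timepoint inputs for one subject's cohort summary."""

    subject_id: str
    counts: dict[int, pd.Series]  # day -> pooled corrected counts per clone (0-filled)
    calls_first: pd.Series  # clone -> call for the first interval
    calls_second: pd.Series  # clone -> call for the second interval


def cohort_dynamics_summary(
    subjects: Sequence[SubjectDynamics],
    size_bins: tuple[tuple[int, int], ...] = ((1, 10), (11, 30), (31, 100)),
) -> pd.DataFrame:
    """Per-subject dynamics fractions over three timepoints.

    Reports, per subject: the fraction of day-3 clones newly detected there
    (zero corrected reads at both earlier timepoints), the fraction of
    clones expanding in the second interval within ranked-size bins of the
    final-day repertoire, the combined final-day frequency of expanding
    clones, and the fraction of first-interval contracting clones that
    re-expand in the second interval.
    """
    rows = []
    for s in subjects:
        days = sorted(s.counts)
        if len(days) < 3:
            raise ClonetrackError(f"subject {s.subject_id}: need 3 timepoints, got {len(days)}")
        d1, d2, d3 = days[:3]
        c1, c2, c3 = s.counts[d1], s.counts[d2], s.counts[d3]
        present3 = c3[c3 > 0]
        if len(present3) == 0:
            raise ClonetrackError(f"subject {s.subject_id}: no clones detected at final timepoint")
        new = (c1.reindex(present3.index, fill_value=0) == 0) & (
            c2.reindex(present3.index, fill_value=0) == 0
        )
        rec = {
            "subject_id": s.subject_id,
            "frac_newly_detected": float(new.mean()),
        }
        order = present3.sort_values(ascending=False)
        ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
        exp2 = s.calls_second.reindex(present3.index).eq("expanding")
        for lo, hi in size_bins:
            sel = (ranks >= lo) & (ranks <= hi)
            rec[f"frac_expanding_rank{lo}_{hi}"] = (
                float(exp2[sel.index[sel]].mean()) if sel.any() else np.nan
            )
        freqs3 = present3 / present3.sum()
        expanding_clones = s.calls_second[s.calls_second == "expanding"].index
        rec["combined_expanding_freq"] = float(
            freqs3.reindex(expanding_clones, fill_value=0.0).sum()
        )
        contracted = s.calls_first[s.calls_first == "contracting"].index
        if len(contracted):
            rec["reexpansion_fraction"] = float(
                s.calls_second.reindex(contracted).eq("expanding").mean()
            )
        else:
            rec["reexpansion_fraction"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows).set_index("subject_id")
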