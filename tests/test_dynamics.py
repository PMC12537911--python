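import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from clonetrack import (
    DispersionModel,
    classify_dynamics,
    cohort_dynamics_summary,
    composition_velocity,
    expansion_log2fc,
    fit_dispersion,
    fold_change_classify,
    state_count_change,
    test_clone_abundance as clone_abundance_test,
    top_clones,
)
from clonetrack.dynamics import InsufficientTrainingError, SubjectDynamics
from clonetrack.io import ClonetrackError


def replicate_pairs(rho, n_clones=60, n_reads=30_000, n_pairs=4, seed=1, sigma=0.3):
    """Replicate repertoires sharing a latent frequency, with known rho."""
    rng = np.random.default_rng(seed)
    sizes = rng.lognormal(0, sigma, n_clones)
    f = sizes / sizes.sum()
    pairs = []
    for _ in range(n_pairs):
        def draw():
            if rho > 0:
                p = rng.dirichlet(np.maximum(f * (1 - rho) / rho, 1e-12))
            else:
                p = f
            return rng.multinomial(n_reads, p)
        pairs.append((draw(), n_reads, draw(), n_reads))
    return pairs


def binom_lrt_oracle(x1, n1, x2, n2):
    """Direct binomial log-likelihood evaluation of the two-sample LRT."""
    def ll(x, n, f):
        if f <= 0:
            return 0.0 if x == 0 else -np.inf
        if f >= 1:
            return 0.0 if x == n else -np.inf
        return (special.gammaln(n + 1) - special.gammaln(x + 1) - special.gammaln(n - x + 1)
                + x * np.log(f) + (n - x) * np.log(1 - f))

    f1, f2, fc = x1 / n1, x2 / n2, (x1 + x2) / (n1 + n2)
    lam = 2 * (ll(x1, n1, f1) + ll(x2, n2, f2) - ll(x1, n1, fc) - ll(x2, n2, fc))
    return stats.chi2.sf(max(lam, 0.0), 1)


class TestFitDispersion:
    def test_binomial_pairs_fit_to_floor(self):
        model = fit_dispersion(replicate_pairs(0.0), n_bins=3, min_clones_per_bin=30)
        mids = model.bin_table["f_mid"].to_numpy()
        assert np.all(model.rho(mids) <= 1e-3)

    def test_constant_rho_recovered_in_populated_bins(self):
        model = fit_dispersion(replicate_pairs(0.02), n_bins=3, min_clones_per_bin=30)
        best = model.bin_table.sort_values("n_clones").iloc[-1]
        assert 0.01 <= best["rho"] <= 0.04
        assert 0.01 <= model.rho(best["f_mid"]) <= 0.04

    def test_single_clone_insufficient(self):
        with pytest.raises(InsufficientTrainingError):
            fit_dispersion([(np.array([10]), 100, np.array([12]), 100)])

    def test_curve_stays_in_valid_range(self):
        model = fit_dispersion(replicate_pairs(0.02), n_bins=3, min_clones_per_bin=30)
        f = np.logspace(-8, 0, 50)
        r = model.rho(f)
        assert np.all((r > 0) & (r < 1))
        # log-linear in log f: monotone by construction
        assert np.all(np.diff(r) >= 0) or np.all(np.diff(r) <= 0)


class TestAbundanceTest:
    def test_identical_proportions_give_p_one(self):
        model = DispersionModel.fixed(0.01)
        lam, p = clone_abundance_test(10, 1000, 10, 1000, model)
        assert lam == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_binomial_limit_matches_oracle(self):
        model = DispersionModel.fixed(1e-8)
        _, p = clone_abundance_test(0, 1000, 50, 1000, model)
        assert abs(p - binom_lrt_oracle(0, 1000, 50, 1000)) < 1e-6

    def test_binomial_limit_over_small_grid(self):
        """p matches the binomial LRT oracle over all x1, x2 <= 30 at N = 30."""
        model = DispersionModel.fixed(1e-8)
        n = 30
        for x1 in range(n + 1):
            for x2 in range(n + 1):
                if x1 == 0 and x2 == 0:
                    continue
                _, p = clone_abundance_test(x1, n, x2, n, model)
                assert abs(p - binom_lrt_oracle(x1, n, x2, n)) < 1e-6

    def test_swap_symmetry(self):
        model = DispersionModel.fixed(0.005)
        _, p_ab = clone_abundance_test(7, 500, 21, 800, model)
        _, p_ba = clone_abundance_test(21, 800, 7, 500, model)
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_double_zero_untestable(self):
        model = DispersionModel.fixed(0.005)
        lam, p = clone_abundance_test(0, 100, 0, 100, model)
        assert np.isnan(p) and np.isnan(lam)

    def test_invalid_counts_rejected(self):
        model = DispersionModel.fixed(0.005)
        with pytest.raises(ValueError):
            clone_abundance_test(101, 100, 5, 100, model)


class TestClassify:
    def _calls(self, pvals, f2_gt_f1=True):
        n = len(pvals)
        x1 = np.full(n, 10)
        x2 = np.full(n, 30 if f2_gt_f1 else 3)
        return pd.DataFrame({
            "x1": x1, "N1": 1000, "x2": x2, "N2": 1000,
            "statistic": 1.0, "p_value": pvals,
            "E": np.log2(x2 / x1),
        })

    def test_all_p_one_all_stable(self):
        out = classify_dynamics(self._calls([1.0, 1.0, 1.0]))
        assert (out["call"] == "stable").all()

    def test_bh_worked_example(self):
        """Hand-computed BH q-values for p = (0.001, 0.01, 0.04, 0.5)."""
        out = classify_dynamics(self._calls([0.001, 0.01, 0.04, 0.5]), alpha=0.05)
        np.testing.assert_allclose(out["q_value"], [0.004, 0.02, 0.04 * 4 / 3, 0.5], rtol=1e-12)
        assert list(out["call"]) == ["expanding", "expanding", "stable", "stable"]

    def test_order_invariance(self):
        calls = self._calls([0.001, 0.01, 0.04, 0.5])
        fwd = classify_dynamics(calls, alpha=0.05)
        rev = classify_dynamics(calls.iloc[::-1], alpha=0.05)
        assert list(fwd["call"]) == list(rev["call"])[::-1]

    def test_contracting_direction(self):
        out = classify_dynamics(self._calls([0.0001], f2_gt_f1=False), alpha=0.05)
        assert list(out["call"]) == ["contracting"]

    def test_untestable_rows_keep_label(self):
        calls = self._calls([0.01, np.nan])
        out = classify_dynamics(calls)
        assert out["call"].iloc[1] == "untestable"


class TestSimpleMeasures:
    def test_log2fc_values(self):
        assert expansion_log2fc(0.01, 0.04) == pytest.approx(2.0)
        assert expansion_log2fc(0.02, 0.02) == 0.0
        assert expansion_log2fc(0.01, 0.04) == pytest.approx(-expansion_log2fc(0.04, 0.01))
        with pytest.raises(ClonetrackError):
            expansion_log2fc(0.0, 0.1)

    def test_composition_velocity(self):
        c14 = pd.Series({"PD1neg": 0.2, "precursor": 0.6, "intermediate": 0.0, "terminal": 0.2})
        c21 = pd.Series({"PD1neg": 0.1, "precursor": 0.3, "intermediate": 0.0, "terminal": 0.6})
        assert composition_velocity(c14, c21) == pytest.approx((-0.3, 0.4))
        assert composition_velocity(c14, c14) == (0.0, 0.0)
        with pytest.raises(ClonetrackError):
            composition_velocity(c14, None)

    def test_state_count_change_hand_example(self):
        freqs = {14: 0.01, 21: 0.01}
        comps = {
            14: pd.Series({"precursor": 0.5, "terminal": 0.2}),
            21: pd.Series({"precursor": 0.25, "terminal": 0.2}),
        }
        totals = {14: 1e4, 21: 4e4}
        d_pre, d_term = state_count_change(freqs, comps, totals, 14, 21)
        assert d_pre == pytest.approx(50.0)  # 0.01*0.25*4e4 - 0.01*0.5*1e4
        with pytest.raises(ClonetrackError):
            state_count_change(freqs, comps, {14: 1e4}, 14, 21)

    def test_state_counts_linear_in_totals(self):
        freqs = {14: 0.01, 21: 0.01}
        comps = {14: pd.Series({"precursor": 0.5, "terminal": 0.1}),
                 21: pd.Series({"precursor": 0.5, "terminal": 0.1})}
        d1 = state_count_change(freqs, comps, {14: 1e4, 21: 1e4}, 14, 21)
        d2 = state_count_change(freqs, comps, {14: 2e4, 21: 2e4}, 14, 21)
        assert d1 == (0.0, 0.0) and d2 == (0.0, 0.0)


class TestFoldChange:
    @pytest.mark.parametrize("c1,c2,label", [
        (2, 3, "stable"),       # exactly 1.5x: strict inequality
        (2, 4, "expanding"),
        (4, 2, "contracting"),
        (0, 3, "expanding"),    # infinite fold
        (3, 0, "contracting"),
    ])
    def test_rule(self, c1, c2, label):
        assert fold_change_classify(c1, c2) == label

    def test_both_zero_errors(self):
        with pytest.raises(ClonetrackError):
            fold_change_classify(0, 0)


class TestTopClones:
    def test_basic_and_ties(self):
        f = pd.Series({"A": 0.5, "B": 0.3, "C": 0.2})
        assert top_clones(f, 1) == ["A"]
        tied = pd.Series({"B": 0.3, "A": 0.3, "C": 0.4})
        assert top_clones(tied, 2) == ["C", "A"]  # ties broken by key
        assert top_clones(f, 10) == ["A", "B", "C"]
        with pytest.raises(ValueError):
            top_clones(f, 0)


class TestCohortSummary:
    def test_toy_subject_hand_tallies(self):
        counts = {
            14: pd.Series({"a": 10, "b": 5, "c": 0, "d": 0}),
            21: pd.Series({"a": 5, "b": 10, "c": 3, "d": 0}),
            28: pd.Series({"a": 20, "b": 5, "c": 3, "d": 2}),
        }
        calls_first = pd.Series({"a": "contracting", "b": "expanding", "c": "untestable", "d": "untestable"})
        calls_second = pd.Series({"a": "expanding", "b": "contracting", "c": "stable", "d": "expanding"})
        out = cohort_dynamics_summary(
            [SubjectDynamics("m1", counts, calls_first, calls_second)],
            size_bins=((1, 2), (3, 4)),
        )
        row = out.loc["m1"]
        assert row["frac_newly_detected"] == pytest.approx(0.25)  # only d
        # day-28 sizes: a=20 > b=5 > c=3 > d=2; ranks 1-2 = {a, b}: a expanding
        assert row["frac_expanding_rank1_2"] == pytest.approx(0.5)
        assert row["frac_expanding_rank3_4"] == pytest.approx(0.5)  # c stable, d expanding
        assert row["combined_expanding_freq"] == pytest.approx((20 + 2) / 30)
        assert row["reexpansion_fraction"] == pytest.approx(1.0)  # a contracted then expanded

    def test_no_expansion_all_zero(self):
        counts = {1: pd.Series({"a": 1}), 2: pd.Series({"a": 1}), 3: pd.Series({"a": 1})}
        stable = pd.Series({"a": "stable"})
        out = cohort_dynamics_summary([SubjectDynamics("m1", counts, stable, stable)],
                                      size_bins=((1, 1),))
        assert out.loc["m1", "combined_expanding_freq"] == 0.0
        assert out.loc["m1", "frac_expanding_rank1_1"] == 0.0

    def test_newly_detected_partitions(self):
        counts = {
            1: pd.Series({"a": 1, "b": 0}),
            2: pd.Series({"a": 1, "b": 0}),
            3: pd.Series({"a": 1, "b": 1}),
        }
        calls = pd.Series({"a": "stable", "b": "untestable"})
        out = cohort_dynamics_summary([SubjectDynamics("m1", counts, calls, calls)],
                                      size_bins=((1, 2),))
        assert out.loc["m1", "frac_newly_detected"] == pytest.approx(0.5)

    def test_two_timepoints_rejected(self):
        counts = {1: pd.Series({"a": 1}), 2: pd.Series({"a": 1})}
        calls = pd.Series({"a": "stable"})
        with pytest.raises(ClonetrackError):
            cohort_dynamics_summary([SubjectDynamics("m1", counts, calls, calls)])


class TestPowerMonotonicity:
    def test_expanding_call_probability_rises_with_effect(self):
        """At fixed depth, stronger true fold changes are flagged more often."""
        model = DispersionModel.fixed(1e-4)
        rng = np.random.default_rng(17)
        n_reads = 50_000
        f1 = 1e-3
        rates = []
        for log2fc in (0.0, 1.0, 2.0):
            f2 = f1 * 2**log2fc
            x1 = rng.binomial(n_reads, f1, size=300)
            x2 = rng.binomial(n_reads, f2, size=300)
            _, p = clone_abundance_test(x1, n_reads, x2, n_reads, model)
            rates.append(np.nanmean(np.asarray(p) < 0.05))
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.9
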