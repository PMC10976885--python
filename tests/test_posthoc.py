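"""Tests of posterior summaries: MPP/MPPI, permutation FDR, BF/RBF,
effect-size posteriors and attenuation paths."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtbvs.bvs import SamplerConfig, SizePrior, VisitedModelLog, residualize, run_guess
from mtbvs.posthoc import (
    bayes_factor,
    compute_mpp,
    compute_mppi,
    effect_posterior,
    empirical_fdr_threshold,
    mppi_attenuation,
    rbf,
    rbf_table,
)
from conftest import make_regression


def fake_log(counts: dict, p: int = 4, names=None) -> VisitedModelLog:
    total = sum(counts.values())
    names = names or [f"x{j}" for j in range(p)]
    return VisitedModelLog(
        counts=dict(counts),
        log_scores={m: -1.0 * len(m) for m in counts},
        trace_size=np.zeros(total, dtype=np.int32),
        trace_logpost=np.zeros(total),
        n_sweeps=total,
        burn_in=0,
        p=p,
        feature_names=names,
        exchange_acceptance=0.5,
        temperatures=np.array([1.0]),
    )


class TestMpp:
    def test_single_model_has_unit_mpp(self):
        log = fake_log({(0,): 100})
        mpp = compute_mpp(log)
        assert mpp.loc[0, "mpp"] == 1.0

    def test_visit_ratio_arithmetic(self):
        log = fake_log({(0,): 10, (1,): 5, (0, 1): 3, (): 2})
        mpp = compute_mpp(log)
        assert list(mpp["mpp"]) == [0.5, 0.25, 0.15, 0.10]
        assert mpp.loc[1, "cumulative_mpp"] == pytest.approx(0.75)

    def test_mpp_sums_to_one(self):
        log = fake_log({(0,): 7, (1, 2): 13, (3,): 5})
        assert compute_mpp(log)["mpp"].sum() == pytest.approx(1.0)

    def test_tie_break_lexicographic_on_model_string(self):
        log = fake_log({(1,): 5, (0,): 5, (2,): 5}, names=["a", "b", "c"], p=3)
        mpp = compute_mpp(log)
        assert list(mpp["model"]) == ["a", "b", "c"]

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_mpp(fake_log({}))


class TestMppi:
    def test_always_and_never_included(self):
        log = fake_log({(0,): 6, (0, 1): 4})
        mppi = compute_mppi(log)
        assert mppi["x0"] == 1.0
        assert mppi["x2"] == 0.0
        assert mppi["x1"] == pytest.approx(0.4)

    def test_mppi_equals_sum_of_containing_mpps_exactly(self):
        rng = np.random.default_rng(0)
        models = [(0,), (1,), (0, 1), (2,), (), (0, 2)]
        counts = {m: int(c) for m, c in zip(models, rng.integers(1, 50, 6))}
        log = fake_log(counts)
        mpp = compute_mpp(log)
        mppi = compute_mppi(log)
        for j, name in enumerate(log.feature_names):
            manual = mpp.loc[
                [i for i, m in enumerate(mpp["_indices"]) if j in m], "mpp"
            ].sum()
            assert mppi[name] == pytest.approx(manual, abs=1e-15)

    def test_bounds(self):
        log = fake_log({(0, 1, 2): 3, (): 1})
        mppi = compute_mppi(log)
        assert ((mppi >= 0) & (mppi <= 1)).all()


class TestFdrThreshold:
    def test_all_permuted_below_min_observed(self):
        obs = pd.Series([0.4, 0.6, 0.9], index=list("abc"))
        perm = np.full((5, 3), 0.1)
        res = empirical_fdr_threshold(obs, perm, level=0.05)
        assert res.threshold == 0.4
        assert res.significant.all()

    def test_level_one_accepts_min_observed(self):
        obs = pd.Series([0.2, 0.5], index=list("ab"))
        perm = np.array([[0.9, 0.9]])
        res = empirical_fdr_threshold(obs, perm, level=1.0)
        assert res.threshold == 0.2

    def test_no_qualifying_threshold_yields_sentinel(self):
        obs = pd.Series([0.1, 0.2], index=list("ab"))
        perm = np.full((4, 2), 0.95)
        res = empirical_fdr_threshold(obs, perm, level=0.05)
        assert np.isinf(res.threshold) and not res.attained
        assert not res.significant.any()

    def test_zero_permutations_rejected(self):
        obs = pd.Series([0.5], index=["a"])
        with pytest.raises(ValueError, match="permutation"):
            empirical_fdr_threshold(obs, np.empty((0, 1)), level=0.05)


class TestBayesFactorAndRbf:
    def test_posterior_equal_prior_gives_unit_bf(self):
        assert bayes_factor(5 / 33, 5 / 33) == pytest.approx(1.0)

    def test_zero_mppi_gives_zero_bf(self):
        assert bayes_factor(0.0, 0.2) == 0.0

    def test_worked_bf_arithmetic(self):
        # mppi 0.9 against prior odds (5/33)/(28/33)
        assert bayes_factor(0.9, 5 / 33) == pytest.approx(50.4, abs=0.05)

    def test_rbf_unity_at_threshold(self):
        for t in (0.11, 0.5, 0.93):
            assert rbf(t, t, 5 / 33) == 1.0

    def test_worked_rbf_arithmetic(self):
        assert rbf(0.9, 0.5, 5 / 33) == pytest.approx(9.0, abs=0.01)

    def test_rbf_zero_at_zero(self):
        assert rbf(0.0, 0.5, 5 / 33) == 0.0

    def test_rbf_strictly_increasing_in_mppi(self):
        grid = np.linspace(0.01, 0.99, 25)
        vals = [rbf(m, 0.4, 5 / 33) for m in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_sentinel_threshold_uses_max_observed_with_flag(self):
        mppi = pd.Series([0.3, 0.6], index=list("ab"))
        table = rbf_table(mppi, np.inf, 5 / 33)
        assert table.attrs["reference_is_max_observed"]
        assert table.loc["b", "rbf"] == pytest.approx(1.0)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError, match="prior inclusion"):
            bayes_factor(0.5, 1.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        m1=st.floats(0.0, 0.99),
        gap=st.floats(1e-4, 0.5),
        t=st.floats(0.01, 0.99),
        pi0=st.floats(0.01, 0.99),
    )
    def test_rbf_order_preserving_property(self, m1, gap, t, pi0):
        """For any threshold and prior, a larger MPPI never gets a smaller RBF."""
        m2 = min(m1 + gap, 0.999)
        assert rbf(m2, t, pi0) > rbf(m1, t, pi0)

    @settings(derandomize=True, max_examples=50)
    @given(m=st.floats(0.0, 0.999), pi0=st.floats(0.01, 0.99))
    def test_bf_crosses_one_at_prior(self, m, pi0):
        bf = bayes_factor(m, pi0)
        assert bf >= 0
        assert (bf > 1) == (m > pi0) or m == pytest.approx(pi0)


class TestEffectPosterior:
    def test_planted_effect_sign_called_positive(self):
        for seed in range(5):
            Yt, Xt, _ = make_regression(
                941, 5, 2, effects={1: [0.5, 0.5]}, seed=100 + seed
            )
            eff = effect_posterior(Yt, Xt, [1], n_rounds=100, seed=seed)
            rows = eff.quantiles
            assert (rows["sign"] == "+").all(), f"replicate {seed}"

    def test_null_coefficient_centered(self):
        Yt, Xt, _ = make_regression(2_000, 4, 1, seed=3)
        eff = effect_posterior(Yt, Xt, [0], n_rounds=200, seed=0)
        assert abs(eff.quantiles["q50"].iloc[0]) < 0.05

    def test_draw_count_and_quantile_order(self):
        Yt, Xt, _ = make_regression(100, 4, 2, seed=4)
        eff = effect_posterior(Yt, Xt, [0, 2], n_rounds=50, n_sigma=2, n_beta=2, seed=1)
        assert eff.draws.shape == (200, 2, 2)
        q = eff.quantiles
        assert (q["q25"] <= q["q50"]).all() and (q["q50"] <= q["q75"]).all()

    def test_noiseless_limit_concentrates_on_least_squares(self):
        rng = np.random.default_rng(5)
        n = 500
        X = rng.standard_normal((n, 3))
        B = np.array([[0.8], [0.0], [-0.4]])
        Y = X @ B + 1e-6 * rng.standard_normal((n, 1))
        Yc = Y - Y.mean(0)
        Xc = X - X.mean(0)
        ols = np.linalg.lstsq(Xc[:, [0, 2]], Yc, rcond=None)[0]
        eff = effect_posterior(Yc, Xc, [0, 2], n_rounds=50, seed=2)
        assert np.max(np.abs(eff.draws - ols)) < 1e-2

    def test_empty_model_rejected(self):
        Yt, Xt, _ = make_regression(50, 3, 1, seed=6)
        with pytest.raises(ValueError, match="no predictors"):
            effect_posterior(Yt, Xt, [])


class TestAttenuation:
    def test_identical_runs_have_zero_difference(self):
        mppi = pd.Series([0.2, 0.8], index=["a", "b"])
        table = mppi_attenuation({"run1": mppi, "run2": mppi.copy()})
        wide = table.pivot(index="feature", columns="run", values="mppi")
        assert (wide["run1"] == wide["run2"]).all()

    def test_row_count_is_features_times_runs(self):
        mppi = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        table = mppi_attenuation({f"r{i}": mppi for i in range(4)})
        assert len(table) == 12

    def test_mismatched_panels_rejected(self):
        a = pd.Series([0.1], index=["a"])
        b = pd.Series([0.1], index=["b"])
        with pytest.raises(ValueError, match="panel"):
            mppi_attenuation({"r1": a, "r2": b})

    def test_confounded_predictor_attenuates_toward_prior(self):
        """Adjusting for the true confounder removes a spurious inclusion."""
        rng = np.random.default_rng(9)
        n, p = 400, 6
        confounder = rng.standard_normal(n)
        X = rng.standard_normal((n, p))
        X[:, 0] += 1.5 * confounder  # exposure driven by the confounder
        Y = (2.0 * confounder + rng.standard_normal(n)).reshape(-1, 1)
        C0 = np.ones((n, 1))
        C1 = np.column_stack([np.ones(n), confounder])
        cfg = SamplerConfig(n_sweeps=4_000, burn_in=1_000, seed=2)
        runs = {}
        for label, C in (("unadjusted", C0), ("adjusted", C1)):
            Yt, Xt = residualize(Y, X, C)
            log = run_guess(Yt, Xt, SizePrior(), cfg)
            runs[label] = compute_mppi(log)
        table = mppi_attenuation(runs)
        wide = table.pivot(index="feature", columns="run", values="mppi")
        assert wide.loc["x0", "unadjusted"] > 0.9
        assert wide.loc["x0", "adjusted"] < 0.5
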