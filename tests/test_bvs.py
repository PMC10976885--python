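"""Tests of the BVS core: residualization, priors, marginal likelihood,
the evolutionary stochastic search sampler, and the enumeration oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, logsumexp

from mtbvs.bvs import (
    SamplerConfig,
    SizePrior,
    enumerate_posterior,
    log_marginal,
    residualize,
    run_guess,
)
from mtbvs.posthoc import compute_mppi
from conftest import make_regression


class TestResidualize:
    def test_intercept_only_centers_and_scales(self, rng):
        Y = rng.normal(3.0, 2.0, size=(100, 2))
        X = rng.normal(-1.0, 0.5, size=(100, 3))
        C = np.ones((100, 1))
        Yt, Xt = residualize(Y, X, C)
        for M in (Yt, Xt):
            assert np.allclose(M.mean(axis=0), 0, atol=1e-12)
            assert np.allclose(M.std(axis=0), 1, atol=1e-12)

    def test_projection_orthogonal_to_covariates(self, rng):
        n = 200
        C = np.column_stack([np.ones(n), rng.standard_normal((n, 3))])
        X = rng.standard_normal((n, 5)) + C[:, 1:2]
        Y = rng.standard_normal((n, 2))
        Yt, Xt = residualize(Y, X, C)
        for j in range(Xt.shape[1]):
            for l in range(1, C.shape[1]):
                r = np.corrcoef(Xt[:, j], C[:, l])[0, 1]
                assert abs(r) < 1e-8

    def test_collinear_predictor_named(self, rng):
        n = 50
        C = np.column_stack([np.ones(n), rng.standard_normal(n)])
        X = pd.DataFrame({"ok": rng.standard_normal(n), "dup": C[:, 1]})
        Y = rng.standard_normal((n, 1))
        with pytest.raises(ValueError, match="dup"):
            residualize(Y, X, C)

    def test_missing_intercept_rejected(self, rng):
        with pytest.raises(ValueError, match="intercept"):
            residualize(
                rng.standard_normal((20, 1)),
                rng.standard_normal((20, 2)),
                rng.standard_normal((20, 2)),
            )


class TestSizePrior:
    def test_truncation_point(self):
        table = SizePrior(E=5, S=4, F=7).fit(33)
        assert table.T == 33

    def test_per_model_prior_normalizes(self):
        table = SizePrior(E=5, S=4, F=7).fit(33)
        k = np.arange(34)
        log_choose = gammaln(34) - gammaln(k + 1) - gammaln(34 - k)
        total = np.exp(logsumexp(table.log_model_prior + log_choose))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_moment_matching_before_truncation(self):
        table = SizePrior(E=5, S=4, F=7).fit(33)
        mean, sd = table.untruncated_moments()
        assert mean == pytest.approx(5.0, abs=0.01)
        assert sd == pytest.approx(4.0, abs=0.01)

    def test_mass_zero_beyond_truncation(self):
        table = SizePrior(E=2, S=1, F=2).fit(20)
        assert table.T == 4  # E + F*S
        assert np.all(np.isneginf(table.log_model_prior[5:]))
        assert table.size_cdf(table.T) == pytest.approx(1.0)

    def test_binomial_fallback_when_underdispersed(self, caplog):
        with caplog.at_level("WARNING"):
            table = SizePrior(E=5, S=0.5, F=7).fit(33)
        assert "binomial" in caplog.text
        mean, _ = table.untruncated_moments()
        assert mean == pytest.approx(5.0, abs=1e-8)

    def test_out_of_range_size_rejected(self):
        table = SizePrior().fit(10)
        with pytest.raises(ValueError):
            table.log_size_prior(11)


def qr_log_marginal(Y, X, idx, g):
    """Independent route: projector via economy QR of X_gamma."""
    n, q = Y.shape
    c = g / (1 + g)
    if len(idx):
        Q, _ = np.linalg.qr(X[:, list(idx)])
        QtY = Q.T @ Y
        S = Y.T @ Y - c * QtY.T @ QtY
        k = len(idx)
    else:
        S = Y.T @ Y
        k = 0
    return -(q * k / 2) * np.log1p(g) - ((n - 1) / 2) * np.log(np.linalg.det(S))


class TestLogMarginal:
    def test_empty_model_reduces_to_null_determinant(self, small_regression):
        Yt, Xt, _ = small_regression
        n = Yt.shape[0]
        expect = -((n - 1) / 2) * np.log(np.linalg.det(Yt.T @ Yt))
        assert log_marginal(Yt, Xt, []) == pytest.approx(expect)

    def test_invariant_to_predictor_ordering(self, small_regression):
        Yt, Xt, _ = small_regression
        a = log_marginal(Yt, Xt, [0, 2, 4])
        b = log_marginal(Yt, Xt, [4, 0, 2])
        assert a == pytest.approx(b, rel=1e-12)

    def test_exhaustive_posterior_matches_qr_oracle(self, small_regression):
        """All 64 model scores agree with a per-model QR computation."""
        Yt, Xt, _ = small_regression
        n, p = Xt.shape
        g = n
        enum = enumerate_posterior(Yt, Xt, SizePrior())
        table = SizePrior().fit(p)
        oracle = np.array(
            [
                qr_log_marginal(Yt, Xt, m, g) + table.log_model_prior[len(m)]
                for m in enum.models
            ]
        )
        oracle_probs = np.exp(oracle - logsumexp(oracle))
        assert np.max(np.abs(oracle_probs - enum.probabilities)) < 1e-8

    def test_rank_deficiency_raises(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, rng.standard_normal(30), x])  # col 2 == col 0
        Y = rng.standard_normal((30, 1))
        Yt = (Y - Y.mean(0)) / Y.std(0)
        Xt = (X - X.mean(0)) / X.std(0)
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            log_marginal(Yt, Xt, [0, 2])


class TestSampler:
    def test_identical_seed_identical_log(self, small_regression):
        Yt, Xt, _ = small_regression
        cfg = SamplerConfig(n_sweeps=2_000, burn_in=500, seed=11)
        a = run_guess(Yt, Xt, SizePrior(), cfg)
        b = run_guess(Yt, Xt, SizePrior(), cfg)
        assert a.counts == b.counts
        assert np.array_equal(a.trace_logpost, b.trace_logpost)

    def test_visit_counts_conserved(self, small_regression):
        Yt, Xt, _ = small_regression
        cfg = SamplerConfig(n_sweeps=3_000, burn_in=1_000, seed=0)
        log = run_guess(Yt, Xt, SizePrior(), cfg)
        assert sum(log.counts.values()) == log.n_recorded == 2_000
        assert len(log.trace_size) == 3_000

    def test_strong_shared_predictor_has_mppi_near_one(self):
        """A predictor explaining ~90% of two traits is always included."""
        Yt, Xt, _ = make_regression(
            200, 10, 2, effects={3: [3.0, 3.0]}, seed=5
        )
        cfg = SamplerConfig(n_sweeps=5_000, burn_in=1_000, seed=6)
        log = run_guess(Yt, Xt, SizePrior(), cfg)
        mppi = compute_mppi(log)
        assert mppi.iloc[3] > 0.99

    def test_null_mppi_tracks_prior_inclusion(self):
        """Pure-noise data leaves the median MPPI near the marginal prior
        inclusion probability E/p ~ 0.15 in the uninformative-shrinkage
        limit, where the likelihood is flat across models.  (At the default
        unit-information g = n the multivariate Occam factor instead drives
        null MPPIs toward zero; see docs/methods.md.)"""
        Yt, Xt, _ = make_regression(500, 33, 2, seed=7)
        cfg = SamplerConfig(n_sweeps=8_000, burn_in=2_000, seed=8, g=1e-8)
        log = run_guess(Yt, Xt, SizePrior(E=5, S=4, F=7), cfg)
        mppi = compute_mppi(log)
        assert abs(np.median(mppi) - 5 / 33) < 0.1

    def test_tv_to_oracle_decreases_with_sweeps(self, small_regression):
        """Sampler visit frequencies converge to the enumerated posterior."""
        Yt, Xt, _ = small_regression
        enum = enumerate_posterior(Yt, Xt, SizePrior())
        lookup = {m: i for i, m in enumerate(enum.models)}

        def tv(n_sweeps):
            cfg = SamplerConfig(n_sweeps=n_sweeps, burn_in=n_sweeps // 4, seed=9)
            log = run_guess(Yt, Xt, SizePrior(), cfg)
            freq = np.zeros(len(enum.models))
            for m, c in log.counts.items():
                freq[lookup[m]] = c / log.n_recorded
            return 0.5 * np.abs(freq - enum.probabilities).sum()

        assert tv(20_000) < tv(1_000)
        assert tv(20_000) < 0.06

    def test_exchange_acceptance_in_target_band(self, small_regression):
        Yt, Xt, _ = small_regression
        cfg = SamplerConfig(n_sweeps=10_000, burn_in=4_000, seed=10)
        log = run_guess(Yt, Xt, SizePrior(), cfg)
        assert 0.2 <= log.exchange_acceptance <= 0.8

    def test_truncation_never_exceeded(self):
        Yt, Xt, _ = make_regression(80, 12, 1, seed=3)
        prior = SizePrior(E=1, S=0.5, F=2)  # T = 2
        cfg = SamplerConfig(n_sweeps=3_000, burn_in=500, seed=4)
        log = run_guess(Yt, Xt, prior, cfg)
        assert max(len(m) for m in log.counts) <= 2
        assert log.trace_size.max() <= 2


class TestEnumeration:
    def test_single_predictor_two_models(self, rng):
        Y = rng.standard_normal((30, 1))
        X = rng.standard_normal((30, 1))
        Yt, Xt = residualize(Y, X, np.ones((30, 1)))
        enum = enumerate_posterior(Yt, Xt, SizePrior())
        assert len(enum.models) == 2
        assert enum.probabilities.sum() == pytest.approx(1.0)

    def test_large_p_guarded(self, rng):
        Y = rng.standard_normal((30, 1))
        X = rng.standard_normal((30, 16))
        with pytest.raises(ValueError, match="p <= 15"):
            enumerate_posterior(Y, X)

    def test_flat_likelihood_limit_recovers_size_prior(self, rng):
        """With vanishing shrinkage the likelihood is flat across models and
        the posterior size distribution equals the truncated size prior."""
        Y = rng.standard_normal((100, 2))
        X = rng.standard_normal((100, 8))
        Yt, Xt = residualize(Y, X, np.ones((100, 1)))
        prior = SizePrior(E=2, S=1.5, F=2)
        enum = enumerate_posterior(Yt, Xt, prior, g=1e-8)
        table = prior.fit(8)
        size_prior = np.exp(table.log_size_pmf)
        tv = 0.5 * np.abs(enum.size_distribution() - size_prior).sum()
        assert tv < 0.05

    def test_mppi_consistent_with_model_probabilities(self, small_regression):
        Yt, Xt, _ = small_regression
        enum = enumerate_posterior(Yt, Xt, SizePrior())
        p = Xt.shape[1]
        manual = np.zeros(p)
        for m, pr in zip(enum.models, enum.probabilities):
            for j in m:
                manual[j] += pr
        assert np.allclose(manual, enum.mppi)
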