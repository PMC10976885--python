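"""Multitrait Bayesian variable selection core.

Implements the conjugate multivariate-Gaussian marginal likelihood over
inclusion indicators gamma, a moment-matched beta-binomial prior on model
size with truncation, and an evolutionary stochastic search MCMC with
parallel tempering (mutation, crossover and between-chain exchange moves).

Model: Y = X_gamma B + E with rows of E iid N(0, Sigma), a g-prior on the
included coefficients (row covariance g (X'X)^-1, column covariance Sigma)
and a Jeffreys prior on Sigma.  Integrating B and Sigma out gives, up to a
gamma-independent constant,

    log m(Y | gamma) = -(q k / 2) log(1 + g)
                       - ((n - 1)/2) log det(Y'Y - g/(1+g) Y'P_gamma Y)

with P_gamma the orthogonal projector onto span(X_gamma).  The default
shrinkage g = n is the unit-information choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.special import gammaln, logsumexp
from scipy.stats import betabinom, binom

logger = logging.getLogger(__name__)

__all__ = [
    "SizePrior",
    "SizePriorTable",
    "SamplerConfig",
    "VisitedModelLog",
    "residualize",
    "log_marginal",
    "run_guess",
    "enumerate_posterior",
    "PosteriorEnumeration",
]


@dataclass
class SizePrior:
    """Beta-binomial prior on model size, moment-matched and truncated.

    ``E`` and ``S`` are the prior expectation and standard deviation of the
    model size; the prior puts zero mass above ``T = min(p, E + F*S)``.
    """

    E: float = 5.0
    S: float = 4.0
    F: float = 7.0

    def fit(self, p: int) -> "SizePriorTable":
        """Resolve the prior for a panel of ``p`` candidate predictors."""
        T = int(min(p, self.E + self.F * self.S))
        mu = self.E / p
        if mu >= 1:
            logger.warning(
                "prior expected size E=%.3g is at or above p=%d; clamping the "
                "marginal inclusion probability below 1",
                self.E,
                p,
            )
            mu = 1.0 - 1e-9
        binom_var = p * mu * (1 - mu)
        a = b = None
        if self.S**2 <= binom_var:
            logger.warning(
                "prior sd S=%.3g is at or below the binomial sd %.3g; "
                "falling back to a pure binomial size prior",
                self.S,
                np.sqrt(binom_var),
            )
            log_pmf = binom.logpmf(np.arange(p + 1), p, mu)
        else:
            phi = (p - 1) / (self.S**2 / binom_var - 1) - 1
            if phi <= 0:
                logger.warning(
                    "prior sd S=%.3g exceeds the maximal beta-binomial "
                    "dispersion for p=%d; falling back to a pure binomial",
                    self.S,
                    p,
                )
                log_pmf = binom.logpmf(np.arange(p + 1), p, mu)
            else:
                a, b = mu * phi, (1 - mu) * phi
                log_pmf = betabinom.logpmf(np.arange(p + 1), p, a, b)
        return SizePriorTable(
            p=p, T=T, a=a, b=b, E=self.E, S=self.S, F=self.F,
            log_pmf_untruncated=log_pmf,
        )


@dataclass
class SizePriorTable:
    """Size prior resolved for a given panel size ``p``."""

    p: int
    T: int
    a: float | None
    b: float | None
    E: float
    S: float
    F: float
    log_pmf_untruncated: np.ndarray

    def __post_init__(self) -> None:
        k = np.arange(self.p + 1)
        log_pmf = np.where(k <= self.T, self.log_pmf_untruncated, -np.inf)
        log_pmf = log_pmf - logsumexp(log_pmf)
        self.log_size_pmf = log_pmf
        # per-model prior: size prior divided by the number of models of
        # that size
        log_choose = (
            gammaln(self.p + 1) - gammaln(k + 1) - gammaln(self.p - k + 1)
        )
        self.log_model_prior = log_pmf - log_choose

    def log_size_prior(self, k: int) -> float:
        """Log prior probability of any *specific* model of size ``k``."""
        if not 0 <= k <= self.p:
            raise ValueError(f"model size {k} outside [0, {self.p}]")
        return float(self.log_model_prior[k])

    def size_cdf(self, k: int) -> float:
        """P(model size <= k) under the truncated prior."""
        return float(np.exp(logsumexp(self.log_size_pmf[: k + 1])))

    def untruncated_moments(self) -> tuple[float, float]:
        """Mean and sd of the moment-matched distribution before truncation."""
        k = np.arange(self.p + 1)
        pmf = np.exp(self.log_pmf_untruncated)
        mean = float((k * pmf).sum())
        var = float(((k - mean) ** 2 * pmf).sum())
        return mean, np.sqrt(var)


def _as_array(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy(dtype=float), [str(c) for c in m.columns]
    m = np.asarray(m, dtype=float)
    return m, [f"x{j}" for j in range(m.shape[1])]


def residualize(Y, X, C):
    """Project ``Y`` and ``X`` onto the orthogonal complement of span(C),
    then scale every column to unit variance.

    ``C`` must contain an intercept (constant) column.  A predictor whose
    residual variance falls below 1e-10 is collinear with the adjustment
    set and is rejected by name.
    """
    Ya, y_names = _as_array(Y)
    Xa, x_names = _as_array(X)
    Ca, _ = _as_array(C)
    if not (Ya.shape[0] == Xa.shape[0] == Ca.shape[0]):
        raise ValueError("Y, X and C must have the same number of rows")
    col_sd = Ca.std(axis=0)
    if not np.any((col_sd < 1e-12) & (np.abs(Ca).mean(axis=0) > 0)):
        raise ValueError("C must include an intercept (constant) column")

    Q, _ = np.linalg.qr(Ca)
    def _project(M):
        return M - Q @ (Q.T @ M)

    Yr, Xr = _project(Ya), _project(Xa)
    for names, M, label in ((x_names, Xr, "predictor"), (y_names, Yr, "outcome")):
        var = M.var(axis=0)
        bad = np.flatnonzero(var < 1e-10)
        if bad.size:
            raise ValueError(
                f"{label} '{names[bad[0]]}' is collinear with the adjustment "
                "set (post-residualization variance < 1e-10)"
            )
    Yr = Yr / Yr.std(axis=0)
    Xr = Xr / Xr.std(axis=0)
    if isinstance(Y, pd.DataFrame):
        Yr = pd.DataFrame(Yr, index=Y.index, columns=Y.columns)
    if isinstance(X, pd.DataFrame):
        Xr = pd.DataFrame(Xr, index=X.index, columns=X.columns)
    return Yr, Xr


class _MarginalCalculator:
    """Precomputed Gram matrices for fast repeated marginal evaluations."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, g: float):
        self.n, self.q = Y.shape
        self.p = X.shape[1]
        self.g = float(g)
        self.shrink = self.g / (1.0 + self.g)
        self.XtX = X.T @ X
        self.XtY = X.T @ Y
        self.YtY = Y.T @ Y
        sign, logdet = np.linalg.slogdet(self.YtY)
        if sign <= 0:
            raise LinAlgError("Y'Y is not positive definite")
        self._logdet_null = logdet
        self._log1pg = np.log1p(self.g)

    def log_marginal(self, idx: Sequence[int]) -> float:
        """log m(Y | gamma) for the model including columns ``idx``;
        -inf when X_gamma is numerically rank deficient."""
        k = len(idx)
        if k == 0:
            return -((self.n - 1) / 2.0) * self._logdet_null
        idx = list(idx)
        A = self.XtX[np.ix_(idx, idx)]
        B = self.XtY[idx]
        try:
            cf = cho_factor(A, check_finite=False)
        except LinAlgError:
            return -np.inf
        # guard against near-singular Cholesky with tiny positive pivots
        diag = np.diag(cf[0])
        if np.any(diag < 1e-6 * np.sqrt(np.diag(A).max())):
            return -np.inf
        quad = B.T @ cho_solve(cf, B, check_finite=False)
        S = self.YtY - self.shrink * quad
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0 or not np.isfinite(logdet):
            return -np.inf
        return -(self.q * k / 2.0) * self._log1pg - ((self.n - 1) / 2.0) * logdet


def log_marginal(Y, X, gamma, g: float | None = None) -> float:
    """Log marginal likelihood of the model ``gamma`` (boolean mask or index
    sequence), up to a gamma-independent constant.

    Inputs must be residualized/standardized (see :func:`residualize`).
    ``g`` defaults to the sample size (unit-information prior).
    """
    Ya, _ = _as_array(Y)
    Xa, x_names = _as_array(X)
    gamma = np.asarray(gamma)
    if gamma.dtype == bool:
        idx = np.flatnonzero(gamma)
    else:
        idx = gamma.astype(int)
    if g is None:
        g = Ya.shape[0]
    calc = _MarginalCalculator(Ya, Xa, g)
    val = calc.log_marginal(list(idx))
    if not np.isfinite(val) and len(idx):
        raise LinAlgError(
            f"X_gamma is rank deficient or yields a non-finite determinant "
            f"for model {[x_names[j] for j in idx]}"
        )
    return val


@dataclass
class SamplerConfig:
    """Settings of the evolutionary stochastic search sampler."""

    n_sweeps: int = 30_000
    burn_in: int = 10_000
    n_chains: int = 3
    temperature_ratio: float = 1.3
    prob_add: float = 0.45
    prob_delete: float = 0.45
    prob_swap: float = 0.10
    prob_crossover: float = 0.33
    g: float | None = None  # defaults to n
    seed: int = 0
    adapt_interval: int = 100

    def validate(self) -> None:
        if not 0 <= self.burn_in < self.n_sweeps:
            raise ValueError("require 0 <= burn_in < n_sweeps")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.temperature_ratio <= 1:
            raise ValueError("temperature_ratio must exceed 1")
        total = self.prob_add + self.prob_delete + self.prob_swap
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mutation move probabilities must sum to 1")


@dataclass
class VisitedModelLog:
    """Cold-chain, post-burn-in record of visited models.

    ``counts`` maps a sorted tuple of included predictor indices to its
    visit count; ``log_scores`` holds the un-normalized log posterior
    (marginal + prior) of each visited model.
    """

    counts: dict[tuple[int, ...], int]
    log_scores: dict[tuple[int, ...], float]
    trace_size: np.ndarray
    trace_logpost: np.ndarray
    n_sweeps: int
    burn_in: int
    p: int
    feature_names: list[str]
    exchange_acceptance: float
    temperatures: np.ndarray

    @property
    def n_recorded(self) -> int:
        return self.n_sweeps - self.burn_in

    def model_names(self, model: tuple[int, ...]) -> str:
        return "+".join(self.feature_names[j] for j in model) or "(empty)"

    def to_tsv(self, models_path: str | Path, trace_path: str | Path | None = None):
        rows = [
            {
                "model": self.model_names(m),
                "size": len(m),
                "count": c,
                "log_score": self.log_scores[m],
            }
            for m, c in sorted(self.counts.items(), key=lambda kv: -kv[1])
        ]
        pd.DataFrame(rows).to_csv(models_path, sep="\t", index=False)
        if trace_path is not None:
            pd.DataFrame(
                {"sweep": np.arange(self.n_sweeps), "size": self.trace_size,
                 "log_posterior": self.trace_logpost}
            ).to_csv(trace_path, sep="\t", index=False)


def _bits(mask: int, p: int) -> tuple[int, ...]:
    return tuple(j for j in range(p) if (mask >> j) & 1)


def run_guess(
    Y,
    X,
    prior: SizePrior | SizePriorTable | None = None,
    config: SamplerConfig | None = None,
) -> VisitedModelLog:
    """Evolutionary stochastic search over inclusion indicators.

    Per sweep, every chain attempts one mutation (add/delete with
    probability 0.45 each, swap 0.10) accepted by Metropolis-Hastings at
    the chain's temperature; with probability ``prob_crossover`` one uniform
    crossover between two random chains is attempted (accepted jointly);
    and one state exchange between an adjacent-temperature pair is
    attempted.  The geometric temperature ladder is adapted during burn-in
    toward a 0.5 exchange acceptance rate and then frozen.  Cold-chain
    states after burn-in are recorded.  Identical seeds give identical logs.
    """
    config = config or SamplerConfig()
    config.validate()
    Ya, _ = _as_array(Y)
    Xa, x_names = _as_array(X)
    n, p = Xa.shape
    g = config.g if config.g is not None else n
    calc = _MarginalCalculator(Ya, Xa, g)
    if prior is None:
        prior = SizePrior()
    table = prior if isinstance(prior, SizePriorTable) else prior.fit(p)
    log_model_prior = table.log_model_prior
    T = table.T

    rng = np.random.default_rng(config.seed)
    n_chains = config.n_chains
    ratio = config.temperature_ratio
    betas = ratio ** -np.arange(n_chains, dtype=float)

    cache: dict[int, float] = {}

    def score(mask: int) -> float:
        s = cache.get(mask)
        if s is None:
            idx = _bits(mask, p)
            k = len(idx)
            if k > T:
                s = -np.inf
            else:
                lm = calc.log_marginal(idx)
                s = lm + log_model_prior[k] if np.isfinite(lm) else -np.inf
            cache[mask] = s
        return s

    masks = [0] * n_chains
    scores = [score(0)] * n_chains
    sizes = [0] * n_chains

    counts: dict[int, int] = {}
    trace_size = np.zeros(config.n_sweeps, dtype=np.int32)
    trace_logpost = np.zeros(config.n_sweeps)

    exch_att = exch_acc = 0
    exch_att_b = exch_acc_b = 0
    win_att = win_acc = 0
    p_add, p_del = config.prob_add, config.prob_add + config.prob_delete

    for sweep in range(config.n_sweeps):
        in_burn = sweep < config.burn_in
        for c in range(n_chains):
            mask, k = masks[c], sizes[c]
            r = rng.random()
            new_mask = -1
            logq = 0.0
            if r < p_add:
                if k < p:
                    free = p - k
                    # pick the (t+1)-th excluded bit
                    t = int(rng.integers(free))
                    j = 0
                    seen = -1
                    for j in range(p):
                        if not (mask >> j) & 1:
                            seen += 1
                            if seen == t:
                                break
                    new_mask = mask | (1 << j)
                    logq = np.log(config.prob_delete / (k + 1)) - np.log(
                        config.prob_add / free
                    )
            elif r < p_del:
                if k > 0:
                    t = int(rng.integers(k))
                    seen = -1
                    for j in range(p):
                        if (mask >> j) & 1:
                            seen += 1
                            if seen == t:
                                break
                    new_mask = mask & ~(1 << j)
                    logq = np.log(config.prob_add / (p - k + 1)) - np.log(
                        config.prob_delete / k
                    )
            else:
                if 0 < k < p:
                    t_in = int(rng.integers(k))
                    t_out = int(rng.integers(p - k))
                    seen_in = seen_out = -1
                    j_in = j_out = 0
                    for j in range(p):
                        if (mask >> j) & 1:
                            seen_in += 1
                            if seen_in == t_in:
                                j_in = j
                        else:
                            seen_out += 1
                            if seen_out == t_out:
                                j_out = j
                    new_mask = (mask & ~(1 << j_in)) | (1 << j_out)
                    logq = 0.0
            if new_mask >= 0:
                s_new = score(new_mask)
                delta = betas[c] * (s_new - scores[c]) + logq
                if delta >= 0 or np.log(rng.random()) < delta:
                    masks[c] = new_mask
                    scores[c] = s_new
                    sizes[c] = bin(new_mask).count("1")

        if n_chains > 1 and rng.random() < config.prob_crossover:
            i, j = rng.choice(n_chains, size=2, replace=False)
            m = int(rng.integers(1 << p)) if p < 63 else int.from_bytes(
                rng.bytes(8), "little"
            ) & ((1 << p) - 1)
            c1 = (masks[i] & m) | (masks[j] & ~m)
            c2 = (masks[j] & m) | (masks[i] & ~m)
            s1, s2 = score(c1), score(c2)
            delta = betas[i] * (s1 - scores[i]) + betas[j] * (s2 - scores[j])
            if delta >= 0 or np.log(rng.random()) < delta:
                masks[i], masks[j] = c1, c2
                scores[i], scores[j] = s1, s2
                sizes[i] = bin(c1).count("1")
                sizes[j] = bin(c2).count("1")

        if n_chains > 1:
            c = int(rng.integers(n_chains - 1))
            exch_att += 1
            win_att += 1
            delta = (betas[c] - betas[c + 1]) * (scores[c + 1] - scores[c])
            if delta >= 0 or np.log(rng.random()) < delta:
                masks[c], masks[c + 1] = masks[c + 1], masks[c]
                scores[c], scores[c + 1] = scores[c + 1], scores[c]
                sizes[c], sizes[c + 1] = sizes[c + 1], sizes[c]
                exch_acc += 1
                win_acc += 1

        # adapt the geometric ladder toward 0.5 exchange acceptance
        if (
            in_burn
            and n_chains > 1
            and (sweep + 1) % config.adapt_interval == 0
            and win_att > 0
        ):
            rate = win_acc / win_att
            ratio = float(np.clip(ratio * np.exp(0.5 * (rate - 0.5)), 1.01, 4.0))
            betas = ratio ** -np.arange(n_chains, dtype=float)
            win_att = win_acc = 0

        trace_size[sweep] = sizes[0]
        trace_logpost[sweep] = scores[0]
        if not in_burn:
            if sweep == config.burn_in:
                exch_att_b, exch_acc_b = exch_att, exch_acc
            counts[masks[0]] = counts.get(masks[0], 0) + 1

    model_counts = {_bits(m, p): c for m, c in counts.items()}
    log_scores = {_bits(m, p): cache[m] for m in counts}
    return VisitedModelLog(
        counts=model_counts,
        log_scores=log_scores,
        trace_size=trace_size,
        trace_logpost=trace_logpost,
        n_sweeps=config.n_sweeps,
        burn_in=config.burn_in,
        p=p,
        feature_names=x_names,
        exchange_acceptance=(
            (exch_acc - exch_acc_b) / (exch_att - exch_att_b)
            if exch_att > exch_att_b
            else float("nan")
        ),
        temperatures=1.0 / betas,
    )


@dataclass
class PosteriorEnumeration:
    """Exact posterior over all 2^p models (testing oracle)."""

    models: list[tuple[int, ...]]
    log_post: np.ndarray
    probabilities: np.ndarray
    mppi: np.ndarray
    feature_names: list[str]

    def probability_of(self, model: Sequence[int]) -> float:
        key = tuple(sorted(model))
        return float(self.probabilities[self.models.index(key)])

    def size_distribution(self) -> np.ndarray:
        p = len(self.feature_names)
        out = np.zeros(p + 1)
        for m, pr in zip(self.models, self.probabilities):
            out[len(m)] += pr
        return out


def enumerate_posterior(
    Y, X, prior: SizePrior | SizePriorTable | None = None, g: float | None = None
) -> PosteriorEnumeration:
    """Exhaustive posterior over all models; requires p <= 15."""
    Ya, _ = _as_array(Y)
    Xa, x_names = _as_array(X)
    p = Xa.shape[1]
    if p > 15:
        raise ValueError(f"exhaustive enumeration limited to p <= 15, got p={p}")
    if g is None:
        g = Ya.shape[0]
    calc = _MarginalCalculator(Ya, Xa, g)
    if prior is None:
        prior = SizePrior()
    table = prior if isinstance(prior, SizePriorTable) else prior.fit(p)

    models: list[tuple[int, ...]] = []
    log_post = []
    for k in range(min(p, table.T) + 1):
        for idx in combinations(range(p), k):
            lm = calc.log_marginal(list(idx))
            models.append(idx)
            log_post.append(lm + table.log_model_prior[k])
    log_post = np.asarray(log_post)
    probs = np.exp(log_post - logsumexp(log_post))
    probs = probs / probs.sum()
    mppi = np.zeros(p)
    for m, pr in zip(models, probs):
        for j in m:
            mppi[j] += pr
    return PosteriorEnumeration(
        models=models,
        log_post=log_post,
        probabilities=probs,
        mppi=mppi,
        feature_names=x_names,
    )
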