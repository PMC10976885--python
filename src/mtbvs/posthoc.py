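"""Posterior summaries and decision rules from the sampler output.

Model posterior probabilities (MPP) are visit frequencies of the cold chain
after burn-in; marginal posterior probabilities of inclusion (MPPI) are the
per-feature sums of MPP over containing models.  Feature significance is
decided by an MPPI threshold calibrated to control the empirical false
discovery rate via permutation reruns of the sampler, and feature strength
is reported as a Bayes factor (BF) and its ratio to the BF at the threshold
(RBF; RBF >= 1 flags informative features).  Effect-size posteriors are
simulated from the conjugate posterior conditional on a chosen model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import invwishart

from .bvs import (
    SamplerConfig,
    SizePrior,
    SizePriorTable,
    VisitedModelLog,
    _as_array,
    run_guess,
)

__all__ = [
    "compute_mpp",
    "compute_mppi",
    "FdrResult",
    "empirical_fdr_threshold",
    "permutation_mppis",
    "bayes_factor",
    "rbf",
    "rbf_table",
    "EffectPosterior",
    "effect_posterior",
    "mppi_attenuation",
]


def compute_mpp(log: VisitedModelLog) -> pd.DataFrame:
    """Per-model MPP with best-models-visited (BMV) ranking.

    MPP(model) = visits / (n_sweeps - burn_in).  Ranking is by descending
    MPP with lexicographic tie-break on the model's predictor-name string.
    """
    if not log.counts:
        raise ValueError("visited-model log is empty")
    total = log.n_recorded
    rows = [
        {
            "model": log.model_names(m),
            "size": len(m),
            "visits": c,
            "mpp": c / total,
            "log_score": log.log_scores[m],
            "_indices": m,
        }
        for m, c in log.counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["mpp", "model"], ascending=[False, True], kind="mergesort"
    )
    df["cumulative_mpp"] = df["mpp"].cumsum()
    return df.reset_index(drop=True)


def compute_mppi(log: VisitedModelLog) -> pd.Series:
    """Per-feature MPPI: sum of MPP over models containing the feature."""
    if not log.counts:
        raise ValueError("visited-model log is empty")
    total = log.n_recorded
    acc = np.zeros(log.p)
    for model, c in log.counts.items():
        for j in model:
            acc[j] += c
    return pd.Series(acc / total, index=log.feature_names, name="mppi")


@dataclass
class FdrResult:
    """Empirical-FDR threshold on the MPPI scale."""

    level: float
    n_permutations: int
    threshold: float  # np.inf when no observed MPPI qualifies
    attained: bool
    significant: pd.Series  # boolean per feature
    fdr_at_threshold: float
    permuted_mppis: np.ndarray  # pooled, one row per permutation run

    @property
    def significant_features(self) -> list[str]:
        return list(self.significant.index[self.significant])


def empirical_fdr_threshold(
    observed_mppi: pd.Series,
    permutation_runs: list[np.ndarray] | np.ndarray,
    level: float = 0.05,
) -> FdrResult:
    """Choose the smallest observed MPPI whose estimated FDR is <= level.

    FDR(t) = [mean over permutation runs of #{j: MPPI_perm,j >= t}]
             / max(1, #{j: MPPI_obs,j >= t}).

    Permutation runs must come from full sampler reruns on outcome-row
    permutations (see :func:`permutation_mppis`).  If no observed value
    qualifies, the significant set is empty and the threshold is the
    sentinel ``inf``.
    """
    perm = np.atleast_2d(np.asarray(permutation_runs, dtype=float))
    if perm.size == 0 or perm.shape[0] == 0:
        raise ValueError("at least one permutation run is required")
    obs = observed_mppi.to_numpy(dtype=float)

    threshold = np.inf
    fdr_at = np.nan
    attained = False
    for t in np.sort(np.unique(obs)):
        n_obs = int((obs >= t).sum())
        n_perm = float((perm >= t).sum(axis=1).mean())
        fdr = n_perm / max(1, n_obs)
        if fdr <= level:
            threshold, fdr_at, attained = float(t), float(fdr), True
            break
    significant = pd.Series(obs >= threshold, index=observed_mppi.index)
    return FdrResult(
        level=level,
        n_permutations=perm.shape[0],
        threshold=threshold,
        attained=attained,
        significant=significant,
        fdr_at_threshold=fdr_at,
        permuted_mppis=perm,
    )


def permutation_mppis(
    Y,
    X,
    prior: SizePrior | SizePriorTable | None,
    config: SamplerConfig,
    n_permutations: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Rerun the sampler on row-permuted outcomes.

    Rows of the (residualized) outcome block are permuted jointly across
    traits, preserving the trait-trait correlation under the null, with the
    predictor block fixed.  Returns an (n_permutations, p) MPPI array.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Ya, _ = _as_array(Y)
    rng = np.random.default_rng(seed)
    out = []
    for b in range(n_permutations):
        perm = rng.permutation(Ya.shape[0])
        cfg_b = SamplerConfig(
            **{**config.__dict__, "seed": int(rng.integers(2**31 - 1))}
        )
        log = run_guess(Ya[perm], X, prior, cfg_b)
        out.append(compute_mppi(log).to_numpy())
    return np.asarray(out)


def bayes_factor(
    mppi: float, pi0: float, n_recorded: int | None = None
) -> float:
    """Bayes factor for one feature as a function of its MPPI.

    BF = posterior inclusion odds / prior inclusion odds, with ``pi0`` the
    marginal prior inclusion probability (E/p under the size prior).  An
    MPPI of exactly 1 is capped at 1 - 1/n_recorded when the number of
    post-burn-in sweeps is supplied (the resolution of the MPPI estimate).
    """
    if not 0 < pi0 < 1:
        raise ValueError(f"prior inclusion probability must be in (0, 1), got {pi0}")
    if not 0 <= mppi <= 1:
        raise ValueError(f"mppi must be in [0, 1], got {mppi}")
    if n_recorded:
        mppi = min(mppi, 1.0 - 1.0 / n_recorded)
    prior_odds = pi0 / (1 - pi0)
    if mppi >= 1.0:
        return np.inf
    posterior_odds = mppi / (1 - mppi)
    return posterior_odds / prior_odds


def rbf(
    mppi: float,
    t_star: float,
    pi0: float,
    n_recorded: int | None = None,
    max_observed: float | None = None,
) -> float:
    """Ratio of Bayes factors: BF(mppi) / BF at the FDR threshold.

    Equals 1 exactly when mppi == t_star; RBF >= 1 marks features at least
    as informative as one sitting on the significance boundary.  When the
    threshold is the sentinel ``inf`` (no feature reached significance), the
    reference is the maximum observed MPPI and the result is flagged by the
    caller (see :func:`rbf_table`).
    """
    if np.isinf(t_star):
        if max_observed is None:
            raise ValueError(
                "threshold is the 'above max' sentinel; supply max_observed"
            )
        if max_observed <= 0:
            # nothing was ever selected: no reference feature exists
            return float("nan")
        t_star = max_observed
    if not 0 < t_star <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {t_star}")
    denom = bayes_factor(t_star, pi0, n_recorded)
    return bayes_factor(mppi, pi0, n_recorded) / denom


def rbf_table(
    mppi: pd.Series,
    t_star: float,
    pi0: float,
    n_recorded: int | None = None,
) -> pd.DataFrame:
    """Per-feature MPPI, BF and RBF table."""
    reference_is_max = bool(np.isinf(t_star))
    max_obs = float(mppi.max())
    rows = {
        "mppi": mppi,
        "bf": mppi.map(lambda m: bayes_factor(m, pi0, n_recorded)),
        "rbf": mppi.map(
            lambda m: rbf(m, t_star, pi0, n_recorded, max_observed=max_obs)
        ),
    }
    out = pd.DataFrame(rows)
    out["informative"] = out["rbf"] >= 1
    out.attrs["pi0"] = pi0
    out.attrs["threshold"] = t_star
    out.attrs["reference_is_max_observed"] = reference_is_max
    return out


@dataclass
class EffectPosterior:
    """Posterior draws of regression coefficients conditional on a model."""

    model: tuple[int, ...]
    draws: np.ndarray  # (n_draws, k, q)
    quantiles: pd.DataFrame  # rows (predictor, trait); q25/q50/q75 + sign
    predictor_names: list[str]
    trait_names: list[str]


def effect_posterior(
    Y,
    X,
    gamma,
    n_rounds: int = 500,
    n_sigma: int = 2,
    n_beta: int = 2,
    g: float | None = None,
    seed: int = 0,
) -> EffectPosterior:
    """Simulate the effect-size posterior for the predictors in ``gamma``.

    Each round draws ``n_sigma`` residual covariances from the conjugate
    inverse-Wishart posterior and, per covariance, ``n_beta`` coefficient
    matrices from the matching matrix-Gaussian, for
    ``n_rounds * n_sigma * n_beta`` draws per coefficient.  The sign of an
    effect is called when the 25th-75th percentile interval excludes zero.
    """
    Ya, y_names = _as_array(Y)
    Xa, x_names = _as_array(X)
    gamma = np.asarray(gamma)
    idx = list(np.flatnonzero(gamma)) if gamma.dtype == bool else [int(j) for j in gamma]
    if not idx:
        raise ValueError("gamma selects no predictors")
    n, q = Ya.shape
    k = len(idx)
    if g is None:
        g = n
    shrink = g / (1.0 + g)

    Xg = Xa[:, idx]
    A = Xg.T @ Xg
    try:
        cf = cho_factor(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("X_gamma is singular") from exc
    try:
        B_hat = cho_solve(cf, Xg.T @ Ya)
    except ValueError as exc:
        raise np.linalg.LinAlgError("X_gamma is singular") from exc
    S = Ya.T @ Ya - shrink * (Xg.T @ Ya).T @ B_hat
    S = (S + S.T) / 2
    post_mean = shrink * B_hat
    Ainv = cho_solve(cf, np.eye(k))
    row_cov = shrink * Ainv
    row_chol = cholesky((row_cov + row_cov.T) / 2, lower=True)
    df = n - 1

    rng = np.random.default_rng(seed)
    draws = np.empty((n_rounds * n_sigma * n_beta, k, q))
    pos = 0
    for _ in range(n_rounds):
        sigmas = invwishart.rvs(df=df, scale=S, size=n_sigma, random_state=rng)
        sigmas = np.atleast_3d(sigmas).reshape(n_sigma, q, q)
        for s in range(n_sigma):
            col_chol = cholesky((sigmas[s] + sigmas[s].T) / 2, lower=True)
            for _ in range(n_beta):
                Z = rng.standard_normal((k, q))
                draws[pos] = post_mean + row_chol @ Z @ col_chol.T
                pos += 1

    q25 = np.percentile(draws, 25, axis=0)
    q50 = np.percentile(draws, 50, axis=0)
    q75 = np.percentile(draws, 75, axis=0)
    records = []
    for a, j in enumerate(idx):
        for b in range(q):
            lo, mid, hi = q25[a, b], q50[a, b], q75[a, b]
            sign = "+" if lo > 0 else ("-" if hi < 0 else "0")
            records.append(
                {
                    "predictor": x_names[j],
                    "trait": y_names[b],
                    "q25": lo,
                    "q50": mid,
                    "q75": hi,
                    "sign": sign,
                }
            )
    return EffectPosterior(
        model=tuple(sorted(idx)),
        draws=draws,
        quantiles=pd.DataFrame(records),
        predictor_names=[x_names[j] for j in idx],
        trait_names=list(y_names),
    )


def mppi_attenuation(runs: dict[str, pd.Series]) -> pd.DataFrame:
    """Long table of per-feature MPPI across covariate-adjustment ladders.

    ``runs`` maps a run label (e.g. 'unadjusted', '+age+sex') to the MPPI
    series of that run; all runs must share the predictor panel.
    """
    if not runs:
        raise ValueError("no runs supplied")
    labels = list(runs)
    panel = list(runs[labels[0]].index)
    for lab in labels[1:]:
        if list(runs[lab].index) != panel:
            raise ValueError(
                f"run '{lab}' has a different predictor panel than '{labels[0]}'"
            )
    rows = [
        {"feature": feat, "run": lab, "mppi": float(runs[lab][feat])}
        for lab in labels
        for feat in panel
    ]
    return pd.DataFrame(rows)
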