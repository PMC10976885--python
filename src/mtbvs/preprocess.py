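"""Cohort preprocessing: exclusions, LOD and missing-data imputation,
log10 transform, diet PCA and descriptive summaries.

Conventions for the raw cohort table (cohort.csv): exposure concentration
columns code a non-detect (below the limit of detection) as ``0`` and a
technically missing measurement as an empty cell.  All other columns use
empty cells for missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import DIET_COLUMNS, DEFAULT_TRAITS

logger = logging.getLogger(__name__)

__all__ = [
    "RawCohort",
    "ExclusionLog",
    "DietScores",
    "AnalysisData",
    "read_cohort",
    "filter_cohort",
    "impute_below_lod",
    "impute_exposures_below_lod",
    "impute_missing",
    "log10_exposures",
    "diet_pca",
    "summarize_cohort",
    "covariate_design",
    "prepare_analysis",
]

COVARIATE_COLUMNS = ["age", "gender", "education", "smoking"]


@dataclass
class RawCohort:
    """A raw participant-level table plus the per-compound LOD lookup."""

    table: pd.DataFrame
    lod: pd.Series
    exposure_cols: list[str]
    trait_cols: list[str]
    diet_cols: list[str] = field(default_factory=lambda: list(DIET_COLUMNS))
    covariate_cols: list[str] = field(default_factory=lambda: list(COVARIATE_COLUMNS))


def read_cohort(cohort_csv: str | Path, lod_csv: str | Path) -> RawCohort:
    """Read cohort.csv and lod.csv, validating the column schema."""
    table = pd.read_csv(cohort_csv)
    lod_df = pd.read_csv(lod_csv)
    if not {"compound", "lod_pg_per_mg"} <= set(lod_df.columns):
        raise ValueError("lod.csv must have columns 'compound' and 'lod_pg_per_mg'")
    lod = lod_df.set_index("compound")["lod_pg_per_mg"]
    missing_cols = [c for c in lod.index if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks exposure columns: {missing_cols}")
    for col in COVARIATE_COLUMNS + DIET_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column '{col}'")
    trait_cols = [t for t in DEFAULT_TRAITS if t in table.columns]
    return RawCohort(
        table=table,
        lod=lod,
        exposure_cols=list(lod.index),
        trait_cols=trait_cols,
    )


@dataclass
class ExclusionLog:
    """Ordered record of cohort exclusion rules and their counts."""

    initial: int
    steps: list[tuple[str, int]]
    retained: int

    def __post_init__(self) -> None:
        excluded = sum(n for _, n in self.steps)
        if any(n < 0 for _, n in self.steps) or self.retained < 0:
            raise ValueError("exclusion counts must be non-negative")
        if self.retained != self.initial - excluded:
            raise ValueError(
                f"retained ({self.retained}) != initial ({self.initial}) - "
                f"excluded ({excluded})"
            )

    def to_dict(self) -> dict:
        return {
            "initial": self.initial,
            "steps": [{"rule": r, "excluded": n} for r, n in self.steps],
            "retained": self.retained,
        }


def _rule_missing_exposures(raw: RawCohort) -> pd.Series:
    # participants with no valid exposure panel at all; a coded non-detect
    # (0) still counts as a measurement
    return raw.table[raw.exposure_cols].isna().all(axis=1)


def _rule_diet_missing(raw: RawCohort, threshold: float = 0.5) -> pd.Series:
    frac = raw.table[raw.diet_cols].isna().mean(axis=1)
    return frac >= threshold


EXCLUSION_RULES: dict[str, Callable[[RawCohort], pd.Series]] = {
    "missing_exposures": _rule_missing_exposures,
    "diet_missing": _rule_diet_missing,
}


def filter_cohort(
    raw: RawCohort,
    rules: Sequence[str] = ("missing_exposures", "diet_missing"),
) -> tuple[RawCohort, ExclusionLog]:
    """Apply exclusion rules in order and log the per-rule counts.

    Default rules drop participants with no chemical measurements at all,
    then those missing at least half of the dietary intake items.
    """
    table = raw.table
    steps: list[tuple[str, int]] = []
    initial = len(table)
    current = raw
    for name in rules:
        if name not in EXCLUSION_RULES:
            raise ValueError(
                f"unknown exclusion rule '{name}'; known: {sorted(EXCLUSION_RULES)}"
            )
        mask = EXCLUSION_RULES[name](current)
        steps.append((name, int(mask.sum())))
        current = RawCohort(
            table=current.table.loc[~mask],
            lod=current.lod,
            exposure_cols=current.exposure_cols,
            trait_cols=current.trait_cols,
            diet_cols=current.diet_cols,
            covariate_cols=current.covariate_cols,
        )
    log = ExclusionLog(initial=initial, steps=steps, retained=len(current.table))
    return current, log


def _censored_normal_mle(
    observed: np.ndarray, lod: float, n_censored: int
) -> tuple[float, float]:
    """MLE of (mu, sigma) for a normal with left-censoring at the LOD."""
    mu0 = float(observed.mean())
    s0 = float(observed.std(ddof=1)) if len(observed) > 1 else lod / 4
    s0 = max(s0, 1e-8 * max(abs(mu0), lod))

    def nll(theta: np.ndarray) -> float:
        mu, log_s = theta
        s = np.exp(log_s)
        ll = stats.norm.logpdf(observed, mu, s).sum()
        if n_censored:
            ll += n_censored * stats.norm.logcdf((lod - mu) / s)
        return -ll

    res = optimize.minimize(nll, np.array([mu0, np.log(s0)]), method="Nelder-Mead")
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    return mu, sigma


def impute_below_lod(
    values: np.ndarray,
    below_lod: np.ndarray,
    lod: float,
    seed: int | np.random.Generator,
    params: tuple[float, float] | None = None,
    min_observed: int = 10,
) -> np.ndarray:
    """Replace below-LOD entries by draws from a truncated Gaussian on (0, LOD).

    The Gaussian's (mu, sigma) are fitted on the natural concentration scale
    by censored-likelihood MLE from the observed (above-LOD) values and the
    censoring count, unless ``params`` fixes them.  With fewer than
    ``min_observed`` quantified values the fit falls back to
    mu = LOD/2, sigma = LOD/4 with a logged warning.  Observed values and
    missing entries (NaN) are never altered.
    """
    if lod <= 0:
        raise ValueError("lod must be positive")
    values = np.asarray(values, dtype=float)
    below_lod = np.asarray(below_lod, dtype=bool)
    out = values.copy()
    flagged = below_lod & ~np.isnan(values)
    n_flagged = int(flagged.sum())
    if n_flagged == 0:
        return out

    if params is not None:
        mu, sigma = params
    else:
        observed = values[~below_lod & ~np.isnan(values)]
        if len(observed) < min_observed:
            logger.warning(
                "fewer than %d observed values above LOD; falling back to "
                "mu=LOD/2, sigma=LOD/4",
                min_observed,
            )
            mu, sigma = lod / 2, lod / 4
        else:
            mu, sigma = _censored_normal_mle(observed, lod, n_flagged)

    rng = np.random.default_rng(seed)
    if sigma <= 0:
        draws = np.full(n_flagged, float(np.clip(mu, np.nextafter(0, 1), lod)))
    else:
        a, b = (0.0 - mu) / sigma, (lod - mu) / sigma
        draws = stats.truncnorm.rvs(
            a, b, loc=mu, scale=sigma, size=n_flagged, random_state=rng
        )
    # keep draws strictly inside the open interval
    eps = 1e-12 * lod
    out[flagged] = np.clip(draws, eps, lod - eps)
    return out


def impute_exposures_below_lod(
    table: pd.DataFrame,
    lod: pd.Series,
    seed: int,
    params: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Column-wise LOD imputation of an exposure table.

    Non-detects are the entries coded 0; missing entries (NaN) are left for
    the missing-data imputer.
    """
    out = table.copy()
    rng = np.random.default_rng(seed)
    for compound in lod.index:
        col = out[compound].to_numpy(dtype=float)
        flagged = (col == 0) & ~np.isnan(col)
        out[compound] = impute_below_lod(
            np.where(flagged, 0.0, col),
            flagged,
            float(lod[compound]),
            rng,
            params=None if params is None else params.get(compound),
        )
    return out


def impute_missing(
    table: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 10,
    tol: float = 1e-3,
) -> pd.DataFrame:
    """Complete a table by round-robin iterative conditional modelling.

    Numeric columns are imputed with scikit-learn's ``IterativeImputer``
    (each column regressed on all others, cycled until the relative change
    falls below ``tol`` or ``max_iter`` rounds); categorical columns are
    filled with their mode.  Observed entries are never altered.
    """
    from sklearn.experimental import enable_iterative_imputer  # noqa: F401
    from sklearn.impute import IterativeImputer

    out = table.copy()
    numeric = out.select_dtypes(include=[np.number]).columns
    all_missing = [c for c in out.columns if out[c].isna().all()]
    if all_missing:
        raise ValueError(f"columns entirely missing, cannot impute: {all_missing}")
    if len(numeric) and out[numeric].isna().to_numpy().any():
        imputer = IterativeImputer(
            random_state=np.random.default_rng(seed).integers(2**31 - 1),
            max_iter=max_iter,
            tol=tol,
            sample_posterior=False,
            keep_empty_features=True,
        )
        out[numeric] = imputer.fit_transform(out[numeric])
    for col in out.columns.difference(numeric):
        if out[col].isna().any():
            mode = out[col].mode(dropna=True)
            out[col] = out[col].fillna(mode.iloc[0])
    return out


def log10_exposures(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10; all entries must be strictly positive."""
    values = matrix.to_numpy(dtype=float)
    bad = ~(values > 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive entry at row {matrix.index[i]!r}, "
            f"column {matrix.columns[j]!r}: {values[i, j]}"
        )
    return pd.DataFrame(np.log10(values), index=matrix.index, columns=matrix.columns)


@dataclass
class DietScores:
    """PCA summary of the five dietary intake variables."""

    scores: pd.DataFrame  # n x n_retained component scores
    loadings: pd.DataFrame  # variable x component
    explained_variance_ratio: np.ndarray  # all five components
    n_retained: int


def diet_pca(diet: pd.DataFrame, variance_threshold: float = 0.95) -> DietScores:
    """Summarize the diet block by the fewest principal components that
    jointly explain more than ``variance_threshold`` of the variance.

    Columns are z-scored first (intakes are on disparate unit scales).
    """
    from sklearn.decomposition import PCA

    if diet.shape[1] < 5:
        raise ValueError(f"diet table must have 5 columns, got {diet.shape[1]}")
    if diet.isna().to_numpy().any():
        raise ValueError("diet table must be complete (impute first)")
    z = (diet - diet.mean()) / diet.std(ddof=0).replace(0.0, 1.0)
    pca = PCA(svd_solver="full").fit(z)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    n_retained = int(np.searchsorted(cumvar, variance_threshold) + 1)
    n_retained = min(n_retained, diet.shape[1])
    scores = pca.transform(z)[:, :n_retained]
    comp_names = [f"dietPC{i + 1}" for i in range(n_retained)]
    return DietScores(
        scores=pd.DataFrame(scores, index=diet.index, columns=comp_names),
        loadings=pd.DataFrame(
            pca.components_[:n_retained].T, index=diet.columns, columns=comp_names
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_retained=n_retained,
    )


def summarize_cohort(raw: RawCohort) -> dict:
    """Descriptive summary: marginals, detection fractions and Spearman maps.

    Percentages use non-missing denominators; detection fraction is the
    share of quantified (above-LOD) measurements among non-missing ones.
    """
    table = raw.table
    summary: dict = {}

    numeric_cols = [c for c in raw.diet_cols + raw.trait_cols if c in table.columns]
    numeric_cols = ["age"] + numeric_cols if "age" in table.columns else numeric_cols
    if numeric_cols:
        num = table[numeric_cols]
        summary["numeric"] = pd.DataFrame(
            {"mean": num.mean(), "sd": num.std(ddof=1)}
        )

    categorical = {}
    for col in ("gender", "education", "smoking"):
        if col in table.columns:
            counts = table[col].value_counts(dropna=True)
            categorical[col] = pd.DataFrame(
                {"count": counts, "percent": 100 * counts / counts.sum()}
            )
    summary["categorical"] = categorical

    expo = table[raw.exposure_cols]
    nonmissing = expo.notna()
    detected = (expo > 0) & nonmissing
    with np.errstate(invalid="ignore"):
        summary["detection_fraction"] = detected.sum() / nonmissing.sum()

    traits = [t for t in raw.trait_cols if t in table.columns]
    if traits:
        summary["spearman_traits"] = table[traits].corr(method="spearman")
    expo_diet = raw.diet_cols + raw.exposure_cols
    summary["spearman_exposures_diet"] = (
        table[expo_diet].corr(method="spearman") if len(table) else pd.DataFrame()
    )
    return summary


def covariate_design(
    covariates: pd.DataFrame, diet_scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Adjustment design: intercept, age, gender, one-hot education and
    smoking (reference levels: low education, never smoker), diet PCs."""
    design = pd.DataFrame(index=covariates.index)
    design["intercept"] = 1.0
    design["age"] = covariates["age"].astype(float)
    design["female"] = (covariates["gender"].astype(str) == "female").astype(float)
    edu = covariates["education"].astype(str)
    design["education_intermediate"] = (edu == "intermediate").astype(float)
    design["education_high"] = (edu == "high").astype(float)
    smoke = covariates["smoking"].astype(str)
    design["smoking_former"] = (smoke == "former").astype(float)
    design["smoking_current"] = (smoke == "current").astype(float)
    if diet_scores is not None:
        design = pd.concat([design, diet_scores], axis=1)
    return design


class AnalysisData(NamedTuple):
    """Analysis-ready matrices produced by the preprocessing chain."""

    traits: pd.DataFrame  # Y: n x q
    log_exposures: pd.DataFrame  # X: n x p, log10 scale
    covariates: pd.DataFrame  # C: adjustment design incl. intercept
    diet: DietScores
    exclusions: ExclusionLog


def prepare_analysis(
    raw: RawCohort,
    seed: int = 0,
    variance_threshold: float = 0.95,
    lod_params: Mapping[str, tuple[float, float]] | None = None,
) -> AnalysisData:
    """Full preprocessing chain: filter, impute (LOD then missing), log10
    transform, diet PCA, and covariate design assembly."""
    filtered, log = filter_cohort(raw)
    table = filtered.table.reset_index(drop=True)

    expo = impute_exposures_below_lod(
        table[raw.exposure_cols], raw.lod, seed=seed, params=lod_params
    )
    table = table.copy()
    table[raw.exposure_cols] = expo

    numeric_part = raw.diet_cols + raw.trait_cols + ["age"] + raw.exposure_cols
    numeric_part = [c for c in numeric_part if c in table.columns]
    completed = impute_missing(
        table[numeric_part + ["gender", "education", "smoking"]], seed=seed
    )
    table[completed.columns] = completed

    log_expo = log10_exposures(table[raw.exposure_cols])
    diet = diet_pca(table[raw.diet_cols], variance_threshold=variance_threshold)
    design = covariate_design(table[raw.covariate_cols], diet.scores)
    return AnalysisData(
        traits=table[raw.trait_cols],
        log_exposures=log_expo,
        covariates=design,
        diet=diet,
        exclusions=log,
    )
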