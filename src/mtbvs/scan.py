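"""Univariate baseline: per-(trait, exposure) adjusted linear regressions.

Each trait is regressed on each log10 exposure with the covariate block,
giving the exploratory 33 x 9 scan against which the multitrait selection
is compared.  Family-wise error is controlled per trait across the exposure
panel by Bonferroni.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["univariate_scan", "bonferroni_flag"]


def bonferroni_flag(
    p_values: np.ndarray | pd.Series, fwer: float = 0.05, m: int = 33
) -> np.ndarray:
    """Flag p-values significant at the Bonferroni-corrected level fwer/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p < fwer / m


def univariate_scan(
    traits: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    fwer: float = 0.05,
) -> pd.DataFrame:
    """OLS of every trait on every exposure, adjusted for the covariates.

    ``covariates`` should include an intercept column (one is added if
    absent).  Returns one row per (trait, exposure) with the exposure
    coefficient, its standard error, the two-sided p-value and a Bonferroni
    flag at the per-trait level ``fwer / n_exposures``.
    """
    if not (len(traits) == len(exposures) == len(covariates)):
        raise ValueError("traits, exposures and covariates must share rows")
    C = covariates.to_numpy(dtype=float)
    if not np.any(C.std(axis=0) < 1e-12):
        C = np.column_stack([np.ones(len(C)), C])
    m = exposures.shape[1]
    rows = []
    for trait in traits.columns:
        y = traits[trait].to_numpy(dtype=float)
        for expo in exposures.columns:
            x = exposures[expo].to_numpy(dtype=float)
            design = np.column_stack([x, C])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                raise ValueError(
                    f"collinear design for trait '{trait}' and exposure '{expo}'"
                )
            fit = sm.OLS(y, design).fit()
            rows.append(
                {
                    "trait": trait,
                    "exposure": expo,
                    "coef": fit.params[0],
                    "se": fit.bse[0],
                    "p_value": fit.pvalues[0],
                }
            )
    out = pd.DataFrame(rows)
    out["bonferroni_significant"] = bonferroni_flag(out["p_value"], fwer=fwer, m=m)
    out.attrs["adjustment"] = list(covariates.columns)
    out.attrs["per_test_level"] = fwer / m
    return out
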