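"""Synthetic cohort generator.

Emulates the statistical structure of a hair-biomonitoring cardiometabolic
cohort: block-correlated log-scale exposure concentrations with per-compound
limit-of-detection (LOD) censoring and sporadic technical missingness,
demographic and dietary covariates with realistic marginals, and a
multivariate trait panel driven by a sparse exposure -> trait effect matrix
plus correlated Gaussian residuals.

Every generator is a pure function of its arguments and a seed, and the
generating truth (true inclusion set, coefficient matrix, residual
covariance) is recorded alongside the data so that downstream selection
methods can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExposureSpec",
    "TraitSpec",
    "ExposurePanel",
    "CohortTruth",
    "SyntheticCohort",
    "DEFAULT_COMPOUNDS",
    "DEFAULT_TRAITS",
    "generate_exposures",
    "generate_covariates",
    "generate_traits",
    "generate_cohort",
    "write_cohort",
]

# 33-compound hair panel: persistent organic pollutants, pesticides and
# their metabolites, grouped by chemical family.
DEFAULT_COMPOUNDS: dict[str, str] = {
    "PCB-138": "PCB",
    "PCB-153": "PCB",
    "PCB-180": "PCB",
    "BDE-47": "PBDE",
    "HCB": "organochlorine",
    "alpha-HCH": "organochlorine",
    "beta-HCH": "organochlorine",
    "gamma-HCH": "organochlorine",
    "p,p'-DDT": "organochlorine",
    "p,p'-DDE": "organochlorine",
    "dieldrin": "organochlorine",
    "heptachlor": "organochlorine",
    "PCP": "organochlorine",
    "chlorpyrifos": "organophosphorus",
    "diazinon": "organophosphorus",
    "parathion": "organophosphorus",
    "malathion": "organophosphorus",
    "DMP": "organophosphorus",
    "DEP": "organophosphorus",
    "DETP": "organophosphorus",
    "PNP": "organophosphorus",
    "3Me4NP": "organophosphorus",
    "permethrin": "pyrethroid",
    "cypermethrin": "pyrethroid",
    "3-PBA": "pyrethroid",
    "Cl2CA": "pyrethroid",
    "fipronil": "phenylpyrazole",
    "fipronil sulfone": "phenylpyrazole",
    "carbofuran": "carbamate",
    "propoxur": "carbamate",
    "diflufenican": "carboxamide",
    "trifluralin": "dinitroaniline",
    "oxadiazon": "oxadiazole",
}

DEFAULT_TRAITS = ["BMI", "WC", "TG", "TC", "HDL-C", "LDL-C", "SBP", "DBP", "FPG"]

DIET_COLUMNS = ["energy", "proteins", "fats", "carbohydrates", "fibres"]
# Table-style marginals: energy kcal/day, macronutrients and fibre g/day.
_DIET_MEAN = np.array([2266.5, 88.6, 96.6, 239.4, 24.0])
_DIET_SD = np.array([763.3, 30.7, 37.7, 89.0, 8.9])

# Three-factor loadings for the diet block (rows: energy, proteins, fats,
# carbohydrates, fibres).  Energy is nearly a linear function of the
# macronutrients, so three principal components carry >95% of the variance,
# and corr(energy, fats) = 0.88 after the 0.5% unique-noise blend.
_DIET_LOADINGS = np.array(
    [
        [0.60000, 0.65550, 0.45860],
        [1.00000, 0.00000, 0.00000],
        [0.60000, 0.80000, 0.00000],
        [0.50000, 0.30000, 0.81240],
        [0.30000, 0.20000, 0.93274],
    ]
)
_DIET_UNIQUENESS = 0.005


def default_diet_correlation() -> np.ndarray:
    """Correlation matrix of the five dietary intake variables."""
    rows = _DIET_LOADINGS / np.linalg.norm(_DIET_LOADINGS, axis=1, keepdims=True)
    corr = (1.0 - _DIET_UNIQUENESS) * rows @ rows.T
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_positive_definite(mat: np.ndarray, what: str) -> None:
    eigmin = float(np.linalg.eigvalsh(mat).min())
    if eigmin <= 1e-10:
        raise ValueError(
            f"implied correlation matrix for {what} is not positive definite "
            f"(smallest eigenvalue {eigmin:.3e})"
        )


@dataclass
class ExposureSpec:
    """Configuration of the simulated exposure panel.

    Concentrations follow a Gaussian copula on the log10 scale: compounds of
    the same chemical family share a latent correlation
    ``latent_corr_within``; compounds of different families share
    ``latent_corr_between``.  The LOD of each compound is placed at the
    ``1 - detection_target`` quantile of its generating log-normal so that a
    prescribed fraction of samples falls above the LOD.
    """

    compounds: Sequence[str] = field(default_factory=lambda: list(DEFAULT_COMPOUNDS))
    families: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COMPOUNDS))
    latent_corr_within: float = 0.5
    latent_corr_between: float = 0.1
    log10_mean: Mapping[str, float] | float | None = None
    log10_sd: Mapping[str, float] | float = 0.5
    detection_target: Mapping[str, float] | float = 0.7
    missing_rate: float = 0.02

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    def _per_compound(self, value, default) -> np.ndarray:
        if value is None:
            value = default
        if isinstance(value, Mapping):
            return np.array([float(value[c]) for c in self.compounds])
        return np.full(self.n_compounds, float(value))

    def log10_means(self) -> np.ndarray:
        if self.log10_mean is None:
            # spread locations over roughly 0.03-30 pg/mg
            return np.linspace(-1.5, 1.5, self.n_compounds)
        return self._per_compound(self.log10_mean, None)

    def log10_sds(self) -> np.ndarray:
        return self._per_compound(self.log10_sd, 0.5)

    def detection_targets(self) -> np.ndarray:
        return self._per_compound(self.detection_target, 0.7)

    def family_labels(self) -> list[str]:
        return [self.families.get(c, "other") for c in self.compounds]

    def latent_correlation(self) -> np.ndarray:
        labels = np.asarray(self.family_labels())
        same = labels[:, None] == labels[None, :]
        corr = np.where(same, self.latent_corr_within, self.latent_corr_between)
        np.fill_diagonal(corr, 1.0)
        return corr

    def validate(self) -> None:
        if not 0 <= self.latent_corr_within < 1:
            raise ValueError("latent_corr_within must lie in [0, 1)")
        if not 0 <= self.latent_corr_between < 1:
            raise ValueError("latent_corr_between must lie in [0, 1)")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        det = self.detection_targets()
        if np.any(det < 0.10) or np.any(det > 1):
            bad = [c for c, d in zip(self.compounds, det) if d < 0.10 or d > 1]
            raise ValueError(
                "detection_target must lie in [0.10, 1] (inclusion floor of 10% "
                f"detection); offending compounds: {bad}"
            )
        if np.any(self.log10_sds() < 0):
            raise ValueError("log10_sd must be non-negative")
        # positive definiteness, family blocks first for a pointed message
        labels = np.asarray(self.family_labels())
        corr = self.latent_correlation()
        for fam in dict.fromkeys(labels):
            idx = np.flatnonzero(labels == fam)
            if len(idx) > 1:
                _check_positive_definite(corr[np.ix_(idx, idx)], f"family block '{fam}'")
        _check_positive_definite(corr, "the full exposure panel")


@dataclass
class TraitSpec:
    """Configuration of the simulated trait panel.

    ``true_effects`` maps compound -> trait -> standardized coefficient; the
    linear predictor acts on z-scored log10 exposures so coefficients are on
    the residual-SD scale.  ``residual_corr`` is the trait-by-trait
    correlation of the Gaussian residuals (unit variances).
    """

    trait_names: Sequence[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    residual_corr: np.ndarray | None = None
    residual_sd: float = 1.0
    true_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    covariate_effects: Mapping[str, Mapping[str, float]] | None = None

    def residual_correlation(self) -> np.ndarray:
        if self.residual_corr is not None:
            mat = np.asarray(self.residual_corr, dtype=float)
        elif list(self.trait_names) == DEFAULT_TRAITS:
            mat = default_trait_residual_correlation()
        else:
            mat = np.eye(len(self.trait_names))
        return mat

    def validate(self, compounds: Sequence[str] | None = None) -> None:
        mat = self.residual_correlation()
        q = len(self.trait_names)
        if mat.shape != (q, q):
            raise ValueError("residual_corr shape does not match trait_names")
        if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 1.0):
            raise ValueError("residual_corr must be symmetric with unit diagonal")
        _check_positive_definite(mat, "trait residuals")
        for comp, per_trait in self.true_effects.items():
            if compounds is not None and comp not in compounds:
                raise ValueError(f"true_effects references unknown compound '{comp}'")
            for trait in per_trait:
                if trait not in self.trait_names:
                    raise ValueError(f"true_effects references unknown trait '{trait}'")


def default_trait_residual_correlation() -> np.ndarray:
    """Residual correlation of the nine cardiometabolic traits.

    Anchored on the strong published pairings (BMI-WC 0.89, TC-LDL-C 0.90,
    SBP-DBP 0.76, WC-FPG 0.51) with moderate, physiologically plausible
    values elsewhere.
    """
    t = DEFAULT_TRAITS
    corr = np.eye(9)
    pairs = {
        ("BMI", "WC"): 0.89,
        ("TC", "LDL-C"): 0.90,
        ("SBP", "DBP"): 0.76,
        ("WC", "FPG"): 0.51,
        ("BMI", "FPG"): 0.45,
        ("BMI", "TG"): 0.30,
        ("WC", "TG"): 0.32,
        ("TG", "HDL-C"): -0.40,
        ("TC", "HDL-C"): 0.10,
        ("HDL-C", "LDL-C"): -0.05,
        ("TG", "TC"): 0.35,
        ("TG", "LDL-C"): 0.20,
        ("BMI", "SBP"): 0.30,
        ("WC", "SBP"): 0.32,
        ("BMI", "DBP"): 0.28,
        ("WC", "DBP"): 0.30,
        ("SBP", "FPG"): 0.25,
        ("DBP", "FPG"): 0.20,
        ("TG", "SBP"): 0.20,
        ("TG", "DBP"): 0.20,
        ("TG", "FPG"): 0.30,
        ("TC", "SBP"): 0.15,
        ("TC", "DBP"): 0.15,
        ("TC", "FPG"): 0.10,
        ("HDL-C", "FPG"): -0.20,
        ("HDL-C", "SBP"): -0.10,
        ("HDL-C", "DBP"): -0.10,
        ("LDL-C", "SBP"): 0.15,
        ("LDL-C", "DBP"): 0.15,
        ("LDL-C", "FPG"): 0.10,
        ("BMI", "TC"): 0.15,
        ("BMI", "HDL-C"): -0.25,
        ("BMI", "LDL-C"): 0.18,
        ("WC", "TC"): 0.17,
        ("WC", "HDL-C"): -0.28,
        ("WC", "LDL-C"): 0.20,
    }
    for (a, b), rho in pairs.items():
        i, j = t.index(a), t.index(b)
        corr[i, j] = corr[j, i] = rho
    return corr


@dataclass
class ExposurePanel:
    """Generated exposure block: true concentrations plus censoring masks."""

    concentrations: pd.DataFrame  # true pg/mg values, n x p
    lod: pd.Series  # per-compound LOD, pg/mg
    below_lod: pd.DataFrame  # True where the true value fell below the LOD
    missing: pd.DataFrame  # True where the measurement is technically missing

    def observed(self) -> pd.DataFrame:
        """Concentrations as an assay would report them.

        Below-LOD entries are coded 0.0 (non-detect), missing entries NaN.
        The true values are never silently substituted.
        """
        out = self.concentrations.where(~self.below_lod.to_numpy(), 0.0)
        return out.where(~self.missing.to_numpy(), np.nan)


@dataclass
class CohortTruth:
    gamma: pd.Series  # per-compound true inclusion indicator
    coefficients: pd.DataFrame  # compound x trait standardized effects
    residual_cov: pd.DataFrame  # trait x trait residual covariance
    seed: int


@dataclass
class SyntheticCohort:
    exposures: ExposurePanel
    covariates: pd.DataFrame
    diet: pd.DataFrame
    traits: pd.DataFrame
    truth: CohortTruth

    @property
    def n(self) -> int:
        return len(self.covariates)


def generate_exposures(
    spec: ExposureSpec, n: int, seed: int | np.random.Generator
) -> ExposurePanel:
    """Draw an n-by-p exposure panel with LOD censoring and missingness.

    Concentrations are log10-normal with a family-block Gaussian copula on
    the latent scale.  The LOD of compound j sits at the
    ``1 - detection_target_j`` quantile of its generating distribution;
    entries falling below it are flagged, not replaced.  The missing mask is
    applied after censoring, independently at ``missing_rate``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec.validate()
    rng = np.random.default_rng(seed)
    p = spec.n_compounds
    corr = spec.latent_correlation()
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, p)) @ chol.T
    mu, sd = spec.log10_means(), spec.log10_sds()
    log10_conc = mu + sd * z
    conc = 10.0 ** log10_conc

    from scipy.stats import norm

    det = spec.detection_targets()
    # quantile of the generating log-normal; sd == 0 degenerates to the
    # point mass, where the LOD sits just below the single attained value
    # when everything is "detected"
    zq = np.asarray(norm.ppf(1.0 - det))
    point_mass = sd == 0
    with np.errstate(over="ignore", invalid="ignore"):
        lod_vals = 10.0 ** (mu + np.where(point_mass, 0.0, sd * zq))
    lod_vals = np.where(point_mass & (det >= 1.0), 10.0 ** mu / 2.0, lod_vals)

    below = conc < lod_vals
    missing = rng.random((n, p)) < spec.missing_rate

    cols = list(spec.compounds)
    idx = pd.RangeIndex(n, name="participant")
    return ExposurePanel(
        concentrations=pd.DataFrame(conc, columns=cols, index=idx),
        lod=pd.Series(lod_vals, index=cols, name="lod_pg_per_mg"),
        below_lod=pd.DataFrame(below, columns=cols, index=idx),
        missing=pd.DataFrame(missing, columns=cols, index=idx),
    )


# Table-style covariate marginals of the study population.
COVARIATE_DEFAULTS = {
    "age_mean": 44.8,
    "age_sd": 13.5,
    "female_fraction": 0.69,
    "education_freqs": {"low": 0.389, "intermediate": 0.228, "high": 0.383},
    "smoking_freqs": {"never": 0.553, "former": 0.235, "current": 0.212},
}


def generate_covariates(
    n: int,
    seed: int | np.random.Generator,
    *,
    age_mean: float = COVARIATE_DEFAULTS["age_mean"],
    age_sd: float = COVARIATE_DEFAULTS["age_sd"],
    female_fraction: float = COVARIATE_DEFAULTS["female_fraction"],
    education_freqs: Mapping[str, float] | None = None,
    smoking_freqs: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw covariate and dietary-intake tables with study-like marginals."""
    if n < 0:
        raise ValueError("n must be >= 0")
    education_freqs = dict(education_freqs or COVARIATE_DEFAULTS["education_freqs"])
    smoking_freqs = dict(smoking_freqs or COVARIATE_DEFAULTS["smoking_freqs"])
    for name, freqs in (("education", education_freqs), ("smoking", smoking_freqs)):
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{name} category frequencies sum to {total}, not 1")

    rng = np.random.default_rng(seed)
    idx = pd.RangeIndex(n, name="participant")
    age = rng.normal(age_mean, age_sd, size=n)
    gender = np.where(rng.random(n) < female_fraction, "female", "male")
    education = rng.choice(
        list(education_freqs), size=n, p=list(education_freqs.values())
    )
    smoking = rng.choice(list(smoking_freqs), size=n, p=list(smoking_freqs.values()))
    covariates = pd.DataFrame(
        {"age": age, "gender": gender, "education": education, "smoking": smoking},
        index=idx,
    )
    covariates["education"] = pd.Categorical(
        covariates["education"], categories=list(education_freqs)
    )
    covariates["smoking"] = pd.Categorical(
        covariates["smoking"], categories=list(smoking_freqs)
    )

    corr = default_diet_correlation()
    z = rng.standard_normal((n, 5)) @ np.linalg.cholesky(corr).T
    diet_vals = _DIET_MEAN + _DIET_SD * z
    diet_vals = np.maximum(diet_vals, 0.01 * _DIET_MEAN)  # keep intakes positive
    diet = pd.DataFrame(diet_vals, columns=DIET_COLUMNS, index=idx)
    return covariates, diet


# Standardized covariate effects on the traits: age raises blood pressure,
# cholesterol and adiposity; female gender lowers WC/blood pressure and
# raises HDL-C; current smoking depresses HDL-C.
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float]] = {
    "age_z": {
        "BMI": 0.15, "WC": 0.18, "TG": 0.10, "TC": 0.30, "LDL-C": 0.28,
        "SBP": 0.35, "DBP": 0.25, "FPG": 0.25,
    },
    "female": {
        "BMI": -0.10, "WC": -0.35, "TG": -0.15, "HDL-C": 0.35,
        "SBP": -0.20, "DBP": -0.10,
    },
    "smoking_current": {"HDL-C": -0.15, "TG": 0.10},
    "education_high": {"BMI": -0.10, "WC": -0.10},
}


def _covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design used by the trait generator (not the analysis)."""
    out = pd.DataFrame(index=covariates.index)
    age = covariates["age"].to_numpy(dtype=float)
    sd = age.std() or 1.0
    out["age_z"] = (age - age.mean()) / sd
    out["female"] = (covariates["gender"].astype(str) == "female").astype(float)
    out["smoking_current"] = (covariates["smoking"].astype(str) == "current").astype(float)
    out["education_high"] = (covariates["education"].astype(str) == "high").astype(float)
    return out


def generate_traits(
    log_exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: TraitSpec,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate the trait panel from exposures, covariates and residuals.

    Traits are the sum of (i) the sparse standardized exposure effects
    applied to z-scored log10 concentrations, (ii) covariate effects, and
    (iii) Gaussian residuals with correlation ``spec.residual_corr`` and
    unit variances.
    """
    if len(log_exposures) != len(covariates):
        raise ValueError(
            f"row mismatch: {len(log_exposures)} exposure rows vs "
            f"{len(covariates)} covariate rows"
        )
    spec.validate(compounds=list(log_exposures.columns))
    rng = np.random.default_rng(seed)
    seed_val = int(seed) if not isinstance(seed, np.random.Generator) else -1
    n = len(log_exposures)
    traits = list(spec.trait_names)
    q = len(traits)

    x = log_exposures.to_numpy(dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - x.mean(axis=0)) / sd

    beta = pd.DataFrame(0.0, index=log_exposures.columns, columns=traits)
    for comp, per_trait in spec.true_effects.items():
        for trait, coef in per_trait.items():
            beta.loc[comp, trait] = float(coef)

    lin = xz @ beta.to_numpy()
    cov_eff = spec.covariate_effects
    if cov_eff is None:
        cov_eff = DEFAULT_COVARIATE_EFFECTS
    design = _covariate_design(covariates)
    for cov_name, per_trait in cov_eff.items():
        if cov_name not in design.columns:
            raise ValueError(f"unknown covariate effect '{cov_name}'")
        col = design[cov_name].to_numpy()
        for trait, coef in per_trait.items():
            if trait not in traits:
                raise ValueError(f"covariate_effects references unknown trait '{trait}'")
            lin[:, traits.index(trait)] += coef * col

    corr = spec.residual_correlation()
    _check_positive_definite(corr, "trait residuals")
    resid = rng.standard_normal((n, q)) @ np.linalg.cholesky(corr).T
    values = pd.DataFrame(
        lin + spec.residual_sd * resid, columns=traits, index=log_exposures.index
    )

    truth = CohortTruth(
        gamma=(beta != 0).any(axis=1),
        coefficients=beta,
        residual_cov=pd.DataFrame(
            spec.residual_sd**2 * corr, index=traits, columns=traits
        ),
        seed=seed_val,
    )
    return values, truth


def generate_cohort(
    n: int = 941,
    seed: int = 0,
    *,
    exposure_spec: ExposureSpec | None = None,
    trait_spec: TraitSpec | None = None,
    n_no_panel: int = 0,
    n_diet_sparse: int = 0,
) -> SyntheticCohort:
    """Generate a complete synthetic cohort of ``n`` analysable participants.

    ``n_no_panel`` extra participants with a fully missing exposure panel and
    ``n_diet_sparse`` extra participants missing at least half of the diet
    items are appended (in that order) so that cohort-exclusion rules can be
    exercised end to end; the analysable block always comes first.
    """
    exposure_spec = exposure_spec or ExposureSpec()
    trait_spec = trait_spec or TraitSpec()
    rng = np.random.default_rng(seed)

    total = n + n_no_panel + n_diet_sparse
    panel = generate_exposures(exposure_spec, total, rng)
    covariates, diet = generate_covariates(total, rng)
    log_conc = np.log10(panel.concentrations)
    traits, truth = generate_traits(log_conc, covariates, trait_spec, rng)
    truth.seed = int(seed)

    if n_no_panel:
        rows = np.arange(n, n + n_no_panel)
        panel.missing.iloc[rows, :] = True
    if n_diet_sparse:
        rows = np.arange(n + n_no_panel, total)
        n_items = max(3, (len(DIET_COLUMNS) + 1) // 2)
        for r in rows:
            drop = rng.choice(len(DIET_COLUMNS), size=n_items, replace=False)
            diet.iloc[r, drop] = np.nan

    return SyntheticCohort(
        exposures=panel, covariates=covariates, diet=diet, traits=traits, truth=truth
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write cohort.csv, lod.csv and truth.json.

    cohort.csv holds one row per participant; exposure columns code a
    non-detect (below LOD) as 0 and a technically missing measurement as an
    empty cell.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.concat(
        [cohort.covariates, cohort.diet, cohort.traits, cohort.exposures.observed()],
        axis=1,
    )
    table.insert(0, "id", [f"P{i:05d}" for i in range(len(table))])
    cohort_path = outdir / "cohort.csv"
    table.to_csv(cohort_path, index=False)

    lod_path = outdir / "lod.csv"
    lod_df = cohort.exposures.lod.rename_axis("compound").reset_index()
    lod_df.to_csv(lod_path, index=False)

    truth_path = outdir / "truth.json"
    truth = cohort.truth
    payload = {
        "seed": truth.seed,
        "gamma_true": {c: bool(v) for c, v in truth.gamma.items()},
        "coefficients": {
            c: {t: float(v) for t, v in row.items() if v != 0}
            for c, row in truth.coefficients.iterrows()
        },
        "residual_cov": truth.residual_cov.to_dict(),
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    return {"cohort": cohort_path, "lod": lod_path, "truth": truth_path}
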