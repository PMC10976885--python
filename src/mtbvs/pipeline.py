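"""End-to-end analysis orchestration.

Runs the full flow on a cohort table: (optional) simulation, preprocessing,
trait and exposure networks, network-driven trait selection, single- and
multitrait Bayesian variable selection, posterior summaries with
permutation FDR, the univariate scan, and the covariate-attenuation ladder.
Every stage writes its artifacts into the run directory and is logged; a
JSON manifest records the configuration, seed and stage timings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bvs import SamplerConfig, SizePrior, residualize, run_guess
from .network import StabilityConfig, calibrate_network, write_network
from .posthoc import (
    compute_mpp,
    compute_mppi,
    effect_posterior,
    empirical_fdr_threshold,
    mppi_attenuation,
    permutation_mppis,
    rbf_table,
)
from .preprocess import covariate_design, prepare_analysis, read_cohort, summarize_cohort
from .scan import univariate_scan
from .synthetic import ExposureSpec, DEFAULT_COMPOUNDS, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration of a pipeline run (YAML-loadable)."""

    seed: int = 0
    output_dir: str = "mtbvs_run"
    cohort_csv: str | None = None  # simulate when absent
    lod_csv: str | None = None
    # simulation block
    n_participants: int = 300
    n_compounds: int | None = None  # subset of the default 33-compound panel
    true_effects: dict = field(default_factory=dict)
    # sampler block
    sweeps: int = 30_000
    burn_in: int = 10_000
    chains: int = 3
    prior_E: float = 5.0
    prior_S: float = 4.0
    prior_F: float = 7.0
    # network block
    subsamples: int = 100
    pfer_traits: float = 10.0
    pfer_exposures: float = 20.0
    # decision block
    fdr_level: float = 0.05
    permutations: int = 20
    effect_rounds: int = 500
    run_attenuation: bool = True
    run_single_trait: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.cohort_csv is not None:
            for p in (self.cohort_csv, self.lod_csv):
                if p is None or not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
        if not 0 <= self.burn_in < self.sweeps:
            raise ValueError("require 0 <= burn_in < sweeps")
        if not 0 < self.fdr_level <= 1:
            raise ValueError("fdr_level must be in (0, 1]")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.time() - self.t0
            if exc is None:
                manifest["stages"].append({"stage": name, "seconds": round(elapsed, 3)})
                logger.info("stage %s: done in %.1fs", name, elapsed)
                return False
            manifest["stages"].append(
                {"stage": name, "seconds": round(elapsed, 3), "error": str(exc)}
            )
            logger.error("stage %s: FAILED (%s)", name, exc)
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    return _Timer()


def _sampler_config(config: RunConfig, seed: int) -> SamplerConfig:
    return SamplerConfig(
        n_sweeps=config.sweeps,
        burn_in=config.burn_in,
        n_chains=config.chains,
        seed=seed,
    )


def _bvs_and_posthoc(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    C: pd.DataFrame,
    prior: SizePrior,
    config: RunConfig,
    seed: int,
    outdir: Path,
    label: str,
    run_fdr: bool = True,
    effect_rounds: int | None = None,
) -> dict:
    """Run one BVS analysis and write its posterior summaries."""
    Yt, Xt = residualize(Y, X, C)
    log = run_guess(Yt, Xt, prior, _sampler_config(config, seed))
    mpp = compute_mpp(log)
    mppi = compute_mppi(log)
    p = Xt.shape[1]
    pi0 = prior.E / p

    result: dict = {"log": log, "mpp": mpp, "mppi": mppi}
    prefix = outdir / label
    prefix.mkdir(parents=True, exist_ok=True)
    log.to_tsv(prefix / "top_models.tsv", prefix / "trace.tsv")
    mppi.rename_axis("feature").reset_index().to_csv(
        prefix / "mppi.tsv", sep="\t", index=False
    )

    if run_fdr:
        perms = permutation_mppis(
            Yt, Xt, prior, _sampler_config(config, seed),
            n_permutations=config.permutations, seed=seed + 1,
        )
        fdr = empirical_fdr_threshold(mppi, perms, level=config.fdr_level)
        table = rbf_table(mppi, fdr.threshold, pi0, n_recorded=log.n_recorded)
        table.rename_axis("feature").reset_index().to_csv(
            prefix / "rbf.tsv", sep="\t", index=False
        )
        result["fdr"] = fdr
        result["rbf"] = table

    top = mpp.iloc[0]["_indices"]
    if top:
        eff = effect_posterior(
            Yt, Xt, list(top),
            n_rounds=effect_rounds or config.effect_rounds,
            seed=seed + 2,
        )
        eff.quantiles.to_csv(prefix / "effects.tsv", sep="\t", index=False)
        result["effects"] = eff
    return result


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mtbvs")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }
    try:
        if config.cohort_csv is None:
            with _stage(manifest, "simulate"):
                spec = ExposureSpec()
                if config.n_compounds is not None:
                    keep = list(DEFAULT_COMPOUNDS)[: config.n_compounds]
                    spec = ExposureSpec(
                        compounds=keep,
                        families={c: DEFAULT_COMPOUNDS[c] for c in keep},
                    )
                from .synthetic import TraitSpec

                cohort = generate_cohort(
                    n=config.n_participants,
                    seed=config.seed,
                    exposure_spec=spec,
                    trait_spec=TraitSpec(true_effects=config.true_effects),
                )
                paths = write_cohort(cohort, outdir / "data")
                cohort_csv, lod_csv = paths["cohort"], paths["lod"]
        else:
            cohort_csv, lod_csv = Path(config.cohort_csv), Path(config.lod_csv)

        with _stage(manifest, "preprocess"):
            raw = read_cohort(cohort_csv, lod_csv)
            data = prepare_analysis(raw, seed=config.seed)
            (outdir / "exclusion_log.json").write_text(
                json.dumps(data.exclusions.to_dict(), indent=1)
            )
            summary = summarize_cohort(raw)
            if "numeric" in summary:
                summary["numeric"].rename_axis("variable").to_csv(
                    outdir / "summary.tsv", sep="\t"
                )
            pd.concat(
                [data.traits, data.log_exposures, data.covariates], axis=1
            ).to_csv(outdir / "analysis_matrix.csv", index=False)

        with _stage(manifest, "network_traits"):
            trait_net = calibrate_network(
                data.traits,
                StabilityConfig(
                    K=config.subsamples, pfer_max=config.pfer_traits, seed=config.seed
                ),
            )
            write_network(trait_net, outdir / "network_traits")

        with _stage(manifest, "network_exposures"):
            diet_raw = pd.DataFrame(
                data.diet.scores.to_numpy(), index=data.log_exposures.index,
                columns=list(data.diet.scores.columns),
            )
            combined = pd.concat([diet_raw, data.log_exposures], axis=1)
            blocks = ["diet"] * diet_raw.shape[1] + ["chemical"] * data.log_exposures.shape[1]
            expo_net = calibrate_network(
                combined,
                StabilityConfig(
                    K=config.subsamples, pfer_max=config.pfer_exposures,
                    seed=config.seed + 10,
                ),
                blocks=blocks,
            )
            write_network(expo_net, outdir / "network_exposures")

        with _stage(manifest, "trait_selection"):
            degrees = trait_net.degrees()
            selected = [t for t in data.traits.columns if degrees.get(t, 0) >= 2]
            if len(selected) < 2:
                logger.warning(
                    "fewer than two traits with degree >= 2; keeping all traits"
                )
                selected = list(data.traits.columns)
            (outdir / "selected_traits.json").write_text(
                json.dumps({"selected": selected, "degrees": degrees.to_dict()})
            )

        prior = SizePrior(E=config.prior_E, S=config.prior_S, F=config.prior_F)
        X = data.log_exposures
        C = data.covariates

        if config.run_single_trait:
            with _stage(manifest, "bvs_single_trait"):
                for trait in selected:
                    _bvs_and_posthoc(
                        data.traits[[trait]], X, C, prior, config,
                        seed=config.seed + 100 + selected.index(trait),
                        outdir=outdir, label=f"single_{trait}", run_fdr=False,
                    )

        with _stage(manifest, "bvs_multitrait"):
            multi = _bvs_and_posthoc(
                data.traits[selected], X, C, prior, config,
                seed=config.seed + 200, outdir=outdir, label="multitrait",
            )

        with _stage(manifest, "scan"):
            scan = univariate_scan(data.traits, X, C)
            scan.to_csv(outdir / "scan.tsv", sep="\t", index=False)

        if config.run_attenuation:
            with _stage(manifest, "attenuation"):
                ladders = _attenuation_ladder(data)
                runs = {}
                for label, C_l in ladders.items():
                    Yt, Xt = residualize(data.traits[selected], X, C_l)
                    log = run_guess(
                        Yt, Xt, prior,
                        _sampler_config(config, config.seed + 300),
                    )
                    runs[label] = compute_mppi(log)
                atten = mppi_attenuation(runs)
                atten.to_csv(outdir / "attenuation.tsv", sep="\t", index=False)
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        root.removeHandler(handler)
        handler.close()
    return outdir


def _attenuation_ladder(data) -> dict[str, pd.DataFrame]:
    """Covariate sets of the sequential-adjustment sensitivity analysis."""
    C = data.covariates
    intercept = C[["intercept"]]
    age_sex = C[["intercept", "age", "female"]]
    edu_smoke = C[
        [
            "intercept", "age", "female", "education_intermediate",
            "education_high", "smoking_former", "smoking_current",
        ]
    ]
    return {
        "unadjusted": intercept,
        "age_sex": age_sex,
        "age_sex_education_smoking": edu_smoke,
        "fully_adjusted": C,
    }
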