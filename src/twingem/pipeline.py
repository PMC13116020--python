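"""End-to-end orchestration: configuration, seeding, stage sequencing,
and publication-shaped outputs.

A run either loads a cohort CSV or simulates one, then executes the
requested stages in order — impute, regress, ICC/model selection,
univariate fits, moderation fit with variance profile — writing per-stage
JSON/CSV files and a combined run log.  All randomness flows from one root
seed through named per-stage substreams, so a run is bit-reproducible from
its config.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .data import (
    TwinCohort,
    impute_covariates_median,
    read_cohort,
    residualize_phenotype,
)
from .moderation import fit_moderation, variance_profile
from .regression import fit_individual, fit_mz_pairwise, incremental_r2
from .simulate import (
    ModerationSimSpec,
    RegressionSimSpec,
    UnivariateSimSpec,
    simulate_moderation,
    simulate_regression_cohort,
    simulate_univariate,
)
from .univariate import (
    compare_models,
    fit_saturated,
    fit_univariate,
    intraclass_correlation,
    select_base_model,
)

ALL_STAGES = ("regression", "univariate", "moderation")

_SIM_SPECS = {
    "univariate": (UnivariateSimSpec, simulate_univariate),
    "moderation": (ModerationSimSpec, simulate_moderation),
    "regression": (RegressionSimSpec, simulate_regression_cohort),
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_csv`` or ``simulate`` must be given.
    ``simulate`` is a mapping {"kind": <univariate|moderation|regression>,
    **spec fields}; its seed is derived from the root ``seed``.
    """

    out_dir: str
    input_csv: str | None = None
    simulate: dict | None = None
    stages: tuple = ALL_STAGES
    adjust: str = "full"
    phenotype: str = "walkability"
    seed: int | None = None
    moderation_variant: str = "auto"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.simulate is None):
            raise ValueError("exactly one of input_csv / simulate must be set")
        if self.simulate is not None and self.seed is None:
            raise ValueError("a seed is required whenever a simulation stage is requested")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        return cls(**raw)


def _stage_seed(root: int, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence([root, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _fit_to_dict(fit) -> dict:
    return {
        "coefficients": fit.coefficients.to_dict(),
        "robust_se": fit.robust_se.to_dict(),
        "ci95": {k: [float(v["lower"]), float(v["upper"])] for k, v in fit.ci95.T.items()},
        "r2": fit.r2,
        "n_used": fit.n_used,
        "cluster_count": fit.cluster_count,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the combined report as a dict (also written to
    ``<out_dir>/report.json``).  Any stage error raises
    :class:`PipelineError` naming the stage; outputs written so far are
    preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "versions": {"twingem": __version__, "python": platform.python_version()},
        "seed": config.seed,
        "stages": list(config.stages),
        "counts": {},
    }

    def _write():
        (out / "report.json").write_text(json.dumps(report, indent=2, default=float))

    # --- ingest / simulate -------------------------------------------
    try:
        if config.input_csv is not None:
            path = Path(config.input_csv)
            if not path.exists():
                raise FileNotFoundError(f"input file not found: {path}")
            cohort = read_cohort(str(path))
            sim_kind = None
        else:
            sim = dict(config.simulate)
            sim_kind = sim.pop("kind")
            spec_cls, sim_fn = _SIM_SPECS[sim_kind]
            sim.setdefault("seed", _stage_seed(config.seed, f"simulate-{sim_kind}"))
            cohort = sim_fn(spec_cls(**sim))
            cohort.write_csv(out / "cohort.csv")
    except Exception as exc:
        _write()
        raise PipelineError(f"stage 'ingest': {exc}") from exc
    report["counts"]["cohort"] = cohort.meta
    (out / "cohort_meta.json").write_text(cohort.meta_json())

    # --- impute ------------------------------------------------------
    try:
        n_missing_before = {
            c: int(cohort.df[c].isna().sum())
            for c in ("work_employed", "edu_high", "lives_with_partner", "deprivation_z")
        }
        cohort = impute_covariates_median(cohort)
        report["counts"]["imputed_covariates"] = cohort.imputation_log
        report["counts"]["missing_covariates_before"] = n_missing_before
    except Exception as exc:
        _write()
        raise PipelineError(f"stage 'impute': {exc}") from exc

    # --- regression --------------------------------------------------
    if "regression" in config.stages:
        try:
            from .regression import MINIMAL_COVARIATES, design_from_cohort, fit_ols_cluster

            minimal = fit_individual(cohort, "minimal")
            y, X, cl = design_from_cohort(cohort, MINIMAL_COVARIATES)
            reduced = fit_ols_cluster(y, X.drop(columns="walkability"), cl)
            block = {
                "individual_minimal": _fit_to_dict(minimal),
                "incremental_r2_walkability": incremental_r2(minimal, reduced),
            }
            if config.adjust == "full":
                full = fit_individual(cohort, "full")
                block["individual_full"] = _fit_to_dict(full)
            try:
                block["mz_pairwise"] = _fit_to_dict(fit_mz_pairwise(cohort, config.adjust))
            except ValueError as e:
                block["mz_pairwise"] = {"error": str(e)}
            report["regression"] = block
            (out / "regression.json").write_text(json.dumps(block, indent=2, default=float))
        except Exception as exc:
            _write()
            raise PipelineError(f"stage 'regression': {exc}") from exc

    # --- univariate twin model ---------------------------------------
    if "univariate" in config.stages:
        try:
            resid = residualize_phenotype(cohort, config.phenotype, ("age", "sex"))
            iccs = {
                z: intraclass_correlation(resid, z, config.phenotype)
                for z in ("MZ", "DZ")
            }
            base = select_base_model(iccs["MZ"].icc, iccs["DZ"].icc)
            fits = [
                fit_univariate(resid, m, config.phenotype, ci="none")
                for m in (base, "AE", "CE", "E")
            ]
            # Table-2-shaped comparison against the full base model
            comp = compare_models(fits, reference=base)
            base_fit = fit_univariate(resid, base, config.phenotype, ci="profile")
            sat = fit_saturated(resid, config.phenotype,
                                constraints=("means_order", "means_zygosity"))
            block = {
                "icc": {z: {"icc": r.icc, "ci95": list(r.ci95), "n_pairs": r.n_pairs}
                        for z, r in iccs.items()},
                "base_model": base,
                "model_comparison": comp.as_records(),
                "best_aic_model": comp.best_aic_model,
                "base_fit": {
                    "standardized": base_fit.standardized,
                    "standardized_ci": {k: list(v) for k, v in base_fit.standardized_ci.items()},
                    "aic": base_fit.aic,
                    "loglik": base_fit.loglik,
                },
                "saturated_equal_means_lrt_p": sat.lrt_p,
            }
            report["univariate"] = block
            (out / "univariate.json").write_text(json.dumps(block, indent=2, default=float))
        except Exception as exc:
            _write()
            raise PipelineError(f"stage 'univariate': {exc}") from exc

    # --- moderation --------------------------------------------------
    if "moderation" in config.stages:
        try:
            resid = residualize_phenotype(cohort, "walkability", ("age", "sex"))
            resid = residualize_phenotype(resid, "bmi", ("age", "sex"))
            fit = fit_moderation(resid, config.moderation_variant,
                                 seed=_stage_seed(config.seed or 0, "moderation"))
            walk = resid.df["walkability"].to_numpy(float)
            walk = walk[~np.isnan(walk)]
            grid = np.linspace(walk.min(), walk.max(), 101)
            profile = variance_profile(fit, grid)
            block = {
                "variant": fit.variant,
                "params": {k: float(getattr(fit.params, k))
                           for k in fit.params.free_names(fit.variant)},
                "loglik": fit.loglik,
                "aic": fit.aic,
                "n_pairs_used": fit.n_pairs_used,
                "n_pairs_excluded": fit.n_pairs_excluded,
                "comparison": fit.comparison,
                "intersections": profile.intersections,
            }
            profile.as_table().to_csv(out / "variance_profile.csv", index=False)
            report["moderation"] = block
            (out / "moderation.json").write_text(json.dumps(block, indent=2, default=float))
        except Exception as exc:
            _write()
            raise PipelineError(f"stage 'moderation': {exc}") from exc

    _write()
    return report
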