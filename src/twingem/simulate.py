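"""Synthetic twin-cohort generators.

Three generators, one per analysis stage:

* :func:`simulate_univariate` — a univariate ACE/ADE phenotype on twin
  pairs, for variance-decomposition recovery.  Additive-genetic latents
  correlate 1 within MZ and 0.5 within DZ pairs (0.25 for dominance),
  shared-environment latents are identical within a pair, unique-environment
  latents are independent.
* :func:`simulate_moderation` — a moderator with its own ACE structure plus
  a trait whose Cholesky loadings are linear in the twin's own realized
  moderator value (definition-variable convention), for GxE moderation
  recovery.
* :func:`simulate_regression_cohort` — walkability/BMI cohorts with
  pair-clustered residuals and optional walkability-correlated covariates,
  for regression recovery.

All latents are standard normal and phenotypes Gaussian, matching the
multivariate-normal likelihood of the fitting modules.  Defaults mirror the
study conditions: 477 MZ + 734 DZ complete pairs, walkability mean 43.4
(SD 12.0), BMI mean 26.5 (SD ~5.1), walkability variance split
A/C/E = 0.22/0.22/0.56.  Every generator is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MZ, DZ, TwinCohort, CANONICAL_COLUMNS

__all__ = [
    "UnivariateSimSpec",
    "ModerationSimSpec",
    "RegressionSimSpec",
    "simulate_univariate",
    "simulate_moderation",
    "simulate_regression_cohort",
]


def _demographics(rng: np.random.Generator, n: int) -> dict:
    return {
        "work_employed": (rng.random(n) < 0.89).astype(float),
        "edu_high": (rng.random(n) < 0.62).astype(float),
        "lives_with_partner": (rng.random(n) < 0.72).astype(float),
        "deprivation_z": rng.normal(0.0, 1.0, n),
    }


def _assemble_cohort(
    rng: np.random.Generator,
    zygosity: np.ndarray,  # per pair
    twin_values: dict[str, np.ndarray],  # phenotype -> (n_pairs, 2)
    singleton_fraction: float = 0.0,
    covariates: dict[str, np.ndarray] | None = None,  # per individual (2n,)
    age: np.ndarray | None = None,  # per pair
    sex: np.ndarray | None = None,  # (n_pairs, 2) of {"male","female"}
) -> TwinCohort:
    n = len(zygosity)
    if age is None:
        age = rng.normal(42.6, 5.2, n)
    if sex is None:
        sex = np.empty((n, 2), dtype=object)
        for i, z in enumerate(zygosity):
            if z == MZ:
                sex[i, :] = "female" if rng.random() < 0.6 else "male"
            else:
                sex[i, 0] = "female" if rng.random() < 0.6 else "male"
                sex[i, 1] = "female" if rng.random() < 0.6 else "male"
    keep_twin2 = rng.random(n) >= singleton_fraction

    idx = np.arange(n)
    pair_idx = np.repeat(idx, 2)
    order = np.tile([1, 2], n)
    keep = (order == 1) | keep_twin2[pair_idx]
    pair_idx, order = pair_idx[keep], order[keep]
    df = pd.DataFrame(
        {
            "person_id": [f"p{i:05d}_{j}" for i, j in zip(pair_idx, order)],
            "pair_id": [f"fam{i:05d}" for i in pair_idx],
            "zygosity": zygosity[pair_idx],
            "sex": sex[pair_idx, order - 1],
            "age": age[pair_idx],
        }
    )
    for ph, vals in twin_values.items():
        df[ph] = vals[pair_idx, order - 1]
    m = len(df)
    cov = covariates if covariates is not None else _demographics(rng, m)
    for name in ("work_employed", "edu_high", "lives_with_partner", "deprivation_z"):
        df[name] = np.asarray(cov[name], float)[:m]
    for col in ("bmi", "walkability"):
        if col not in df.columns:
            df[col] = np.nan
    return TwinCohort(df[list(CANONICAL_COLUMNS)])


def _kinship_latents(
    rng: np.random.Generator, n: int, r: float
) -> np.ndarray:
    """(n, 2) standard-normal latents with within-pair correlation ``r``."""
    shared = rng.normal(size=n)
    own = rng.normal(size=(n, 2))
    return np.sqrt(r) * shared[:, None] + np.sqrt(1.0 - r) * own


@dataclass(frozen=True)
class UnivariateSimSpec:
    """Generative truth for the univariate twin model.

    ``a2``/``c2``/``d2``/``e2`` are standardized variance proportions
    (``c2`` and ``d2`` are mutually exclusive); ``total_var`` and ``mean``
    set the phenotype scale.
    """

    n_mz_pairs: int = 477
    n_dz_pairs: int = 734
    a2: float = 0.22
    c2: float = 0.22
    d2: float = 0.0
    e2: float = 0.56
    total_var: float = 144.0
    mean: float = 43.4
    singleton_fraction: float = 0.0
    phenotype: str = "walkability"
    seed: int = 0

    def validate(self) -> None:
        props = (self.a2, self.c2, self.d2, self.e2)
        if any(p < 0 for p in props):
            raise ValueError("variance proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-8:
            raise ValueError("variance proportions must sum to 1 (within 1e-8)")
        if self.c2 > 0 and self.d2 > 0:
            raise ValueError("specify shared environment (c2) or dominance (d2), not both")
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be non-negative")
        if not 0.0 <= self.singleton_fraction < 1.0:
            raise ValueError("singleton_fraction must be in [0, 1)")


def simulate_univariate(spec: UnivariateSimSpec) -> TwinCohort:
    """Simulate a twin cohort under the ACE (or ADE) generative model.

    Each twin's phenotype is ``mean + sqrt(total_var) * (a*A + c*C + e*E)``
    (``d*D`` replacing ``c*C`` under ADE) with standard-normal latents.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    a, c, d, e = (np.sqrt(spec.a2), np.sqrt(spec.c2), np.sqrt(spec.d2), np.sqrt(spec.e2))
    sd = np.sqrt(spec.total_var)

    blocks = []
    zygs = []
    for zyg, n, rA, rD in ((MZ, spec.n_mz_pairs, 1.0, 1.0), (DZ, spec.n_dz_pairs, 0.5, 0.25)):
        if n == 0:
            continue
        A = _kinship_latents(rng, n, rA)
        C = rng.normal(size=n)[:, None] * np.ones((1, 2))
        D = _kinship_latents(rng, n, rD)
        E = rng.normal(size=(n, 2))
        pheno = spec.mean + sd * (a * A + c * C + d * D + e * E)
        blocks.append(pheno)
        zygs.append(np.full(n, zyg, dtype=object))
    values = np.vstack(blocks) if blocks else np.empty((0, 2))
    zygosity = np.concatenate(zygs) if zygs else np.empty(0, dtype=object)
    return _assemble_cohort(
        rng, zygosity, {spec.phenotype: values}, singleton_fraction=spec.singleton_fraction
    )


@dataclass(frozen=True)
class ModerationSimSpec:
    """Generative truth for the bivariate Cholesky moderation model.

    The moderator M (walkability, residualized scale around ``mu_m``) has its
    own ACE structure (``a_m``, ``c_m``, ``e_m``, index units).  The trait T
    (BMI, around ``mu_t``) loads on the moderator's A and E common factors
    via shared paths ``a_c``, ``e_c`` (optionally a shared-C path ``c_c``)
    and on its own unique factors via ``a_u``, ``e_u``; each loading is
    moderated linearly by the twin's own realized (centered) moderator value
    with slope ``beta_*`` (kg/m^2 per latent unit per index unit).

    Defaults place the moderator at the walkability variance decomposition
    (A/C/E = 0.22/0.22/0.56 of 144) and the trait at an AE structure with
    variance ~26 (kg/m^2)^2 and an additive-genetic share of ~0.65 at the
    moderator's center, with moderation betas that make unique-environment
    variance dominate at both moderator extremes.
    """

    n_mz_pairs: int = 477
    n_dz_pairs: int = 734
    # moderator paths (index units)
    a_m: float = float(np.sqrt(0.22 * 144.0))
    c_m: float = float(np.sqrt(0.22 * 144.0))
    e_m: float = float(np.sqrt(0.56 * 144.0))
    # shared (cross-trait) paths, kg/m^2 per latent unit
    a_c: float = -0.6
    e_c: float = -0.25
    c_c: float = 0.0
    # trait-unique paths
    a_u: float = 4.06
    e_u: float = 3.0
    # moderation betas, kg/m^2 per latent unit per index unit
    beta_ac: float = 0.0
    beta_ec: float = 0.05
    beta_au: float = -0.05
    beta_eu: float = 0.4
    beta_cc: float = 0.0
    gamma_m: float = 0.0  # optional linear effect of M on the trait mean
    mu_m: float = 43.4
    mu_t: float = 26.5
    seed: int = 0

    def validate(self) -> None:
        if self.a_m**2 + self.c_m**2 + self.e_m**2 <= 0:
            raise ValueError("moderator variance must be positive")
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise ValueError("pair counts must be non-negative")


def simulate_moderation(spec: ModerationSimSpec) -> TwinCohort:
    """Simulate co-twin (moderator, trait) observations under GxE moderation.

    Walkability column holds ``mu_m + M``, BMI column ``mu_t + T``.  The
    moderation operates on the centered moderator ``M`` (the fitting module
    expects a residualized/centered moderator as the definition variable).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    blocks_m, blocks_t, zygs = [], [], []
    for zyg, n, r in ((MZ, spec.n_mz_pairs, 1.0), (DZ, spec.n_dz_pairs, 0.5)):
        if n == 0:
            continue
        A_c = _kinship_latents(rng, n, r)  # common A factor per twin
        C_c = rng.normal(size=n)[:, None] * np.ones((1, 2))
        E_c = rng.normal(size=(n, 2))
        A_u = _kinship_latents(rng, n, r)
        E_u = rng.normal(size=(n, 2))
        M = spec.a_m * A_c + spec.c_m * C_c + spec.e_m * E_c
        T = (
            (spec.a_c + spec.beta_ac * M) * A_c
            + (spec.c_c + spec.beta_cc * M) * C_c
            + (spec.e_c + spec.beta_ec * M) * E_c
            + (spec.a_u + spec.beta_au * M) * A_u
            + (spec.e_u + spec.beta_eu * M) * E_u
            + spec.gamma_m * M
        )
        blocks_m.append(spec.mu_m + M)
        blocks_t.append(spec.mu_t + T)
        zygs.append(np.full(n, zyg, dtype=object))
    walk = np.vstack(blocks_m)
    bmi = np.vstack(blocks_t)
    zygosity = np.concatenate(zygs)
    return _assemble_cohort(rng, zygosity, {"walkability": walk, "bmi": bmi})


@dataclass(frozen=True)
class RegressionSimSpec:
    """Generative truth for regression recovery cohorts.

    ``slope`` is the conditional (covariate-adjusted) walkability effect on
    BMI in kg/m^2 per index unit.  ``covariate_effects`` gives each
    covariate's additive effect on BMI; ``covariate_walkability_corr`` gives
    the latent correlation between each covariate and walkability (binary
    covariates are thresholded latents), inducing confounding when both are
    nonzero.  Residual BMI noise has SD ``noise_sd`` and within-pair
    correlation ``bmi_pair_corr``; walkability itself shares
    ``walkability_pair_corr`` within pairs.
    """

    n_pairs: int = 2156
    slope: float = -0.04
    walk_mean: float = 43.4
    walk_sd: float = 12.0
    bmi_mean: float = 26.5
    noise_sd: float = 5.0
    bmi_pair_corr: float = 0.5
    walkability_pair_corr: float = 0.4
    age_effect: float = 0.05
    female_effect: float = -1.0
    covariate_effects: dict = field(
        default_factory=lambda: {
            "work_employed": 0.0,
            "edu_high": 0.0,
            "lives_with_partner": 0.0,
            "deprivation_z": 0.0,
        }
    )
    covariate_walkability_corr: dict = field(default_factory=dict)
    mz_fraction: float = 477.0 / 1211.0
    singleton_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name, rho in (
            ("bmi_pair_corr", self.bmi_pair_corr),
            ("walkability_pair_corr", self.walkability_pair_corr),
        ):
            if not abs(rho) < 1.0:
                raise ValueError(f"{name} must satisfy |rho| < 1")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


_COV_PREVALENCE = {"work_employed": 0.89, "edu_high": 0.62, "lives_with_partner": 0.72}


def simulate_regression_cohort(spec: RegressionSimSpec) -> TwinCohort:
    """Simulate a walkability/BMI cohort with pair-clustered residuals.

    BMI = intercept + slope*walkability + age/sex effects + covariate
    effects + pair-shared noise + individual noise, with the intercept set
    from the covariates' expected values so that E[BMI] = ``bmi_mean``.
    """
    from scipy.stats import norm

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pairs
    walk = spec.walk_mean + spec.walk_sd * _kinship_latents(
        rng, n, spec.walkability_pair_corr
    )
    age = rng.normal(42.6, 5.2, n)
    zygosity = np.where(rng.random(n) < spec.mz_fraction, MZ, DZ).astype(object)
    sex = np.empty((n, 2), dtype=object)
    for i in range(n):
        if zygosity[i] == MZ:
            sex[i, :] = "female" if rng.random() < 0.6 else "male"
        else:
            sex[i, :] = ["female" if rng.random() < 0.6 else "male" for _ in range(2)]
    female = (sex == "female").astype(float)

    # covariates per individual, optionally correlated with walkability
    walk_z = (walk - spec.walk_mean) / spec.walk_sd
    cov_vals: dict[str, np.ndarray] = {}
    expected: dict[str, float] = {}
    for name in ("work_employed", "edu_high", "lives_with_partner", "deprivation_z"):
        rho = float(spec.covariate_walkability_corr.get(name, 0.0))
        latent = rho * walk_z + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=(n, 2))
        if name == "deprivation_z":
            cov_vals[name] = latent
            expected[name] = 0.0
        else:
            p = _COV_PREVALENCE[name]
            cov_vals[name] = (latent < norm.ppf(p)).astype(float)
            expected[name] = p

    effects = dict(spec.covariate_effects)
    intercept = (
        spec.bmi_mean
        - spec.slope * spec.walk_mean
        - spec.age_effect * 42.6
        - spec.female_effect * 0.6
        - sum(effects.get(k, 0.0) * expected[k] for k in expected)
    )
    noise = spec.noise_sd * _kinship_latents(rng, n, spec.bmi_pair_corr)
    bmi = (
        intercept
        + spec.slope * walk
        + spec.age_effect * age[:, None]
        + spec.female_effect * female
        + sum(effects.get(k, 0.0) * cov_vals[k] for k in cov_vals)
        + noise
    )
    covariates = {k: v.reshape(-1) for k, v in cov_vals.items()}
    # _assemble_cohort flattens twin-major per pair; reshape matches row order
    # only when no singletons are dropped before covariate assignment, so we
    # pre-flatten in the same (pair, twin) order and drop afterwards.
    cohort = _assemble_cohort(
        rng,
        zygosity,
        {"walkability": walk, "bmi": bmi},
        singleton_fraction=0.0,
        covariates=covariates,
        age=age,
        sex=sex,
    )
    if spec.singleton_fraction > 0:
        drop = rng.random(n) < spec.singleton_fraction
        drop_ids = {f"p{i:05d}_2" for i in range(n) if drop[i]}
        df = cohort.df[~cohort.df["person_id"].isin(drop_ids)].reset_index(drop=True)
        cohort = TwinCohort(df)
    return cohort
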