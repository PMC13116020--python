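"""Individual-level and co-twin-control regression of BMI on walkability.

``fit_ols_cluster`` gives ordinary-least-squares point estimates with
pair-clustered sandwich standard errors (small-sample factor
G/(G-1) * (n-1)/(n-k)), the standard fix for the non-independence of
co-twins in individual-level models.  ``fit_mz_pairwise`` is the MZ
co-twin-control design: regressing within-pair BMI differences on
within-pair walkability differences cancels everything the co-twins share
(all genetic and early shared-environment confounding), so a pair-level
confounder that drives the individual-level association leaves the
within-pair slope at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import MZ, TwinCohort, BINARY_COVARIATES

MINIMAL_COVARIATES = ("age", "sex")
FULL_COVARIATES = MINIMAL_COVARIATES + (
    "work_employed",
    "edu_high",
    "lives_with_partner",
    "deprivation_z",
)


@dataclass
class RegressionFit:
    """OLS fit summary: estimates, (robust) SEs, normal-quantile 95% CIs."""

    coefficients: pd.Series
    robust_se: pd.Series
    ci95: pd.DataFrame  # columns "lower", "upper"
    r2: float
    n_used: int
    cluster_count: int

    def __getitem__(self, term: str) -> float:
        return float(self.coefficients[term])


def _package_fit(params, bse, r2, n_used, cluster_count) -> RegressionFit:
    ci = pd.DataFrame(
        {"lower": params - 1.96 * bse, "upper": params + 1.96 * bse},
        index=params.index,
    )
    return RegressionFit(
        coefficients=params,
        robust_se=bse,
        ci95=ci,
        r2=float(r2),
        n_used=int(n_used),
        cluster_count=int(cluster_count),
    )


def fit_ols_cluster(
    y: np.ndarray, X: pd.DataFrame, clusters: np.ndarray
) -> RegressionFit:
    """OLS with cluster-robust (sandwich) SEs grouped by twin pair.

    Point estimates are ordinary least squares; only the standard errors
    change with clustering.  ``X`` must be a complete-case design frame
    (an intercept is added if absent).
    """
    X = pd.DataFrame(X).copy()
    if "const" not in X.columns and not (X.nunique() == 1).any():
        X.insert(0, "const", 1.0)
    y = np.asarray(y, float)
    groups = pd.factorize(np.asarray(clusters))[0]
    n, k = X.shape
    g = len(np.unique(groups))
    if g < 2:
        raise ValueError("need at least 2 clusters")
    if g < k:
        raise ValueError(f"fewer clusters ({g}) than parameters ({k})")
    if np.linalg.matrix_rank(X.to_numpy(float)) < k:
        raise ValueError("singular design matrix")
    model = sm.OLS(y, X)
    res = model.fit()
    if res.ssr <= 1e-12 * max(1.0, float(np.sum(y**2))):
        # perfect fit: sandwich is identically zero, statsmodels would warn
        bse = pd.Series(0.0, index=res.params.index)
        return _package_fit(res.params, bse, 1.0, n, g)
    robust = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
    return _package_fit(robust.params, robust.bse, robust.rsquared, n, g)


def incremental_r2(full: RegressionFit, reduced: RegressionFit) -> float:
    """R-squared gained by the terms present in ``full`` but not ``reduced``.

    Both fits must be on the same observations with nested designs.
    """
    if full.n_used != reduced.n_used:
        raise ValueError("fits use different observation counts; designs not comparable")
    if not set(reduced.coefficients.index) <= set(full.coefficients.index):
        raise ValueError("reduced design is not nested in the full design")
    return max(0.0, full.r2 - reduced.r2)


def design_from_cohort(
    cohort: TwinCohort, covariates=MINIMAL_COVARIATES, outcome: str = "bmi"
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Complete-case (y, X, clusters) for the individual-level model.

    X has walkability first, then the requested covariates (sex coded
    female=1).  Covariates should be imputed beforehand.
    """
    df = cohort.df.copy()
    df["sex"] = (df["sex"] == "female").astype(float)
    cols = ["walkability", *covariates]
    use = df.dropna(subset=[outcome, *cols])
    X = use[cols].astype(float)
    X.insert(0, "const", 1.0)
    return use[outcome].to_numpy(float), X, use["pair_id"].to_numpy()


def fit_individual(
    cohort: TwinCohort, adjust: str = "minimal", outcome: str = "bmi"
) -> RegressionFit:
    """Individual-level cluster-robust OLS of BMI on walkability.

    ``adjust``: "minimal" (age, sex) or "full" (adds work status, education,
    living status, community deprivation z-score).
    """
    covs = MINIMAL_COVARIATES if adjust == "minimal" else FULL_COVARIATES
    y, X, cl = design_from_cohort(cohort, covs, outcome)
    return fit_ols_cluster(y, X, cl)


def fit_individual_stratified(
    cohort: TwinCohort, by: str = "sex", adjust: str = "minimal",
    outcome: str = "bmi",
) -> dict:
    """Individual-level fits within strata of ``by`` (currently "sex").

    Sex is dropped from the covariate set inside sex strata (it is
    constant there).
    """
    if by != "sex":
        raise ValueError(f"unsupported stratification variable {by!r}")
    out = {}
    covs = MINIMAL_COVARIATES if adjust == "minimal" else FULL_COVARIATES
    covs = tuple(c for c in covs if c != "sex")
    for level in ("male", "female"):
        sub = cohort.df[cohort.df["sex"] == level]
        if sub.empty:
            continue
        y, X, cl = design_from_cohort(
            TwinCohort(sub.reset_index(drop=True)), covs, outcome
        )
        out[level] = fit_ols_cluster(y, X, cl)
    return out


def fit_mz_pairwise(
    cohort: TwinCohort, adjust: str = "minimal", outcome: str = "bmi"
) -> RegressionFit:
    """Co-twin-control regression on MZ within-pair differences.

    Response and predictor are twin1 - twin2 differences of BMI and
    walkability (canonical within-pair order); continuous covariates are
    differenced, binary covariates enter as signed discordance codes
    (-1/0/+1), sex enters as the pair-level value (well defined for MZ),
    and age is excluded (co-twins share it).  Classical OLS standard errors
    (no clustering: one observation per pair).
    """
    phenos = [outcome, "walkability"]
    covs = [] if adjust == "minimal" else list(BINARY_COVARIATES) + ["deprivation_z"]
    wide = cohort.df[cohort.df["zygosity"] == MZ]
    if wide.empty:
        raise ValueError("no MZ pairs in cohort")
    sub = TwinCohort(wide.reset_index(drop=True))
    table = sub.paired_table(phenos + covs)
    if table.empty:
        raise ValueError("no complete MZ pairs with both phenotypes present")
    y = (table[f"{outcome}_1"] - table[f"{outcome}_2"]).to_numpy(float)
    X = pd.DataFrame(index=table.index)
    X["const"] = 1.0
    X["d_walkability"] = table["walkability_1"] - table["walkability_2"]
    sex_by_pair = (
        wide.drop_duplicates("pair_id").set_index("pair_id")["sex"] == "female"
    ).astype(float)
    X["female"] = sex_by_pair.reindex(table.index).to_numpy()
    for c in covs:
        X[f"d_{c}"] = table[f"{c}_1"] - table[f"{c}_2"]
    if float(np.var(X["d_walkability"])) == 0.0:
        raise ValueError(
            "within-pair walkability differences have zero variance; "
            "co-twins identical on the predictor, pairwise model not estimable"
        )
    keep = [
        c
        for c in X.columns
        if c in ("const", "d_walkability") or X[c].nunique() > 1
    ]
    X = X[keep]
    res = sm.OLS(y, X).fit()
    return _package_fit(res.params, res.bse, res.rsquared, len(y), len(y))
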