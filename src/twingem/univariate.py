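"""Univariate twin models: intraclass correlations, Falconer's closed form,
saturated assumption tests, and FIML fitting of the ACE family.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C) or dominance genetic (D), and unique
environmental (E) components from the contrast between MZ pairs (who share
all segregating alleles) and DZ pairs (who share half, a quarter for
dominance deviations).  Models are parameterized in path coefficients
(a, c, e); the implied within-pair covariance is

    diag = a^2 + c^2 + e^2            (ADE: a^2 + d^2 + e^2)
    MZ off-diagonal = a^2 + c^2       (ADE: a^2 + d^2)
    DZ off-diagonal = a^2/2 + c^2     (ADE: a^2/2 + d^2/4)

Fitting is full-information maximum likelihood: complete pairs contribute
bivariate-normal terms, singletons univariate-normal terms, with one mean
shared across twins and zygosities.  Confidence intervals for the
standardized components are profile-likelihood intervals at the chi-square
3.84 cutoff by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data import MZ, DZ, TwinCohort

_LOG2PI = np.log(2.0 * np.pi)

MODELS = ("ACE", "ADE", "AE", "CE", "E")
#: free path coefficients per model (a mean parameter is always added)
_MODEL_PATHS = {
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

@dataclass
class IccResult:
    zygosity: str
    icc: float
    ci95: tuple[float, float]
    n_pairs: int


def intraclass_correlation(
    cohort: TwinCohort, zygosity: str, phenotype: str = "walkability"
) -> IccResult:
    """ML intraclass correlation for complete pairs of one zygosity.

    The estimate maximizes the bivariate-normal likelihood under equal
    means and variances across twin order (the constrained saturated
    model); the 95% CI is the Fisher-z interval
    atanh(r) +/- 1.96 / sqrt(n - 3/2).
    """
    pairs = cohort.paired_values(phenotype, zygosity)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >= 3 complete {zygosity} pairs, got {n}")
    mu0 = pairs.mean()
    v0 = pairs.var()
    d = pairs - mu0
    r0 = float(np.clip((d[:, 0] * d[:, 1]).mean() / v0, -0.99, 0.99))

    def nll(theta):
        mu, logv, z = theta
        v = np.exp(logv)
        r = float(np.clip(np.tanh(z), -1 + 1e-12, 1 - 1e-12))
        det = v * v * (1 - r * r)
        d0 = pairs[:, 0] - mu
        d1 = pairs[:, 1] - mu
        q = (d0 * d0 - 2 * r * d0 * d1 + d1 * d1) / (v * (1 - r * r))
        return 0.5 * (n * (2 * _LOG2PI + np.log(det)) + q.sum())

    res = optimize.minimize(
        nll, x0=[mu0, np.log(v0), np.arctanh(r0)], method="BFGS",
        options={"gtol": 1e-8},
    )
    icc = float(np.tanh(res.x[2]))
    half = 1.96 / np.sqrt(n - 1.5)
    lo, hi = np.tanh(res.x[2] - half), np.tanh(res.x[2] + half)
    return IccResult(zygosity=zygosity, icc=icc, ci95=(float(lo), float(hi)), n_pairs=n)


# ---------------------------------------------------------------------------
# closed forms and model selection
# ---------------------------------------------------------------------------

def falconer_decomposition(r_mz: float, r_dz: float) -> tuple[float, float, float, bool]:
    """Falconer's closed-form (A, C, E) from twin correlations.

    A = 2(r_MZ - r_DZ), C = 2 r_DZ - r_MZ, E = 1 - r_MZ.  Values are
    returned unclamped; the fourth element flags any component outside
    [0, 1].
    """
    A = 2.0 * (r_mz - r_dz)
    C = 2.0 * r_dz - r_mz
    E = 1.0 - r_mz
    out_of_range = any(not (0.0 <= x <= 1.0) for x in (A, C, E))
    return A, C, E, out_of_range


def select_base_model(r_mz: float, r_dz: float) -> str:
    """ADE iff r_MZ strictly exceeds twice r_DZ (no room for shared
    environment), otherwise ACE."""
    return "ADE" if r_mz > 2.0 * r_dz else "ACE"


@dataclass
class UnivariateParams:
    """Path coefficients in phenotype-SD-free (original) units.

    ``c_or_d`` is the shared-environment path for ACE/AE/CE and the
    dominance path for ADE; the square of each path is the unstandardized
    variance it contributes.  Paths are reported non-negative (the sign is
    not identified).
    """

    model: str
    a: float
    c_or_d: float
    e: float

    @property
    def total_variance(self) -> float:
        return self.a**2 + self.c_or_d**2 + self.e**2


def expected_cov_univariate(params: UnivariateParams, zygosity: str) -> np.ndarray:
    """Model-implied 2x2 co-twin covariance for one zygosity."""
    a2 = params.a**2
    x2 = params.c_or_d**2
    total = a2 + x2 + params.e**2
    if params.model == "ADE":
        off = a2 + x2 if zygosity == MZ else 0.5 * a2 + 0.25 * x2
    else:
        off = a2 + x2 if zygosity == MZ else 0.5 * a2 + x2
    return np.array([[total, off], [off, total]])


# ---------------------------------------------------------------------------
# FIML machinery
# ---------------------------------------------------------------------------

def _pair_nll(pairs: np.ndarray, mu: float, total: float, off: float) -> float:
    """Negative bivariate-normal loglik for (n,2) pairs, common mean/variance."""
    if len(pairs) == 0:
        return 0.0
    det = total * total - off * off
    if det <= 0 or total <= 0:
        return np.inf
    d0 = pairs[:, 0] - mu
    d1 = pairs[:, 1] - mu
    q = (total * (d0 * d0 + d1 * d1) - 2 * off * d0 * d1) / det
    return 0.5 * (len(pairs) * (2 * _LOG2PI + np.log(det)) + q.sum())


def _single_nll(x: np.ndarray, mu: float, total: float) -> float:
    if len(x) == 0:
        return 0.0
    if total <= 0:
        return np.inf
    d = x - mu
    return 0.5 * (len(x) * (_LOG2PI + np.log(total)) + (d * d).sum() / total)


def univariate_loglik(
    params: UnivariateParams,
    mu: float,
    mz_pairs: np.ndarray,
    dz_pairs: np.ndarray,
    singles: np.ndarray,
) -> float:
    """FIML log-likelihood of the data under ``params`` with mean ``mu``.

    Complete pairs contribute bivariate-normal terms with the model-implied
    covariance; singletons contribute univariate terms with the total
    variance.  Exposed so its agreement with a general multivariate-normal
    density can be checked independently.
    """
    cov_mz = expected_cov_univariate(params, MZ)
    cov_dz = expected_cov_univariate(params, DZ)
    nll = (
        _pair_nll(mz_pairs, mu, cov_mz[0, 0], cov_mz[0, 1])
        + _pair_nll(dz_pairs, mu, cov_dz[0, 0], cov_dz[0, 1])
        + _single_nll(singles, mu, cov_mz[0, 0])
    )
    return -nll


@dataclass
class UnivariateFit:
    params: UnivariateParams
    mean: float
    loglik: float
    aic: float
    n_pairs_used: int
    n_singletons_used: int
    standardized: dict  # component -> proportion
    standardized_ci: dict  # component -> (lo, hi)
    ci_method: str
    e_at_bound: bool = False
    n_free_params: int = 0

    @property
    def component_labels(self) -> tuple[str, ...]:
        return tuple(self.standardized)


def _extract_arrays(cohort: TwinCohort, phenotype: str):
    mz = cohort.paired_values(phenotype, MZ)
    dz = cohort.paired_values(phenotype, DZ)
    singles = cohort.singleton_values(phenotype)
    return mz, dz, singles


def _moment_start(mz, dz, singles, model):
    """Falconer-style moment starting values on the data's own scale."""
    allv = np.concatenate([mz.ravel(), dz.ravel(), singles])
    mu = float(allv.mean())
    var = float(allv.var())

    def _corr(p):
        if len(p) < 3:
            return 0.0
        d = p - p.mean()
        return float(np.clip((d[:, 0] * d[:, 1]).mean() / p.var(), -0.95, 0.95))

    r_mz, r_dz = _corr(mz), _corr(dz)
    A, C, E, _ = falconer_decomposition(r_mz, r_dz)
    props = {"a": A, "c": C, "d": max(0.0, 2 * (2 * r_mz - r_dz) - A), "e": E}
    paths = _MODEL_PATHS[model]
    p0 = []
    floor = 0.05
    for name in paths:
        key = "c" if name == "c" else name
        prop = max(floor, props.get(key, 0.3))
        p0.append(np.sqrt(prop * var))
    return mu, np.array(p0), var


def _fit_ml(nll, x0, jitter_scale, n_restarts, rng):
    """Minimize ``nll`` from x0 and jittered restarts; return best result."""
    best = None
    starts = [np.asarray(x0, float)]
    for _ in range(n_restarts):
        starts.append(x0 * (1.0 + 0.2 * rng.standard_normal(len(x0))) + 0.01 * jitter_scale * rng.standard_normal(len(x0)))
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nll, s, method="BFGS", options={"gtol": 1e-8, "maxiter": 2000})
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        raise RuntimeError("FIML optimization failed to converge from any start")
    return best


def fit_univariate(
    cohort: TwinCohort,
    model: str = "ACE",
    phenotype: str = "walkability",
    ci: str = "profile",
    n_restarts: int = 5,
    seed: int = 0,
) -> UnivariateFit:
    """Fit a univariate twin model by FIML.

    The phenotype should be residualized (age, sex) beforehand; pass the
    cohort through :func:`twingem.data.residualize_phenotype` first.

    Parameters
    ----------
    ci
        "profile" (likelihood-based, chi-square 3.84 cutoff), "delta"
        (normal approximation), or "none".
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    mz, dz, singles = _extract_arrays(cohort, phenotype)
    if model != "E" and (len(mz) < 10 or len(dz) < 10):
        raise ValueError(
            f"need >= 10 complete pairs per zygosity (got MZ={len(mz)}, DZ={len(dz)})"
        )
    mu0, p0, var0 = _moment_start(mz, dz, singles, model)
    paths = _MODEL_PATHS[model]
    rng = np.random.default_rng(seed)

    def nll(theta):
        mu = theta[0]
        vals = dict(zip(paths, theta[1:]))
        params = UnivariateParams(
            model=model,
            a=vals.get("a", 0.0),
            c_or_d=vals.get("c", vals.get("d", 0.0)),
            e=vals["e"],
        )
        return -univariate_loglik(params, mu, mz, dz, singles)

    best = _fit_ml(nll, np.concatenate([[mu0], p0]), np.sqrt(var0), n_restarts, rng)
    theta = best.x
    vals = {name: abs(v) for name, v in zip(paths, theta[1:])}  # canonical sign
    params = UnivariateParams(
        model=model,
        a=vals.get("a", 0.0),
        c_or_d=vals.get("c", vals.get("d", 0.0)),
        e=vals["e"],
    )
    loglik = -float(best.fun)
    k = 1 + len(paths)
    total = params.total_variance
    comp_label = "D" if model == "ADE" else "C"
    std = {
        "A": params.a**2 / total,
        comp_label: params.c_or_d**2 / total,
        "E": params.e**2 / total,
    }
    if model == "AE":
        std.pop(comp_label)
    elif model == "CE":
        std.pop("A")
    elif model == "E":
        std = {"E": 1.0}
    e_at_bound = params.e**2 < 1e-6 * total
    if e_at_bound:
        warnings.warn("unique-environment path estimated at its lower bound", RuntimeWarning)

    ci_out: dict = {}
    ci_method = ci
    if ci == "profile":
        ci_out, ci_method = _profile_cis(std, loglik, model, paths, mz, dz, singles, theta)
    elif ci == "delta":
        ci_out = _delta_cis(std, nll, theta, paths, model)
    return UnivariateFit(
        params=params,
        mean=float(theta[0]),
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        n_pairs_used=len(mz) + len(dz),
        n_singletons_used=len(singles),
        standardized=std,
        standardized_ci=ci_out,
        ci_method=ci_method,
        e_at_bound=bool(e_at_bound),
        n_free_params=k,
    )


def _nll_at_fixed_share(h, comp, model, paths, mz, dz, singles, theta_hat):
    """Profile NLL with one standardized component fixed at ``h``.

    Free parameters: mean, log total variance, and (for three-component
    models) a logit split of the remaining share between the other two
    components.
    """
    comp_label = "D" if model == "ADE" else "C"
    labels = ["A", comp_label, "E"][: len(paths)] if len(paths) == 3 else (
        ["A", "E"] if model == "AE" else ["C", "E"] if model == "CE" else ["E"]
    )
    others = [l for l in labels if l != comp]

    vals_hat = {n: v for n, v in zip(paths, theta_hat[1:])}
    total_hat = sum(v * v for v in vals_hat.values())

    def props_from(free):
        if len(others) == 2:
            w = 1.0 / (1.0 + np.exp(-free[0]))
            rest = {others[0]: (1 - h) * w, others[1]: (1 - h) * (1 - w)}
        else:
            rest = {others[0]: 1 - h}
        rest[comp] = h
        return rest

    def nll(free):
        mu = free[0]
        logv = free[1]
        split = free[2:]
        pr = props_from(split)
        total = np.exp(logv)
        lab2path = {"A": "a", "C": "c", "D": "d", "E": "e"}
        vals = {lab2path[l]: np.sqrt(max(pr[l], 0.0) * total) for l in pr}
        params = UnivariateParams(
            model=model,
            a=vals.get("a", 0.0),
            c_or_d=vals.get("c", vals.get("d", 0.0)),
            e=vals.get("e", 0.0),
        )
        return -univariate_loglik(params, mu, mz, dz, singles)

    x0 = [theta_hat[0], np.log(total_hat)]
    if len(others) == 2:
        x0.append(0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
    return float(res.fun)


def _profile_cis(std, loglik, model, paths, mz, dz, singles, theta_hat):
    """Profile-likelihood 95% CIs for each standardized component."""
    cutoff = stats.chi2.ppf(0.95, df=1)  # 3.84
    out = {}
    method = "profile"
    for comp, h_hat in std.items():
        if model == "E":
            out[comp] = (1.0, 1.0)
            continue

        def dev(h):
            return 2.0 * (_nll_at_fixed_share(h, comp, model, paths, mz, dz, singles, theta_hat) + loglik) - cutoff

        eps = 1e-6
        try:
            lo = 0.0 if dev(eps) <= 0 else optimize.brentq(dev, eps, max(h_hat, 2 * eps), xtol=1e-5)
            hi = 1.0 if dev(1 - eps) <= 0 else optimize.brentq(dev, min(h_hat, 1 - 2 * eps), 1 - eps, xtol=1e-5)
            out[comp] = (float(lo), float(hi))
        except ValueError:
            method = "delta-fallback"
            out[comp] = (np.nan, np.nan)
    return out, method


def _delta_cis(std, nll, theta_hat, paths, model):
    """Delta-method CIs from the numerical Hessian at the optimum."""
    from statsmodels.tools.numdiff import approx_hess

    H = approx_hess(theta_hat, nll)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return {c: (np.nan, np.nan) for c in std}
    vals = np.asarray(theta_hat[1:], float)
    total = float(np.sum(vals**2))
    out = {}
    labels = list(std)
    for idx, comp in enumerate(labels):
        if len(vals) < len(labels):
            out[comp] = (np.nan, np.nan)
            continue
        grad = np.zeros(len(theta_hat))
        for j, v in enumerate(vals):
            share_j = vals[idx] ** 2 / total
            d = (2 * v * ((1.0 if j == idx else 0.0) * total - vals[idx] ** 2) / total**2)
            grad[1 + j] = d
        se = float(np.sqrt(max(0.0, grad @ cov @ grad)))
        h = vals[idx] ** 2 / total
        out[comp] = (max(0.0, h - 1.96 * se), min(1.0, h + 1.96 * se))
    return out


# ---------------------------------------------------------------------------
# saturated model
# ---------------------------------------------------------------------------

SATURATED_CONSTRAINTS = (
    "means_order",
    "means_zygosity",
    "vars_order",
    "vars_zygosity",
)


@dataclass
class SaturatedFit:
    constraints: tuple
    loglik: float
    aic: float
    n_free_params: int
    lrt_stat: float | None = None
    lrt_df: int | None = None
    lrt_p: float | None = None


def _saturated_nll_factory(mz, dz, constraints):
    """Build the saturated NLL and its parameter layout.

    Unconstrained: per (zygosity x twin order) mean and log-variance plus a
    per-zygosity Fisher-z correlation (10 parameters).  Each constraint
    ties cells together, reducing the count.
    """
    c = set(constraints)
    mean_cells = _cell_layout("means" , c)
    var_cells = _cell_layout("vars", c)
    n_mean = max(mean_cells.values()) + 1
    n_var = max(var_cells.values()) + 1
    n_par = n_mean + n_var + 2

    def unpack(theta):
        mus = theta[:n_mean]
        logvs = theta[n_mean:n_mean + n_var]
        z = theta[n_mean + n_var:]
        out = {}
        for zi, zyg in enumerate((MZ, DZ)):
            m1 = mus[mean_cells[(zyg, 1)]]
            m2 = mus[mean_cells[(zyg, 2)]]
            v1 = np.exp(logvs[var_cells[(zyg, 1)]])
            v2 = np.exp(logvs[var_cells[(zyg, 2)]])
            r = np.tanh(z[zi])
            out[zyg] = (m1, m2, v1, v2, r)
        return out

    def nll(theta):
        cells = unpack(theta)
        tot = 0.0
        for pairs, zyg in ((mz, MZ), (dz, DZ)):
            if len(pairs) == 0:
                continue
            m1, m2, v1, v2, r = cells[zyg]
            s12 = r * np.sqrt(v1 * v2)
            det = v1 * v2 - s12 * s12
            d0 = pairs[:, 0] - m1
            d1 = pairs[:, 1] - m2
            q = (v2 * d0 * d0 - 2 * s12 * d0 * d1 + v1 * d1 * d1) / det
            tot += 0.5 * (len(pairs) * (2 * _LOG2PI + np.log(det)) + q.sum())
        return tot

    return nll, n_par


def _cell_layout(kind, constraints):
    """Map (zygosity, order) -> parameter index under the active equalities."""
    by_order = f"{kind}_order" in constraints
    by_zyg = f"{kind}_zygosity" in constraints
    cells = {}
    idx = {}
    nxt = 0
    for zyg in (MZ, DZ):
        for order in (1, 2):
            key = (
                "all" if by_order and by_zyg
                else zyg if by_order
                else order if by_zyg
                else (zyg, order)
            )
            if key not in idx:
                idx[key] = nxt
                nxt += 1
            cells[(zyg, order)] = idx[key]
    return cells


def fit_saturated(
    cohort: TwinCohort,
    phenotype: str = "walkability",
    constraints: tuple = (),
) -> SaturatedFit:
    """Fit the saturated model on complete pairs, optionally constrained.

    ``constraints`` is a subset of :data:`SATURATED_CONSTRAINTS`; each
    imposed equality is tested against the unconstrained model by a
    likelihood-ratio test whose df equals the reduction in free parameters.
    """
    bad = set(constraints) - set(SATURATED_CONSTRAINTS)
    if bad:
        raise ValueError(f"unknown constraint(s): {sorted(bad)}")
    mz = cohort.paired_values(phenotype, MZ)
    dz = cohort.paired_values(phenotype, DZ)
    if len(mz) < 3 or len(dz) < 3:
        raise ValueError("need >= 3 complete pairs per zygosity")

    def _fit(cons):
        nll, n_par = _saturated_nll_factory(mz, dz, cons)
        allv = np.vstack([mz, dz])
        mu0, v0 = float(allv.mean()), float(allv.var())
        x0 = np.concatenate([
            np.full(_n_cells("means", cons), mu0),
            np.full(_n_cells("vars", cons), np.log(v0)),
            [0.3, 0.3],
        ])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 2000})
        return -float(res.fun), n_par

    ll_u, k_u = _fit(())
    if not constraints:
        return SaturatedFit((), ll_u, -2 * ll_u + 2 * k_u, k_u)
    ll_c, k_c = _fit(tuple(constraints))
    df = k_u - k_c
    stat = max(0.0, 2.0 * (ll_u - ll_c))
    return SaturatedFit(
        tuple(constraints), ll_c, -2 * ll_c + 2 * k_c, k_c,
        lrt_stat=stat, lrt_df=df, lrt_p=float(stats.chi2.sf(stat, df)),
    )


def _n_cells(kind, constraints):
    return max(_cell_layout(kind, set(constraints)).values()) + 1


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    reference: str
    rows: list  # dicts: model, loglik, aic, df, lrt_p
    best_aic_model: str = ""

    def as_records(self) -> list[dict]:
        return list(self.rows)


def compare_models(fits: list[UnivariateFit], reference: str = "ACE") -> ModelComparison:
    """AIC table plus LRT of each nested model against the reference.

    All fits must be on the same observations (checked by pair/singleton
    counts).  df is the difference in free parameters; identical models
    give p = 1.
    """
    by_model = {f.params.model: f for f in fits}
    if reference not in by_model:
        raise ValueError(f"reference model {reference!r} not among the fits")
    ref = by_model[reference]
    for f in fits:
        if (f.n_pairs_used, f.n_singletons_used) != (ref.n_pairs_used, ref.n_singletons_used):
            raise ValueError("fits use different observation sets; comparison invalid")
    rows = []
    for f in fits:
        df = ref.n_free_params - f.n_free_params
        if df == 0:
            p = 1.0
        else:
            stat = max(0.0, 2.0 * (ref.loglik - f.loglik))
            p = float(stats.chi2.sf(stat, df))
        rows.append(
            {
                "model": f.params.model,
                "loglik": f.loglik,
                "aic": f.aic,
                "df_vs_reference": df,
                "lrt_p": p,
            }
        )
    best = min(rows, key=lambda r: r["aic"])["model"]
    return ModelComparison(reference=reference, rows=rows, best_aic_model=best)
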