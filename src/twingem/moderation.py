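"""Bivariate Cholesky moderation model (GxE with a measured moderator).

The moderator M (residualized walkability) carries its own ACE structure;
the trait T (residualized BMI) loads on the moderator's latent factors
through shared Cholesky paths and on its own factors through unique paths,
and every path toward T is allowed to vary linearly in the twin's own
observed moderator value (a per-pair definition variable):

    alpha_i = a_C + beta_aC * m_i      (shared A)
    gamma_i = c_C + beta_cC * m_i      (shared C; "full" variant only)
    eps_i   = e_C + beta_eC * m_i      (shared E)
    u_i     = a_U + beta_aU * m_i      (unique A)
    w_i     = e_U + beta_eU * m_i      (unique E)

Because the moderator's own A paths feed T through the shared loadings, the
model simultaneously captures gene-environment correlation (heritable
selection into walkable neighborhoods) and moderation of the genetic and
environmental variance of BMI.  Fitting is FIML over complete pairs: each
pair contributes a 4-variate normal term (M1, T1, M2, T2) with a
pair-specific expected covariance built from (m1, m2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .data import MZ, TwinCohort

_LOG2PI = np.log(2.0 * np.pi)

_FREE_NO_C = (
    "mu_m", "mu_t", "a_m", "c_m", "e_m",
    "a_c", "e_c", "a_u", "e_u",
    "beta_ac", "beta_ec", "beta_au", "beta_eu",
)
_FREE_FULL = _FREE_NO_C + ("c_c", "beta_cc")
_BETA_NAMES = ("beta_ac", "beta_ec", "beta_au", "beta_eu")


@dataclass
class ModerationParams:
    """Paths and moderation betas of the bivariate Cholesky moderation model."""

    a_m: float
    c_m: float
    e_m: float
    a_c: float
    e_c: float
    a_u: float
    e_u: float
    beta_ac: float = 0.0
    beta_ec: float = 0.0
    beta_au: float = 0.0
    beta_eu: float = 0.0
    c_c: float = 0.0
    beta_cc: float = 0.0
    mu_m: float = 0.0
    mu_t: float = 0.0
    gamma_m: float = 0.0  # linear effect of the moderator on the trait mean

    def free_names(self, variant: str) -> tuple[str, ...]:
        return _FREE_FULL if variant == "full" else _FREE_NO_C


def expected_cov_moderation(
    params: ModerationParams, m1: float, m2: float, zygosity: str
) -> np.ndarray:
    """Model-implied 4x4 covariance of (M1, T1, M2, T2) for one pair.

    ``m1``/``m2`` are the pair's observed (residualized) moderator values;
    the genetic cross-twin correlation r is 1 for MZ and 0.5 for DZ.
    """
    r = 1.0 if zygosity == MZ else 0.5
    S = _batched_cov(params, np.array([m1]), np.array([m2]), np.array([r]))[0]
    return S


def _batched_cov(p: ModerationParams, m1, m2, r) -> np.ndarray:
    """(n,4,4) expected covariances for arrays of definition variables."""
    a1 = p.a_c + p.beta_ac * m1
    a2 = p.a_c + p.beta_ac * m2
    g1 = p.c_c + p.beta_cc * m1
    g2 = p.c_c + p.beta_cc * m2
    e1 = p.e_c + p.beta_ec * m1
    e2 = p.e_c + p.beta_ec * m2
    u1 = p.a_u + p.beta_au * m1
    u2 = p.a_u + p.beta_au * m2
    w1 = p.e_u + p.beta_eu * m1
    w2 = p.e_u + p.beta_eu * m2

    vM = p.a_m**2 + p.c_m**2 + p.e_m**2
    n = len(m1)
    S = np.zeros((n, 4, 4))
    S[:, 0, 0] = vM
    S[:, 2, 2] = vM
    S[:, 0, 2] = r * p.a_m**2 + p.c_m**2
    S[:, 0, 1] = p.a_m * a1 + p.c_m * g1 + p.e_m * e1
    S[:, 2, 3] = p.a_m * a2 + p.c_m * g2 + p.e_m * e2
    S[:, 0, 3] = r * p.a_m * a2 + p.c_m * g2
    S[:, 1, 2] = r * p.a_m * a1 + p.c_m * g1
    S[:, 1, 1] = a1**2 + g1**2 + e1**2 + u1**2 + w1**2
    S[:, 3, 3] = a2**2 + g2**2 + e2**2 + u2**2 + w2**2
    S[:, 1, 3] = r * (a1 * a2 + u1 * u2) + g1 * g2
    iu = np.triu_indices(4, 1)
    for i, j in zip(*iu):
        S[:, j, i] = S[:, i, j]
    return S


def _pairs_arrays(cohort: TwinCohort):
    """Complete-pair arrays (m1, t1, m2, t2, r) in canonical twin order."""
    table = cohort.paired_table(["walkability", "bmi"])
    m1 = table["walkability_1"].to_numpy(float)
    m2 = table["walkability_2"].to_numpy(float)
    t1 = table["bmi_1"].to_numpy(float)
    t2 = table["bmi_2"].to_numpy(float)
    r = np.where(table["zygosity"].to_numpy() == MZ, 1.0, 0.5)
    return m1, t1, m2, t2, r


def _mean_matrix(p: ModerationParams, m1, m2) -> np.ndarray:
    """(n,4) model-implied means; the trait mean is linear in the moderator
    when ``gamma_m`` is nonzero (mean moderation)."""
    n = len(m1)
    mu = np.empty((n, 4))
    mu[:, 0] = p.mu_m
    mu[:, 2] = p.mu_m
    mu[:, 1] = p.mu_t + p.gamma_m * m1
    mu[:, 3] = p.mu_t + p.gamma_m * m2
    return mu


def moderation_loglik(params: ModerationParams, m1, t1, m2, t2, r) -> float:
    """FIML log-likelihood over complete pairs (vectorized 4-variate normal)."""
    X = np.stack([m1, t1, m2, t2], axis=1)
    mu = _mean_matrix(params, m1, m2)
    S = _batched_cov(params, m1, m2, r)
    sign, logdet = np.linalg.slogdet(S)
    if np.any(sign <= 0):
        return -np.inf
    d = X - mu
    sol = np.linalg.solve(S, d[:, :, None])[:, :, 0]
    q = np.einsum("ij,ij->i", d, sol)
    return float(-0.5 * (4 * _LOG2PI * len(m1) + logdet.sum() + q.sum()))


def _cov_grads(p: ModerationParams, m1, m2, r, names):
    """dS/dtheta as {name: (n,4,4)} for the requested free parameters."""
    a1 = p.a_c + p.beta_ac * m1
    a2 = p.a_c + p.beta_ac * m2
    g1 = p.c_c + p.beta_cc * m1
    g2 = p.c_c + p.beta_cc * m2
    e1 = p.e_c + p.beta_ec * m1
    e2 = p.e_c + p.beta_ec * m2
    u1 = p.a_u + p.beta_au * m1
    u2 = p.a_u + p.beta_au * m2
    w1 = p.e_u + p.beta_eu * m1
    w2 = p.e_u + p.beta_eu * m2
    n = len(m1)
    one = np.ones(n)

    def sym(entries):
        D = np.zeros((n, 4, 4))
        for (i, j), v in entries.items():
            D[:, i, j] = v
            if i != j:
                D[:, j, i] = v
        return D

    out = {}
    for name in names:
        if name in ("mu_m", "mu_t", "gamma_m"):
            continue
        if name == "a_m":
            out[name] = sym({(0, 0): 2 * p.a_m * one, (2, 2): 2 * p.a_m * one,
                             (0, 2): 2 * r * p.a_m, (0, 1): a1, (2, 3): a2,
                             (0, 3): r * a2, (1, 2): r * a1})
        elif name == "c_m":
            out[name] = sym({(0, 0): 2 * p.c_m * one, (2, 2): 2 * p.c_m * one,
                             (0, 2): 2 * p.c_m * one, (0, 1): g1, (2, 3): g2,
                             (0, 3): g2, (1, 2): g1})
        elif name == "e_m":
            out[name] = sym({(0, 0): 2 * p.e_m * one, (2, 2): 2 * p.e_m * one,
                             (0, 1): e1, (2, 3): e2})
        elif name in ("a_c", "beta_ac"):
            f1, f2 = (m1, m2) if name == "beta_ac" else (one, one)
            out[name] = sym({(0, 1): p.a_m * f1, (2, 3): p.a_m * f2,
                             (0, 3): r * p.a_m * f2, (1, 2): r * p.a_m * f1,
                             (1, 1): 2 * a1 * f1, (3, 3): 2 * a2 * f2,
                             (1, 3): r * (f1 * a2 + f2 * a1)})
        elif name in ("c_c", "beta_cc"):
            f1, f2 = (m1, m2) if name == "beta_cc" else (one, one)
            out[name] = sym({(0, 1): p.c_m * f1, (2, 3): p.c_m * f2,
                             (0, 3): p.c_m * f2, (1, 2): p.c_m * f1,
                             (1, 1): 2 * g1 * f1, (3, 3): 2 * g2 * f2,
                             (1, 3): f1 * g2 + f2 * g1})
        elif name in ("e_c", "beta_ec"):
            f1, f2 = (m1, m2) if name == "beta_ec" else (one, one)
            out[name] = sym({(0, 1): p.e_m * f1, (2, 3): p.e_m * f2,
                             (1, 1): 2 * e1 * f1, (3, 3): 2 * e2 * f2})
        elif name in ("a_u", "beta_au"):
            f1, f2 = (m1, m2) if name == "beta_au" else (one, one)
            out[name] = sym({(1, 1): 2 * u1 * f1, (3, 3): 2 * u2 * f2,
                             (1, 3): r * (f1 * u2 + f2 * u1)})
        elif name in ("e_u", "beta_eu"):
            f1, f2 = (m1, m2) if name == "beta_eu" else (one, one)
            out[name] = sym({(1, 1): 2 * w1 * f1, (3, 3): 2 * w2 * f2})
        else:
            raise KeyError(name)
    return out


def _nll_and_grad(theta, names, m1, t1, m2, t2, r):
    """Negative FIML loglik and its exact gradient in the free parameters."""
    p = _params_from_vector(theta, names)
    X = np.stack([m1, t1, m2, t2], axis=1)
    mu = _mean_matrix(p, m1, m2)
    S = _batched_cov(p, m1, m2, r)
    sign, logdet = np.linalg.slogdet(S)
    if np.any(sign <= 0):
        return np.inf, np.zeros(len(theta))
    K = np.linalg.inv(S)
    d = X - mu
    u = np.einsum("nij,nj->ni", K, d)
    q = np.einsum("ni,ni->n", d, u)
    nll = 0.5 * (4 * _LOG2PI * len(m1) + logdet.sum() + q.sum())
    # dNLL/dtheta = 0.5 sum_i tr[(K_i - u_i u_i^T) dS_i] - sum_i dmu^T u_i
    G = K - np.einsum("ni,nj->nij", u, u)
    dS = _cov_grads(p, m1, m2, r,
                    [nm for nm in names if nm != "gamma_m"])
    grad = np.zeros(len(theta))
    for k, name in enumerate(names):
        if name == "mu_m":
            grad[k] = -(u[:, 0].sum() + u[:, 2].sum())
        elif name == "mu_t":
            grad[k] = -(u[:, 1].sum() + u[:, 3].sum())
        elif name == "gamma_m":
            grad[k] = -((u[:, 1] * m1).sum() + (u[:, 3] * m2).sum())
        else:
            grad[k] = 0.5 * np.einsum("nij,nij->", G, dS[name])
    return float(nll), grad


@dataclass
class ModerationFit:
    params: ModerationParams
    loglik: float
    aic: float
    variant: str
    n_pairs_used: int
    n_pairs_excluded: int = 0
    hessian_pd: bool | None = None
    comparison: dict | None = None  # filled by variant="auto"
    mean_moderation: bool = False

    @property
    def n_free_params(self) -> int:
        return len(self.params.free_names(self.variant)) + int(self.mean_moderation)


def _params_from_vector(theta, names) -> ModerationParams:
    return ModerationParams(**dict(zip(names, theta)))


def _vector_from_params(p: ModerationParams, names) -> np.ndarray:
    return np.array([getattr(p, n) for n in names], float)


def _start_values(m1, t1, m2, t2, r) -> ModerationParams:
    """Moment-based starting values: univariate ACE moments for M, the
    pooled M-T covariance for the shared paths, the residual trait variance
    split across unique paths, betas at zero."""
    M = np.concatenate([m1, m2])
    T = np.concatenate([t1, t2])
    vM, vT = M.var(), T.var()
    covMT = np.cov(M, T)[0, 1]

    def _c(p1, p2, mask):
        if mask.sum() < 3:
            return 0.0
        d1, d2 = p1[mask] - M.mean(), p2[mask] - M.mean()
        return float(np.clip((d1 * d2).mean() / vM, -0.9, 0.9))

    r_mz = _c(m1, m2, r == 1.0)
    r_dz = _c(m1, m2, r == 0.5)
    a2 = float(np.clip(2 * (r_mz - r_dz), 0.05, 0.9))
    c2 = float(np.clip(2 * r_dz - r_mz, 0.02, 0.9))
    e2 = max(0.05, 1 - a2 - c2)
    s = a2 + c2 + e2
    a_m, c_m, e_m = (np.sqrt(a2 / s * vM), np.sqrt(c2 / s * vM), np.sqrt(e2 / s * vM))
    b = covMT / vM
    a_c, e_c = b * a_m, b * e_m
    resid = max(0.1 * vT, vT - b * b * vM)
    a_u = e_u = np.sqrt(resid / 2.0)
    return ModerationParams(
        a_m=a_m, c_m=c_m, e_m=e_m, a_c=a_c, e_c=e_c, a_u=a_u, e_u=e_u,
        mu_m=float(M.mean()), mu_t=float(T.mean()),
    )


def fit_moderation(
    cohort: TwinCohort,
    variant: str = "no_shared_C",
    fix_betas: bool = False,
    n_restarts: int = 2,
    seed: int = 0,
    check_hessian: bool = False,
    start: ModerationParams | None = None,
    thorough: bool = True,
    mean_moderation: bool = False,
) -> ModerationFit:
    """Fit the bivariate Cholesky moderation model by FIML.

    Both phenotypes should be residualized (age, sex) so the moderator
    definition variable is centered.  Only complete pairs (both twins, both
    phenotypes) enter the likelihood; excluded pairs are counted.

    ``variant``: "no_shared_C" (the trait has no shared-C paths, matching
    an AE trait), "full" (adds c_C and beta_cC), or "auto" (fits both and
    keeps the nested variant when its AIC improves on the full one by more
    than 2; the LRT across the two extra parameters is reported either
    way).  ``fix_betas=True`` pins all moderation betas at zero (the plain
    bivariate Cholesky model).
    """
    if variant == "auto":
        return _fit_auto(cohort, n_restarts=n_restarts, seed=seed,
                         check_hessian=check_hessian, thorough=thorough)
    if variant not in ("no_shared_C", "full"):
        raise ValueError(f"unknown variant {variant!r}")
    m1, t1, m2, t2, r = _pairs_arrays(cohort)
    n_total = cohort.meta["n_pairs"]
    n = len(m1)
    if n < 10:
        raise ValueError(f"need >= 10 complete pairs with both phenotypes, got {n}")
    names = list(_FREE_FULL if variant == "full" else _FREE_NO_C)
    if fix_betas:
        names = [x for x in names if not x.startswith("beta")]
    if mean_moderation:
        names.append("gamma_m")

    def nll_grad(theta):
        return _nll_and_grad(theta, names, m1, t1, m2, t2, r)

    def nll(theta):
        return nll_grad(theta)[0]

    if start is not None:
        p0 = start
    elif fix_betas:
        p0 = _start_values(m1, t1, m2, t2, r)
    else:
        # two-stage start: the unmoderated Cholesky optimum with betas at 0
        base = fit_moderation(
            cohort, variant, fix_betas=True, n_restarts=max(1, n_restarts),
            seed=seed, thorough=False, mean_moderation=mean_moderation,
        )
        p0 = base.params
    x0 = _vector_from_params(p0, names)
    rng = np.random.default_rng(seed)
    scale = np.maximum(0.05, np.abs(x0))
    beta_idx = [i for i, nm in enumerate(names) if nm.startswith("beta")]
    sd_t = np.std(np.concatenate([t1, t2]))
    sd_m = np.std(np.concatenate([m1, m2]))
    beta_scale = 0.5 * sd_t / max(sd_m, 1e-12)

    def _grad_fit(s):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return optimize.minimize(nll_grad, s, jac=True, method="L-BFGS-B",
                                     options={"maxiter": 5000, "ftol": 1e-13,
                                              "gtol": 1e-9})

    # the beta directions carry genuine local optima (a small beta with a
    # large baseline path can mimic a large beta of opposite curvature), so
    # restarts jitter the betas on their natural scale sd(T)/sd(M)
    n_jitter = max(n_restarts, 6) if (thorough and not fix_betas) else n_restarts
    cands = [_grad_fit(x0)]
    for _ in range(n_jitter):
        s = x0 + 0.15 * scale * rng.standard_normal(len(x0))
        if beta_idx:
            s[beta_idx] = x0[beta_idx] + beta_scale * rng.standard_normal(len(beta_idx))
        cands.append(_grad_fit(s))
    cands = [c for c in cands if np.isfinite(c.fun)]
    if not cands:
        raise RuntimeError("moderation FIML failed to converge from any start")
    best = min(cands, key=lambda c: c.fun)
    params = _params_from_vector(best.x, names)
    # canonical signs: moderator paths non-negative (their sign is not
    # identified); flip the matching shared path and beta with them so the
    # likelihood is unchanged
    for path, shared, beta in (("a_m", "a_c", "beta_ac"), ("c_m", "c_c", "beta_cc"),
                               ("e_m", "e_c", "beta_ec")):
        if getattr(params, path) < 0:
            params = replace(
                params,
                **{
                    path: -getattr(params, path),
                    shared: -getattr(params, shared),
                    beta: -getattr(params, beta),
                },
            )
    # unique-path sign pairs (u_i enters only via u^2 and u1*u2)
    for path, beta in (("a_u", "beta_au"), ("e_u", "beta_eu")):
        if getattr(params, path) < 0:
            params = replace(
                params,
                **{path: -getattr(params, path), beta: -getattr(params, beta)},
            )
    loglik = -float(best.fun)
    k = len(names)
    hess_pd = None
    if check_hessian:
        from statsmodels.tools.numdiff import approx_hess

        H = approx_hess(best.x, nll)
        hess_pd = bool(np.all(np.linalg.eigvalsh((H + H.T) / 2) > 0))
        if not hess_pd:
            warnings.warn("Hessian not positive definite at the optimum", RuntimeWarning)
    return ModerationFit(
        params=params,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * k,
        variant=variant,
        n_pairs_used=n,
        n_pairs_excluded=n_total - n,
        hessian_pd=hess_pd,
        mean_moderation=mean_moderation,
    )


def _fit_auto(cohort, n_restarts, seed, check_hessian, thorough=True) -> ModerationFit:
    nested = fit_moderation(cohort, "no_shared_C", n_restarts=n_restarts, seed=seed,
                            check_hessian=check_hessian, thorough=thorough)
    # start the full model from the nested optimum so it can only improve
    # on it, keeping the AIC/LRT comparison internally consistent
    full = fit_moderation(cohort, "full", n_restarts=n_restarts, seed=seed,
                          check_hessian=check_hessian, thorough=thorough,
                          start=nested.params)
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    comparison = {
        "aic_full": full.aic,
        "aic_no_shared_C": nested.aic,
        "lrt_stat": stat,
        "lrt_df": 2,
        "lrt_p": float(stats.chi2.sf(stat, 2)),
        "aic_rule": "nested kept when AIC(full) - AIC(no_shared_C) > 2",
    }
    chosen = nested if full.aic - nested.aic > 2.0 else full
    chosen.comparison = comparison
    return chosen


def moderation_lrt(cohort: TwinCohort, variant: str = "no_shared_C",
                   n_restarts: int = 1, seed: int = 0,
                   thorough: bool = True) -> dict:
    """Joint LRT of all moderation betas against the unmoderated Cholesky.

    Fits the beta-free model first and uses it as the start for the
    moderated model, so under the null the statistic is computed on nested
    optima.  Returns the statistic, df, and p-value.
    """
    base = fit_moderation(cohort, variant, fix_betas=True, n_restarts=n_restarts, seed=seed)
    mod = fit_moderation(cohort, variant, n_restarts=n_restarts, seed=seed,
                         start=base.params, thorough=thorough)
    df = 5 if variant == "full" else 4
    stat = max(0.0, 2.0 * (mod.loglik - base.loglik))
    return {
        "lrt_stat": stat,
        "df": df,
        "p": float(stats.chi2.sf(stat, df)),
        "loglik_moderated": mod.loglik,
        "loglik_unmoderated": base.loglik,
    }


# ---------------------------------------------------------------------------
# variance profiles (moderator-dependent A and E variance of the trait)
# ---------------------------------------------------------------------------

@dataclass
class VarianceProfile:
    grid: np.ndarray
    var_A: np.ndarray
    var_E: np.ndarray
    var_C: np.ndarray
    share_A: np.ndarray
    share_E: np.ndarray
    intersections: list

    def as_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "moderator": self.grid,
                "var_A": self.var_A,
                "var_E": self.var_E,
                "share_A": self.share_A,
                "share_E": self.share_E,
            }
        )


def variance_profile(fit: ModerationFit, grid: np.ndarray) -> VarianceProfile:
    """Project the trait's A and E variance along the moderator.

    var_A(m) = (a_C + beta_aC m)^2 + (a_U + beta_aU m)^2 and analogously
    for E (shared-C contributes to var_C in the full variant).  Shares are
    each variance over the A+E total (plus C when present).  Intersections
    are the moderator values inside the grid range where var_A = var_E,
    located by sign-change bracketing and bisection to 1e-6.
    """
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty moderator grid")
    p = fit.params
    var_A = (p.a_c + p.beta_ac * grid) ** 2 + (p.a_u + p.beta_au * grid) ** 2
    var_E = (p.e_c + p.beta_ec * grid) ** 2 + (p.e_u + p.beta_eu * grid) ** 2
    var_C = (p.c_c + p.beta_cc * grid) ** 2
    total = var_A + var_E + var_C
    share_A = var_A / total
    share_E = var_E / total

    def diff(m):
        return ((p.a_c + p.beta_ac * m) ** 2 + (p.a_u + p.beta_au * m) ** 2
                - (p.e_c + p.beta_ec * m) ** 2 - (p.e_u + p.beta_eu * m) ** 2)

    roots = []
    fine = np.linspace(grid.min(), grid.max(), max(2001, 4 * grid.size))
    vals = diff(fine)
    for i in range(len(fine) - 1):
        if vals[i] == 0.0:
            roots.append(float(fine[i]))
        elif vals[i] * vals[i + 1] < 0:
            roots.append(float(optimize.brentq(diff, fine[i], fine[i + 1], xtol=1e-6)))
    # dedupe near-identical roots
    uniq = []
    for rt in roots:
        if not uniq or abs(rt - uniq[-1]) > 1e-5:
            uniq.append(rt)
    return VarianceProfile(
        grid=grid, var_A=var_A, var_E=var_E, var_C=var_C,
        share_A=share_A, share_E=share_E, intersections=uniq,
    )
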