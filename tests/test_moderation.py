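"""Bivariate Cholesky moderation model: covariance expectations, FIML,
beta recovery, and variance profiles."""

import numpy as np
import pytest
from scipy import stats

from twingem.data import TwinCohort
from twingem.moderation import (
    ModerationFit,
    ModerationParams,
    expected_cov_moderation,
    fit_moderation,
    moderation_loglik,
    moderation_lrt,
    variance_profile,
    _pairs_arrays,
)
from twingem.simulate import ModerationSimSpec, simulate_moderation
from twingem.data import residualize_phenotype


def _cholesky_cov_oracle(p, zygosity):
    """Independent oracle: the unmoderated bivariate Cholesky expectation
    assembled from loading matrices (no moderation terms)."""
    r = 1.0 if zygosity == "MZ" else 0.5
    # loadings of (M, T) on (A_c, C_c, E_c, A_u, E_u), per twin
    L = np.array(
        [
            [p.a_m, p.c_m, p.e_m, 0.0, 0.0],
            [p.a_c, p.c_c, p.e_c, p.a_u, p.e_u],
        ]
    )
    # cross-twin latent correlations
    R_within = np.eye(5)
    R_cross = np.diag([r, 1.0, 0.0, r, 0.0])
    top = np.hstack([L @ R_within @ L.T, L @ R_cross @ L.T])
    bottom = np.hstack([L @ R_cross @ L.T, L @ R_within @ L.T])
    return np.vstack([top, bottom])


def _resid(cohort):
    cohort = residualize_phenotype(cohort, "walkability", ("age", "sex"))
    return residualize_phenotype(cohort, "bmi", ("age", "sex"))


class TestExpectedCov:
    def test_zero_betas_match_cholesky_oracle(self):
        p = ModerationParams(a_m=5.0, c_m=4.0, e_m=8.0, a_c=-0.6, e_c=-0.3,
                             a_u=4.0, e_u=3.0, c_c=0.7)
        for z in ("MZ", "DZ"):
            got = expected_cov_moderation(p, m1=3.0, m2=-7.0, zygosity=z)
            assert np.allclose(got, _cholesky_cov_oracle(p, z))

    def test_null_trait_paths(self):
        p = ModerationParams(a_m=1.0, c_m=0.0, e_m=0.0, a_c=0.0, e_c=0.0,
                             a_u=0.0, e_u=0.0)
        S = expected_cov_moderation(p, 0.5, -0.5, "DZ")
        assert np.allclose(S[[1, 3]], 0.0) and np.allclose(S[:, [1, 3]], 0.0)
        assert np.allclose(S[np.ix_([0, 2], [0, 2])], [[1.0, 0.5], [0.5, 1.0]])

    def test_hand_arithmetic_strong_moderation(self):
        # a_C=1, beta_aC=0.5, m=(2,-2), MZ: loadings (1+1)=2 and (1-1)=0,
        # so Var(T1)=4, Var(T2)=0, Cov(T1,T2)=0
        p = ModerationParams(a_m=1.0, c_m=0.0, e_m=0.0, a_c=1.0, e_c=0.0,
                             a_u=0.0, e_u=0.0, beta_ac=0.5)
        S = expected_cov_moderation(p, 2.0, -2.0, "MZ")
        assert S[1, 1] == pytest.approx(4.0)
        assert S[3, 3] == pytest.approx(0.0)
        assert S[1, 3] == pytest.approx(0.0)

    def test_symmetric(self):
        p = ModerationParams(a_m=5.0, c_m=4.0, e_m=8.0, a_c=-0.6, e_c=-0.3,
                             a_u=4.0, e_u=3.0, beta_au=-0.1, beta_eu=0.3)
        S = expected_cov_moderation(p, 1.5, -4.0, "DZ")
        assert np.allclose(S, S.T)


class TestLoglik:
    def _small_cohort(self, seed=0, **kw):
        spec = ModerationSimSpec(n_mz_pairs=40, n_dz_pairs=60, seed=seed, **kw)
        return _resid(simulate_moderation(spec))

    def test_matches_scipy_mvn_oracle(self):
        cohort = self._small_cohort(seed=1)
        m1, t1, m2, t2, r = _pairs_arrays(cohort)
        p = ModerationParams(a_m=5.0, c_m=4.0, e_m=8.0, a_c=-0.5, e_c=-0.2,
                             a_u=4.0, e_u=3.0, beta_eu=0.2, mu_m=0.1, mu_t=-0.2)
        ll = moderation_loglik(p, m1, t1, m2, t2, r)
        oracle = 0.0
        mu = [p.mu_m, p.mu_t, p.mu_m, p.mu_t]
        for i in range(len(m1)):
            z = "MZ" if r[i] == 1.0 else "DZ"
            S = expected_cov_moderation(p, m1[i], m2[i], z)
            oracle += stats.multivariate_normal(mu, S).logpdf(
                [m1[i], t1[i], m2[i], t2[i]]
            )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_invariant_to_twin_order(self):
        cohort = self._small_cohort(seed=2)
        m1, t1, m2, t2, r = _pairs_arrays(cohort)
        p = ModerationParams(a_m=5.0, c_m=4.0, e_m=8.0, a_c=-0.5, e_c=-0.2,
                             a_u=4.0, e_u=3.0, beta_au=0.1, beta_eu=0.2)
        ll = moderation_loglik(p, m1, t1, m2, t2, r)
        ll_swapped = moderation_loglik(p, m2, t2, m1, t1, r)
        assert ll == pytest.approx(ll_swapped, abs=1e-9)


class TestFitModeration:
    def test_betas_fixed_zero_reproduces_unmoderated(self):
        spec = ModerationSimSpec(n_mz_pairs=150, n_dz_pairs=220, seed=3,
                                 beta_ac=0.0, beta_ec=0.0, beta_au=0.0, beta_eu=0.0)
        cohort = _resid(simulate_moderation(spec))
        base = fit_moderation(cohort, fix_betas=True, n_restarts=1)
        mod_at_base = moderation_loglik(base.params, *_pairs_arrays(cohort))
        assert mod_at_base == pytest.approx(base.loglik, abs=1e-6)
        # the moderated fit can only improve the loglik
        mod = fit_moderation(cohort, n_restarts=0, thorough=False,
                             start=base.params)
        assert mod.loglik >= base.loglik - 1e-6

    def test_beta_recovery_fixed_alternative(self):
        # true beta_aU = -0.3 on the unique genetic path, other betas zero
        est, signs = [], 0
        n_rep = 12
        for s in range(n_rep):
            spec = ModerationSimSpec(
                n_mz_pairs=250, n_dz_pairs=380, seed=700 + s,
                beta_ac=0.0, beta_ec=0.0, beta_au=-0.3, beta_eu=0.0,
            )
            cohort = _resid(simulate_moderation(spec))
            fit = fit_moderation(cohort, n_restarts=0)
            est.append(fit.params.beta_au)
            signs += fit.params.beta_au < 0
        assert np.mean(est) == pytest.approx(-0.3, abs=0.1)
        assert signs >= 0.9 * n_rep

    def test_aic_selects_no_shared_c_when_absent(self):
        wins = 0
        n_rep = 8
        for s in range(n_rep):
            spec = ModerationSimSpec(n_mz_pairs=200, n_dz_pairs=300,
                                     seed=800 + s, c_c=0.0, beta_cc=0.0,
                                     beta_ac=0.0, beta_ec=0.0,
                                     beta_au=0.0, beta_eu=0.0)
            cohort = _resid(simulate_moderation(spec))
            fit = fit_moderation(cohort, "auto", n_restarts=0, thorough=False)
            wins += fit.comparison["aic_no_shared_C"] < fit.comparison["aic_full"]
        assert wins > n_rep / 2

    def test_auto_variant_reports_comparison(self):
        spec = ModerationSimSpec(n_mz_pairs=120, n_dz_pairs=180, seed=9)
        cohort = _resid(simulate_moderation(spec))
        fit = fit_moderation(cohort, "auto", n_restarts=0, thorough=False)
        assert fit.comparison is not None
        assert fit.comparison["lrt_df"] == 2
        assert 0.0 <= fit.comparison["lrt_p"] <= 1.0

    def test_mean_moderation_recovers_total_slope(self):
        # gamma_m and the shared paths are only jointly identified: the
        # identified quantity is the total moderator->trait mean slope
        # gamma_m + (a_m*a_c + c_m*c_c + e_m*e_c)/Var(M)
        spec = ModerationSimSpec(
            n_mz_pairs=800, n_dz_pairs=1200, seed=23, gamma_m=-0.04,
            beta_ac=0.0, beta_ec=0.0, beta_au=0.0, beta_eu=0.0,
        )
        cohort = _resid(simulate_moderation(spec))
        fit = fit_moderation(cohort, "no_shared_C", mean_moderation=True,
                             n_restarts=1, thorough=False)
        base = fit_moderation(cohort, "no_shared_C", n_restarts=1, thorough=False)
        assert fit.loglik >= base.loglik - 1e-6  # base is nested (gamma=0)
        assert fit.n_free_params == base.n_free_params + 1
        p = fit.params
        v_m = p.a_m**2 + p.c_m**2 + p.e_m**2
        implied = p.gamma_m + (p.a_m * p.a_c + p.e_m * p.e_c) / v_m
        truth = -0.04 + (spec.a_m * spec.a_c + spec.e_m * spec.e_c) / 144.0
        assert implied == pytest.approx(truth, abs=0.02)

    def test_too_few_pairs(self):
        spec = ModerationSimSpec(n_mz_pairs=3, n_dz_pairs=3, seed=10)
        with pytest.raises(ValueError, match="pairs"):
            fit_moderation(_resid(simulate_moderation(spec)))


class TestVarianceProfile:
    def _fit_with(self, **params):
        defaults = dict(a_m=5.0, c_m=4.0, e_m=8.0, a_c=-0.6, e_c=-0.25,
                        a_u=4.0, e_u=3.0)
        defaults.update(params)
        p = ModerationParams(**defaults)
        return ModerationFit(params=p, loglik=0.0, aic=0.0,
                             variant="no_shared_C", n_pairs_used=0)

    def test_flat_without_betas(self):
        prof = variance_profile(self._fit_with(), np.linspace(-20, 20, 41))
        assert np.ptp(prof.var_A) < 1e-12
        assert np.ptp(prof.var_E) < 1e-12

    def test_shares_sum_to_one(self):
        prof = variance_profile(
            self._fit_with(beta_au=-0.05, beta_eu=0.4), np.linspace(-25, 25, 51)
        )
        assert np.allclose(prof.share_A + prof.share_E, 1.0)

    def test_two_intersections_with_quadratic_e_growth(self):
        # A dominates at the center, E grows quadratically on both sides:
        # exactly two crossings, one negative, one positive
        fit = self._fit_with(beta_au=-0.05, beta_eu=0.4)
        prof = variance_profile(fit, np.linspace(-25, 25, 101))
        assert len(prof.intersections) == 2
        lo, hi = sorted(prof.intersections)
        assert lo < 0 < hi
        p = fit.params
        for m in (lo, hi):
            va = (p.a_c + p.beta_ac * m) ** 2 + (p.a_u + p.beta_au * m) ** 2
            ve = (p.e_c + p.beta_ec * m) ** 2 + (p.e_u + p.beta_eu * m) ** 2
            assert va == pytest.approx(ve, abs=1e-4)

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            variance_profile(self._fit_with(), np.array([]))


class TestNullCalibrationSmoke:
    def test_lrt_null_statistic_plausible(self):
        # small smoke version of the chi-square(4) calibration
        stats_l = []
        for s in range(10):
            spec = ModerationSimSpec(
                n_mz_pairs=100, n_dz_pairs=150, seed=900 + s,
                beta_ac=0.0, beta_ec=0.0, beta_au=0.0, beta_eu=0.0,
            )
            cohort = _resid(simulate_moderation(spec))
            stats_l.append(moderation_lrt(cohort, n_restarts=0, thorough=False)["lrt_stat"])
        arr = np.array(stats_l)
        assert np.all(arr >= -1e-9)
        assert np.median(arr) < 12.0  # chi2(4) median is 3.36
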