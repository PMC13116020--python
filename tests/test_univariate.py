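"""Univariate twin modelling: ICC, Falconer, covariance expectations,
FIML fitting, saturated model, model comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from twingem.data import TwinCohort
from twingem.simulate import UnivariateSimSpec, simulate_univariate
from twingem.univariate import (
    UnivariateParams,
    compare_models,
    expected_cov_univariate,
    falconer_decomposition,
    fit_saturated,
    fit_univariate,
    intraclass_correlation,
    select_base_model,
    univariate_loglik,
)

from conftest import make_cohort


class TestICC:
    def test_perfect_concordance(self):
        vals = np.tile(np.linspace(30, 50, 20)[:, None], (1, 2))
        res = intraclass_correlation(make_cohort(vals), "MZ")
        assert res.icc > 0.999

    def test_independent_cotwins_near_zero(self):
        rng = np.random.default_rng(0)
        iccs = [
            intraclass_correlation(
                make_cohort(rng.normal(size=(200, 2))), "MZ"
            ).icc
            for _ in range(50)
        ]
        # 3 Monte-Carlo SEs of the replicate mean around zero
        assert abs(np.mean(iccs)) < 3 * np.std(iccs) / np.sqrt(50)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(1)
        L = np.linalg.cholesky([[1, 0.5], [0.5, 1]])
        res = intraclass_correlation(
            make_cohort(rng.standard_normal((100, 2)) @ L.T), "MZ"
        )
        assert res.ci95[0] < res.icc < res.ci95[1]

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            intraclass_correlation(make_cohort([[1.0, 2.0], [2.0, 1.0]]), "MZ")


class TestFalconer:
    @pytest.mark.parametrize(
        "r_mz,r_dz,expected",
        [
            ((0.46), 0.34, (0.24, 0.22, 0.54)),  # study twin correlations
            (1.0, 0.5, (1.0, 0.0, 0.0)),  # pure additive limit
        ],
    )
    def test_closed_form(self, r_mz, r_dz, expected):
        A, C, E, flag = falconer_decomposition(r_mz, r_dz)
        assert (A, C, E) == pytest.approx(expected, abs=1e-12)
        assert not flag

    def test_negative_estimate_flagged(self):
        A, C, E, flag = falconer_decomposition(0.2, 0.3)
        assert A == pytest.approx(-0.2)
        assert flag

    @given(st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=100, deadline=None)
    def test_components_always_sum_to_one(self, r_mz, r_dz):
        A, C, E, _ = falconer_decomposition(r_mz, r_dz)
        assert A + C + E == pytest.approx(1.0, abs=1e-9)


class TestSelectBaseModel:
    @pytest.mark.parametrize(
        "r_mz,r_dz,expected",
        [(0.46, 0.34, "ACE"), (0.6, 0.25, "ADE"), (0.6, 0.30, "ACE")],
    )
    def test_rule(self, r_mz, r_dz, expected):
        assert select_base_model(r_mz, r_dz) == expected


class TestExpectedCov:
    def test_pure_additive(self):
        p = UnivariateParams("ACE", a=1.0, c_or_d=0.0, e=0.0)
        assert np.allclose(expected_cov_univariate(p, "MZ"), [[1, 1], [1, 1]])
        assert expected_cov_univariate(p, "DZ")[0, 1] == pytest.approx(0.5)

    def test_ace_study_components(self):
        p = UnivariateParams("ACE", a=np.sqrt(0.22), c_or_d=np.sqrt(0.22), e=np.sqrt(0.56))
        mz = expected_cov_univariate(p, "MZ")
        dz = expected_cov_univariate(p, "DZ")
        assert mz[0, 0] == pytest.approx(1.0)
        assert mz[0, 1] == pytest.approx(0.44)
        assert dz[0, 1] == pytest.approx(0.33)

    def test_ade_quarter_dominance(self):
        p = UnivariateParams("ADE", a=0.0, c_or_d=1.0, e=0.0)
        assert expected_cov_univariate(p, "MZ")[0, 1] == pytest.approx(1.0)
        assert expected_cov_univariate(p, "DZ")[0, 1] == pytest.approx(0.25)

    @given(st.floats(0, 2), st.floats(0, 2), st.floats(0.1, 2))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_psd(self, a, c, e):
        p = UnivariateParams("ACE", a=a, c_or_d=c, e=e)
        for z in ("MZ", "DZ"):
            S = expected_cov_univariate(p, z)
            assert np.allclose(S, S.T)
            assert np.all(np.linalg.eigvalsh(S) >= -1e-12)


class TestFIMLLoglik:
    def test_matches_general_multivariate_normal(self):
        # independent oracle: scipy's multivariate normal density term by term
        spec = UnivariateSimSpec(n_mz_pairs=30, n_dz_pairs=40,
                                 singleton_fraction=0.2, seed=2)
        cohort = simulate_univariate(spec)
        mz = cohort.paired_values("walkability", "MZ")
        dz = cohort.paired_values("walkability", "DZ")
        singles = cohort.singleton_values("walkability")
        p = UnivariateParams("ACE", a=5.0, c_or_d=6.0, e=9.0)
        mu = 43.0
        ll = univariate_loglik(p, mu, mz, dz, singles)
        oracle = 0.0
        for pairs, z in ((mz, "MZ"), (dz, "DZ")):
            cov = expected_cov_univariate(p, z)
            oracle += stats.multivariate_normal([mu, mu], cov).logpdf(pairs).sum()
        oracle += stats.norm(mu, np.sqrt(p.total_variance)).logpdf(singles).sum()
        assert ll == pytest.approx(oracle, abs=1e-8)


class TestFitUnivariate:
    def test_pure_noise_recovery(self):
        estimates = []
        for s in range(10):
            spec = UnivariateSimSpec(n_mz_pairs=300, n_dz_pairs=400,
                                     a2=0.0, c2=0.0, e2=1.0, seed=s)
            fit = fit_univariate(simulate_univariate(spec), "ACE", ci="none")
            estimates.append([fit.standardized["A"], fit.standardized["C"],
                              fit.standardized["E"]])
        mean = np.mean(estimates, axis=0)
        assert mean[2] > 0.9
        assert mean[0] < 0.08 and mean[1] < 0.08

    def test_nesting_monotonicity(self):
        cohort = simulate_univariate(UnivariateSimSpec(seed=3))
        lls = {
            m: fit_univariate(cohort, m, ci="none").loglik
            for m in ("ACE", "AE", "E")
        }
        assert lls["E"] <= lls["AE"] + 1e-6 <= lls["ACE"] + 2e-6

    def test_invariant_to_twin_order_and_row_shuffle(self):
        cohort = simulate_univariate(UnivariateSimSpec(
            n_mz_pairs=60, n_dz_pairs=80, seed=4))
        fit1 = fit_univariate(cohort, "ACE", ci="none")
        df = cohort.df.copy()
        # swap canonical order by renaming, then shuffle rows
        df["person_id"] = df["person_id"].str.replace("_1", "_9")
        df = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = fit_univariate(TwinCohort(df), "ACE", ci="none")
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)
        assert fit1.standardized["A"] == pytest.approx(fit2.standardized["A"], abs=1e-5)

    def test_standardized_sums_to_one(self):
        fit = fit_univariate(
            simulate_univariate(UnivariateSimSpec(seed=5)), "ACE", ci="none"
        )
        assert sum(fit.standardized.values()) == pytest.approx(1.0, abs=1e-6)

    def test_aic_definition(self):
        fit = fit_univariate(
            simulate_univariate(UnivariateSimSpec(n_mz_pairs=50, n_dz_pairs=50, seed=6)),
            "AE", ci="none",
        )
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * 3)  # a, e, mean

    def test_profile_ci_brackets_estimate(self):
        fit = fit_univariate(
            simulate_univariate(UnivariateSimSpec(n_mz_pairs=200, n_dz_pairs=300, seed=7)),
            "ACE", ci="profile",
        )
        assert fit.ci_method == "profile"
        for comp, (lo, hi) in fit.standardized_ci.items():
            assert lo - 1e-6 <= fit.standardized[comp] <= hi + 1e-6
            assert hi - lo < 1.0  # informative at this sample size

    def test_singletons_enter_likelihood(self):
        spec = UnivariateSimSpec(n_mz_pairs=200, n_dz_pairs=300,
                                 singleton_fraction=0.25, seed=8)
        fit = fit_univariate(simulate_univariate(spec), "ACE", ci="none")
        assert fit.n_singletons_used > 50
        assert sum(fit.standardized.values()) == pytest.approx(1.0, abs=1e-6)

    def test_falconer_agreement_at_scale(self):
        # closed-form and FIML standardized estimates agree on large samples
        spec = UnivariateSimSpec(n_mz_pairs=4000, n_dz_pairs=4000, seed=9)
        cohort = simulate_univariate(spec)
        fit = fit_univariate(cohort, "ACE", ci="none")
        r_mz = intraclass_correlation(cohort, "MZ").icc
        r_dz = intraclass_correlation(cohort, "DZ").icc
        A, C, E, _ = falconer_decomposition(r_mz, r_dz)
        assert fit.standardized["A"] == pytest.approx(A, abs=0.02)
        assert fit.standardized["E"] == pytest.approx(E, abs=0.02)


class TestSaturated:
    def test_unconstrained_beats_constrained(self):
        cohort = simulate_univariate(UnivariateSimSpec(n_mz_pairs=100, n_dz_pairs=100, seed=10))
        free = fit_saturated(cohort)
        con = fit_saturated(cohort, constraints=("means_order", "vars_order"))
        assert con.loglik <= free.loglik + 1e-6
        assert con.lrt_df == 4  # two mean + two variance equalities

    def test_detects_forced_order_difference(self):
        # +1 SD shift on twin2: equal-means-by-order should reject
        rejections = 0
        for s in range(10):
            cohort = simulate_univariate(UnivariateSimSpec(seed=200 + s))
            df = cohort.df.copy()
            shift = df["person_id"].str.endswith("_2")
            df.loc[shift, "walkability"] += 12.0
            sat = fit_saturated(TwinCohort(df), constraints=("means_order",))
            rejections += sat.lrt_p < 0.05
        assert rejections >= 9

    def test_ace_nested_in_constrained_saturated(self):
        cohort = simulate_univariate(UnivariateSimSpec(n_mz_pairs=150, n_dz_pairs=150, seed=11))
        sat = fit_saturated(
            cohort,
            constraints=("means_order", "means_zygosity", "vars_order", "vars_zygosity"),
        )
        ace = fit_univariate(cohort, "ACE", ci="none")
        assert ace.loglik <= sat.loglik + 1e-6

    def test_unknown_constraint(self):
        cohort = simulate_univariate(UnivariateSimSpec(n_mz_pairs=10, n_dz_pairs=10, seed=12))
        with pytest.raises(ValueError, match="unknown"):
            fit_saturated(cohort, constraints=("bogus",))


class TestCompareModels:
    def test_identity_comparison(self):
        cohort = simulate_univariate(UnivariateSimSpec(n_mz_pairs=60, n_dz_pairs=60, seed=13))
        fit = fit_univariate(cohort, "ACE", ci="none")
        comp = compare_models([fit, fit], reference="ACE")
        assert comp.rows[0]["aic"] == comp.rows[1]["aic"]
        assert all(r["lrt_p"] == 1.0 for r in comp.rows)

    def test_ae_truth_selects_ae(self):
        wins = 0
        for s in range(15):
            spec = UnivariateSimSpec(a2=0.48, c2=0.0, e2=0.52, seed=300 + s)
            cohort = simulate_univariate(spec)
            fits = [fit_univariate(cohort, m, ci="none") for m in ("ACE", "AE", "E")]
            wins += compare_models(fits, "ACE").best_aic_model == "AE"
        assert wins > 8

    def test_ace_truth_penalizes_dropping_components(self):
        # mirrors the published model-comparison logic: at the study's
        # sample size and ACE truth, dropping A or C usually worsens AIC
        better = 0
        for s in range(15):
            cohort = simulate_univariate(UnivariateSimSpec(seed=400 + s))
            fits = [fit_univariate(cohort, m, ci="none") for m in ("ACE", "AE", "CE", "E")]
            comp = compare_models(fits, "ACE")
            aic = {r["model"]: r["aic"] for r in comp.rows}
            better += aic["ACE"] < min(aic["AE"], aic["E"])
        assert better > 8

    def test_mismatched_observations_error(self):
        c1 = simulate_univariate(UnivariateSimSpec(n_mz_pairs=50, n_dz_pairs=50, seed=14))
        c2 = simulate_univariate(UnivariateSimSpec(n_mz_pairs=40, n_dz_pairs=50, seed=15))
        f1 = fit_univariate(c1, "ACE", ci="none")
        f2 = fit_univariate(c2, "AE", ci="none")
        with pytest.raises(ValueError, match="observation"):
            compare_models([f1, f2], "ACE")
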