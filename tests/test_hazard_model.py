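"""Hazard evaluation, polar reparameterization, and the two estimators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seasonmort as sm
from seasonmort import cohort_data
from seasonmort.hazard_model import OMEGA, direct_loglik
from conftest import SEED


class TestHazardRate:
    def test_constant_hazard(self):
        p = sm.HazardParams(mu=1e-4, beta=0.0)
        assert sm.hazard_rate(p, 123.0, 50) == pytest.approx(1e-4, rel=1e-12)

    def test_seasonal_doubling_at_origin(self):
        p = sm.HazardParams.from_polar(mu=1e-4, beta=0.0, alpha=np.log(2), theta=0.0)
        assert sm.hazard_rate(p, 0.0, 365) == pytest.approx(2e-4, rel=1e-12)

    def test_closed_form_second_path(self):
        """Independent re-evaluation of the formula, term by term."""
        p = sm.HazardParams.from_polar(mu=5e-5, beta=2.4e-4, alpha=0.3, theta=2.4)
        t, b = 1000.0, 180
        expected = (
            5e-5
            * np.exp(2.4e-4 * (t + 365 - b))
            * np.exp(0.3 * np.cos(2 * np.pi * t / 365.25 + 2.4))
        )
        assert sm.hazard_rate(p, t, b) == pytest.approx(expected, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sm.HazardParams(mu=-1e-4, beta=0.0)
        with pytest.raises(ValueError):
            sm.HazardParams(mu=1e-4, beta=-1e-4)


class TestPolar:
    @pytest.mark.parametrize(
        "a1, a2, alpha, theta",
        [
            (0.0, 1.0, 1.0, 0.0),
            (-1.0, 0.0, 1.0, np.pi / 2),
            (0.0, -1.0, 1.0, np.pi),
        ],
    )
    def test_known_points(self, a1, a2, alpha, theta):
        got_alpha, got_theta = sm.to_polar(a1, a2)
        assert got_alpha == pytest.approx(alpha)
        assert got_theta == pytest.approx(theta)

    def test_degenerate_origin(self):
        assert sm.to_polar(0.0, 0.0) == (0.0, 0.0)

    @given(
        st.floats(min_value=-2, max_value=2),
        st.floats(min_value=-2, max_value=2),
    )
    def test_sinusoid_reconstruction(self, a1, a2):
        """a1*sin + a2*cos equals alpha*cos(x + theta) pointwise over a year."""
        alpha, theta = sm.to_polar(a1, a2)
        t = np.arange(365.0)
        lhs = a1 * np.sin(OMEGA * t) + a2 * np.cos(OMEGA * t)
        rhs = alpha * np.cos(OMEGA * t + theta)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)
        b1, b2 = sm.from_polar(alpha, theta)
        assert (b1, b2) == pytest.approx((a1, a2), abs=1e-12)


class TestFitPoisson:
    def test_parameter_recovery_within_3_se(self, recovery_cohort):
        """Estimates from a 100k-person cohort sit within 3 SE of truth."""
        truth, fit = recovery_cohort["truth"], recovery_cohort["fit"]
        # the fitted intercept absorbs the cohort-mean age offset
        log_mu_cohort = np.log(truth.mu) + truth.beta * (365.0 - fit.b_mean)
        z = np.array(
            [
                (np.log(fit.params.mu) - log_mu_cohort) / fit.se[0],
                (fit.params.beta - truth.beta) / fit.se[1],
                (fit.params.a1 - truth.a1) / fit.se[2],
                (fit.params.a2 - truth.a2) / fit.se[3],
            ]
        )
        assert np.all(np.abs(z) < 3), z
        assert fit.converged
        assert fit.seasonality_pvalue < 1e-3

    def test_null_model_flat_hazard(self):
        """With no seasonality or ageing in truth, estimates stay near zero."""
        rng = np.random.default_rng(SEED + 1)
        p = sm.HazardParams(mu=2e-4, beta=0.0)
        df = sm.simulate_cohort(p, 1830, "male", 50_000, rng)
        cohort = cohort_data.build_cohort(df, 1830, "male")
        fit = sm.fit_poisson(cohort_data.build_daily_counts(cohort))
        assert abs(fit.params.beta) < 3 * fit.se[1]
        assert fit.params.alpha < 3 * np.hypot(fit.se[2], fit.se[3])
        assert fit.seasonality_pvalue > 0.05

    def test_no_deaths_not_identifiable(self):
        from conftest import make_records

        records = make_records([("1800-03-15", "1896-06-01", "male")] * 3)
        counts = sm.build_daily_counts(sm.build_cohort(records, 1800, "male"))
        with pytest.raises(ValueError, match="identifiable"):
            sm.fit_poisson(counts)

    def test_se_shrinks_with_cohort_size(self):
        """Standard errors scale like 1/sqrt(N) across cohort sizes."""
        p = sm.HazardParams(mu=6e-5, beta=2.4e-4, a1=0.2, a2=0.25)
        ses = []
        for i, n in enumerate((5_000, 45_000)):
            rng = np.random.default_rng(SEED + 10 + i)
            df = sm.simulate_cohort(p, 1830, "male", n, rng)
            cohort = cohort_data.build_cohort(df, 1830, "male")
            ses.append(sm.fit_poisson(cohort_data.build_daily_counts(cohort)).se)
        ratio = ses[0] / ses[1]          # expect ~3 for a 9x size increase
        np.testing.assert_allclose(ratio, 3.0, rtol=0.2)


class TestFitDirectML:
    def test_agrees_with_poisson(self, recovery_cohort):
        """Exact per-individual likelihood and the Poisson aggregate agree."""
        fit_p = recovery_cohort["fit"]
        fit_d = sm.fit_direct_ml(recovery_cohort["cohort"])
        assert fit_d.converged
        for key in ("beta", "a1", "a2"):
            rel = abs(fit_p.estimates()[key] - fit_d.estimates()[key]) / abs(
                fit_d.estimates()[key]
            )
            assert rel < 0.01, (key, rel)

    def test_single_person_constant_hazard(self):
        """With everything else pinned, the MLE rate is ~1/lifetime."""
        from conftest import make_records

        lifetime = 2000  # days from t0
        records = make_records([("1800-01-01", "1865-06-23", "male")])
        cohort = sm.build_cohort(records, 1800, "male")
        td = (cohort.members["death_date"][0] - np.datetime64("1860-01-01")).days
        fit = sm.fit_direct_ml(cohort, fix={"beta": 0.0, "a1": 0.0, "a2": 0.0})
        # discrete daily-hazard MLE is log(1 + 1/t_d), within half a day of 1/t_d
        assert fit.params.mu == pytest.approx(np.log(1 + 1 / td), rel=1e-6)
        assert fit.params.mu == pytest.approx(1 / td, rel=1e-3)

    def test_optimum_beats_truth(self, recovery_cohort):
        """The fitted likelihood is at least the likelihood at the truth."""
        cohort = recovery_cohort["cohort"]
        truth = recovery_cohort["truth"]
        fit_d = sm.fit_direct_ml(cohort)
        # evaluate at the fitted params on the individual scale
        mu_ind = fit_d.params.mu * np.exp(-fit_d.params.beta * (365 - fit_d.b_mean))
        at_fit = direct_loglik(
            cohort,
            sm.HazardParams(mu=mu_ind, beta=fit_d.params.beta,
                            a1=fit_d.params.a1, a2=fit_d.params.a2),
        )
        at_truth = direct_loglik(cohort, truth)
        assert at_fit >= at_truth


def test_fit_result_covariance_is_psd(recovery_cohort):
    cov = recovery_cohort["fit"].covariance
    np.testing.assert_allclose(cov, cov.T, atol=1e-15)
    assert np.linalg.eigvalsh(cov).min() > 0
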