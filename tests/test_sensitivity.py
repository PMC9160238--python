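"""Residual-correlation (rho) sensitivity analysis for the mediated effect."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathmed import (
    GeneratorConfig,
    PathModelSpec,
    acme_curve,
    fit_paths,
    generate_cohort,
    rho_to_r2,
)
from pathmed.sensitivity import acme_at_rho


class TestRhoToR2:
    def test_published_zero_crossing_converts_to_twelve_percent(self):
        assert rho_to_r2(0.35) == pytest.approx(0.1225)

    @pytest.mark.parametrize("rho,expected", [(0.0, 0.0), (-0.5, 0.25)])
    def test_values(self, rho, expected):
        assert rho_to_r2(rho) == expected

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_sign_invariance(self, rho):
        assert rho_to_r2(rho) == rho_to_r2(-rho)

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.5])
    def test_domain_enforced(self, rho):
        with pytest.raises(ValueError):
            rho_to_r2(rho)


class TestAcmeCurve:
    def test_acme_at_zero_equals_fitted_indirect(self, ucc_cohort, two_mediator_spec):
        fit = fit_paths(ucc_cohort, two_mediator_spec)
        curve = acme_curve(fit, "ctq_total", rho_grid=np.linspace(-0.9, 0.9, 19))
        at_zero = curve.acme[np.argmin(np.abs(curve.rho))]
        assert at_zero == pytest.approx(
            fit.a["ctq_total"] * fit.b["ctq_total"], abs=1e-10
        )

    def test_monotone_and_zero_crossing_accurate(self, ucc_cohort, two_mediator_spec):
        fit = fit_paths(ucc_cohort, two_mediator_spec)
        curve = acme_curve(fit, "ctq_total")
        assert (np.diff(curve.acme) < 0).all()  # a > 0: decreasing in rho
        assert curve.rho_zero is not None
        sigma_m = np.sqrt(fit.residual_var["ctq_total"])
        sigma_y = np.sqrt(fit.residual_var["cape_total"])
        residual = acme_at_rho(
            fit.a["ctq_total"], fit.b["ctq_total"], sigma_m, sigma_y, curve.rho_zero
        )
        assert abs(residual) < 1e-4 * abs(curve.acme[np.argmin(np.abs(curve.rho))])
        assert curve.r2_at_zero == curve.rho_zero**2

    def test_no_crossing_reported_as_none(self, ucc_cohort, two_mediator_spec):
        fit = fit_paths(ucc_cohort, two_mediator_spec)
        curve = acme_curve(fit, "ctq_total", rho_grid=np.linspace(-0.2, 0.2, 9))
        assert curve.rho_zero is None and curve.r2_at_zero is None

    def test_unknown_mediator_rejected(self, ucc_cohort, two_mediator_spec):
        fit = fit_paths(ucc_cohort, two_mediator_spec)
        with pytest.raises(ValueError):
            acme_curve(fit, "neuroticism")

    def test_planted_confounder_recovers_its_residual_correlation(self):
        """Zero true mediation plus a mediator-outcome confounder with
        residual correlation rho*: the estimated zero-crossing is rho*."""
        rho_star = 0.35
        sd_m, sd_y = 8.0, 12.0
        cfg = GeneratorConfig(
            n_individuals=100_000,
            path_coefficients={
                ("prs", "ctq_total"): 0.171,
                ("prs", "cape_total"): 0.1,
                ("ctq_total", "cape_total"): 0.0,
            },
            residual_sds={"ctq_total": sd_m, "cape_total": sd_y},
            residual_covariances={("ctq_total", "cape_total"): rho_star * sd_m * sd_y},
            marginal_means={"ctq_total": 31.9, "cape_total": 67.3},
        )
        t = generate_cohort(cfg, seed=13)
        spec = PathModelSpec("prs_pt_0.5", ("ctq_total",), "cape_total")
        fit = fit_paths(t, spec)
        curve = acme_curve(fit, "ctq_total")
        # Monte-Carlo error at n=1e5 is a few thousandths on rho
        assert curve.rho_zero == pytest.approx(rho_star, abs=0.015)

    def test_closed_form_agrees_with_brute_force_oracle(self):
        """Generate from a model with known residual correlation and known
        true paths, fit ignoring the correlation, and check the curve at
        the true rho returns the true a*b."""
        rho_true, a_true, b_true = 0.4, 0.171, 0.575
        sd_m, sd_y = 8.0, 12.0
        cfg = GeneratorConfig(
            n_individuals=200_000,
            path_coefficients={
                ("prs", "ctq_total"): a_true,
                ("prs", "cape_total"): 0.19,
                ("ctq_total", "cape_total"): b_true,
            },
            residual_sds={"ctq_total": sd_m, "cape_total": sd_y},
            residual_covariances={("ctq_total", "cape_total"): rho_true * sd_m * sd_y},
            marginal_means={"ctq_total": 31.9, "cape_total": 67.3},
        )
        t = generate_cohort(cfg, seed=17)
        spec = PathModelSpec("prs_pt_0.5", ("ctq_total",), "cape_total")
        fit = fit_paths(t, spec)
        # naive fitted indirect is biased upward by the confounding ...
        assert fit.a["ctq_total"] * fit.b["ctq_total"] > a_true * b_true * 1.5
        # ... but the curve evaluated at the true rho recovers the truth
        sigma_m = np.sqrt(fit.residual_var["ctq_total"])
        sigma_y = np.sqrt(fit.residual_var["cape_total"])
        acme_true = acme_at_rho(
            fit.a["ctq_total"], fit.b["ctq_total"], sigma_m, sigma_y, rho_true
        )
        assert acme_true == pytest.approx(a_true * b_true, abs=0.01)
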