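"""Path-model fitting, effect decomposition and ML equivalences."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathmed import (
    EffectTable,
    MissingSpec,
    ParallelMediation,
    PathModelSpec,
    compute_effects,
    fit_paths,
    generate_cohort,
    inject_missingness,
    linear_adjusted_regression,
)
from pathmed.mediation import FittedPathModel


def fit_from_printed(a: dict, b: dict, direct: float) -> FittedPathModel:
    """A minimal fitted-model object carrying externally supplied paths."""
    mediators = tuple(a)
    spec = PathModelSpec("exposure", mediators, "outcome")
    k = len(spec.variables)
    return FittedPathModel(
        spec=spec,
        n=0,
        mean=np.zeros(k),
        cov=np.eye(k),
        a=a,
        b=b,
        direct=direct,
        covariate_paths={},
        intercepts={},
        residual_var={m: 1.0 for m in mediators} | {"outcome": 1.0},
        mediator_residual_cov=pd.DataFrame(np.eye(len(mediators))),
        standardized_a={m: 0.0 for m in mediators},
        standardized_b={m: 0.0 for m in mediators},
        standardized_direct=0.0,
        r_squared={},
        loglik=0.0,
        method="complete_ml",
    )


class TestEffectDecomposition:
    def test_published_discovery_arithmetic(self):
        """a*b through maltreatment from the printed discovery paths."""
        fit = fit_from_printed(
            a={"cm": 0.171, "cannabis": 0.015},
            b={"cm": 0.575, "cannabis": 2.71},
            direct=0.190,
        )
        eff = compute_effects(fit)
        assert round(eff.indirect["cm"], 3) == 0.098
        assert eff.total == pytest.approx(eff.direct + eff.sum_indirect)

    def test_proportions_from_printed_components(self):
        eff = EffectTable.from_components(
            direct=0.489, indirect={"cm": 0.299, "cannabis": 0.074}
        )
        assert eff.total == pytest.approx(0.862)
        assert 100 * eff.proportion["cm"] == pytest.approx(34.7, abs=0.05)
        assert 100 * eff.proportion["cannabis"] == pytest.approx(8.6, abs=0.05)

    def test_zero_a_paths_total_equals_direct(self):
        fit = fit_from_printed(
            a={"m1": 0.0, "m2": 0.0}, b={"m1": 2.0, "m2": -1.0}, direct=0.3
        )
        eff = compute_effects(fit)
        assert eff.total == eff.direct
        assert all(v == 0.0 for v in eff.proportion.values())

    def test_zero_total_flags_proportions_undefined(self):
        eff = EffectTable.from_components(direct=-0.1, indirect={"m": 0.1})
        assert np.isnan(eff.proportion["m"])

    @given(
        direct=st.floats(-10, 10, allow_nan=False),
        ind1=st.floats(-10, 10, allow_nan=False),
        ind2=st.floats(-10, 10, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_decomposition_identity_exact(self, direct, ind1, ind2):
        eff = EffectTable.from_components(direct, {"m1": ind1, "m2": ind2})
        # bitwise identity: total is direct + sum of indirects
        assert eff.total == eff.direct + eff.sum_indirect
        assert eff.sum_indirect == sum(eff.indirect.values())


class TestFitPaths:
    def test_casewise_equals_complete_on_complete_data(
        self, ucc_cohort, two_mediator_spec
    ):
        f1 = fit_paths(ucc_cohort, two_mediator_spec, "complete_ml")
        f2 = fit_paths(ucc_cohort, two_mediator_spec, "casewise_ml")
        for m in two_mediator_spec.mediators:
            assert f2.a[m] == pytest.approx(f1.a[m], rel=1e-8)
            assert f2.b[m] == pytest.approx(f1.b[m], rel=1e-8)
        assert f2.direct == pytest.approx(f1.direct, rel=1e-8)

    def test_consistency_against_generator_truth(self, big_cohort, two_mediator_spec):
        fit = fit_paths(big_cohort, two_mediator_spec)
        n = len(big_cohort)
        # 3 Monte-Carlo SEs (residual sd / (sqrt(n) * sd of predictor))
        assert fit.a["ctq_total"] == pytest.approx(0.171, abs=3 * 8.36 / (np.sqrt(n) * 5.2))
        assert fit.b["ctq_total"] == pytest.approx(0.575, abs=3 * 12.9 / (np.sqrt(n) * 8.35))
        assert fit.direct == pytest.approx(0.190, abs=3 * 12.9 / (np.sqrt(n) * 5.2))
        assert fit.b["cannabis_case"] == pytest.approx(2.71, abs=3 * 12.9 / (np.sqrt(n) * 0.45))

    def test_equationwise_matches_statsmodels_ols(self, ucc_cohort, two_mediator_spec):
        import statsmodels.api as sm

        fit = fit_paths(ucc_cohort, two_mediator_spec)
        X = sm.add_constant(ucc_cohort[["prs_pt_0.5", "ctq_total", "cannabis_case"]])
        ols = sm.OLS(ucc_cohort["cape_total"], X).fit()
        assert fit.direct == pytest.approx(ols.params["prs_pt_0.5"], rel=1e-9)
        assert fit.b["ctq_total"] == pytest.approx(ols.params["ctq_total"], rel=1e-9)
        med = sm.OLS(
            ucc_cohort["ctq_total"], sm.add_constant(ucc_cohort[["prs_pt_0.5"]])
        ).fit()
        assert fit.a["ctq_total"] == pytest.approx(med.params["prs_pt_0.5"], rel=1e-9)

    def test_joint_likelihood_maximizer_oracle(self, ucc_config, two_mediator_spec):
        """Numerically maximizing the joint Gaussian likelihood of the
        recursive system reproduces the equation-wise ML fit."""
        from scipy.optimize import minimize

        t = generate_cohort(ucc_config, seed=77, n=200)
        fit = fit_paths(t, two_mediator_spec)
        z = t["prs_pt_0.5"].to_numpy()
        m = t[["ctq_total", "cannabis_case"]].to_numpy()
        y = t["cape_total"].to_numpy()

        def negloglik(theta):
            i1, i2, a1, a2, iy, c, b1, b2 = theta[:8]
            ls1, ls2, zr, lsy = theta[8:]
            s1, s2, sy = np.exp(ls1), np.exp(ls2), np.exp(lsy)
            rho = np.tanh(zr)
            mu = np.column_stack([i1 + a1 * z, i2 + a2 * z])
            S = np.array(
                [[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]]
            )
            d = m - mu
            inv = np.linalg.inv(S)
            ll_m = -0.5 * (
                len(z) * (2 * np.log(2 * np.pi) + np.log(np.linalg.det(S)))
                + np.einsum("ij,jk,ik->", d, inv, d)
            )
            r = y - (iy + c * z + b1 * m[:, 0] + b2 * m[:, 1])
            ll_y = -0.5 * (
                len(z) * (np.log(2 * np.pi) + 2 * lsy) + (r**2).sum() / sy**2
            )
            return -(ll_m + ll_y)

        x0 = np.array([30, 0.3, 0.1, 0.01, 50, 0.2, 0.5, 2.0, 2.0, -1.0, 0.1, 2.5])
        opt = minimize(negloglik, x0, method="Nelder-Mead",
                       options={"maxiter": 40000, "xatol": 1e-10, "fatol": 1e-12})
        i1, i2, a1, a2, iy, c, b1, b2 = opt.x[:8]
        assert a1 == pytest.approx(fit.a["ctq_total"], abs=1e-5)
        assert a2 == pytest.approx(fit.a["cannabis_case"], abs=1e-5)
        assert c == pytest.approx(fit.direct, abs=1e-5)
        assert b1 == pytest.approx(fit.b["ctq_total"], abs=1e-5)
        assert b2 == pytest.approx(fit.b["cannabis_case"], abs=1e-4)

    def test_casewise_unbiased_listwise_noisier_under_mcar(self, ucc_config, two_mediator_spec):
        """20% MCAR on the maltreatment score: FIML stays centered on the
        generating a*b while listwise deletion loses precision."""
        cfg = ucc_config.with_updates(
            missingness={"ctq_total": MissingSpec(rate=0.20)}
        )
        truth = 0.171 * 0.575
        cw, lw = [], []
        for s in range(40):
            t = generate_cohort(cfg, seed=500 + s)
            masked = inject_missingness(t, cfg, seed=900 + s)
            f_cw = fit_paths(masked, two_mediator_spec, "casewise_ml")
            f_lw = fit_paths(masked, two_mediator_spec, "listwise")
            cw.append(f_cw.a["ctq_total"] * f_cw.b["ctq_total"])
            lw.append(f_lw.a["ctq_total"] * f_lw.b["ctq_total"])
        cw, lw = np.array(cw), np.array(lw)
        assert cw.mean() == pytest.approx(truth, abs=3 * cw.std() / np.sqrt(len(cw)))
        assert lw.std() > cw.std()

    def test_missing_rule_validation(self, ucc_cohort, ucc_config, two_mediator_spec):
        masked = inject_missingness(ucc_cohort, ucc_config, seed=3)
        with pytest.raises(ValueError, match="complete_ml"):
            fit_paths(masked, two_mediator_spec, "complete_ml")
        with pytest.raises(ValueError, match="missing_rule"):
            fit_paths(ucc_cohort, two_mediator_spec, "banana")

    def test_singular_design_rejected(self, ucc_cohort):
        t = ucc_cohort.copy()
        t["dup"] = t["ctq_total"]
        spec = PathModelSpec("prs_pt_0.5", ("ctq_total", "dup"), "cape_total")
        with pytest.raises(np.linalg.LinAlgError):
            fit_paths(t, spec)

    def test_spec_overlap_rejected(self):
        with pytest.raises(ValueError):
            PathModelSpec("x", ("x",), "y")
        with pytest.raises(ValueError):
            PathModelSpec("x", ("m",), "m")


class TestLinearAdjustedRegression:
    def test_maltreatment_and_prs_raise_ple(self, ucc_cohort):
        res = linear_adjusted_regression(
            ucc_cohort, "cape_total", ["ctq_total", "prs_pt_0.5"], ["age", "gender"]
        )
        assert res.loc["ctq_total", "B"] > 0 and res.loc["ctq_total", "p"] < 0.001
        assert res.loc["prs_pt_0.5", "B"] > 0 and res.loc["prs_pt_0.5", "p"] < 0.05

    def test_outcome_as_predictor_rejected(self, ucc_cohort):
        with pytest.raises(ValueError):
            linear_adjusted_regression(ucc_cohort, "cape_total", ["cape_total"])

    def test_null_predictor_within_noise(self, ucc_cohort):
        res = linear_adjusted_regression(ucc_cohort, "cape_total", ["pc2"])
        assert abs(res.loc["pc2", "B"]) < 3 * res.loc["pc2", "SE"]


class TestEstimatorFacade:
    def test_fit_predict_score(self, ucc_cohort):
        est = ParallelMediation(random_state=0).fit(ucc_cohort)
        assert est.model_.converged
        pred = est.predict(ucc_cohort)
        assert pred.shape == (len(ucc_cohort),)
        assert 0.05 < est.score(ucc_cohort) < 0.5

    def test_get_params_clone_compatible(self):
        from sklearn.base import clone

        est = ParallelMediation(n_boot=200, random_state=5)
        c = clone(est)
        assert c.get_params() == est.get_params()
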