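"""Synthetic-cohort generator: calibration, invariants, missingness."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pathmed import (
    GeneratorConfig,
    MissingSpec,
    default_imagen_config,
    default_ucc_config,
    generate_cohort,
    implied_moments,
    inject_missingness,
)
from pathmed.config import CTQ_SUBSCALES, calibrated_config


class TestDefaultConfigs:
    def test_ucc_design(self, ucc_config):
        assert ucc_config.n_individuals == 1262
        assert ucc_config.path("prs", "ctq_total") == 0.171
        assert ucc_config.path("ctq_total", "cape_total") == 0.575
        assert ucc_config.binary_prevalences["cannabis_case"] == 0.32

    def test_imagen_design(self):
        cfg = default_imagen_config()
        assert cfg.n_individuals == 1740
        assert cfg.path("ctq_total", "cape_total") == 0.496
        assert cfg.binary_prevalences["cannabis_case"] == 0.21

    def test_implied_marginal_sds_match_descriptives(self, ucc_config):
        """Residual SDs are back-solved so implied SDs hit the targets."""
        mean, cov = implied_moments(ucc_config)
        sds = dict(zip(mean.index, np.sqrt(np.diag(cov))))
        assert sds["ctq_total"] == pytest.approx(8.4, abs=1e-9)
        assert sds["cape_total"] == pytest.approx(13.9, abs=1e-9)
        assert mean["ctq_total"] == pytest.approx(31.9)
        assert mean["cape_total"] == pytest.approx(67.3)

    def test_implied_ple_sd_against_monte_carlo(self, ucc_config):
        """Closed-form variance propagation agrees with a large sample."""
        t = generate_cohort(ucc_config, seed=5, n=200_000)
        # SE of an SD estimate is sd/sqrt(2n) ~ 0.022; allow 4 SEs
        assert t["cape_total"].std() == pytest.approx(13.9, abs=0.1)
        assert t["ctq_total"].std() == pytest.approx(8.4, abs=0.06)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_individuals=5)
        with pytest.raises(ValueError):
            GeneratorConfig(binary_prevalences={"cannabis_case": 1.5})
        with pytest.raises(ValueError):
            MissingSpec(rate=1.2)
        with pytest.raises(ValueError):
            # residual covariance far beyond what the scales allow
            GeneratorConfig(
                residual_sds={"ctq_total": 1.0, "neuroticism": 1.0},
                residual_covariances={("ctq_total", "neuroticism"): 50.0},
                marginal_means={"ctq_total": 30.0, "neuroticism": 85.0},
            )


class TestGenerateCohort:
    def test_sample_moments_near_targets_at_design_size(self, ucc_cohort):
        # 3 SEs at n=1262: 3*8.4/sqrt(1262) ~ 0.71 for CTQ
        assert ucc_cohort["ctq_total"].mean() == pytest.approx(31.9, abs=0.71)
        assert ucc_cohort["cape_total"].mean() == pytest.approx(67.3, abs=1.18)

    def test_cannabis_prevalence_imagen(self):
        cfg = default_imagen_config()
        t = generate_cohort(cfg, seed=9, n=1_000_000)
        assert t["cannabis_case"].mean() == pytest.approx(0.21, abs=0.0013)

    def test_path_recovery_by_ols(self, big_cohort):
        """Equation-wise OLS on a large cohort recovers configured slopes."""
        n = len(big_cohort)
        X = sm.add_constant(big_cohort[["prs_pt_0.5", "ctq_total", "cannabis_case"]])
        fit = sm.OLS(big_cohort["cape_total"], X).fit()
        assert fit.params["prs_pt_0.5"] == pytest.approx(0.190, abs=3 * fit.bse["prs_pt_0.5"])
        assert fit.params["ctq_total"] == pytest.approx(0.575, abs=3 * fit.bse["ctq_total"])
        assert fit.params["cannabis_case"] == pytest.approx(2.71, abs=3 * fit.bse["cannabis_case"])
        med = sm.OLS(
            big_cohort["ctq_total"], sm.add_constant(big_cohort[["prs_pt_0.5"]])
        ).fit()
        assert med.params["prs_pt_0.5"] == pytest.approx(0.171, abs=3 * med.bse["prs_pt_0.5"])
        can = sm.OLS(
            big_cohort["cannabis_case"], sm.add_constant(big_cohort[["prs_pt_0.5"]])
        ).fit()
        assert can.params["prs_pt_0.5"] == pytest.approx(0.015, abs=3 * can.bse["prs_pt_0.5"])

    def test_zero_slopes_give_independence(self):
        cfg = calibrated_config(
            "ucc",
            {
                ("prs", "ctq_total"): 0.0,
                ("prs", "cannabis_case"): 0.0,
                ("prs", "cape_total"): 0.0,
                ("ctq_total", "cape_total"): 0.0,
                ("cannabis_case", "cape_total"): 0.0,
                ("prs", "neuroticism"): 0.0,
                ("prs", "tobacco_case"): 0.0,
            },
        )
        t = generate_cohort(cfg, seed=3, n=20_000)
        r = np.corrcoef(t["prs_pt_0.5"], t["cape_total"])[0, 1]
        assert abs(r) < 3 / np.sqrt(len(t))

    def test_seed_determinism(self, ucc_config):
        a = generate_cohort(ucc_config, seed=42)
        b = generate_cohort(ucc_config, seed=42)
        assert a.to_csv() == b.to_csv()
        c = generate_cohort(ucc_config, seed=43)
        assert not a.equals(c)

    def test_prs_interthreshold_correlation(self, big_cohort):
        r = np.corrcoef(big_cohort["prs_pt_0.5"], big_cohort["prs_pt_0.3"])[0, 1]
        assert r == pytest.approx(0.99, abs=0.005)

    def test_subscales_sum_to_total(self, ucc_cohort):
        total = ucc_cohort[list(CTQ_SUBSCALES)].sum(axis=1)
        assert np.allclose(total, ucc_cohort["ctq_total"], atol=1e-8)

    def test_minimum_size_enforced(self, ucc_config):
        with pytest.raises(ValueError):
            generate_cohort(ucc_config, seed=0, n=5)


class TestInjectMissingness:
    def test_zero_rate_is_identity(self, ucc_cohort, ucc_config):
        cfg = ucc_config.with_updates(
            missingness={"ctq_total": MissingSpec(rate=0.0)}
        )
        out = inject_missingness(ucc_cohort, cfg, seed=1)
        pd.testing.assert_frame_equal(out, ucc_cohort)

    def test_mcar_count_mean_matches_configured_rate(self):
        """Cannabis masking at the replication cohort's observed rate."""
        cfg = default_imagen_config()
        t = generate_cohort(cfg, seed=2)
        counts = [
            inject_missingness(t, cfg, seed=s)["cannabis_case"].isna().sum()
            for s in range(30)
        ]
        # Binomial(1740, 234/1740): mean 234, SE of the mean over 30 draws ~2.6
        assert np.mean(counts) == pytest.approx(234, abs=10)

    def test_fully_observed_variables_never_masked(self, ucc_cohort, ucc_config):
        out = inject_missingness(ucc_cohort, ucc_config, seed=4)
        for col in ("age", "gender", "prs_pt_0.5", "pc1"):
            assert out[col].notna().all()
        cfg = ucc_config.with_updates(missingness={"age": MissingSpec(rate=0.1)})
        with pytest.raises(ValueError):
            inject_missingness(ucc_cohort, cfg, seed=4)

    def test_mar_masking_depends_on_covariate_not_masked_value(self, ucc_config):
        """MAR-on-neuroticism: the mask tracks neuroticism; given it, the
        (pre-masking) CTQ value adds nothing."""
        cfg = ucc_config.with_updates(
            missingness={
                "ctq_total": MissingSpec(rate=0.25, mechanism="mar", on="neuroticism")
            }
        )
        t = generate_cohort(cfg, seed=6, n=20_000)
        masked = inject_missingness(t, cfg, seed=7)
        ind = masked["ctq_total"].isna().astype(float)
        X = sm.add_constant(
            pd.DataFrame(
                {
                    "neuroticism": t["neuroticism"],
                    "ctq_true": t["ctq_total"],
                }
            )
        )
        logit = sm.Logit(ind, X).fit(disp=0)
        assert logit.tvalues["neuroticism"] > 5
        assert abs(logit.tvalues["ctq_true"]) < 3
        assert ind.mean() == pytest.approx(0.25, abs=0.02)
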