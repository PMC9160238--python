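"""Population model for synthetic cohort generation.

The generator emulates a young-adult cohort in which a schizophrenia
polygenic risk score (SZ-PRS, available at several GWAS p-value inclusion
thresholds) influences psychotic-like experiences (PLE, CAPE-42 total)
directly and through childhood maltreatment (CTQ total) and cannabis use
(lifetime >= 10 uses, binary).  The structural system is recursive and
linear; binary mediators are produced by thresholding a latent Gaussian
propensity calibrated so that the *linear-probability* slope of the 0/1
indicator on the PRS equals the configured path coefficient, matching how
a linear ML path analysis treats a binary mediator.

All default numbers are calibrated so that the implied marginal moments
match the cohort descriptives and the implied regression slopes match the
published path coefficients of the discovery (UCC, n=1262) and replication
(IMAGEN, n=1740) samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "GeneratorConfig",
    "default_ucc_config",
    "default_imagen_config",
    "calibrated_config",
    "implied_moments",
    "PRS_THRESHOLDS",
    "prs_column_name",
    "CTQ_SUBSCALES",
]

#: GWAS p-value inclusion thresholds at which the PRS is computed.
PRS_THRESHOLDS = (
    5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 5e-3, 5e-2,
    0.1, 0.2, 0.3, 0.4, 0.5, 1.0,
)

#: CTQ maltreatment subscales (5 items each, range 5-25).
CTQ_SUBSCALES = (
    "ctq_emotional_abuse",
    "ctq_physical_abuse",
    "ctq_sexual_abuse",
    "ctq_emotional_neglect",
    "ctq_physical_neglect",
)

#: Variables the generator treats as structural (mediators + outcome).
CONTINUOUS_STRUCTURAL = ("ctq_total", "neuroticism", "cape_total")
BINARY_STRUCTURAL = ("cannabis_case", "tobacco_case")


def prs_column_name(threshold: float) -> str:
    """Canonical column name for the PRS at a p-value threshold."""
    if threshold >= 0.01:
        return f"prs_pt_{threshold:g}"
    return f"prs_pt_{threshold:.0e}".replace("e-0", "e-")


@dataclass
class MissingSpec:
    """Per-variable missingness: rate plus mechanism.

    mechanism "mcar" masks cells independently at `rate`; "mar" makes the
    masking probability a logistic function of the named covariate with
    slope `strength` (per SD of the covariate), with the intercept solved
    so the marginal rate still equals `rate`.
    """

    rate: float
    mechanism: str = "mcar"  # "mcar" | "mar"
    on: str | None = None
    strength: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"missingness rate must be in [0, 1], got {self.rate}")
        if self.mechanism not in ("mcar", "mar"):
            raise ValueError(f"unknown missingness mechanism {self.mechanism!r}")
        if self.mechanism == "mar" and not self.on:
            raise ValueError("MAR missingness needs a conditioning variable ('on')")


@dataclass
class GeneratorConfig:
    """Full population model for a synthetic cohort.

    Path coefficients are unstandardized slopes keyed by
    ``(source, target)`` with the exposure called ``"prs"``; slopes into a
    binary variable are linear-probability slopes (probability points per
    PRS unit).  Residual SDs are on the observed scale of each continuous
    structural variable; residual covariances are on the observed scale
    (for a binary variable, the covariance between the other variable's
    residual and the 0/1 indicator net of the exposure).
    """

    n_individuals: int = 1262
    prs_thresholds: tuple[float, ...] = PRS_THRESHOLDS
    prs_interthreshold_corr: float = 0.99
    prs_sd: float = 5.2
    signal_threshold: float = 0.5
    path_coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    residual_sds: dict[str, float] = field(default_factory=dict)
    residual_covariances: dict[tuple[str, str], float] = field(default_factory=dict)
    marginal_means: dict[str, float] = field(default_factory=dict)
    binary_prevalences: dict[str, float] = field(default_factory=dict)
    missingness: dict[str, MissingSpec] = field(default_factory=dict)
    age_mean: float = 20.5
    age_sd: float = 2.5
    male_fraction: float = 0.48
    pc_prs_corr: dict[str, float] = field(default_factory=lambda: {"pc1": 0.15})
    ctq_subscale_weights: dict[str, float] = field(
        default_factory=lambda: {
            "ctq_emotional_abuse": 0.25,
            "ctq_physical_abuse": 0.15,
            "ctq_sexual_abuse": 0.12,
            "ctq_emotional_neglect": 0.30,
            "ctq_physical_neglect": 0.18,
        }
    )
    ctq_subscale_means: dict[str, float] = field(default_factory=dict)
    ctq_subscale_noise_sd: float = 1.5
    round_scores: bool = False
    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        if self.n_individuals < 10:
            raise ValueError("n_individuals must be at least 10")
        if not 0.0 <= self.prs_interthreshold_corr <= 1.0:
            raise ValueError("prs_interthreshold_corr must be in [0, 1]")
        for var, p in self.binary_prevalences.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence of {var} must be in (0, 1), got {p}")
        if self.signal_threshold not in self.prs_thresholds:
            raise ValueError("signal_threshold must be one of prs_thresholds")
        if not self.ctq_subscale_means:
            mean = self.marginal_means.get("ctq_total", 31.9)
            w = self.ctq_subscale_weights
            self.ctq_subscale_means = {
                k: 5.0 + w[k] * (mean - 25.0) for k in CTQ_SUBSCALES
            }
        if abs(sum(self.ctq_subscale_weights.values()) - 1.0) > 1e-9:
            raise ValueError("ctq_subscale_weights must sum to 1")
        # construction-time check of the implied residual structure
        self.latent_residual_corr()

    # ------------------------------------------------------------------
    @property
    def signal_column(self) -> str:
        return prs_column_name(self.signal_threshold)

    def path(self, source: str, target: str) -> float:
        return self.path_coefficients.get((source, target), 0.0)

    def residual_cov(self, a: str, b: str) -> float:
        return self.residual_covariances.get(
            (a, b), self.residual_covariances.get((b, a), 0.0)
        )

    # -- latent calibration of binary variables ------------------------
    def binary_cut(self, var: str) -> float:
        """Latent threshold: the indicator is 1 when the N(0,1) latent exceeds it."""
        return stats.norm.ppf(1.0 - self.binary_prevalences[var])

    def binary_loading(self, var: str) -> float:
        """Loading of the standardized PRS on the latent propensity.

        Calibrated so the linear-probability OLS slope of the indicator on
        the PRS equals the configured path coefficient:
        cov(I, Z) = alpha * phi(cut) * sd(Z) must equal slope * var(Z).
        """
        slope = self.path("prs", var)
        alpha = slope * self.prs_sd / stats.norm.pdf(self.binary_cut(var))
        if abs(alpha) >= 1.0:
            raise ValueError(
                f"linear-probability slope {slope} for {var} is not attainable "
                f"at prevalence {self.binary_prevalences[var]}"
            )
        return alpha

    def _residual_scales(self) -> dict[str, float]:
        """SD of each structural residual on its generating (latent) scale."""
        scales = {}
        for var in CONTINUOUS_STRUCTURAL:
            if var in self.residual_sds:
                scales[var] = self.residual_sds[var]
        for var in BINARY_STRUCTURAL:
            if var in self.binary_prevalences:
                scales[var] = math.sqrt(1.0 - self.binary_loading(var) ** 2)
        return scales

    def latent_residual_corr(self) -> tuple[list[str], np.ndarray]:
        """Correlation matrix of structural residuals on the latent scale.

        Observed-scale residual covariances are converted: for a
        continuous pair r = cov/(sd_i sd_j); for continuous-binary the
        thresholding attenuates covariance by phi(cut); for binary-binary
        the latent correlation is recovered by inverting the bivariate
        normal orthant probability.  Positive semidefiniteness of the
        result is a validity requirement of the configuration.
        """
        scales = self._residual_scales()
        names = [v for v in (*CONTINUOUS_STRUCTURAL, *BINARY_STRUCTURAL) if v in scales]
        k = len(names)
        corr = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                a, b = names[i], names[j]
                target = self.residual_cov(a, b)
                if target == 0.0:
                    continue
                r = self._latent_pair_corr(a, b, target, scales)
                corr[i, j] = corr[j, i] = r
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-8:
            raise ValueError(
                "implied residual correlation matrix is not positive "
                f"semidefinite (min eigenvalue {eigvals.min():.3g})"
            )
        return names, corr

    def _latent_pair_corr(self, a, b, target, scales) -> float:
        bin_a, bin_b = a in BINARY_STRUCTURAL, b in BINARY_STRUCTURAL
        if not bin_a and not bin_b:
            r = target / (scales[a] * scales[b])
        elif bin_a != bin_b:
            cont, binv = (b, a) if bin_a else (a, b)
            phi = stats.norm.pdf(self.binary_cut(binv))
            r = target / (scales[cont] * scales[binv] * phi)
        else:
            r = self._binary_pair_corr(a, b, target, scales)
        if abs(r) >= 1.0:
            raise ValueError(
                f"residual covariance {target} between {a} and {b} is not "
                f"attainable (implied latent correlation {r:.3f})"
            )
        return r

    def _binary_pair_corr(self, a, b, target, scales) -> float:
        from scipy.optimize import brentq

        ca, cb = self.binary_cut(a), self.binary_cut(b)
        pa = self.binary_prevalences[a]
        pb = self.binary_prevalences[b]
        aa, ab = self.binary_loading(a), self.binary_loading(b)
        sa, sb = self.path("prs", a), self.path("prs", b)
        # total indicator covariance = residual target + exposure-shared part
        total = target + sa * sb * self.prs_sd**2

        def orthant_cov(rho_total: float) -> float:
            cov = np.array([[1.0, rho_total], [rho_total, 1.0]])
            p11 = stats.multivariate_normal.cdf([-ca, -cb], mean=[0, 0], cov=cov)
            return p11 - pa * pb

        lo, hi = -0.999, 0.999
        f_lo, f_hi = orthant_cov(lo) - total, orthant_cov(hi) - total
        if f_lo * f_hi > 0:
            raise ValueError(
                f"binary-binary residual covariance {target} between {a} and "
                f"{b} is not attainable at the configured prevalences"
            )
        rho_total = brentq(lambda r: orthant_cov(r) - total, lo, hi, xtol=1e-10)
        return (rho_total - aa * ab) / (scales[a] * scales[b])

    def with_updates(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with replaced top-level fields."""
        return replace(self, **kwargs)


# ----------------------------------------------------------------------
# implied moments of the structural system (closed form)
# ----------------------------------------------------------------------

def implied_moments(config: GeneratorConfig):
    """Population mean vector and covariance matrix implied by a config.

    Covers the exposure (signal PRS column) and the structural variables.
    Indicator moments use exact Gaussian-threshold formulas, including the
    bivariate-normal orthant probability for indicator pairs, so the
    result can be validated against Monte-Carlo samples.
    """
    import pandas as pd

    names = [config.signal_column]
    means = [0.0]
    present_cont = [v for v in CONTINUOUS_STRUCTURAL if v != "cape_total"
                    and v in config.residual_sds]
    present_bin = [v for v in BINARY_STRUCTURAL if v in config.binary_prevalences]
    mediators = present_cont + present_bin
    for v in present_cont:
        names.append(v)
        means.append(config.marginal_means.get(v, 0.0))
    for v in present_bin:
        names.append(v)
        means.append(config.binary_prevalences[v])

    k = len(names)
    cov = np.zeros((k, k))
    var_z = config.prs_sd**2
    cov[0, 0] = var_z
    scales = config._residual_scales()
    res_names, res_corr = config.latent_residual_corr()

    def rescov(a: str, b: str) -> float:
        """Residual covariance on the *indicator/observed* scale."""
        if a not in res_names or b not in res_names:
            return 0.0
        i, j = res_names.index(a), res_names.index(b)
        r = res_corr[i, j]
        bin_a, bin_b = a in present_bin, b in present_bin
        if not bin_a and not bin_b:
            return r * scales[a] * scales[b]
        if bin_a != bin_b:
            binv = a if bin_a else b
            cont = b if bin_a else a
            return r * scales[cont] * scales[binv] * stats.norm.pdf(config.binary_cut(binv))
        rho_total = r * scales[a] * scales[b] + config.binary_loading(a) * config.binary_loading(b)
        ca, cb = config.binary_cut(a), config.binary_cut(b)
        p11 = stats.multivariate_normal.cdf(
            [-ca, -cb], mean=[0, 0], cov=[[1, rho_total], [rho_total, 1]]
        )
        pa, pb = config.binary_prevalences[a], config.binary_prevalences[b]
        return (p11 - pa * pb) - config.path("prs", a) * config.path("prs", b) * var_z

    # mediator block
    for vi in mediators:
        i = names.index(vi)
        ai = config.path("prs", vi)
        cov[0, i] = cov[i, 0] = ai * var_z
        for vj in mediators:
            j = names.index(vj)
            if j < i:
                continue
            aj = config.path("prs", vj)
            if i == j:
                if vi in present_bin:
                    p = config.binary_prevalences[vi]
                    cov[i, i] = p * (1.0 - p)
                else:
                    cov[i, i] = ai**2 * var_z + scales[vi] ** 2
            else:
                cov[i, j] = cov[j, i] = ai * aj * var_z + rescov(vi, vj)

    # outcome
    if "cape_total" in config.residual_sds:
        y = len(names)
        names.append("cape_total")
        betas = {v: config.path(v, "cape_total") for v in mediators}
        c_prime = config.path("prs", "cape_total")
        mu_y = config.marginal_means.get("cape_total", 0.0)
        means.append(mu_y)
        cov = np.pad(cov, ((0, 1), (0, 1)))
        sigma_y = config.residual_sds["cape_total"]
        for i, vi in enumerate(names[:-1]):
            c = c_prime * cov[0, i]
            for v, b in betas.items():
                c += b * cov[names.index(v), i]
            if vi != config.signal_column:
                c += rescov(vi, "cape_total")
            cov[y, i] = cov[i, y] = c
        # Var(Y) = c' Cov(Z,Y) + sum_k beta_k Cov(X_k,Y) + Cov(e_y,Y),
        # with Cov(e_y,Y) = sigma^2 + sum_k beta_k Cov(e_y, X_k)
        cov[y, y] = (
            c_prime * cov[0, y]
            + sum(b * cov[names.index(v), y] for v, b in betas.items())
            + sigma_y**2
            + sum(b * rescov(v, "cape_total") for v, b in betas.items())
        )

    mean = pd.Series(means, index=names)
    cov_df = pd.DataFrame(cov, index=names, columns=names)
    return mean, cov_df


# ----------------------------------------------------------------------
# default configurations calibrated to the two cohorts
# ----------------------------------------------------------------------

def _backsolve_residuals(
    cfg: GeneratorConfig, marginal_sds: dict[str, float]
) -> GeneratorConfig:
    """Fill residual SDs so implied marginal SDs match the targets.

    Mediator equations depend only on the exposure, so their residual SDs
    follow directly; the outcome residual SD absorbs everything the linear
    predictor (and any mediator-outcome residual covariance) explains.
    """
    var_z = cfg.prs_sd**2
    res = dict(cfg.residual_sds)
    for var in ("ctq_total", "neuroticism"):
        if var in marginal_sds:
            a = cfg.path("prs", var)
            v = marginal_sds[var] ** 2 - a**2 * var_z
            if v <= 0:
                raise ValueError(f"marginal SD of {var} too small for its a-path")
            res[var] = math.sqrt(v)
    cfg = cfg.with_updates(residual_sds=res)
    if "cape_total" in marginal_sds:
        # moments of exposure + mediators only (no outcome row yet)
        mean, cov = implied_moments(cfg)
        names = list(mean.index)
        w = np.array(
            [cfg.path("prs", "cape_total")]
            + [cfg.path(v, "cape_total") for v in names[1:]]
        )
        quadform = float(w @ cov.to_numpy() @ w)
        extra = 2.0 * sum(
            cfg.path(v, "cape_total") * cfg.residual_cov(v, "cape_total")
            for v in names[1:]
        )
        v = marginal_sds["cape_total"] ** 2 - quadform - extra
        if v <= 0:
            raise ValueError("marginal SD of cape_total too small for the paths")
        res["cape_total"] = math.sqrt(v)
    return cfg.with_updates(residual_sds=res)


def default_ucc_config() -> GeneratorConfig:
    """Discovery-cohort population model (UCC, n=1262).

    Slopes are the published unstandardized path estimates; the PRS SD of
    5.2 is back-derived from the ratio of standardized to unstandardized
    coefficients, and residual SDs are back-solved so the implied marginal
    SDs reproduce the cohort descriptives (CTQ 31.9/8.4, CAPE 67.3/13.9).
    Neuroticism and tobacco carry their published a-paths and mediator
    residual covariances but no direct effect on the outcome.
    """
    cfg = GeneratorConfig(
        n_individuals=1262,
        prs_sd=5.2,
        path_coefficients={
            ("prs", "ctq_total"): 0.171,
            ("prs", "cannabis_case"): 0.015,
            ("prs", "cape_total"): 0.190,
            ("ctq_total", "cape_total"): 0.575,
            ("cannabis_case", "cape_total"): 2.71,
            ("prs", "neuroticism"): 0.247,
            ("prs", "tobacco_case"): 0.012,
        },
        residual_sds={},
        residual_covariances={
            ("ctq_total", "cannabis_case"): 0.489,
            ("ctq_total", "neuroticism"): 80.89,
            ("ctq_total", "tobacco_case"): 0.149,
            ("cannabis_case", "tobacco_case"): 0.129,
            ("cannabis_case", "neuroticism"): 0.080,
            ("neuroticism", "tobacco_case"): 0.472,
        },
        marginal_means={
            "ctq_total": 31.9,
            "cape_total": 67.3,
            "neuroticism": 85.0,
        },
        binary_prevalences={"cannabis_case": 0.32, "tobacco_case": 0.30},
        missingness={"ctq_total": MissingSpec(rate=341 / 1262)},
        age_mean=20.5,
        age_sd=2.5,
        male_fraction=0.48,
    )
    return _backsolve_residuals(
        cfg, {"ctq_total": 8.4, "cape_total": 13.9, "neuroticism": 25.0}
    )


def default_imagen_config() -> GeneratorConfig:
    """Replication-cohort population model (IMAGEN, n=1740)."""
    cfg = GeneratorConfig(
        n_individuals=1740,
        prs_sd=0.93,
        path_coefficients={
            ("prs", "ctq_total"): 0.603,
            ("prs", "cannabis_case"): 0.041,
            ("prs", "cape_total"): 0.489,
            ("ctq_total", "cape_total"): 0.496,
            ("cannabis_case", "cape_total"): 1.79,
        },
        residual_sds={},
        residual_covariances={("ctq_total", "cannabis_case"): 0.389},
        marginal_means={
            "ctq_total": 40.2,
            "cape_total": 60.6,
            "neuroticism": 85.0,
        },
        binary_prevalences={"cannabis_case": 0.21, "tobacco_case": 0.34},
        missingness={
            "ctq_total": MissingSpec(rate=396 / 1740),
            "cannabis_case": MissingSpec(rate=234 / 1740),
        },
        age_mean=19.4,
        age_sd=1.5,
        male_fraction=0.47,
    )
    return _backsolve_residuals(
        cfg, {"ctq_total": 6.5, "cape_total": 11.4, "neuroticism": 25.0}
    )


_MARGINAL_SD_TARGETS = {
    "ucc": {"ctq_total": 8.4, "cape_total": 13.9, "neuroticism": 25.0},
    "imagen": {"ctq_total": 6.5, "cape_total": 11.4, "neuroticism": 25.0},
}


def calibrated_config(
    cohort: str = "ucc",
    path_overrides: dict[tuple[str, str], float] | None = None,
    **field_overrides,
) -> GeneratorConfig:
    """Default cohort config with selected paths replaced, re-calibrated.

    Residual SDs are re-solved so the implied marginal SDs still match
    the cohort targets after the override — useful for what-if studies
    (e.g. setting a single a-path to zero while keeping everything else
    at the published operating point).
    """
    base = default_ucc_config() if cohort == "ucc" else default_imagen_config()
    paths = dict(base.path_coefficients)
    if path_overrides:
        paths.update(path_overrides)
    cfg = base.with_updates(
        path_coefficients=paths,
        residual_sds={},
        **field_overrides,
    )
    return _backsolve_residuals(cfg, _MARGINAL_SD_TARGETS[cohort])
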