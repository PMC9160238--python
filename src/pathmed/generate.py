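"""Synthetic cohort generation and missingness injection."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import (
    BINARY_STRUCTURAL,
    CTQ_SUBSCALES,
    GeneratorConfig,
    MissingSpec,
    prs_column_name,
)

__all__ = ["generate_cohort", "inject_missingness"]


def generate_cohort(
    config: GeneratorConfig, seed: int | None = None, n: int | None = None
) -> pd.DataFrame:
    """Draw a complete synthetic cohort from the structural model.

    Exogenous block first (PRS columns as an equicorrelated Gaussian
    vector, demographics, genetic PCs), then mediators and outcome from
    the recursive linear system with correlated residuals.  Binary
    variables arise by thresholding a latent propensity at the quantile
    matching the configured prevalence.  The returned table is fully
    observed; use :func:`inject_missingness` afterwards.

    Parameters
    ----------
    config : population model (validated at construction).
    seed : overrides ``config.seed``.
    n : overrides ``config.n_individuals``.
    """
    if seed is None:
        seed = config.seed
    if n is None:
        n = config.n_individuals
    if n < 10:
        raise ValueError("cohort size must be at least 10")
    rng = np.random.default_rng(seed)

    # --- exogenous block ------------------------------------------------
    r = config.prs_interthreshold_corr
    k = len(config.prs_thresholds)
    common = rng.standard_normal(n)
    unique = rng.standard_normal((n, k))
    prs_std = np.sqrt(r) * common[:, None] + np.sqrt(1.0 - r) * unique
    prs = prs_std * config.prs_sd
    prs_cols = [prs_column_name(t) for t in config.prs_thresholds]
    z_std = prs_std[:, prs_cols.index(config.signal_column)]
    z = z_std * config.prs_sd

    age = rng.normal(config.age_mean, config.age_sd, size=n)
    gender = (rng.random(n) < config.male_fraction).astype(int)  # 1 = male
    pcs = {}
    for name in ("pc1", "pc2", "pc3"):
        rho = config.pc_prs_corr.get(name, 0.0)
        pcs[name] = rho * z_std + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    # --- structural residuals -------------------------------------------
    res_names, res_corr = config.latent_residual_corr()
    scales = config._residual_scales()
    chol = np.linalg.cholesky(res_corr + 1e-12 * np.eye(len(res_names)))
    resid = rng.standard_normal((n, len(res_names))) @ chol.T
    resid = {v: resid[:, i] * scales[v] for i, v in enumerate(res_names)}

    # --- mediators -------------------------------------------------------
    cols: dict[str, np.ndarray] = {}
    mediator_values: dict[str, np.ndarray] = {}
    for var in res_names:
        if var == "cape_total":
            continue
        if var in BINARY_STRUCTURAL:
            latent = config.binary_loading(var) * z_std + resid[var]
            values = (latent > config.binary_cut(var)).astype(int)
        else:
            values = (
                config.marginal_means.get(var, 0.0)
                + config.path("prs", var) * z
                + resid[var]
            )
        cols[var] = values
        mediator_values[var] = values

    # --- outcome ---------------------------------------------------------
    if "cape_total" in res_names:
        mu_y = config.marginal_means.get("cape_total", 0.0)
        intercept = mu_y - sum(
            config.path(v, "cape_total")
            * (
                config.binary_prevalences[v]
                if v in BINARY_STRUCTURAL
                else config.marginal_means.get(v, 0.0)
            )
            for v in mediator_values
        )
        y = intercept + config.path("prs", "cape_total") * z + resid["cape_total"]
        for v, values in mediator_values.items():
            y = y + config.path(v, "cape_total") * values
        cols["cape_total"] = y

    # --- CTQ subscales: partition the total into correlated components ---
    if "ctq_total" in cols:
        total = cols["ctq_total"]
        mu = config.marginal_means.get("ctq_total", 0.0)
        weights = config.ctq_subscale_weights
        noise = rng.normal(0.0, config.ctq_subscale_noise_sd, size=(n, len(CTQ_SUBSCALES)))
        w = np.array([weights[s] for s in CTQ_SUBSCALES])
        noise -= noise.sum(axis=1, keepdims=True) * w  # zero-sum so parts add up
        for j, sub in enumerate(CTQ_SUBSCALES):
            cols[sub] = config.ctq_subscale_means[sub] + w[j] * (total - mu) + noise[:, j]

    table = pd.DataFrame(
        {
            "id": [f"S{i:06d}" for i in range(n)],
            "age": age,
            "gender": gender,
            **pcs,
            **{c: prs[:, j] for j, c in enumerate(prs_cols)},
        }
    )
    for name, values in cols.items():
        table[name] = values

    if config.round_scores:
        _round_to_instruments(table)
    return table


def _round_to_instruments(table: pd.DataFrame) -> None:
    """Optional integer rounding and clipping to questionnaire ranges."""
    bounds = {"ctq_total": (25, 125), "cape_total": (42, 168)}
    bounds.update({s: (5, 25) for s in CTQ_SUBSCALES})
    for col, (lo, hi) in bounds.items():
        if col in table:
            table[col] = table[col].round().clip(lo, hi)
    if "neuroticism" in table:
        table["neuroticism"] = table["neuroticism"].round()
    if set(CTQ_SUBSCALES) <= set(table.columns):
        table["ctq_total"] = table[list(CTQ_SUBSCALES)].sum(axis=1)


#: variables that are never masked (fully observed by design)
ALWAYS_OBSERVED_PREFIXES = ("prs_pt_", "pc")
ALWAYS_OBSERVED = ("id", "age", "gender")


def inject_missingness(
    table: pd.DataFrame, config: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Mask cells according to the configured per-variable missingness.

    MCAR masks cells independently at the configured rate; MAR masks with
    a logistic probability in the conditioning covariate (standardized),
    intercept solved so the marginal rate is preserved.  Masking
    ``ctq_total`` also masks the five subscales of the same rows, keeping
    the total-equals-sum-of-subscales identity on observed data.
    Variables declared fully observed are never masked.
    """
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    for var, spec in config.missingness.items():
        if spec.rate == 0.0:
            continue
        if var in ALWAYS_OBSERVED or var.startswith(ALWAYS_OBSERVED_PREFIXES):
            raise ValueError(f"{var} is declared fully observed and cannot be masked")
        if var not in out.columns:
            raise ValueError(f"missingness configured for unknown variable {var!r}")
        mask = _draw_mask(out, spec, n, rng)
        out.loc[mask, var] = np.nan
        if var == "ctq_total":
            for sub in CTQ_SUBSCALES:
                if sub in out.columns:
                    out.loc[mask, sub] = np.nan
    return out


def _draw_mask(
    table: pd.DataFrame, spec: MissingSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.mechanism == "mcar":
        return rng.random(n) < spec.rate
    w = table[spec.on].to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValueError(f"MAR conditioning variable {spec.on!r} has missing values")
    w_std = (w - w.mean()) / w.std()
    beta1 = spec.strength

    def marginal(beta0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(beta0 + beta1 * w_std)))))

    beta0 = brentq(lambda b: marginal(b) - spec.rate, -30.0, 30.0, xtol=1e-10)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * w_std)))
    return rng.random(n) < p
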