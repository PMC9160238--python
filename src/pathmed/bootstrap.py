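"""Nonparametric bootstrap with bias-corrected accelerated (BCa) intervals.

Individuals (rows) are resampled with replacement; every replicate refits
the path model and recomputes the effect decomposition.  For complete
data the refit reduces to re-weighted first and second moments, which is
computed for all replicates at once from multinomial resampling weights
(algebraically identical to resampling rows).  The bias-correction
constant z0 comes from the share of replicates below the point estimate
and the acceleration constant from jackknife influence values; with both
zero the interval is the plain percentile interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mediation import (
    PathModelSpec,
    _extract,
    effect_quantity_names,
    fit_paths,
    paths_from_moments_batch,
    quantity_vector,
)

__all__ = ["BootstrapResult", "bootstrap_ci"]


@dataclass
class BootstrapResult:
    """Replicate summaries and BCa intervals for the effect quantities."""

    quantities: list[str]
    estimate: dict[str, float]
    n_boot: int
    n_effective: int                 # replicates that produced a valid refit
    n_skipped: int
    z0: dict[str, float]
    accel: dict[str, float]
    ci: dict[str, tuple[float, float]]
    pvalue: dict[str, float]
    alpha: float
    seed: int
    replicates: np.ndarray = field(repr=False, default=None)

    def significant(self, quantity: str) -> bool:
        lo, hi = self.ci[quantity]
        return lo > 0.0 or hi < 0.0


def _augment(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Columns [x, vech(x x')] so weighted moments are one matmul."""
    n, p = X.shape
    iu = np.triu_indices(p)
    cross = (X[:, :, None] * X[:, None, :])[:, iu[0], iu[1]]
    return np.hstack([X, cross]), iu[0], iu[1]


def _moments_from_weights(
    WA: np.ndarray, n: int, p: int, iu_r: np.ndarray, iu_c: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    B = WA.shape[0]
    means = WA[:, :p] / n
    covs = np.empty((B, p, p))
    covs[:, iu_r, iu_c] = WA[:, p:] / n
    covs[:, iu_c, iu_r] = WA[:, p:] / n
    covs -= means[:, :, None] * means[:, None, :]
    return means, covs


def _batch_quantities(
    means: np.ndarray, covs: np.ndarray, spec: PathModelSpec
) -> np.ndarray:
    """(B, q) effect quantities; NaN rows where the refit is degenerate."""
    B = means.shape[0]
    q = len(effect_quantity_names(spec))
    out = np.full((B, q), np.nan)
    # a replicate with a constant column yields a singular weighted design
    diag = np.einsum("bii->bi", covs)
    ok = (diag > 1e-12 * np.maximum(1.0, diag.max(axis=0))).all(axis=1)
    idx = np.where(ok)[0]
    if idx.size:
        try:
            batch = paths_from_moments_batch(means[idx], covs[idx], spec)
            out[idx] = quantity_vector(batch)
        except np.linalg.LinAlgError:
            for i in idx:
                try:
                    b = paths_from_moments_batch(
                        means[i : i + 1], covs[i : i + 1], spec
                    )
                    out[i] = quantity_vector(b)[0]
                except np.linalg.LinAlgError:
                    pass
    return out


def _jackknife_quantities(X: np.ndarray, spec: PathModelSpec) -> np.ndarray:
    """Leave-one-out effect quantities via moment downdating."""
    n, p = X.shape
    s1 = X.sum(axis=0)
    s2 = X.T @ X
    means = (s1[None, :] - X) / (n - 1)
    covs = (s2[None, :, :] - X[:, :, None] * X[:, None, :]) / (n - 1)
    covs -= means[:, :, None] * means[:, None, :]
    return _batch_quantities(means, covs, spec)


def _point_and_replicates_casewise(
    X: np.ndarray, spec: PathModelSpec, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Row-resampling loop with an EM refit per replicate (missing data)."""
    from .mediation import paths_from_moments
    from ._em import em_mvnorm

    n = X.shape[0]
    reps = np.full((n_boot, len(effect_quantity_names(spec))), np.nan)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        Xb = X[idx]
        obs_per_col = (~np.isnan(Xb)).sum(axis=0)
        if (obs_per_col < 3).any():
            continue
        try:
            em = em_mvnorm(Xb)
            if not em.converged:
                continue
            p = paths_from_moments(em.mean, em.cov, spec)
            ind = p["a"] * p["b"]
            reps[i] = [p["direct"], *ind, ind.sum(), p["direct"] + ind.sum()]
        except (np.linalg.LinAlgError, ValueError):
            continue
    return reps


def _jackknife_casewise(
    X: np.ndarray, spec: PathModelSpec, rng: np.random.Generator, n_groups: int = 50
) -> np.ndarray:
    """Delete-a-group jackknife for the acceleration constant under FIML."""
    from .mediation import paths_from_moments
    from ._em import em_mvnorm

    n = X.shape[0]
    perm = rng.permutation(n)
    groups = np.array_split(perm, min(n_groups, n))
    out = np.full((len(groups), len(effect_quantity_names(spec))), np.nan)
    for g, drop in enumerate(groups):
        keep = np.setdiff1d(np.arange(n), drop)
        try:
            em = em_mvnorm(X[keep])
            p = paths_from_moments(em.mean, em.cov, spec)
            ind = p["a"] * p["b"]
            out[g] = [p["direct"], *ind, ind.sum(), p["direct"] + ind.sum()]
        except (np.linalg.LinAlgError, ValueError):
            continue
    return out


def _bca_interval(
    reps: np.ndarray, theta: float, jack: np.ndarray, alpha: float
) -> tuple[float, float, float, float]:
    """BCa bounds for one quantity. Returns (lo, hi, z0, accel)."""
    reps = reps[np.isfinite(reps)]
    B = reps.size
    if B == 0:
        return float("nan"), float("nan"), 0.0, 0.0
    frac = (np.sum(reps < theta) + 0.5 * np.sum(reps == theta)) / B
    frac = min(max(frac, 0.5 / B), 1.0 - 0.5 / B)
    z0 = stats.norm.ppf(frac)
    jack = jack[np.isfinite(jack)]
    if jack.size >= 3:
        d = jack.mean() - jack
        denom = (d**2).sum() ** 1.5
        accel = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0
    else:
        accel = 0.0
    z_lo, z_hi = stats.norm.ppf(alpha / 2.0), stats.norm.ppf(1.0 - alpha / 2.0)

    def adj(z):
        num = z0 + z
        return stats.norm.cdf(z0 + num / (1.0 - accel * num))

    lo = float(np.quantile(reps, adj(z_lo)))
    hi = float(np.quantile(reps, adj(z_hi)))
    return lo, hi, float(z0), accel


def _boot_pvalue(reps: np.ndarray) -> float:
    """Two-sided bootstrap p: 2*min tail share with the +1 convention."""
    reps = reps[np.isfinite(reps)]
    B = reps.size
    if B == 0:
        return float("nan")
    p_lo = (1.0 + np.sum(reps <= 0.0)) / (B + 1.0)
    p_hi = (1.0 + np.sum(reps >= 0.0)) / (B + 1.0)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def bootstrap_ci(
    table: pd.DataFrame,
    spec: PathModelSpec,
    n_boot: int = 5000,
    seed: int = 0,
    missing_rule: str = "complete_ml",
    alpha: float = 0.05,
    chunk: int = 512,
) -> BootstrapResult:
    """BCa bootstrap intervals for the effect decomposition.

    Deterministic given (table, spec, n_boot, seed).  Replicates whose
    resample is degenerate (e.g. a constant mediator column) are skipped
    and counted in ``n_skipped``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    fit = fit_paths(table, spec, missing_rule=missing_rule)
    names = effect_quantity_names(spec)
    indirect = {m: fit.a[m] * fit.b[m] for m in spec.mediators}
    point = {
        "direct": fit.direct,
        **{f"indirect_{m}": indirect[m] for m in spec.mediators},
        "sum_indirect": sum(indirect.values()),
        "total": fit.direct + sum(indirect.values()),
    }

    X = _extract(table, spec)
    rng = np.random.default_rng(seed)
    if missing_rule == "listwise":
        X = X[~np.isnan(X).any(axis=1)]
    has_missing = bool(np.isnan(X).any())

    if has_missing and missing_rule == "casewise_ml":
        reps = _point_and_replicates_casewise(X, spec, n_boot, rng)
        jack = _jackknife_casewise(X, spec, rng)
    else:
        n, p = X.shape
        A, iu_r, iu_c = _augment(X)
        reps_list = []
        pvals = np.full(n, 1.0 / n)
        done = 0
        while done < n_boot:
            b = min(chunk, n_boot - done)
            W = rng.multinomial(n, pvals, size=b).astype(float)
            means, covs = _moments_from_weights(W @ A, n, p, iu_r, iu_c)
            reps_list.append(_batch_quantities(means, covs, spec))
            done += b
        reps = np.vstack(reps_list)
        jack = _jackknife_quantities(X, spec)

    valid = np.isfinite(reps).all(axis=1)
    n_eff = int(valid.sum())
    ci, z0s, accels, pvalues = {}, {}, {}, {}
    for j, name in enumerate(names):
        lo, hi, z0, acc = _bca_interval(reps[:, j], point[name], jack[:, j], alpha)
        ci[name] = (lo, hi)
        z0s[name] = z0
        accels[name] = acc
        pvalues[name] = _boot_pvalue(reps[:, j])
    return BootstrapResult(
        quantities=names,
        estimate=point,
        n_boot=n_boot,
        n_effective=n_eff,
        n_skipped=n_boot - n_eff,
        z0=z0s,
        accel=accels,
        ci=ci,
        pvalue=pvalues,
        alpha=alpha,
        seed=seed,
        replicates=reps,
    )
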