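"""EM estimation of multivariate-normal moments from incomplete data.

This is the computational core of case-wise ("full-information") maximum
likelihood: the joint mean vector and covariance matrix of all model
variables are estimated over the observed-data patterns, after which path
coefficients follow from the ML moments by partitioned regression.  On
complete data the result coincides with the sample moments (ML, divisor
n) to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["em_mvnorm", "EMResult", "mvnorm_loglik"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class EMResult:
    mean: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool


def _pattern_groups(mask: np.ndarray) -> dict[bytes, np.ndarray]:
    """Row indices grouped by missingness pattern (True = observed)."""
    keys = np.packbits(mask, axis=1).tobytes()
    width = mask.shape[1] // 8 + (mask.shape[1] % 8 > 0)
    groups: dict[bytes, list[int]] = {}
    for i in range(mask.shape[0]):
        key = keys[i * width : (i + 1) * width]
        groups.setdefault(key, []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


def mvnorm_loglik(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Observed-data Gaussian log-likelihood with NaNs marking missing cells."""
    mask = ~np.isnan(X)
    total = 0.0
    for rows in _pattern_groups(mask).values():
        obs = mask[rows[0]]
        if not obs.any():
            continue
        sub = X[np.ix_(rows, np.where(obs)[0])]
        mu = mean[obs]
        sig = cov[np.ix_(obs, obs)]
        sign, logdet = np.linalg.slogdet(sig)
        if sign <= 0:
            return -np.inf
        diff = sub - mu
        maha = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(sig), diff)
        p = obs.sum()
        total += -0.5 * (p * _LOG2PI + logdet) * len(rows) - 0.5 * maha.sum()
    return float(total)


def em_mvnorm(
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> EMResult:
    """ML mean/covariance of an incomplete Gaussian sample via EM.

    Parameters
    ----------
    X : (n, p) array with np.nan for missing cells; every column must
        have at least one observed value and every row at least one.
    tol : relative log-likelihood change declaring convergence.
    max_iter : iteration cap; non-convergence is reported, not raised.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    mask = ~np.isnan(X)
    if not mask.any(axis=0).all():
        raise ValueError("a variable has no observed values")
    if not mask.any(axis=1).all():
        raise ValueError("a row has no observed values")

    if mask.all():
        mean = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, bias=True)
        cov = np.atleast_2d(cov)
        return EMResult(mean, cov, mvnorm_loglik(X, mean, cov), 0, True)

    # start from available-case moments, PSD-repaired if needed
    mean = np.nanmean(X, axis=0)
    dm = np.where(mask, X - mean, 0.0)
    counts = mask.T.astype(float) @ mask.astype(float)
    cov = (dm.T @ dm) / np.maximum(counts, 1.0)
    w, v = np.linalg.eigh(cov)
    floor = max(1e-6, 1e-6 * w.max())
    cov = (v * np.maximum(w, floor)) @ v.T

    groups = _pattern_groups(mask)
    loglik = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for rows in groups.values():
            obs = mask[rows[0]]
            mis = ~obs
            xo = X[np.ix_(rows, np.where(obs)[0])]
            if not mis.any():
                s1 += xo.sum(axis=0)
                s2 += xo.T @ xo
                continue
            soo = cov[np.ix_(obs, obs)]
            smo = cov[np.ix_(mis, obs)]
            smm = cov[np.ix_(mis, mis)]
            beta = np.linalg.solve(soo, smo.T).T  # (n_mis, n_obs)
            mu_m = mean[mis] + (xo - mean[obs]) @ beta.T
            cond = smm - beta @ smo.T
            # accumulate expected sufficient statistics
            full = np.zeros((len(rows), p))
            full[:, obs] = xo
            full[:, mis] = mu_m
            s1 += full.sum(axis=0)
            s2 += full.T @ full
            s2[np.ix_(mis, mis)] += cond * len(rows)
        mean = s1 / n
        cov = s2 / n - np.outer(mean, mean)
        cov = (cov + cov.T) / 2.0
        new_loglik = mvnorm_loglik(X, mean, cov)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= tol * (
            abs(loglik) + 1e-12
        ):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    return EMResult(mean, cov, loglik, it, converged)
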