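"""Parallel multiple-mediator linear path models.

The model is the standard recursive system

    M_j = i_j + a_j X (+ covariates) + e_j          (mediator equations)
    Y   = i_y + c' X + sum_j b_j M_j (+ covariates) + e_y   (outcome)

with freely correlated mediator residuals.  For this system joint
Gaussian maximum likelihood coincides with equation-wise least squares on
complete data; with missing data the joint mean and covariance of all
model variables are estimated by EM over the observed-data patterns
(case-wise / full-information ML) and the path coefficients derived from
the ML moments by partitioned regression.  Binary mediators are treated
as numeric 0/1, i.e. the a-paths into them are linear-probability slopes.

Effects decompose as: indirect_j = a_j * b_j, total = c' + sum indirect_j
(exact identity), proportion mediated_j = indirect_j / total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._em import EMResult, em_mvnorm, mvnorm_loglik

__all__ = [
    "PathModelSpec",
    "FittedPathModel",
    "EffectTable",
    "fit_paths",
    "compute_effects",
    "linear_adjusted_regression",
    "ParallelMediation",
]


@dataclass(frozen=True)
class PathModelSpec:
    """Variable roles of a parallel mediation model."""

    exposure: str
    mediators: tuple[str, ...]
    outcome: str
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "mediators", tuple(self.mediators))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        names = [self.exposure, *self.mediators, self.outcome, *self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("exposure, mediators, outcome and covariates overlap")
        if not 1 <= len(self.mediators) <= 5:
            raise ValueError("between 1 and 5 mediators are supported")

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.exposure, *self.mediators, *self.covariates, self.outcome)


@dataclass
class FittedPathModel:
    """Estimated paths, residual structure and fit metadata."""

    spec: PathModelSpec
    n: int
    mean: np.ndarray           # ML mean of spec.variables
    cov: np.ndarray            # ML covariance of spec.variables
    a: dict[str, float]        # mediator <- exposure slopes
    b: dict[str, float]        # outcome <- mediator slopes
    direct: float              # c'
    covariate_paths: dict[str, dict[str, float]]
    intercepts: dict[str, float]
    residual_var: dict[str, float]           # per-equation residual variance
    mediator_residual_cov: pd.DataFrame      # across mediator equations
    standardized_a: dict[str, float]
    standardized_b: dict[str, float]
    standardized_direct: float
    r_squared: dict[str, float]              # per equation
    loglik: float
    method: str                # complete_ml | casewise_ml | listwise
    converged: bool = True
    n_iter: int = 0

    def sd(self, var: str) -> float:
        i = self.spec.variables.index(var)
        return math.sqrt(self.cov[i, i])


@dataclass
class EffectTable:
    """Direct/indirect/total effect decomposition with optional intervals."""

    mediators: tuple[str, ...]
    direct: float
    indirect: dict[str, float]
    sum_indirect: float
    total: float
    proportion: dict[str, float]     # NaN when |total| ~ 0
    std_direct: float = float("nan")
    std_indirect: dict[str, float] = field(default_factory=dict)
    std_total: float = float("nan")
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    pvalue: dict[str, float] = field(default_factory=dict)

    #: |total| below this is treated as zero when forming proportions
    TOTAL_TOL = 1e-12

    @classmethod
    def from_components(
        cls, direct: float, indirect: dict[str, float]
    ) -> "EffectTable":
        """Decomposition arithmetic from externally supplied components.

        Useful for reproducing a published table from its printed direct
        and per-mediator indirect estimates.
        """
        s = float(sum(indirect.values()))
        total = direct + s
        if abs(total) <= cls.TOTAL_TOL:
            prop = {m: float("nan") for m in indirect}
        else:
            prop = {m: v / total for m, v in indirect.items()}
        return cls(
            mediators=tuple(indirect),
            direct=float(direct),
            indirect={m: float(v) for m, v in indirect.items()},
            sum_indirect=s,
            total=total,
            proportion=prop,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []

        def row(name, est, prop=float("nan")):
            lo, hi = self.ci.get(name, (float("nan"), float("nan")))
            rows.append(
                {
                    "quantity": name,
                    "estimate": est,
                    "proportion_mediated_pct": 100.0 * prop if prop == prop else float("nan"),
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "p_value": self.pvalue.get(name, float("nan")),
                }
            )

        row("direct", self.direct)
        for m in self.mediators:
            row(f"indirect_{m}", self.indirect[m], self.proportion[m])
        row("sum_indirect", self.sum_indirect)
        row("total", self.total)
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# moments -> paths (single and batched)
# ----------------------------------------------------------------------

def _indices(spec: PathModelSpec):
    names = spec.variables
    ix = {v: i for i, v in enumerate(names)}
    e = ix[spec.exposure]
    med = [ix[m] for m in spec.mediators]
    cov_ = [ix[c] for c in spec.covariates]
    y = ix[spec.outcome]
    return e, med, cov_, y


def paths_from_moments(
    mean: np.ndarray, cov: np.ndarray, spec: PathModelSpec
) -> dict:
    """Path coefficients and residual structure from joint ML moments."""
    e, med, covs, y = _indices(spec)
    x1 = [e, *covs]                       # mediator-equation regressors
    x2 = [e, *med, *covs]                 # outcome-equation regressors

    s11 = cov[np.ix_(x1, x1)]
    s1m = cov[np.ix_(x1, med)]
    beta_med = np.linalg.solve(s11, s1m)  # (len(x1), n_med)
    res_med = cov[np.ix_(med, med)] - s1m.T @ beta_med

    s22 = cov[np.ix_(x2, x2)]
    s2y = cov[np.ix_(x2, [y])]
    beta_y = np.linalg.solve(s22, s2y)[:, 0]
    res_y = float(cov[y, y] - s2y[:, 0] @ beta_y)

    a = beta_med[0, :]
    b = beta_y[1 : 1 + len(med)]
    direct = float(beta_y[0])

    sds = np.sqrt(np.diag(cov))
    out = {
        "a": a,
        "b": b,
        "direct": direct,
        "beta_med": beta_med,
        "beta_y": beta_y,
        "res_med": res_med,
        "res_y": res_y,
        "std_a": a * sds[e] / sds[med],
        "std_b": b * sds[med] / sds[y],
        "std_direct": direct * sds[e] / sds[y],
        "r2_med": 1.0 - np.diag(res_med) / np.diag(cov)[med],
        "r2_y": 1.0 - res_y / cov[y, y],
        "intercept_med": mean[med] - beta_med.T @ mean[x1],
        "intercept_y": float(mean[y] - beta_y @ mean[x2]),
    }
    return out


def paths_from_moments_batch(
    means: np.ndarray, covs: np.ndarray, spec: PathModelSpec
) -> dict[str, np.ndarray]:
    """Vectorized version over a stack of moment estimates.

    Returns the per-replicate effect quantities used by the bootstrap:
    direct, each indirect, their sum, and the total effect.
    """
    e, med, covariates, y = _indices(spec)
    x1 = [e, *covariates]
    x2 = [e, *med, *covariates]
    s11 = covs[:, np.ix_(x1, x1)[0], np.ix_(x1, x1)[1]]
    s1m = covs[:, np.ix_(x1, med)[0], np.ix_(x1, med)[1]]
    beta_med = np.linalg.solve(s11, s1m)                 # (B, len(x1), n_med)
    a = beta_med[:, 0, :]                                # (B, n_med)
    s22 = covs[:, np.ix_(x2, x2)[0], np.ix_(x2, x2)[1]]
    s2y = covs[:, np.ix_(x2, [y])[0], np.ix_(x2, [y])[1]]
    beta_y = np.linalg.solve(s22, s2y)[..., 0]           # (B, len(x2))
    direct = beta_y[:, 0]
    b = beta_y[:, 1 : 1 + len(med)]
    indirect = a * b
    s = indirect.sum(axis=1)
    return {
        "direct": direct,
        "indirect": indirect,
        "sum_indirect": s,
        "total": direct + s,
    }


def effect_quantity_names(spec: PathModelSpec) -> list[str]:
    return (
        ["direct"]
        + [f"indirect_{m}" for m in spec.mediators]
        + ["sum_indirect", "total"]
    )


def quantity_vector(batch: dict[str, np.ndarray]) -> np.ndarray:
    """Stack the batched quantities as (B, n_quantities)."""
    return np.column_stack(
        [batch["direct"], batch["indirect"], batch["sum_indirect"], batch["total"]]
    )


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------

def _extract(table: pd.DataFrame, spec: PathModelSpec) -> np.ndarray:
    missing_cols = [v for v in spec.variables if v not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks model variables: {missing_cols}")
    X = table.loc[:, list(spec.variables)].to_numpy(dtype=float)
    return X


def fit_paths(
    table: pd.DataFrame,
    spec: PathModelSpec,
    missing_rule: str = "complete_ml",
    em_tol: float = 1e-8,
    em_max_iter: int = 500,
) -> FittedPathModel:
    """Fit the parallel mediation model by maximum likelihood.

    missing_rule:
      * ``complete_ml`` — requires complete data (raises otherwise);
        equation-wise least squares, the Gaussian-ML solution.
      * ``casewise_ml`` — full-information ML via EM over observed-data
        patterns; equals ``complete_ml`` when nothing is missing.
      * ``listwise`` — drop incomplete rows, then ``complete_ml``.
    """
    X = _extract(table, spec)
    n_params = 2 * len(spec.variables) + len(spec.variables) ** 2 // 2
    if X.shape[0] <= n_params:
        raise ValueError("too few rows for the number of model parameters")

    converged, n_iter = True, 0
    if missing_rule == "listwise":
        X = X[~np.isnan(X).any(axis=1)]
        if X.shape[0] <= n_params:
            raise ValueError("too few complete rows after listwise deletion")
        missing = False
    elif missing_rule == "complete_ml":
        if np.isnan(X).any():
            raise ValueError(
                "complete_ml requires complete data; use casewise_ml or listwise"
            )
        missing = False
    elif missing_rule == "casewise_ml":
        missing = bool(np.isnan(X).any())
    else:
        raise ValueError(f"unknown missing_rule {missing_rule!r}")

    if missing:
        em: EMResult = em_mvnorm(X, tol=em_tol, max_iter=em_max_iter)
        mean, cov, loglik = em.mean, em.cov, em.loglik
        converged, n_iter = em.converged, em.n_iter
    else:
        mean = X.mean(axis=0)
        cov = np.atleast_2d(np.cov(X, rowvar=False, bias=True))
        loglik = mvnorm_loglik(X, mean, cov)

    if np.linalg.matrix_rank(cov) < cov.shape[0]:
        raise np.linalg.LinAlgError("singular design: model variables are collinear")

    p = paths_from_moments(mean, cov, spec)
    med = spec.mediators
    res_cov = pd.DataFrame(p["res_med"], index=list(med), columns=list(med))
    covariate_paths = {
        m: {c: float(p["beta_med"][1 + k, j]) for k, c in enumerate(spec.covariates)}
        for j, m in enumerate(med)
    }
    covariate_paths[spec.outcome] = {
        c: float(p["beta_y"][1 + len(med) + k]) for k, c in enumerate(spec.covariates)
    }
    return FittedPathModel(
        spec=spec,
        n=X.shape[0],
        mean=mean,
        cov=cov,
        a={m: float(p["a"][j]) for j, m in enumerate(med)},
        b={m: float(p["b"][j]) for j, m in enumerate(med)},
        direct=p["direct"],
        covariate_paths=covariate_paths,
        intercepts={
            **{m: float(p["intercept_med"][j]) for j, m in enumerate(med)},
            spec.outcome: p["intercept_y"],
        },
        residual_var={
            **{m: float(p["res_med"][j, j]) for j, m in enumerate(med)},
            spec.outcome: p["res_y"],
        },
        mediator_residual_cov=res_cov,
        standardized_a={m: float(p["std_a"][j]) for j, m in enumerate(med)},
        standardized_b={m: float(p["std_b"][j]) for j, m in enumerate(med)},
        standardized_direct=float(p["std_direct"]),
        r_squared={
            **{m: float(p["r2_med"][j]) for j, m in enumerate(med)},
            spec.outcome: float(p["r2_y"]),
        },
        loglik=loglik,
        method="casewise_ml" if missing_rule == "casewise_ml" else missing_rule,
        converged=converged,
        n_iter=n_iter,
    )


def compute_effects(fit: FittedPathModel) -> EffectTable:
    """Decompose the fitted paths into direct, indirect and total effects.

    The identity total = direct + sum of indirects holds exactly; when
    the total effect is numerically zero the proportions mediated are
    returned as NaN rather than divided through.
    """
    if not fit.converged:
        raise ValueError("cannot decompose effects of a non-converged fit")
    indirect = {m: fit.a[m] * fit.b[m] for m in fit.spec.mediators}
    table = EffectTable.from_components(fit.direct, indirect)
    table.std_direct = fit.standardized_direct
    table.std_indirect = {
        m: fit.standardized_a[m] * fit.standardized_b[m] for m in fit.spec.mediators
    }
    table.std_total = table.std_direct + sum(table.std_indirect.values())
    return table


def linear_adjusted_regression(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: list[str] = (),
) -> pd.DataFrame:
    """Covariate-adjusted OLS of the outcome on the predictors.

    Complete-case analysis; returns B, SE, t and p per term.
    """
    import statsmodels.api as sm

    terms = list(predictors) + list(covariates)
    if outcome in terms:
        raise ValueError("outcome cannot also be a predictor")
    data = table.loc[:, [outcome, *terms]].dropna()
    X = sm.add_constant(data[terms])
    model = sm.OLS(data[outcome], X).fit()
    return pd.DataFrame(
        {
            "B": model.params,
            "SE": model.bse,
            "t": model.tvalues,
            "p": model.pvalues,
        }
    )


# ----------------------------------------------------------------------
# estimator facade
# ----------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402


class ParallelMediation(BaseEstimator):
    """Parallel multiple-mediator path model as a scikit-learn estimator.

    Parameters
    ----------
    exposure, mediators, outcome, covariates : variable roles; columns of
        the DataFrame passed to :meth:`fit`.
    missing : 'complete_ml' | 'casewise_ml' | 'listwise'.
    n_boot : bootstrap replicates for BCa intervals (0 disables).
    alpha : two-sided interval level (0.05 -> 95% CI).
    random_state : seed for the bootstrap resampling.

    Attributes (after fit)
    ----------------------
    model_ : FittedPathModel with coefficients and residual structure.
    effects_ : EffectTable (with BCa CIs and bootstrap p-values when
        ``n_boot > 0``).
    bootstrap_ : BootstrapResult or None.
    """

    def __init__(
        self,
        exposure: str = "prs_pt_0.5",
        mediators: tuple[str, ...] = ("ctq_total", "cannabis_case"),
        outcome: str = "cape_total",
        covariates: tuple[str, ...] = (),
        missing: str = "complete_ml",
        n_boot: int = 0,
        alpha: float = 0.05,
        random_state: int | None = None,
    ):
        self.exposure = exposure
        self.mediators = mediators
        self.outcome = outcome
        self.covariates = covariates
        self.missing = missing
        self.n_boot = n_boot
        self.alpha = alpha
        self.random_state = random_state

    def _spec(self) -> PathModelSpec:
        return PathModelSpec(
            exposure=self.exposure,
            mediators=tuple(self.mediators),
            outcome=self.outcome,
            covariates=tuple(self.covariates),
        )

    def fit(self, X: pd.DataFrame, y=None) -> "ParallelMediation":
        from .bootstrap import bootstrap_ci

        spec = self._spec()
        self.model_ = fit_paths(X, spec, missing_rule=self.missing)
        self.effects_ = compute_effects(self.model_)
        self.bootstrap_ = None
        if self.n_boot:
            self.bootstrap_ = bootstrap_ci(
                X,
                spec,
                n_boot=self.n_boot,
                seed=self.random_state if self.random_state is not None else 0,
                missing_rule=self.missing,
                alpha=self.alpha,
            )
            self.effects_.ci = dict(self.bootstrap_.ci)
            self.effects_.pvalue = dict(self.bootstrap_.pvalue)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Model-implied outcome from exposure, mediators and covariates."""
        fit = self.model_
        spec = fit.spec
        pred = np.full(len(X), fit.intercepts[spec.outcome])
        pred += fit.direct * X[spec.exposure].to_numpy(dtype=float)
        for m in spec.mediators:
            pred += fit.b[m] * X[m].to_numpy(dtype=float)
        for c in spec.covariates:
            pred += fit.covariate_paths[spec.outcome][c] * X[c].to_numpy(dtype=float)
        return pred

    def score(self, X: pd.DataFrame, y=None) -> float:
        """R^2 of the outcome equation on new data."""
        obs = X[self.outcome].to_numpy(dtype=float)
        pred = self.predict(X)
        keep = ~np.isnan(obs) & ~np.isnan(pred)
        resid = obs[keep] - pred[keep]
        return 1.0 - resid.var() / obs[keep].var()
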