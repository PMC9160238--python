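"""PRS p-value threshold selection.

The PRS is available at many GWAS p-value inclusion thresholds whose
columns are nearly collinear.  Selection follows a two-stage rule: an
L1-penalized regression of the outcome on all candidate PRS columns with
unpenalized covariates (age, gender, first genetic PCs) prunes the set,
then the surviving threshold with the highest linear-model R-squared is
chosen.  Covariates are kept unpenalized by residualizing the outcome and
the standardized PRS columns on them before the lasso, which is
algebraically equivalent by Frisch-Waugh-Lovell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = ["PrsSelectionResult", "lasso_select", "pick_by_r2", "LassoThresholdSelector"]


@dataclass
class PrsSelectionResult:
    """Outcome of the two-stage threshold selection."""

    candidates: list[str]
    survivors: list[str]
    chosen: str
    r2_full: dict[str, float]           # full-model R^2 per survivor
    r2_incremental: dict[str, float]    # R^2 added by the PRS term
    chosen_r2: float
    tie_broken: bool = False
    alphas: np.ndarray | None = field(repr=False, default=None)
    coef_path: np.ndarray | None = field(repr=False, default=None)
    penalty: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prs_column": list(self.r2_full),
                "r2_full": list(self.r2_full.values()),
                "r2_incremental": [self.r2_incremental[c] for c in self.r2_full],
                "chosen": [c == self.chosen for c in self.r2_full],
            }
        )


def _threshold_of(column: str) -> float:
    return float(column.removeprefix("prs_pt_"))


def _residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, C] via least squares."""
    X = np.column_stack([np.ones(len(y)), C]) if C.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def lasso_select(
    table: pd.DataFrame,
    outcome: str,
    prs_columns: list[str],
    covariates: list[str] = (),
    penalty_rule: str = "cv",
    seed: int = 0,
    alpha: float | None = None,
    cv: int = 10,
) -> tuple[list[str], dict]:
    """PRS columns with nonzero lasso coefficients at the chosen penalty.

    ``penalty_rule='cv'`` (default) picks the penalty by k-fold
    cross-validation minimizing prediction error; pass ``alpha`` to use a
    fixed penalty instead.  PRS columns are standardized before
    penalization so selection is scale-equivariant; covariates are never
    penalized.  Complete cases for the involved variables are used.

    Returns (selected columns, path metadata).  An empty selection (all
    coefficients shrunk away) is returned with a warning.
    """
    if len(prs_columns) < 2:
        raise ValueError("need at least two candidate PRS columns")
    cols = [outcome, *prs_columns, *covariates]
    data = table.loc[:, cols].dropna()
    y = data[outcome].to_numpy(dtype=float)
    P = data[list(prs_columns)].to_numpy(dtype=float)
    C = data[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((len(y), 0))

    P = (P - P.mean(axis=0)) / P.std(axis=0)
    y_r = _residualize(y, C)
    P_r = np.column_stack([_residualize(P[:, j], C) for j in range(P.shape[1])])

    meta: dict = {}
    if alpha is not None:
        model = Lasso(alpha=alpha, max_iter=50000)
        model.fit(P_r, y_r)
        coefs = model.coef_
        meta["penalty"] = alpha
    elif penalty_rule == "cv":
        folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
        model = LassoCV(cv=folds, max_iter=50000)
        model.fit(P_r, y_r)
        coefs = model.coef_
        meta["penalty"] = float(model.alpha_)
        meta["alphas"] = model.alphas_
    else:
        raise ValueError(f"unknown penalty_rule {penalty_rule!r}")

    selected = [c for c, w in zip(prs_columns, coefs) if w != 0.0]
    meta["coefficients"] = dict(zip(prs_columns, coefs))
    if not selected:
        logger.warning(
            "lasso eliminated every PRS column at penalty %.4g; "
            "caller should fall back to the best marginal R^2",
            meta["penalty"],
        )
    return selected, meta


def pick_by_r2(
    table: pd.DataFrame,
    outcome: str,
    survivors: list[str],
    covariates: list[str] = (),
) -> PrsSelectionResult:
    """Choose the survivor whose single-PRS linear model explains most.

    One model ``outcome ~ survivor + covariates`` per survivor; the
    full-model R^2 decides, with the incremental R^2 of the PRS term
    (over the covariate-only model) also reported.  Exact ties are broken
    toward the less stringent (larger) threshold and logged.
    """
    if not survivors:
        raise ValueError("survivors must be non-empty")
    import statsmodels.api as sm

    r2_full: dict[str, float] = {}
    r2_inc: dict[str, float] = {}
    for col in survivors:
        data = table.loc[:, [outcome, col, *covariates]].dropna()
        X = sm.add_constant(data[[col, *covariates]])
        full = sm.OLS(data[outcome], X).fit()
        r2_full[col] = float(full.rsquared)
        if covariates:
            X0 = sm.add_constant(data[list(covariates)])
            base = sm.OLS(data[outcome], X0).fit()
            r2_inc[col] = float(full.rsquared - base.rsquared)
        else:
            r2_inc[col] = float(full.rsquared)

    best = max(r2_full.values())
    tied = [c for c, v in r2_full.items() if abs(v - best) <= 1e-12]
    tie_broken = len(tied) > 1
    chosen = max(tied, key=_threshold_of)
    if tie_broken:
        logger.info(
            "R^2 tie among %s resolved toward the larger threshold %s", tied, chosen
        )
    return PrsSelectionResult(
        candidates=list(survivors),
        survivors=list(survivors),
        chosen=chosen,
        r2_full=r2_full,
        r2_incremental=r2_inc,
        chosen_r2=r2_full[chosen],
        tie_broken=tie_broken,
    )


class LassoThresholdSelector(BaseEstimator):
    """Two-stage PRS threshold selection as a scikit-learn estimator.

    ``fit`` runs the lasso pruning followed by the R^2 choice; when the
    lasso eliminates every column the fallback is the best marginal R^2
    over all candidates.  ``transform`` returns the chosen PRS column.
    """

    def __init__(
        self,
        outcome: str = "cape_total",
        prs_columns: tuple[str, ...] = (),
        covariates: tuple[str, ...] = ("age", "gender", "pc1", "pc2", "pc3"),
        penalty_rule: str = "cv",
        alpha: float | None = None,
        cv: int = 10,
        random_state: int = 0,
    ):
        self.outcome = outcome
        self.prs_columns = prs_columns
        self.covariates = covariates
        self.penalty_rule = penalty_rule
        self.alpha = alpha
        self.cv = cv
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "LassoThresholdSelector":
        prs_cols = list(self.prs_columns) or [
            c for c in X.columns if c.startswith("prs_pt_")
        ]
        survivors, meta = lasso_select(
            X,
            self.outcome,
            prs_cols,
            list(self.covariates),
            penalty_rule=self.penalty_rule,
            seed=self.random_state,
            alpha=self.alpha,
            cv=self.cv,
        )
        pool = survivors or prs_cols  # fallback: best marginal R^2
        self.result_ = pick_by_r2(X, self.outcome, pool, list(self.covariates))
        self.result_.candidates = prs_cols
        self.result_.penalty = meta.get("penalty")
        self.survivors_ = survivors
        self.chosen_ = self.result_.chosen
        self.chosen_r2_ = self.result_.chosen_r2
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[[self.chosen_]]
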