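"""Two-step confounder screen and the extended four-mediator model.

Step 1 correlates every candidate (genetic PCs, age, gender, ...) with
the outcome and with the exposure; candidates with |r| > 0.7 with either
variable, or a correlation p-value < 0.05 for either, pass.  Step 2
refits the outcome-on-exposure regression with each passing candidate
added and flags those moving the exposure coefficient by more than 10%.
Both steps are invariant to affine rescaling of the candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mediation import (
    EffectTable,
    FittedPathModel,
    ParallelMediation,
    PathModelSpec,
)

logger = logging.getLogger(__name__)

__all__ = ["ScreenReport", "screen", "fit_four_mediator_model", "FOUR_MEDIATORS"]

FOUR_MEDIATORS = ("ctq_total", "cannabis_case", "neuroticism", "tobacco_case")

R_THRESHOLD = 0.7
P_THRESHOLD = 0.05
BETA_CHANGE_THRESHOLD = 10.0  # percent


@dataclass
class ScreenReport:
    outcome: str
    exposure: str
    step1: pd.DataFrame
    step2: pd.DataFrame
    confounders: list[str] = field(default_factory=list)


def _corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    keep = ~np.isnan(x) & ~np.isnan(y)
    return stats.pearsonr(x[keep], y[keep])


def screen(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    candidates: list[str],
) -> ScreenReport:
    """Run the two-step screen; constant candidates are skipped."""
    overlap = {outcome, exposure} & set(candidates)
    if overlap:
        raise ValueError(f"candidates overlap outcome/exposure: {sorted(overlap)}")

    y = table[outcome].to_numpy(dtype=float)
    x = table[exposure].to_numpy(dtype=float)
    rows1 = []
    passers = []
    for cand in candidates:
        c = table[cand].to_numpy(dtype=float)
        if np.nanstd(c) == 0.0:
            logger.warning("candidate %s is constant; correlation undefined, skipped", cand)
            continue
        r_out, p_out = _corr(c, y)
        r_exp, p_exp = _corr(c, x)
        passed = (
            abs(r_out) > R_THRESHOLD
            or abs(r_exp) > R_THRESHOLD
            or p_out < P_THRESHOLD
            or p_exp < P_THRESHOLD
        )
        rows1.append(
            {
                "candidate": cand,
                "r_outcome": r_out,
                "p_outcome": p_out,
                "r_exposure": r_exp,
                "p_exposure": p_exp,
                "passed_step1": passed,
            }
        )
        if passed:
            passers.append(cand)

    # step 2: does adding the candidate move the exposure coefficient >10%?
    rows2 = []
    confounders = []
    base = table[[outcome, exposure]].dropna()
    slope_base = np.polynomial.polynomial.polyfit(
        base[exposure].to_numpy(), base[outcome].to_numpy(), 1
    )[1]
    for cand in passers:
        data = table[[outcome, exposure, cand]].dropna()
        X = np.column_stack(
            [np.ones(len(data)), data[exposure].to_numpy(), data[cand].to_numpy()]
        )
        beta, *_ = np.linalg.lstsq(X, data[outcome].to_numpy(), rcond=None)
        slope_with = beta[1]
        change = 100.0 * abs(slope_with - slope_base) / abs(slope_base)
        flagged = change > BETA_CHANGE_THRESHOLD
        rows2.append(
            {
                "candidate": cand,
                "beta_without": slope_base,
                "beta_with": slope_with,
                "percent_change": change,
                "confounder": flagged,
            }
        )
        if flagged:
            confounders.append(cand)

    return ScreenReport(
        outcome=outcome,
        exposure=exposure,
        step1=pd.DataFrame(rows1),
        step2=pd.DataFrame(rows2),
        confounders=confounders,
    )


def fit_four_mediator_model(
    table: pd.DataFrame,
    exposure: str = "prs_pt_0.5",
    outcome: str = "cape_total",
    seed: int = 0,
    n_boot: int = 5000,
    missing_rule: str = "complete_ml",
) -> tuple[EffectTable, FittedPathModel]:
    """Parallel model with maltreatment, cannabis, neuroticism, tobacco.

    Same engine as the two-mediator model, with all six mediator-residual
    covariances estimated.
    """
    est = ParallelMediation(
        exposure=exposure,
        mediators=FOUR_MEDIATORS,
        outcome=outcome,
        missing=missing_rule,
        n_boot=n_boot,
        random_state=seed,
    )
    est.fit(table)
    return est.effects_, est.model_


def four_mediator_spec(
    exposure: str = "prs_pt_0.5", outcome: str = "cape_total"
) -> PathModelSpec:
    return PathModelSpec(exposure=exposure, mediators=FOUR_MEDIATORS, outcome=outcome)
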