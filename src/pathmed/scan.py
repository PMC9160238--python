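"""Genetic-risk threshold scan for the mediated effect.

To locate the level of polygenic risk above which mediation is
statistically detectable, the cohort is first upscaled (parametric
simulation from the fitted model's implied joint distribution, by
default ten-fold), then the mediation model is refitted while stepwise
removing the top slice of the PRS distribution (default five percentile
points per step, cutoffs computed once on the original upscaled sample
so removed sets are nested) until the BCa bootstrap interval of the
designated indirect effect includes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_ci
from .config import GeneratorConfig
from .generate import generate_cohort
from .mediation import FittedPathModel, PathModelSpec, fit_paths

__all__ = ["ThresholdScanResult", "upscale_sample", "scan_percentiles"]


@dataclass
class ScanStep:
    cutoff_percentile: float     # upper percentile retained after removal
    n_remaining: int
    indirect: float
    ci_lower: float
    ci_upper: float
    significant: bool


@dataclass
class ThresholdScanResult:
    upscale_factor: int
    step_percent: float
    mediator: str
    steps: list[ScanStep] = field(default_factory=list)
    stopped_at_step: int | None = None       # first non-significant step
    threshold_percentile: float | None = None
    mediation_detected: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff_percentile": [s.cutoff_percentile for s in self.steps],
                "n_remaining": [s.n_remaining for s in self.steps],
                "indirect": [s.indirect for s in self.steps],
                "ci_lower": [s.ci_lower for s in self.steps],
                "ci_upper": [s.ci_upper for s in self.steps],
                "significant": [s.significant for s in self.steps],
            }
        )


def upscale_sample(
    fit_or_config: FittedPathModel | GeneratorConfig,
    factor: int = 10,
    seed: int = 0,
    n_base: int | None = None,
) -> pd.DataFrame:
    """Parametric sample of ``factor`` times the base size.

    From a fitted path model the draw is multivariate normal with the
    model's ML mean and covariance (the recursive system is saturated,
    so the implied joint moments are exactly those); from a generator
    config it is a fresh structural simulation.  Row duplication is
    deliberately avoided: it would corrupt bootstrap variance.
    """
    if factor < 1:
        raise ValueError("upscale factor must be >= 1")
    if isinstance(fit_or_config, GeneratorConfig):
        n = (n_base or fit_or_config.n_individuals) * factor
        return generate_cohort(fit_or_config, seed=seed, n=n)
    fit = fit_or_config
    n = (n_base or fit.n) * factor
    eigvals = np.linalg.eigvalsh(fit.cov)
    if eigvals.min() < -1e-8:
        raise ValueError("implied covariance of the fit is not positive semidefinite")
    rng = np.random.default_rng(seed)
    draw = rng.multivariate_normal(fit.mean, fit.cov, size=n, method="cholesky")
    return pd.DataFrame(draw, columns=list(fit.spec.variables))


def scan_percentiles(
    table: pd.DataFrame,
    spec: PathModelSpec,
    step_percent: float = 5.0,
    n_boot: int = 1000,
    seed: int = 0,
    mediator: str | None = None,
    alpha: float = 0.05,
    missing_rule: str = "complete_ml",
) -> ThresholdScanResult:
    """Stepwise removal of the top PRS slice until mediation is void.

    Step k removes every row above the (100 - k*step) percentile of the
    *original* exposure distribution; the scan stops at the first step
    whose BCa interval for the designated indirect effect covers zero.
    The reported threshold percentile is the cutoff of the last step at
    which mediation was still significant; a scan that is void already
    on the full sample reports no threshold.
    """
    if 100.0 % step_percent != 0:
        raise ValueError("step_percent must divide 100")
    mediator = mediator or spec.mediators[0]
    exposure = table[spec.exposure].to_numpy(dtype=float)
    n_steps = int(100.0 // step_percent)
    quantity = f"indirect_{mediator}"

    result = ThresholdScanResult(
        upscale_factor=1, step_percent=step_percent, mediator=mediator
    )
    last_significant_cutoff: float | None = None
    for k in range(n_steps):
        cutoff = 100.0 - k * step_percent
        if k == 0:
            keep = np.ones(len(table), dtype=bool)
        else:
            threshold = np.percentile(exposure, cutoff)
            keep = exposure <= threshold
        sub = table.loc[keep]
        boot = bootstrap_ci(
            sub,
            spec,
            n_boot=n_boot,
            seed=seed + k,
            missing_rule=missing_rule,
            alpha=alpha,
        )
        lo, hi = boot.ci[quantity]
        significant = lo > 0.0 or hi < 0.0
        result.steps.append(
            ScanStep(
                cutoff_percentile=cutoff,
                n_remaining=int(keep.sum()),
                indirect=boot.estimate[quantity],
                ci_lower=lo,
                ci_upper=hi,
                significant=significant,
            )
        )
        if not significant:
            result.stopped_at_step = k
            break
        last_significant_cutoff = cutoff

    result.mediation_detected = last_significant_cutoff is not None
    result.threshold_percentile = last_significant_cutoff
    return result
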