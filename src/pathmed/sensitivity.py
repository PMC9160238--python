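"""Omitted-confounder sensitivity analysis for a mediated effect.

An unobserved confounder of the mediator-outcome relation induces a
correlation rho between the residuals of the mediator and outcome
equations.  For the linear structural model the mediated effect as a
function of rho has the closed form

    ACME(rho) = a * ( b - rho * s_y / (s_m * sqrt(1 - rho^2)) )

where a and b are the fitted paths for the designated mediator, s_m the
residual SD of its mediator equation and s_y the residual SD of the
outcome equation (which conditions on the other mediators).  rho = 0
returns the fitted a*b.  The zero-crossing rho0 is reported together
with rho0^2, the share of residual variance an omitted confounder would
have to explain in both equations to nullify the mediated effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mediation import FittedPathModel

__all__ = ["SensitivityCurve", "acme_curve", "rho_to_r2", "acme_at_rho"]


@dataclass
class SensitivityCurve:
    mediator: str
    rho: np.ndarray
    acme: np.ndarray
    rho_zero: float | None          # zero-crossing, None if not in (-1, 1)
    r2_at_zero: float | None        # rho_zero ** 2

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"rho": self.rho, "acme": self.acme})


def rho_to_r2(rho: float) -> float:
    """Residual-variance share corresponding to a sensitivity parameter.

    The squared residual correlation: the fraction of residual variance
    in the mediator (and outcome) an omitted confounder must explain.
    Sign-invariant.
    """
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    return rho * rho


def acme_at_rho(
    a: float, b: float, sigma_m: float, sigma_y: float, rho: float
) -> float:
    """Closed-form mediated effect at residual correlation rho."""
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1, got {rho}")
    return a * (b - rho * sigma_y / (sigma_m * math.sqrt(1.0 - rho * rho)))


def acme_curve(
    fit: FittedPathModel,
    mediator: str,
    rho_grid=None,
) -> SensitivityCurve:
    """Mediated effect of one mediator as a function of rho.

    The other mediators remain covariates of the outcome equation (their
    residual SDs enter through the fitted outcome residual).  The
    zero-crossing is located by bisection between the bracketing grid
    points to |rho| tolerance 1e-6.
    """
    if mediator not in fit.spec.mediators:
        raise ValueError(f"{mediator!r} is not a mediator of the fitted model")
    if rho_grid is None:
        rho_grid = np.linspace(-0.95, 0.95, 39)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if (np.abs(rho_grid) >= 1.0).any():
        raise ValueError("all grid points must satisfy |rho| < 1")

    a = fit.a[mediator]
    b = fit.b[mediator]
    sigma_m = math.sqrt(fit.residual_var[mediator])
    sigma_y = math.sqrt(fit.residual_var[fit.spec.outcome])
    acme = np.array([acme_at_rho(a, b, sigma_m, sigma_y, r) for r in rho_grid])

    rho_zero = _zero_crossing(a, b, sigma_m, sigma_y, rho_grid, acme)
    return SensitivityCurve(
        mediator=mediator,
        rho=rho_grid,
        acme=acme,
        rho_zero=rho_zero,
        r2_at_zero=None if rho_zero is None else rho_zero**2,
    )


def _zero_crossing(a, b, sigma_m, sigma_y, grid, acme) -> float | None:
    if a == 0.0:
        return None
    signs = np.sign(acme)
    change = np.where(signs[:-1] * signs[1:] < 0)[0]
    if (acme == 0.0).any():
        return float(grid[np.argmin(np.abs(acme))])
    if change.size == 0:
        return None
    i = int(change[0])
    lo, hi = float(grid[i]), float(grid[i + 1])
    f = lambda r: acme_at_rho(a, b, sigma_m, sigma_y, r)
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2.0
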