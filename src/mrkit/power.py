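"""Analytical power for two-sample MR with a continuous outcome.

With standardized exposure and outcome, the IVW estimate behaves
asymptotically like a Wald test whose noncentrality is
``|beta| * sqrt(n * R²)``, where ``n`` is the outcome GWAS sample size
and ``R²`` the total exposure variance explained by the instruments.
Two-sided power at level alpha is then

    power = Phi(-z_{1-alpha/2} + |beta| sqrt(n R²))
          + Phi(-z_{1-alpha/2} - |beta| sqrt(n R²)),

the same closed form used by the mRnd web calculator for continuous
outcomes in the no-confounding limit.  Raw-scale effects can be passed
through :func:`standardize_effect` first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq


@dataclass
class PowerParams:
    """Inputs for the continuous-outcome MR power formula."""

    n_outcome: float
    r2_total: float
    beta_std: float
    alpha: float = 0.05

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1); got {self.alpha}")
        if not (0.0 <= self.r2_total < 1.0):
            raise ValueError(f"r2_total must lie in [0, 1); got {self.r2_total}")
        if self.n_outcome <= 0:
            raise ValueError(f"n_outcome must be positive; got {self.n_outcome}")


def standardize_effect(beta_raw: float, sd_exposure: float, sd_outcome: float) -> float:
    """Convert a raw-units effect to SD-outcome per SD-exposure."""
    return beta_raw * sd_exposure / sd_outcome


def mr_power_continuous(params: PowerParams) -> float:
    """Two-sided power of the IVW test; equals alpha at beta_std = 0 and
    is strictly increasing in n_outcome, r2_total and |beta_std|."""
    params.validate()
    z = stats.norm.ppf(1.0 - params.alpha / 2.0)
    ncp = abs(params.beta_std) * np.sqrt(params.n_outcome * params.r2_total)
    return float(stats.norm.cdf(-z + ncp) + stats.norm.cdf(-z - ncp))


def min_detectable_effect(n_outcome: float, alpha: float, r2_total: float,
                          target_power: float) -> float:
    """Smallest |beta_std| with power >= target_power (bisection to 1e-6).

    ``target_power == alpha`` returns 0 (the null sizing); targets below
    alpha are unreachable for a two-sided test and raise.
    """
    if not (0.0 < target_power < 1.0):
        raise ValueError(f"target power must lie in (0, 1); got {target_power}")
    if target_power < alpha:
        raise ValueError(
            f"target power {target_power} below the test size {alpha} is unreachable"
        )
    if target_power == alpha:
        return 0.0
    if r2_total <= 0:
        raise ValueError("r2_total must be positive for a finite detectable effect")

    def gap(beta: float) -> float:
        return mr_power_continuous(PowerParams(n_outcome, r2_total, beta, alpha)) - target_power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("target power unreachable at any plausible effect size")
    return float(brentq(gap, 0.0, hi, xtol=1e-12))


def power_table(n_grid, r2_grid, beta_grid, alpha: float = 0.05):
    """Power over the cartesian grid of the three inputs, as a DataFrame."""
    import pandas as pd

    rows = [
        {"n_outcome": n, "r2_total": r2, "beta_std": b,
         "power": mr_power_continuous(PowerParams(n, r2, b, alpha))}
        for n in n_grid for r2 in r2_grid for b in beta_grid
    ]
    return pd.DataFrame(rows)
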