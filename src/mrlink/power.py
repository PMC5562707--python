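"""Design analysis for summary-level Mendelian randomization.

On standardized scales the IVW estimate of a causal effect beta behaves
approximately like a normal variable with variance
1 / (n_outcome * R²_GX), where R²_GX is the variance of the exposure
explained by the instruments and n_outcome the outcome-sample size (the
ratio estimator's variance is driven by the outcome dataset). The
detectable effect at a given two-sided significance level and power, and
the power at a given effect, follow in closed form. Because
beta² equals the variance of the outcome explained by the exposure on
these scales, the detectable effect is reported as an explained-variance
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerQuery:
    """Inputs of a detectable-effect / power calculation."""

    alpha: float = 0.00625
    target_power: float = 0.80
    n_outcome: int = 0
    r2_gx: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.target_power < 1.0):
            raise ValueError("target_power must lie in (0, 1)")
        if not self.n_outcome > 0:
            raise ValueError("n_outcome must be a positive integer")
        if not (0.0 < self.r2_gx < 1.0):
            raise ValueError("r2_gx must lie in (0, 1)")


def detectable_causal_r2(q: PowerQuery) -> float:
    """Smallest causal explained variance detectable at the queried power.

    The detectable standardized effect is
    beta_det = (z_{1-alpha/2} + z_{power}) / sqrt(n_outcome * r2_gx);
    the returned value is beta_det², the explained variance of the
    exposure on the outcome.
    """
    z_alpha = stats.norm.ppf(1.0 - q.alpha / 2.0)
    z_power = stats.norm.ppf(q.target_power)
    denom = q.n_outcome * q.r2_gx
    if denom <= 0:
        raise ValueError("n_outcome * r2_gx must be positive")
    beta_det = (z_alpha + z_power) / np.sqrt(denom)
    return float(beta_det ** 2)


def power_at_effect(q: PowerQuery, beta_causal: float) -> float:
    """Two-sided power to detect a standardized causal effect of the given
    size (``q.target_power`` is ignored)."""
    z_alpha = stats.norm.ppf(1.0 - q.alpha / 2.0)
    shift = abs(beta_causal) * np.sqrt(q.n_outcome * q.r2_gx)
    return float(stats.norm.cdf(-z_alpha + shift) + stats.norm.cdf(-z_alpha - shift))
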