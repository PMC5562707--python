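"""NOME diagnostics for MR-Egger: the I²_GX statistic and simulation
extrapolation (SIMEX).

MR-Egger assumes No Measurement Error (NOME) in the SNP-exposure
estimates. When that fails, the Egger slope is attenuated towards zero by
roughly the factor I²_GX — a heterogeneity-type statistic on the
SNP-exposure betas. SIMEX corrects the attenuation empirically: the
exposure betas are perturbed with extra noise at several inflation levels
lambda, the Egger slope is re-estimated at each level, and a polynomial in
lambda is extrapolated back to lambda = -1, the no-measurement-error
point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .estimators import EggerRegression, MREstimate, _as_1d, _check_xy
from .summary_data import HarmonizedPanel


def i2_gx(gamma, sigma_x) -> float:
    """I²_GX: fraction of variation in the SNP-exposure betas not due to
    estimation error.

    With weights u_j = sigma_Xj^-2 and their weighted mean gamma_bar,
    Q_GX = sum u_j (gamma_j - gamma_bar)^2 and
    I²_GX = max(0, (Q_GX - (k - 1)) / Q_GX). Values near 1 mean the NOME
    assumption is nearly satisfied; 1 - I²_GX approximates the relative
    attenuation of the Egger slope.
    """
    gamma = _as_1d(gamma, "gamma")
    sigma_x = _as_1d(sigma_x, "sigma_x")
    if gamma.size < 2:
        raise ValueError("I2_GX needs at least 2 SNPs")
    if sigma_x.shape != gamma.shape or np.any(~np.isfinite(sigma_x)) or np.any(
        sigma_x <= 0
    ):
        raise ValueError("I2_GX needs a positive exposure SE per SNP")
    u = sigma_x ** -2.0
    gbar = float(np.sum(u * gamma) / np.sum(u))
    q = float(np.sum(u * (gamma - gbar) ** 2))
    if q <= 0:
        return 0.0
    return max(0.0, (q - (gamma.size - 1)) / q)


def i2_gx_panel(panel: HarmonizedPanel) -> float:
    return i2_gx(panel.gamma, panel.sigma_x)


@dataclass(frozen=True)
class SimexSettings:
    """Configuration of the simulation-extrapolation correction."""

    lambdas: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    n_sim: int = 1000
    extrapolant: int = 2  # polynomial order: 1 linear, 2 quadratic
    seed: int | None = None

    def __post_init__(self) -> None:
        lam = tuple(self.lambdas)
        if not lam or any(l <= 0 for l in lam):
            raise ValueError("lambdas must be a nonempty grid of positive levels")
        if list(lam) != sorted(lam):
            raise ValueError("lambdas must be increasing")
        if self.n_sim < 100:
            raise ValueError("n_sim must be at least 100")
        if self.extrapolant not in (1, 2):
            raise ValueError("extrapolant order must be 1 or 2")


def _egger_slopes_batch(
    Xb: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted simple regression with intercept for a batch of exposure
    vectors. Returns (slopes, intercepts, squared SEs) per batch row."""
    sw = w.sum()
    xbar = (Xb * w).sum(axis=1) / sw
    ybar = float((y * w).sum() / sw)
    xc = Xb - xbar[:, None]
    sxx = (w * xc ** 2).sum(axis=1)
    sxy = (xc * (w * (y - ybar))).sum(axis=1)
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y[None, :] - intercept[:, None] - slope[:, None] * Xb
    rss = (w * resid ** 2).sum(axis=1)
    k = y.size
    dispersion2 = rss / (k - 2)
    se2 = np.maximum(1.0, dispersion2) / sxx
    return slope, intercept, se2


class SimexEgger(BaseEstimator):
    """SIMEX-corrected MR-Egger regression.

    For each noise-inflation level lambda the SNP-exposure betas are
    perturbed with Normal(0, lambda * sigma_X^2) noise ``n_sim`` times and
    the Egger slope averaged; a polynomial (default quadratic) in lambda —
    anchored at the unperturbed fit at lambda = 0 — is extrapolated to
    lambda = -1. The SE uses the standard SIMEX variance construction
    (mean sampling variance minus between-simulation variance,
    extrapolated the same way) and is approximate.
    """

    def __init__(
        self,
        lambdas: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
        n_sim: int = 1000,
        extrapolant: int = 2,
        random_state: int | None = None,
    ):
        self.lambdas = lambdas
        self.n_sim = n_sim
        self.extrapolant = extrapolant
        self.random_state = random_state

    def fit(self, X, y, y_se=None, x_se=None):
        settings = SimexSettings(
            tuple(self.lambdas), self.n_sim, self.extrapolant, self.random_state
        )
        X, y, y_se = _check_xy(X, y, y_se, min_snps=3)
        x = X[:, 0]
        if x_se is None:
            raise ValueError("SIMEX needs exposure SEs (x_se)")
        x_se = _as_1d(x_se, "x_se")
        if np.any(x_se < 0):
            raise ValueError("exposure SEs must be nonnegative")

        naive = EggerRegression().fit(x, y, y_se=y_se)
        self.naive_ = naive
        w = y_se ** -2.0
        rng = np.random.default_rng(self.random_state)

        lam_grid = [0.0]
        slope_means = [naive.beta_]
        int_means = [naive.intercept_]
        tau2 = [naive.se_ ** 2]
        for lam in settings.lambdas:
            noise = rng.standard_normal((settings.n_sim, x.size)) * np.sqrt(lam) * x_se
            slopes, intercepts, se2 = _egger_slopes_batch(x + noise, y, w)
            if not np.all(np.isfinite(slopes)):
                raise FloatingPointError(
                    f"non-finite Egger fit at inflation level lambda={lam}"
                )
            lam_grid.append(lam)
            slope_means.append(float(slopes.mean()))
            int_means.append(float(intercepts.mean()))
            # SIMEX variance: average sampling variance minus the
            # between-simulation variance of the point estimates
            tau2.append(float(se2.mean() - slopes.var(ddof=1)))
        lam_grid = np.asarray(lam_grid)

        def extrapolate(values) -> float:
            coefs = np.polyfit(lam_grid, np.asarray(values, dtype=float),
                               settings.extrapolant)
            return float(np.polyval(coefs, -1.0))

        self.beta_ = extrapolate(slope_means)
        self.intercept_ = extrapolate(int_means)
        tau2_ext = extrapolate(tau2)
        if not tau2_ext > 0:
            # extrapolated variance can turn negative; fall back on the
            # smallest positive grid value
            positive = [t for t in tau2 if t > 0]
            tau2_ext = min(positive) if positive else naive.se_ ** 2
        self.se_ = float(np.sqrt(tau2_ext))
        self.intercept_se_ = naive.intercept_se_
        self.df_ = naive.df_
        tq = float(stats.t.ppf(0.975, self.df_))
        self.ci_ = (self.beta_ - tq * self.se_, self.beta_ + tq * self.se_)
        self.pvalue_ = float(2.0 * stats.t.sf(abs(self.beta_) / self.se_, self.df_))
        self.intercept_pvalue_ = float(
            2.0 * stats.t.sf(abs(self.intercept_) / self.intercept_se_, self.df_)
        )
        self.lambda_grid_ = lam_grid
        self.slope_means_ = np.asarray(slope_means)
        self.n_snps_ = x.size
        return self

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method="egger_simex",
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            pvalue=self.pvalue_,
            n_snps=self.n_snps_,
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_p=self.intercept_pvalue_,
            model_flags={
                "lambdas": tuple(float(l) for l in self.lambda_grid_[1:]),
                "n_sim": self.n_sim,
                "extrapolant": self.extrapolant,
                "seed": self.random_state,
                "se_approximate": True,
                "naive_beta": self.naive_.beta_,
            },
        )


def simex_egger(
    panel: HarmonizedPanel, settings: SimexSettings | None = None
) -> MREstimate:
    settings = settings or SimexSettings()
    est = SimexEgger(
        lambdas=settings.lambdas,
        n_sim=settings.n_sim,
        extrapolant=settings.extrapolant,
        random_state=settings.seed,
    )
    est.fit(panel.gamma, panel.Gamma, y_se=panel.sigma_y, x_se=panel.sigma_x)
    return est.to_estimate()
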