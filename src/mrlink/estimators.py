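"""Two-sample Mendelian randomization causal estimators.

All estimators operate on per-SNP summary statistics: the SNP-exposure
effects gamma_j (with SE sigma_Xj) and the SNP-outcome effects Gamma_j
(with SE sigma_Yj) of a harmonized panel. They are written as
scikit-learn-style estimator classes — ``fit(X, y, ...)`` with fitted
attributes carrying a trailing underscore — where ``X`` holds the
SNP-exposure betas (a column per exposure for the multivariable model) and
``y`` the SNP-outcome betas. Thin module-level functions accept a
:class:`~mrlink.summary_data.HarmonizedPanel` and return an
:class:`MREstimate` record.

Estimators implemented:

* fixed-effect (optionally multiplicative random-effects) inverse-variance
  weighted (IVW) regression through the origin;
* MR-Egger weighted regression with intercept, whose intercept estimates
  directional pleiotropy and whose slope is consistent under InSIDE;
* the weighted median of the per-SNP ratio estimates, robust to up to 50%
  invalid weight, with a parametric-bootstrap SE;
* multivariable IVW, regressing outcome betas on several exposures' betas
  simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .summary_data import HarmonizedPanel

Z_95 = float(stats.norm.ppf(0.975))  # 1.959964...


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect result on the outcome scale per unit exposure."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    model_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("estimate SE must be positive")
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")

    def report_row(self, exposure: str, outcome: str, alpha: float | None = None,
                   notes: str = "") -> dict:
        row = {
            "exposure": exposure,
            "outcome": outcome,
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "intercept_p": self.intercept_p,
            "notes": notes,
        }
        if alpha is not None:
            row["significant"] = bool(self.pvalue < alpha)
        return row


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def _check_xy(X, y, y_se, *, min_snps: int, allow_matrix: bool = False):
    y = _as_1d(y, "y")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not allow_matrix and X.shape[1] != 1:
        raise ValueError("this estimator takes a single exposure column")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y carry different numbers of SNPs")
    if y_se is None:
        y_se = np.ones_like(y)
    else:
        y_se = _as_1d(y_se, "y_se")
        if y_se.shape != y.shape:
            raise ValueError("y_se must match y")
        if np.any(y_se <= 0):
            raise ValueError("outcome standard errors must be positive")
    k = y.shape[0]
    if k < min_snps:
        raise ValueError(f"estimator needs at least {min_snps} SNPs, got {k}")
    return X, y, y_se


def ratio_estimates(panel: HarmonizedPanel) -> list[tuple[str, float, float]]:
    """Per-SNP Wald ratio estimates Gamma_j / gamma_j.

    First-order SEs sigma_Yj / |gamma_j|: uncertainty in the SNP-exposure
    estimate is ignored here and assessed separately through the NOME
    diagnostics.
    """
    gamma = panel.gamma
    if np.any(gamma == 0):
        raise ValueError("ratio estimates undefined for gamma = 0")
    ratios = panel.Gamma / gamma
    ses = panel.sigma_y / np.abs(gamma)
    return list(zip(panel.rsids, ratios.tolist(), ses.tolist()))


class IVWEstimator(RegressorMixin, BaseEstimator):
    """Inverse-variance weighted regression of outcome on exposure betas
    through the origin.

    Fixed-effect by default; with ``random_effects=True`` the SE is
    inflated multiplicatively by max(1, sqrt(Q / (k - 1))) where Q is
    Cochran's heterogeneity statistic.
    """

    def __init__(self, random_effects: bool = False):
        self.random_effects = random_effects

    def fit(self, X, y, y_se=None, x_se=None):
        X, y, y_se = _check_xy(X, y, y_se, min_snps=1)
        x = X[:, 0]
        w = y_se ** -2.0
        sxx = float(np.sum(w * x * x))
        if sxx <= 0:
            raise ValueError("degenerate panel: sum of weighted gamma^2 is zero")
        beta = float(np.sum(w * x * y) / sxx)
        se = sxx ** -0.5
        k = y.shape[0]
        resid = y - beta * x
        q = float(np.sum(w * resid ** 2))
        self.cochran_q_ = q
        self.q_df_ = k - 1
        self.q_pvalue_ = float(stats.chi2.sf(q, k - 1)) if k >= 2 else np.nan
        if self.random_effects:
            if k < 2:
                raise ValueError("random-effects IVW needs at least 2 SNPs")
            se *= max(1.0, np.sqrt(q / (k - 1)))
        self.coef_ = np.array([beta])
        self.beta_ = beta
        self.se_ = float(se)
        self.ci_ = (beta - Z_95 * se, beta + Z_95 * se)
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(beta) / se))
        self.n_snps_ = k
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method="ivw",
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            pvalue=self.pvalue_,
            n_snps=self.n_snps_,
            model_flags={
                "random_effects": self.random_effects,
                "cochran_q": self.cochran_q_,
                "q_pvalue": self.q_pvalue_,
            },
        )


def _wls_with_design(D: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (coef, unit covariance, weighted RSS)."""
    sw = np.sqrt(w)
    A = D * sw[:, None]
    b = y * sw
    xtx = A.T @ A
    # pseudo-inverse: an all-zero column (an exposure with no instrument
    # signal) gets a zero coefficient rather than a hard failure
    cov_unit = np.linalg.pinv(xtx)
    coef = cov_unit @ (A.T @ b)
    resid = b - A @ coef
    rss = float(resid @ resid)
    return coef, cov_unit, rss


class EggerRegression(RegressorMixin, BaseEstimator):
    """MR-Egger: weighted regression of outcome betas on exposure betas
    with an intercept.

    The intercept estimates the average directional pleiotropic effect;
    the slope estimates the causal effect and remains consistent under the
    InSIDE assumption even when every instrument is pleiotropic. SEs use
    the weighted-regression covariance scaled by max(1, residual
    dispersion); inference uses a t distribution on k - 2 df.
    """

    def fit(self, X, y, y_se=None, x_se=None):
        X, y, y_se = _check_xy(X, y, y_se, min_snps=3)
        x = X[:, 0]
        k = y.shape[0]
        w = y_se ** -2.0
        D = np.column_stack([np.ones(k), x])
        coef, cov_unit, rss = _wls_with_design(D, y, w)
        dispersion = np.sqrt(rss / (k - 2))
        scale = max(1.0, dispersion)
        ses = np.sqrt(np.diag(cov_unit)) * scale
        tq = float(stats.t.ppf(0.975, k - 2))
        self.coef_ = coef[1:]
        self.intercept_ = float(coef[0])
        self.beta_ = float(coef[1])
        self.se_ = float(ses[1])
        self.intercept_se_ = float(ses[0])
        self.dispersion_ = float(dispersion)
        self.df_ = k - 2
        self.ci_ = (self.beta_ - tq * self.se_, self.beta_ + tq * self.se_)
        self.intercept_ci_ = (
            self.intercept_ - tq * self.intercept_se_,
            self.intercept_ + tq * self.intercept_se_,
        )
        self.pvalue_ = float(2.0 * stats.t.sf(abs(self.beta_) / self.se_, k - 2))
        self.intercept_pvalue_ = float(
            2.0 * stats.t.sf(abs(self.intercept_) / self.intercept_se_, k - 2)
        )
        self.n_snps_ = k
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def to_estimate(self, method: str = "egger") -> MREstimate:
        return MREstimate(
            method=method,
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            pvalue=self.pvalue_,
            n_snps=self.n_snps_,
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            intercept_p=self.intercept_pvalue_,
            model_flags={"dispersion": self.dispersion_, "df": self.df_},
        )


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median.

    Values are sorted ascending; with normalized weights w_j and running
    sums S_j, each value sits at cumulative midpoint p_j = S_j - w_j / 2.
    The estimate is the piecewise-linear interpolation of the sorted
    values at p = 1/2.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    w = w / w.sum()
    p = np.cumsum(w) - 0.5 * w
    if 0.5 <= p[0]:
        return float(v[0])
    if 0.5 >= p[-1]:
        return float(v[-1])
    j = int(np.searchsorted(p, 0.5))
    frac = (0.5 - p[j - 1]) / (p[j] - p[j - 1])
    return float(v[j - 1] + frac * (v[j] - v[j - 1]))


def _weighted_median_rows(V: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise interpolated weighted median of (B, k) arrays."""
    order = np.argsort(V, axis=1, kind="stable")
    v = np.take_along_axis(V, order, axis=1)
    w = np.take_along_axis(W, order, axis=1)
    w = w / w.sum(axis=1, keepdims=True)
    p = np.cumsum(w, axis=1) - 0.5 * w
    below = (p < 0.5).sum(axis=1)  # index of first p_j >= 0.5
    out = np.empty(V.shape[0])
    k = V.shape[1]
    lo_mask = below == 0
    hi_mask = below == k
    out[lo_mask] = v[lo_mask, 0]
    out[hi_mask] = v[hi_mask, -1]
    mid = ~(lo_mask | hi_mask)
    j = below[mid]
    rows = np.nonzero(mid)[0]
    p_hi = p[rows, j]
    p_lo = p[rows, j - 1]
    frac = (0.5 - p_lo) / (p_hi - p_lo)
    out[mid] = v[rows, j - 1] + frac * (v[rows, j] - v[rows, j - 1])
    return out


class WeightedMedianEstimator(RegressorMixin, BaseEstimator):
    """Weighted median of the per-SNP ratio estimates.

    Consistent when at least half of the total weight comes from valid
    instruments. The SE comes from a parametric bootstrap: exposure and
    outcome betas are resampled from normal distributions centred on their
    estimates, and the weighted median recomputed ``n_boot`` times.
    """

    def __init__(self, n_boot: int = 10_000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def fit(self, X, y, y_se=None, x_se=None):
        if y_se is None:
            raise ValueError("weighted median needs outcome standard errors")
        X, y, y_se = _check_xy(X, y, y_se, min_snps=3)
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        x = X[:, 0]
        if np.any(x == 0):
            raise ValueError("ratio estimates undefined for gamma = 0")
        if x_se is None:
            raise ValueError("weighted median bootstrap needs exposure SEs (x_se)")
        x_se = _as_1d(x_se, "x_se")
        ratios = y / x
        rse = y_se / np.abs(x)
        weights = rse ** -2.0
        self.beta_ = weighted_median(ratios, weights)

        rng = np.random.default_rng(self.random_state)
        gx = x + rng.standard_normal((self.n_boot, x.size)) * x_se
        gy = y + rng.standard_normal((self.n_boot, y.size)) * y_se
        # guard exact zeros in the resampled exposure betas
        gx = np.where(gx == 0.0, np.finfo(float).tiny, gx)
        boot_ratios = gy / gx
        boot_w = (y_se / np.abs(gx)) ** -2.0
        reps = _weighted_median_rows(boot_ratios, boot_w)
        se = float(np.std(reps, ddof=1))
        if se <= 0:  # fully degenerate panel; report a tiny positive SE
            se = np.finfo(float).tiny
        self.bootstrap_replicates_ = reps
        self.se_ = se
        self.ci_ = (self.beta_ - Z_95 * se, self.beta_ + Z_95 * se)
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(self.beta_) / se))
        self.n_snps_ = x.size
        self.coef_ = np.array([self.beta_])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def to_estimate(self) -> MREstimate:
        return MREstimate(
            method="weighted_median",
            beta=self.beta_,
            se=self.se_,
            ci_low=self.ci_[0],
            ci_high=self.ci_[1],
            pvalue=self.pvalue_,
            n_snps=self.n_snps_,
            model_flags={"n_boot": self.n_boot, "seed": self.random_state},
        )


class MultivariableIVW(RegressorMixin, BaseEstimator):
    """Multivariable IVW: outcome betas regressed on the betas of several
    exposures simultaneously, weights sigma_Y^-2, no intercept.

    Adjusts the causal estimate of the exposure of interest for the
    instruments' associations with the other modelled exposures. Inference
    uses a t distribution on k - m df with the dispersion-scaled
    covariance, as in the Egger model.
    """

    def fit(self, X, y, y_se=None, x_se=None, exposure_names=None):
        X, y, y_se = _check_xy(X, y, y_se, min_snps=2, allow_matrix=True)
        k, m = X.shape
        if k < m + 1:
            raise ValueError(
                f"multivariable IVW needs at least {m + 1} SNPs for {m} exposures"
            )
        names = list(exposure_names) if exposure_names is not None else [
            f"x{i}" for i in range(m)
        ]
        nonzero_cols = [j for j in range(m) if np.any(X[:, j] != 0.0)]
        Xnz = X[:, nonzero_cols]
        if Xnz.size and np.linalg.matrix_rank(Xnz) < len(nonzero_cols):
            collinear = names
            if m > 1:
                cc = np.corrcoef(X, rowvar=False)
                pairs = [
                    (names[i], names[j])
                    for i in range(m)
                    for j in range(i + 1, m)
                    if abs(cc[i, j]) > 1 - 1e-10
                ]
                if pairs:
                    collinear = sorted({n for p in pairs for n in p})
            raise np.linalg.LinAlgError(
                f"exposure beta matrix is rank deficient; collinear exposures: "
                f"{collinear}"
            )
        w = y_se ** -2.0
        coef, cov_unit, rss = _wls_with_design(X, y, w)
        df = k - m
        dispersion = np.sqrt(rss / df)
        scale = max(1.0, dispersion)
        ses = np.sqrt(np.diag(cov_unit)) * scale
        tq = float(stats.t.ppf(0.975, df))
        self.coef_ = coef
        self.se_all_ = ses
        self.exposure_names_ = names
        self.df_ = df
        self.dispersion_ = float(dispersion)
        self.t_quantile_ = tq
        with np.errstate(divide="ignore", invalid="ignore"):
            self.pvalues_ = 2.0 * stats.t.sf(np.abs(coef) / ses, df)
        self.n_snps_ = k
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def to_estimate(self, target) -> MREstimate:
        if isinstance(target, str):
            idx = self.exposure_names_.index(target)
        else:
            idx = int(target)
        beta = float(self.coef_[idx])
        se = float(self.se_all_[idx])
        return MREstimate(
            method="mv_ivw",
            beta=beta,
            se=se,
            ci_low=beta - self.t_quantile_ * se,
            ci_high=beta + self.t_quantile_ * se,
            pvalue=float(self.pvalues_[idx]),
            n_snps=self.n_snps_,
            model_flags={
                "exposures": list(self.exposure_names_),
                "df": self.df_,
                "dispersion": self.dispersion_,
            },
        )


# ---------------------------------------------------------------------------
# panel-level convenience wrappers

def ivw_estimate(panel: HarmonizedPanel, random_effects: bool = False) -> MREstimate:
    est = IVWEstimator(random_effects=random_effects)
    est.fit(panel.gamma, panel.Gamma, y_se=panel.sigma_y)
    return est.to_estimate()


def egger_estimate(panel: HarmonizedPanel) -> MREstimate:
    est = EggerRegression()
    est.fit(panel.gamma, panel.Gamma, y_se=panel.sigma_y)
    return est.to_estimate()


def weighted_median_estimate(
    panel: HarmonizedPanel, n_boot: int = 10_000, seed: int | None = None
) -> MREstimate:
    est = WeightedMedianEstimator(n_boot=n_boot, random_state=seed)
    est.fit(panel.gamma, panel.Gamma, y_se=panel.sigma_y, x_se=panel.sigma_x)
    return est.to_estimate()


def multivariable_ivw_estimate(
    exposure_betas: np.ndarray,
    outcome_betas: np.ndarray,
    outcome_se: np.ndarray,
    exposure_names: Sequence[str],
    target_exposure: str,
) -> MREstimate:
    est = MultivariableIVW()
    est.fit(
        exposure_betas,
        outcome_betas,
        y_se=outcome_se,
        exposure_names=exposure_names,
    )
    return est.to_estimate(target_exposure)
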