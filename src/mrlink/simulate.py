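"""Synthetic two-sample summary-statistics generator with known ground
truth.

The generator embodies the standard two-sample MR data model: for SNP j
with minor-allele frequency maf_j, a true SNP-exposure effect gamma_j and
(for invalid instruments) a direct pleiotropic effect alpha_j on the
outcome, the true SNP-outcome effect is

    Gamma_j = beta_causal * gamma_j + alpha_j,

with alpha drawn independently of gamma (the InSIDE condition).
Observed estimates carry independent sampling error in both samples, with
standard errors sigma = 1 / sqrt(2 n maf (1 - maf)) — the standardized
single-SNP regression SE under Hardy-Weinberg equilibrium. Instruments
are simulated mutually independent (real instrument sets are pruned to
pairwise r² < 0.1, so LD between instruments is not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .summary_data import HarmonizedPanel, PanelRecord, VariantAssociation

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "A"),
                 ("G", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimPanelConfig:
    """Full parameterization of the two-sample generator.

    Defaults emulate a well-powered consortium setting scaled to
    simulation size: 50 genome-wide-significant instruments measured in
    two non-overlapping samples of 50,000 and a modest causal effect of
    0.1 SD per SD. The SNP-exposure effect distribution is set deep in
    the strong-instrument regime (per-variant F in the hundreds,
    I²_GX > 0.99), so that estimator behaviour under the default
    conditions reflects the pleiotropy architecture rather than
    weak-instrument attenuation; measurement-error regimes are produced
    by shrinking ``n_exposure``.
    """

    k: int = 50
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    beta_causal: float = 0.1
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_mean: float = 0.3
    gamma_sd: float = 0.15
    pleiotropy_mode: str = "none"  # none | balanced | directional
    invalid_fraction: float = 0.0
    alpha_mean: float = 0.02
    alpha_sd: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must be a nondegenerate interval in (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy_mode must be none, balanced or directional")
        if not (0.0 <= self.invalid_fraction <= 1.0):
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if self.pleiotropy_mode == "balanced" and self.alpha_mean != 0.0:
            raise ValueError("balanced pleiotropy forces alpha_mean = 0")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be positive")


@dataclass
class PanelTruth:
    """Ground truth behind a generated panel."""

    beta_causal: float
    gamma_true: np.ndarray
    alpha: np.ndarray
    invalid: np.ndarray  # boolean mask
    maf: np.ndarray
    config: SimPanelConfig

    @property
    def invalid_rsids(self) -> list[str]:
        return [f"rs{j + 1}" for j in np.nonzero(self.invalid)[0]]


def _truncated_positive_normal(rng, mean, sd, size) -> np.ndarray:
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _draw_alpha(rng, cfg: SimPanelConfig, n_invalid: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    invalid = np.zeros(k, dtype=bool)
    alpha = np.zeros(k)
    if cfg.pleiotropy_mode == "none" or n_invalid == 0:
        return alpha, invalid
    idx = rng.choice(k, size=n_invalid, replace=False)
    invalid[idx] = True
    mean = 0.0 if cfg.pleiotropy_mode == "balanced" else cfg.alpha_mean
    alpha[idx] = rng.normal(mean, cfg.alpha_sd, size=n_invalid)
    return alpha, invalid


def generate_two_sample_panel(
    cfg: SimPanelConfig,
) -> tuple[HarmonizedPanel, PanelTruth]:
    """Generate an already-harmonized panel plus its ground truth.

    True SNP-exposure effects are drawn truncated-positive so the
    orientation invariant holds by construction; sampling noise can still
    flip an observed exposure sign, in which case the record is re-oriented
    exactly as harmonization would do (and the truth flipped with it).
    """
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
    gamma_true = _truncated_positive_normal(rng, cfg.gamma_mean, cfg.gamma_sd, k)
    n_invalid = int(round(cfg.invalid_fraction * k))
    alpha, invalid = _draw_alpha(rng, cfg, n_invalid, k)
    Gamma_true = cfg.beta_causal * gamma_true + alpha

    het = 2.0 * maf * (1.0 - maf)
    sigma_x = 1.0 / np.sqrt(cfg.n_exposure * het)
    sigma_y = 1.0 / np.sqrt(cfg.n_outcome * het)
    gamma_obs = gamma_true + rng.standard_normal(k) * sigma_x
    Gamma_obs = Gamma_true + rng.standard_normal(k) * sigma_y

    # re-orient SNPs whose observed exposure beta came out negative
    flip = gamma_obs < 0
    gamma_obs = np.where(flip, -gamma_obs, gamma_obs)
    Gamma_obs = np.where(flip, -Gamma_obs, Gamma_obs)
    gamma_true = np.where(flip, -gamma_true, gamma_true)
    alpha = np.where(flip, -alpha, alpha)
    eaf = np.where(flip, 1.0 - maf, maf)
    nonzero = gamma_obs > 0
    if not np.all(nonzero):  # measure-zero guard
        gamma_obs = np.where(nonzero, gamma_obs, np.finfo(float).tiny)

    alleles = [_ALLELE_PAIRS[int(i)] for i in rng.integers(0, len(_ALLELE_PAIRS), k)]
    records = [
        PanelRecord(
            rsid=f"rs{j + 1}",
            effect_allele=alleles[j][0],
            other_allele=alleles[j][1],
            gamma=float(gamma_obs[j]),
            sigma_x=float(sigma_x[j]),
            Gamma=float(Gamma_obs[j]),
            sigma_y=float(sigma_y[j]),
            eaf=float(eaf[j]),
        )
        for j in range(k)
    ]
    panel = HarmonizedPanel(
        "sim_exposure", "sim_outcome", records,
        [f"simulated panel (seed={cfg.seed})"],
    )
    truth = PanelTruth(cfg.beta_causal, gamma_true, alpha, invalid, maf, cfg)
    return panel, truth


@dataclass
class MultiPanel:
    """Harmonized panel with a matrix of exposure betas per SNP."""

    exposure_names: list[str]
    outcome_name: str
    rsids: list[str]
    X: np.ndarray       # (k, m) exposure betas
    x_se: np.ndarray    # (k, m)
    y: np.ndarray       # (k,) outcome betas
    y_se: np.ndarray
    eaf: np.ndarray


@dataclass
class MultiPanelTruth:
    causal_vector: np.ndarray
    gamma_true: np.ndarray  # (k, m)
    alpha: np.ndarray
    invalid: np.ndarray
    config: SimPanelConfig


def generate_multivariable_panel(
    cfg: SimPanelConfig,
    n_exposures: int = 2,
    causal_vector: Sequence[float] = (0.1, 0.0),
    cross_loadings: np.ndarray | None = None,
) -> tuple[MultiPanel, MultiPanelTruth]:
    """Generate a panel whose SNPs load on several correlated exposures.

    Latent per-SNP effects Z (one column per exposure, the first column
    truncated positive) are mixed through the ``cross_loadings`` matrix L
    into true exposure betas G = Z @ L, so off-diagonal loadings create
    instruments shared between exposures — the situation of strongly
    overlapping instrument sets among correlated traits. The outcome is
    built from ``causal_vector``.
    """
    if n_exposures < 2:
        raise ValueError("n_exposures must be at least 2")
    causal = np.asarray(causal_vector, dtype=float)
    if causal.shape != (n_exposures,):
        raise ValueError("causal_vector length must match n_exposures")
    if cross_loadings is None:
        L = np.eye(n_exposures)
    else:
        L = np.asarray(cross_loadings, dtype=float)
        if L.shape != (n_exposures, n_exposures):
            raise ValueError("cross_loadings must be square (m x m)")
        if abs(np.linalg.det(L)) < 1e-12:
            raise ValueError("cross_loadings mixing matrix is singular")

    rng = np.random.default_rng(cfg.seed)
    k, m = cfg.k, n_exposures
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
    Z = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=(k, m))
    Z[:, 0] = _truncated_positive_normal(rng, cfg.gamma_mean, cfg.gamma_sd, k)
    G = Z @ L
    n_invalid = int(round(cfg.invalid_fraction * k))
    alpha, invalid = _draw_alpha(rng, cfg, n_invalid, k)
    y_true = G @ causal + alpha

    het = 2.0 * maf * (1.0 - maf)
    sigma_x = (1.0 / np.sqrt(cfg.n_exposure * het))[:, None] * np.ones((1, m))
    sigma_y = 1.0 / np.sqrt(cfg.n_outcome * het)
    X = G + rng.standard_normal((k, m)) * sigma_x
    y = y_true + rng.standard_normal(k) * sigma_y

    # orient on the first (target) exposure
    flip = X[:, 0] < 0
    X[flip] *= -1.0
    y = np.where(flip, -y, y)
    G[flip] *= -1.0
    alpha = np.where(flip, -alpha, alpha)
    eaf = np.where(flip, 1.0 - maf, maf)

    panel = MultiPanel(
        exposure_names=[f"exposure_{i + 1}" for i in range(m)],
        outcome_name="sim_outcome",
        rsids=[f"rs{j + 1}" for j in range(k)],
        X=X,
        x_se=sigma_x,
        y=y,
        y_se=sigma_y,
        eaf=eaf,
    )
    truth = MultiPanelTruth(causal, G, alpha, invalid, cfg)
    return panel, truth


def panel_to_associations(
    panel: HarmonizedPanel, truth: PanelTruth | None = None
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Split a harmonized panel back into exposure and outcome association
    lists (the round-trip counterpart of ``harmonize_panel``)."""
    n_exp = truth.config.n_exposure if truth is not None else None
    n_out = truth.config.n_outcome if truth is not None else None
    exposure, outcome = [], []
    for r in panel.records:
        z = abs(r.gamma) / r.sigma_x
        p_exp = float(2.0 * stats.norm.sf(z))
        exposure.append(
            VariantAssociation(
                r.rsid, r.effect_allele, r.other_allele, r.gamma, r.sigma_x,
                eaf=r.eaf, pvalue=max(p_exp, np.finfo(float).tiny), n=n_exp,
            )
        )
        zo = abs(r.Gamma) / r.sigma_y
        p_out = float(2.0 * stats.norm.sf(zo))
        outcome.append(
            VariantAssociation(
                r.rsid, r.effect_allele, r.other_allele, r.Gamma, r.sigma_y,
                eaf=r.eaf, pvalue=max(p_out, np.finfo(float).tiny), n=n_out,
            )
        )
    return exposure, outcome
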