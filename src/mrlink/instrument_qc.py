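"""Instrument validity checks: explained variance, cross-trait / LD
overlap exclusion, and stepwise Q-statistic heterogeneity filtering.

The F statistic cannot be computed from summary data alone; instrument
sets restricted to genome-wide-significant, mutually independent SNPs
imply per-variant F > 30, which is logged as a heuristic rather than
computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .estimators import IVWEstimator
from .summary_data import HarmonizedPanel, LDTable, VariantAssociation

logger = logging.getLogger(__name__)

F_STAT_HEURISTIC = (
    "genome-wide-significant, independent instruments imply a per-variant "
    "F statistic > 30; F itself is not computable from summary data"
)


@dataclass
class FilterTrace:
    """Ordered record of SNPs removed by the heterogeneity filter."""

    removed: list[tuple[str, float, float]]  # (rsid, Q before removal, p before)
    final_q: float
    final_p: float
    retained: list[str]
    floor_reached: bool = False

    def __post_init__(self) -> None:
        overlap = {r for r, _, _ in self.removed} & set(self.retained)
        if overlap:
            raise ValueError(f"removed and retained SNPs overlap: {sorted(overlap)}")


def explained_variance(
    assocs: Sequence[VariantAssociation], var_x: float = 1.0
) -> float:
    """Trait variance explained by a set of instruments.

    Sum over SNPs of beta_i^2 * 2 * MAF_i * (1 - MAF_i) / var(X), with
    MAF the minor-allele frequency and var(X) = 1 for traits analysed in
    SD units. Under Hardy-Weinberg equilibrium 2*MAF*(1-MAF) is the
    variance of the additively coded genotype.
    """
    if not var_x > 0:
        raise ValueError("var_x must be positive")
    missing = [a.rsid for a in assocs if a.eaf is None]
    if missing:
        raise ValueError(
            f"explained variance needs allele frequencies; missing eaf for {missing}"
        )
    total = 0.0
    for a in assocs:
        maf = min(a.eaf, 1.0 - a.eaf)
        total += a.beta ** 2 * 2.0 * maf * (1.0 - maf)
    return total / var_x


def exclude_cross_trait_overlap(
    panel: HarmonizedPanel,
    other_trait_snps: Mapping[str, Iterable[str]],
    ld: LDTable | None = None,
    r2_threshold: float = 0.8,
    include_lists: Iterable[str] | None = None,
) -> tuple[HarmonizedPanel, list[dict]]:
    """Remove panel SNPs present in (or in LD with) other traits' instrument
    sets.

    A SNP is removed when it appears verbatim in any named list, or when
    the LD table reports r² strictly greater than ``r2_threshold`` with any
    listed SNP. ``include_lists`` restricts the check to a subset of list
    names (e.g. only the non-lipid traits). An empty resulting panel is
    legal and signalled by the exclusion log, not an error.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must lie in (0, 1]")
    names = list(other_trait_snps)
    if include_lists is not None:
        wanted = set(include_lists)
        names = [n for n in names if n in wanted]
    lists = {n: set(other_trait_snps[n]) for n in names}

    exclusions: list[dict] = []
    keep: list[str] = []
    for rsid in panel.rsids:
        hit = None
        for name in names:
            if rsid in lists[name]:
                hit = {"rsid": rsid, "list": name, "reason": "overlap"}
                break
            if ld is not None:
                for other in lists[name]:
                    r2 = ld.get(rsid, other)
                    if r2 is not None and r2 > r2_threshold:
                        hit = {
                            "rsid": rsid,
                            "list": name,
                            "reason": "ld_proxy",
                            "proxy": other,
                            "r2": r2,
                        }
                        break
            if hit:
                break
        if hit:
            exclusions.append(hit)
        else:
            keep.append(rsid)

    if not keep:
        logger.warning(
            "cross-trait exclusion removed every SNP from panel %s -> %s",
            panel.exposure_name,
            panel.outcome_name,
        )
        empty = HarmonizedPanel(
            panel.exposure_name,
            panel.outcome_name,
            [],
            list(panel.provenance) + ["cross-trait exclusion removed all SNPs"],
        )
        return empty, exclusions
    note = (
        f"cross-trait exclusion removed {len(exclusions)} SNP(s)"
        if exclusions
        else None
    )
    return panel.subset(keep, note=note), exclusions


def _ivw_q_contributions(panel: HarmonizedPanel) -> tuple[float, float, np.ndarray]:
    est = IVWEstimator().fit(panel.gamma, panel.Gamma, y_se=panel.sigma_y)
    w = panel.sigma_y ** -2.0
    contrib = w * (panel.Gamma - est.beta_ * panel.gamma) ** 2
    q = float(contrib.sum())
    p = float(stats.chi2.sf(q, len(panel) - 1))
    return q, p, contrib


def qrs_heterogeneity_filter(
    panel: HarmonizedPanel, p_threshold: float = 0.05
) -> tuple[HarmonizedPanel, FilterTrace]:
    """Stepwise downward heterogeneity filter on the genetic risk score.

    Iteratively fits the IVW model, computes Cochran's Q against a
    chi-square with k - 1 df, and — while Q is significant at
    ``p_threshold`` — removes the SNP with the largest individual Q
    contribution (ties broken by lexicographically smaller rsid), refits,
    and repeats. Stops when the test is no longer significant or when only
    two SNPs remain (a Q test needs at least two); hitting that floor with
    a still-significant Q sets ``floor_reached`` instead of erroring.
    """
    if len(panel) < 2:
        raise ValueError("heterogeneity filtering needs at least 2 SNPs")
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")

    current = panel
    removed: list[tuple[str, float, float]] = []
    while True:
        q, p, contrib = _ivw_q_contributions(current)
        if p >= p_threshold:
            return current, FilterTrace(removed, q, p, list(current.rsids))
        if len(current) <= 2:
            return current, FilterTrace(
                removed, q, p, list(current.rsids), floor_reached=True
            )
        # tie-break deterministically by smaller rsid
        max_c = contrib.max()
        tied = [j for j in range(len(current)) if contrib[j] == max_c]
        worst = min(tied, key=lambda j: current.rsids[j])
        rsid = current.rsids[worst]
        removed.append((rsid, q, p))
        current = current.drop(
            [rsid], note=f"qrs filter removed {rsid} (Q={q:.4g}, p={p:.4g})"
        )
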