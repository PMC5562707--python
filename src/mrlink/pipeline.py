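"""Bidirectional analysis driver.

Runs every requested estimator and sensitivity analysis for each
exposure–outcome pair in both directions (trait as exposure on the second
trait, then the reverse), applies the multiple-testing threshold, and
emits a tabular report plus heterogeneity-filter traces. Methods whose
minimum instrument count a direction cannot meet are skipped with a
logged reason rather than failing the run — with two or three SNPs only
the IVW estimate is meaningful.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .estimators import (
    MREstimate,
    MultivariableIVW,
    egger_estimate,
    ivw_estimate,
    weighted_median_estimate,
)
from .instrument_qc import FilterTrace, exclude_cross_trait_overlap, qrs_heterogeneity_filter
from .nome_simex import SimexSettings, simex_egger
from .summary_data import (
    HarmonizedPanel,
    VariantAssociation,
    _align_outcome,
    harmonize_panel,
    load_associations,
    load_ld_table,
    write_report,
)

logger = logging.getLogger(__name__)

#: minimum panel size per method
MIN_SNPS = {"ivw": 1, "egger": 3, "weighted_median": 3, "egger_simex": 3}
KNOWN_METHODS = ("ivw", "egger", "weighted_median", "mv_ivw", "egger_simex")


@dataclass
class TableSpec:
    name: str
    path: str
    column_map: dict = field(default_factory=dict)


@dataclass
class PairSpec:
    exposure: TableSpec
    outcome: TableSpec
    covariates: list[TableSpec] = field(default_factory=list)


@dataclass
class SensitivitySpec:
    qrs_filter: bool = False
    qrs_p_threshold: float = 0.05
    exclude_snps: list[str] = field(default_factory=list)
    cross_trait_lists: dict[str, str] = field(default_factory=dict)
    cross_trait_include: list[str] | None = None
    ld_table: str | None = None
    r2_threshold: float = 0.8


@dataclass
class AnalysisPlan:
    pairs: list[PairSpec]
    methods: list[str] = field(default_factory=lambda: ["ivw"])
    sensitivity: SensitivitySpec = field(default_factory=SensitivitySpec)
    alpha: float = 0.05 / 8  # four correlated trait blocks, two directions
    seed: int = 0
    n_boot: int = 10_000
    simex: SimexSettings = field(default_factory=SimexSettings)
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not self.pairs:
            raise ValueError("the analysis plan needs at least one pair")
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if "mv_ivw" in self.methods and not any(p.covariates for p in self.pairs):
            raise ValueError("mv_ivw requested but no pair provides covariate tables")


def _table_spec(node: Mapping, default_map: Mapping) -> TableSpec:
    cmap = dict(default_map)
    cmap.update(node.get("column_map", {}))
    return TableSpec(name=node["name"], path=node["path"], column_map=cmap)


def load_plan(path) -> AnalysisPlan:
    """Parse a YAML analysis plan."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    default_map = cfg.get("column_map", {})
    pairs = []
    for node in cfg["pairs"]:
        pairs.append(
            PairSpec(
                exposure=_table_spec(node["exposure"], default_map),
                outcome=_table_spec(node["outcome"], default_map),
                covariates=[
                    _table_spec(c, default_map) for c in node.get("covariates", [])
                ],
            )
        )
    sens_cfg = cfg.get("sensitivity", {}) or {}
    cross = sens_cfg.get("cross_trait", {}) or {}
    sensitivity = SensitivitySpec(
        qrs_filter=bool(sens_cfg.get("qrs_filter", False)),
        qrs_p_threshold=float(sens_cfg.get("p_threshold", 0.05)),
        exclude_snps=list(sens_cfg.get("exclude_snps", [])),
        cross_trait_lists=dict(cross.get("lists", {})),
        cross_trait_include=cross.get("include"),
        ld_table=cross.get("ld_table"),
        r2_threshold=float(cross.get("r2_threshold", 0.8)),
    )
    simex_cfg = cfg.get("simex", {}) or {}
    simex = SimexSettings(
        lambdas=tuple(simex_cfg.get("lambdas", (0.5, 1.0, 1.5, 2.0))),
        n_sim=int(simex_cfg.get("n_sim", 1000)),
        extrapolant=int(simex_cfg.get("extrapolant", 2)),
        seed=simex_cfg.get("seed"),
    )
    return AnalysisPlan(
        pairs=pairs,
        methods=list(cfg.get("methods", ["ivw"])),
        sensitivity=sensitivity,
        alpha=float(cfg.get("alpha", 0.05 / 8)),
        seed=int(cfg.get("seed", 0)),
        n_boot=int(cfg.get("n_boot", 10_000)),
        simex=simex,
        column_map=default_map,
    )


def _child_seed(seed: int, *parts: str) -> int:
    tag = zlib.crc32("|".join(parts).encode())
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2 ** 31))


def _align_covariates(
    panel: HarmonizedPanel, covariates: Sequence[tuple[str, list[VariantAssociation]]]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Build the (k, m) exposure-beta matrix for multivariable IVW.

    Column 0 holds the panel's own exposure betas; each covariate's beta
    is re-expressed on the panel's effect allele. Returns (matrix, names,
    rsids retained) — SNPs missing from any covariate table are dropped.
    """
    cov_maps = [(name, {a.rsid: a for a in assocs}) for name, assocs in covariates]
    rows, rsids = [], []
    for rec in panel.records:
        exp_like = VariantAssociation(
            rec.rsid, rec.effect_allele, rec.other_allele, rec.gamma, rec.sigma_x,
            eaf=rec.eaf,
        )
        vals = [rec.gamma]
        ok = True
        for _, amap in cov_maps:
            cov = amap.get(rec.rsid)
            aligned = _align_outcome(exp_like, cov) if cov is not None else None
            if aligned is None:
                ok = False
                break
            vals.append(aligned[0])
        if ok:
            rows.append(vals)
            rsids.append(rec.rsid)
    names = [panel.exposure_name] + [name for name, _ in covariates]
    return np.asarray(rows, dtype=float), names, rsids


def run_bidirectional_analysis(
    plan: AnalysisPlan, out_path=None
) -> tuple[pd.DataFrame, dict[str, FilterTrace], list[str]]:
    """Execute the plan; returns (report, filter traces, log lines).

    One report row per (exposure, outcome, method) actually run; the
    ``significant`` column is exactly ``pvalue < plan.alpha``. Exit is
    determined by operational success only, never by scientific outcome.
    """
    log: list[str] = []
    traces: dict[str, FilterTrace] = {}
    rows: list[dict] = []

    def say(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    table_cache: dict[str, list[VariantAssociation]] = {}

    def load(spec: TableSpec) -> list[VariantAssociation]:
        if spec.path not in table_cache:
            table_cache[spec.path] = load_associations(
                spec.path, column_map=spec.column_map or None, trait_name=spec.name
            )
        return table_cache[spec.path]

    sens = plan.sensitivity
    ld = load_ld_table(sens.ld_table) if sens.ld_table else None
    cross_lists = {
        name: [l.strip() for l in Path(p).read_text().splitlines() if l.strip()]
        for name, p in sens.cross_trait_lists.items()
    }

    for pair in plan.pairs:
        directions = [
            (pair.exposure, pair.outcome, pair.covariates),
            (pair.outcome, pair.exposure, []),
        ]
        for exp_spec, out_spec, covariates in directions:
            tag = f"{exp_spec.name}->{out_spec.name}"
            panel = harmonize_panel(
                load(exp_spec), load(out_spec),
                exposure_name=exp_spec.name, outcome_name=out_spec.name,
            )
            say(f"{tag}: harmonized {len(panel)} SNP(s)")
            notes: list[str] = []

            if sens.exclude_snps:
                before = len(panel)
                panel = panel.drop(sens.exclude_snps, note="named exclusion list")
                if len(panel) < before:
                    msg = f"excluded {before - len(panel)} named SNP(s)"
                    notes.append(msg)
                    say(f"{tag}: {msg}")

            if cross_lists:
                before = len(panel)
                panel, excl = exclude_cross_trait_overlap(
                    panel, cross_lists, ld=ld, r2_threshold=sens.r2_threshold,
                    include_lists=sens.cross_trait_include,
                )
                if excl:
                    msg = f"cross-trait exclusion removed {len(excl)} SNP(s)"
                    notes.append(msg)
                    say(f"{tag}: {msg}")

            if sens.qrs_filter:
                if len(panel) >= 2:
                    panel, trace = qrs_heterogeneity_filter(
                        panel, p_threshold=sens.qrs_p_threshold
                    )
                    traces[tag] = trace
                    if trace.removed:
                        msg = (
                            f"heterogeneity filter removed "
                            f"{[r for r, _, _ in trace.removed]}"
                        )
                        notes.append(msg)
                    say(
                        f"{tag}: heterogeneity filter retained {len(panel)} SNP(s), "
                        f"final Q={trace.final_q:.4g} (p={trace.final_p:.4g})"
                    )
                else:
                    say(f"{tag}: skipped heterogeneity filter (needs >= 2 SNPs)")

            if len(panel) == 0:
                say(f"{tag}: no SNPs left after filtering; all methods skipped")
                continue

            note_text = "; ".join(notes)
            for method in plan.methods:
                if method == "mv_ivw":
                    if not covariates:
                        say(f"{tag}: skipped mv_ivw (no covariate tables here)")
                        continue
                    covs = [(c.name, load(c)) for c in covariates]
                    X, names, rsids = _align_covariates(panel, covs)
                    if X.shape[0] < X.shape[1] + 1:
                        say(
                            f"{tag}: skipped mv_ivw (needs >= {X.shape[1] + 1} "
                            f"SNPs, has {X.shape[0]})"
                        )
                        continue
                    sub = panel.subset(rsids)
                    est = (
                        MultivariableIVW()
                        .fit(X, sub.Gamma, y_se=sub.sigma_y, exposure_names=names)
                        .to_estimate(exp_spec.name)
                    )
                elif len(panel) < MIN_SNPS[method]:
                    say(
                        f"{tag}: skipped {method} (needs >= {MIN_SNPS[method]} "
                        f"SNPs, has {len(panel)})"
                    )
                    continue
                elif method == "ivw":
                    est = ivw_estimate(panel)
                elif method == "egger":
                    est = egger_estimate(panel)
                elif method == "weighted_median":
                    est = weighted_median_estimate(
                        panel,
                        n_boot=plan.n_boot,
                        seed=_child_seed(plan.seed, tag, method),
                    )
                elif method == "egger_simex":
                    settings = SimexSettings(
                        lambdas=plan.simex.lambdas,
                        n_sim=plan.simex.n_sim,
                        extrapolant=plan.simex.extrapolant,
                        seed=plan.simex.seed
                        if plan.simex.seed is not None
                        else _child_seed(plan.seed, tag, method),
                    )
                    est = simex_egger(panel, settings)
                rows.append(
                    est.report_row(
                        exp_spec.name, out_spec.name, alpha=plan.alpha,
                        notes=note_text,
                    )
                )
                say(f"{tag}: {method} beta={est.beta:.6g} p={est.pvalue:.3g}")
            if not any(
                r["exposure"] == exp_spec.name and r["outcome"] == out_spec.name
                for r in rows
            ):
                logger.warning("%s: every method was skipped", tag)

    report = write_report(rows, out_path)
    return report, traces, log
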