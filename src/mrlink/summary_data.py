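"""Reading, validation, and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization combines per-SNP association estimates
from an exposure GWAS and an outcome GWAS. Before any estimator can run,
the two tables must be joined on the variant identifier, the outcome
estimate must refer to the same allele as the exposure estimate, and both
must be oriented towards the exposure-increasing allele so that every
SNP-exposure effect is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names expected in delimited summary-statistics tables
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pvalue": "pval",
    "n": "n",
}

_MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se")

#: eaf window in which a palindromic SNP's strand cannot be resolved by
#: allele frequency (both strands look alike near 0.5)
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele estimate on the trait scale (SD units
    for standardized traits, log scale for eGFR/apoA-IV, mmol/L for fasting
    glucose); ``se`` its standard error; ``eaf`` the effect-allele
    frequency, which may be unknown.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be a non-empty string")
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise ValueError(
                f"{self.rsid}: alleles must be single nucleotides A/C/G/T, "
                f"got {ea!r}/{oa!r}"
            )
        if ea == oa:
            raise ValueError(f"{self.rsid}: effect and other allele are identical")
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: beta must be finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.rsid}: se must be a positive number")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf must lie in [0, 1]")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: p-value must lie in (0, 1]")
        if self.n is not None and not self.n > 0:
            raise ValueError(f"{self.rsid}: sample size must be positive")

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


class PanelRecord(NamedTuple):
    """One harmonized SNP: exposure and outcome estimates on the same,
    exposure-increasing allele."""

    rsid: str
    effect_allele: str
    other_allele: str
    gamma: float      # SNP-exposure beta (> 0 by orientation)
    sigma_x: float    # its SE
    Gamma: float      # SNP-outcome beta, aligned to the same allele
    sigma_y: float    # its SE
    eaf: float | None  # exposure-side frequency of the effect allele


@dataclass
class HarmonizedPanel:
    """Aligned SNP-exposure/SNP-outcome estimate pairs.

    The unit every MR estimator consumes. Invariants: unique rsids, all
    gamma strictly positive, all SEs positive.
    """

    exposure_name: str
    outcome_name: str
    records: list[PanelRecord]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        # a useful panel has >= 1 SNP; emptiness can arise from filtering
        # and is flagged by the caller, so the container tolerates it
        seen: set[str] = set()
        for r in self.records:
            if r.rsid in seen:
                raise ValueError(f"duplicate rsid in panel: {r.rsid}")
            seen.add(r.rsid)
            if not r.gamma > 0:
                raise ValueError(
                    f"{r.rsid}: gamma must be > 0 after orientation (got {r.gamma})"
                )
            if not (r.sigma_x > 0 and r.sigma_y > 0):
                raise ValueError(f"{r.rsid}: standard errors must be positive")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(r.rsid for r in self.records)

    @property
    def gamma(self) -> np.ndarray:
        return np.array([r.gamma for r in self.records], dtype=float)

    @property
    def sigma_x(self) -> np.ndarray:
        return np.array([r.sigma_x for r in self.records], dtype=float)

    @property
    def Gamma(self) -> np.ndarray:
        return np.array([r.Gamma for r in self.records], dtype=float)

    @property
    def sigma_y(self) -> np.ndarray:
        return np.array([r.sigma_y for r in self.records], dtype=float)

    @property
    def eaf(self) -> np.ndarray:
        return np.array(
            [np.nan if r.eaf is None else r.eaf for r in self.records], dtype=float
        )

    def subset(self, rsids: Iterable[str], note: str | None = None) -> "HarmonizedPanel":
        keep = set(rsids)
        recs = [r for r in self.records if r.rsid in keep]
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return HarmonizedPanel(self.exposure_name, self.outcome_name, recs, prov)

    def drop(self, rsids: Iterable[str], note: str | None = None) -> "HarmonizedPanel":
        bad = set(rsids)
        return self.subset([r.rsid for r in self.records if r.rsid not in bad], note)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=PanelRecord._fields)


@dataclass
class LDTable:
    """Symmetric lookup of pairwise linkage disequilibrium (r²) values."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r² must lie in [0, 1], got {r2} for ({a}, {b})")
        if a == b and r2 != 1.0:
            raise ValueError(f"self-pair ({a}, {a}) must have r² = 1, got {r2}")
        key = self._key(a, b)
        # duplicate pairs collapse to the maximum r²
        prev = self.entries.get(key)
        self.entries[key] = r2 if prev is None else max(prev, r2)

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        return self.entries.get(self._key(a, b), default)

    def __len__(self) -> int:
        return len(self.entries)


class ConfigurationError(KeyError):
    """A required column is missing from the configured column map."""


def _read_table(path) -> pd.DataFrame:
    # sniff tab vs comma from the header line; round_trip parsing keeps
    # written floats bit-exact through a save/load cycle
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def load_associations(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "",
) -> list[VariantAssociation]:
    """Read a delimited summary-statistics table into association records.

    Rows violating the record invariants (non-positive SE, malformed
    alleles, out-of-range frequencies ...) are dropped and counted in the
    log rather than aborting the load. Alleles are upper-cased.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    for fld in _MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(
                f"{path}: mandatory column {cmap[fld]!r} (for field {fld!r}) "
                f"not found; available: {list(df.columns)}"
            )
    optional_present = {
        fld: (cmap[fld] in df.columns) for fld in ("eaf", "pvalue", "n")
    }

    records: list[VariantAssociation] = []
    dropped = 0
    for _, row in df.iterrows():
        def _opt(fld: str) -> float | None:
            if not optional_present[fld]:
                return None
            v = row[cmap[fld]]
            return None if pd.isna(v) else float(v)

        try:
            records.append(
                VariantAssociation(
                    rsid=str(row[cmap["rsid"]]),
                    effect_allele=str(row[cmap["effect_allele"]]).upper(),
                    other_allele=str(row[cmap["other_allele"]]).upper(),
                    beta=float(row[cmap["beta"]]),
                    se=float(row[cmap["se"]]),
                    eaf=_opt("eaf"),
                    pvalue=_opt("pvalue"),
                    n=_opt("n"),
                )
            )
        except (ValueError, TypeError) as exc:
            dropped += 1
            logger.debug("dropped row in %s: %s", path, exc)
    if dropped:
        logger.warning(
            "%s: dropped %d row(s) violating record invariants", path, dropped
        )
    if not records:
        raise ValueError(f"{path}: no valid rows for trait {trait_name or '<unnamed>'}")
    return records


def load_ld_table(path) -> LDTable:
    """Read a three-column (snp1, snp2, r2) table into a symmetric lookup."""
    df = _read_table(path)
    table = LDTable()
    if df.shape[1] < 3:
        raise ValueError(f"{path}: LD table needs three columns (snp1, snp2, r2)")
    for a, b, r2 in df.iloc[:, :3].itertuples(index=False):
        table.add(str(a), str(b), float(r2))
    return table


def _complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def _align_outcome(
    exp: VariantAssociation, out: VariantAssociation
) -> tuple[float, float | None] | None:
    """Return the outcome (beta, eaf) expressed on the exposure's effect
    allele, or None when the allele pairs cannot be reconciled."""
    ea, oa = exp.effect_allele, exp.other_allele
    pairs = [
        ((out.effect_allele, out.other_allele), +1),
        ((out.other_allele, out.effect_allele), -1),
        ((_complement(out.effect_allele), _complement(out.other_allele)), +1),
        ((_complement(out.other_allele), _complement(out.effect_allele)), -1),
    ]
    for (cand_ea, cand_oa), sign in pairs:
        if (cand_ea, cand_oa) == (ea, oa):
            if sign == +1:
                return out.beta, out.eaf
            return -out.beta, None if out.eaf is None else 1.0 - out.eaf
    return None


def harmonize_panel(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    palindromic_eaf_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW,
) -> HarmonizedPanel:
    """Join exposure and outcome association lists into a harmonized panel.

    SNPs are matched on rsid; the outcome estimate is re-expressed on the
    exposure's effect allele (allowing for swapped allele order and strand
    complement); finally each record is oriented so the SNP-exposure effect
    is positive. Palindromic (A/T, C/G) SNPs are strand-ambiguous and are
    kept only when both allele frequencies are available and informative
    (outside ``palindromic_eaf_window``), in which case frequency
    concordance decides the strand; otherwise they are dropped.
    """
    if not exposure or not outcome:
        raise ValueError("exposure and outcome association lists must be nonempty")
    out_by_rsid = {a.rsid: a for a in outcome}
    records: list[PanelRecord] = []
    provenance: list[str] = []
    lo, hi = palindromic_eaf_window

    for exp in exposure:
        out = out_by_rsid.get(exp.rsid)
        if out is None:
            continue
        aligned = _align_outcome(exp, out)
        if aligned is None:
            provenance.append(
                f"dropped {exp.rsid}: irreconcilable alleles "
                f"{exp.effect_allele}/{exp.other_allele} vs "
                f"{out.effect_allele}/{out.other_allele}"
            )
            continue
        beta_out, eaf_out = aligned

        if exp.is_palindromic:
            if exp.eaf is None or eaf_out is None:
                provenance.append(
                    f"dropped {exp.rsid}: palindromic without both frequencies"
                )
                continue
            if (lo <= exp.eaf <= hi) or (lo <= eaf_out <= hi):
                provenance.append(
                    f"dropped {exp.rsid}: palindromic with ambiguous frequency"
                )
                continue
            # frequency discordance across datasets implies a strand flip
            if (exp.eaf < 0.5) != (eaf_out < 0.5):
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
                provenance.append(
                    f"flipped {exp.rsid}: palindromic strand resolved by eaf"
                )

        gamma, sigma_x, eaf = exp.beta, exp.se, exp.eaf
        ea, oa = exp.effect_allele, exp.other_allele
        if gamma == 0:
            provenance.append(f"dropped {exp.rsid}: null SNP-exposure estimate")
            continue
        if gamma < 0:
            # orient towards the exposure-increasing allele
            gamma, beta_out = -gamma, -beta_out
            ea, oa = oa, ea
            eaf = None if eaf is None else 1.0 - eaf
        records.append(
            PanelRecord(exp.rsid, ea, oa, gamma, sigma_x, beta_out, out.se, eaf)
        )

    if not records:
        raise ValueError(
            f"no SNPs shared between exposure {exposure_name!r} and "
            f"outcome {outcome_name!r} after harmonization"
        )
    return HarmonizedPanel(exposure_name, outcome_name, records, provenance)


REPORT_COLUMNS = [
    "exposure",
    "outcome",
    "method",
    "n_snps",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "pvalue",
    "intercept",
    "intercept_se",
    "intercept_p",
    "significant",
    "notes",
]


def write_report(rows: Iterable[Mapping], path=None) -> pd.DataFrame:
    """Assemble (and, given a path, write) one TSV row per
    (exposure, outcome, method) result."""
    df = pd.DataFrame(list(rows))
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[REPORT_COLUMNS]
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return df


def write_associations(records: Sequence[VariantAssociation], path) -> None:
    """Write association records in the dialect ``load_associations`` reads."""
    df = pd.DataFrame(
        {
            "SNP": [r.rsid for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [np.nan if r.eaf is None else r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [np.nan if r.pvalue is None else r.pvalue for r in records],
            "n": [np.nan if r.n is None else r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
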