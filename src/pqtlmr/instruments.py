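"""Instrument selection and harmonization for cis-pQTL MR.

The selection cascade, applied per protein in this order:

1. exposure significance (``p < p_exposure_max``, default genome-wide 5e-8)
2. cis restriction: within ``cis_window`` bp of the gene start, same chromosome
3. minor allele frequency ``>= maf_min``
4. MHC exclusion (default chr6:28477897-33448354, inclusive endpoints)
5. instrument strength: per-SNP F statistic ``(beta/se)^2 >= f_min``
6. cross-protein pleiotropy: SNPs associated with more than
   ``max_proteins_per_snp`` proteins are removed everywhere
7. harmonization of exposure and outcome effect alleles (allele swaps,
   strand flips, palindromic SNPs with ambiguous frequency dropped)
8. Steiger filtering: keep only SNPs explaining significantly more variance
   of the exposure than of the outcome
9. greedy LD clumping at ``r^2 < clump_r2`` against a reference panel

Each dropped SNP is recorded once, labelled with the *first* filter it
failed, so the audit trail partitions the candidate list.  A protein is
eligible for MR only when at least ``min_ivs`` instruments survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .gwas_io import ReferencePanel

__all__ = [
    "FilterConfig",
    "HarmonizedPair",
    "InstrumentSet",
    "ConfigurationError",
    "per_snp_f",
    "snp_r2",
    "steiger_filter",
    "SteigerResult",
    "pleiotropy_counts",
    "pleiotropy_flagged_snps",
    "region_filters",
    "harmonize",
    "harmonize_tables",
    "ld_clump",
    "build_instrument_set",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PAIR_COLUMNS = [
    "variant_id", "chrom", "pos",
    "beta_exp", "se_exp", "eaf_exp", "n_exp", "pval_exp",
    "beta_out", "se_out", "eaf_out", "n_out",
    "f_stat", "r2_exp", "r2_out", "flipped",
]


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration (e.g. unknown gene annotation)."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the instrument-selection cascade.

    Defaults follow standard proteome-wide cis-MR practice: genome-wide
    exposure significance, F >= 10, removal of SNPs associated with more
    than five protein targets, MAF > 1%, MHC exclusion, a ±1 Mb cis window
    around the gene start, LD clumping at r² < 0.1, Steiger filtering at
    p < 0.05, and at least three instruments per protein.
    """

    p_exposure_max: float = 5e-8
    f_min: float = 10.0
    max_proteins_per_snp: int = 5
    maf_min: float = 0.01
    mhc: tuple[str, int, int] = ("6", 28_477_897, 33_448_354)
    cis_window: int = 1_000_000
    clump_r2: float = 0.1
    steiger_p: float = 0.05
    min_ivs: int = 3
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58)

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ConfigurationError("cis_window must be > 0")
        for name, lo, hi in [
            ("p_exposure_max", 0, 1), ("maf_min", 0, 0.5),
            ("clump_r2", 0, 1), ("steiger_p", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ConfigurationError(f"{name}={v} outside ({lo}, {hi}]")
        if self.f_min < 0 or self.min_ivs < 1 or self.max_proteins_per_snp < 1:
            raise ConfigurationError("f_min, min_ivs, max_proteins_per_snp out of range")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown filter config keys: {sorted(unknown)}")
        if "mhc" in raw:
            c, s, e = raw["mhc"]
            raw["mhc"] = (str(c), int(s), int(e))
        for tup in ("palindromic_eaf_band",):
            if tup in raw:
                raw[tup] = tuple(raw[tup])
        return cls(**raw)


@dataclass
class HarmonizedPair:
    """One variant's exposure/outcome effects on a common effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    eaf_exp: float
    n_exp: int
    beta_out: float
    se_out: float
    eaf_out: float
    n_out: int
    f_stat: float = np.nan
    r2_exp: float = np.nan
    r2_out: float = np.nan
    flags: set[str] = field(default_factory=set)
    chrom: str = ""
    pos: int = 0
    pval_exp: float = np.nan

    @property
    def dropped(self) -> bool:
        return any(f.endswith("_dropped") for f in self.flags)

    @property
    def drop_reason(self) -> str | None:
        for f in sorted(self.flags):
            if f.endswith("_dropped"):
                return f
        return None


@dataclass
class InstrumentSet:
    """Analysis-ready instruments for one protein, plus a complete audit of
    every dropped candidate (first failing filter each)."""

    protein: str
    gene: str
    pairs: pd.DataFrame          # surviving harmonized pairs (PAIR_COLUMNS)
    audit: pd.DataFrame          # columns: variant_id, drop_reason
    min_ivs: int = 3

    @property
    def n_candidates(self) -> int:
        return len(self.pairs) + len(self.audit)

    @property
    def eligible(self) -> bool:
        return len(self.pairs) >= self.min_ivs


def per_snp_f(beta_exp: float, se_exp: float) -> float:
    """Per-SNP instrument-strength F statistic, the squared z score
    ``(beta/se)^2``."""
    if np.any(np.asarray(se_exp) <= 0):
        raise ValueError("se_exp must be > 0")
    return (np.asarray(beta_exp) / np.asarray(se_exp)) ** 2


def snp_r2(beta: float, se: float, n: float) -> float:
    """Variance of a trait explained by one SNP, from summary statistics.

    Uses the exact univariate least-squares identity r² = t²/(t² + n − 2)
    with t = beta/se; no assumption about the trait's scale is needed.
    """
    n = np.asarray(n)
    if np.any(n <= 2):
        raise ValueError("n must be > 2")
    if np.any(np.asarray(se) <= 0):
        raise ValueError("se must be > 0")
    t2 = (np.asarray(beta) / np.asarray(se)) ** 2
    return t2 / (t2 + n - 2)


class SteigerResult(NamedTuple):
    keep: bool
    p: float
    z: float


def steiger_filter(r2_exp: float, r2_out: float, n_exp: float, n_out: float,
                   alpha: float = 0.05) -> SteigerResult:
    """Steiger filtering for one variant: does it explain significantly more
    exposure variance than outcome variance?

    Fisher z-transforms of |r| in the two (independent) samples are compared
    with ``z = (z_exp − z_out)/sqrt(1/(n_exp−3) + 1/(n_out−3))``; the variant
    is kept iff r²_exp > r²_out and the one-sided p-value is below ``alpha``.
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes must be > 3 for the Steiger z test")
    z_exp = np.arctanh(min(np.sqrt(max(r2_exp, 0.0)), 1 - 1e-12))
    z_out = np.arctanh(min(np.sqrt(max(r2_out, 0.0)), 1 - 1e-12))
    z = (z_exp - z_out) / np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    p = float(stats.norm.sf(z))
    keep = bool(r2_exp > r2_out and p < alpha)
    return SteigerResult(keep, p, float(z))


def pleiotropy_counts(
    exposure_tables: Mapping[str, pd.DataFrame],
    p_threshold: float = 5e-8,
    protein_of: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Number of distinct protein targets each variant is associated with.

    ``exposure_tables`` maps an exposure label (aptamer or protein) to its
    summary statistics; ``protein_of`` optionally collapses aptamer labels to
    unique protein targets so a protein measured by several aptamers counts
    once.
    """
    hits: dict[str, set[str]] = {}
    for label, df in exposure_tables.items():
        protein = protein_of.get(label, label) if protein_of else label
        sig = df.loc[df["pval"] < p_threshold, "variant_id"]
        for vid in sig:
            hits.setdefault(vid, set()).add(protein)
    return {vid: len(prots) for vid, prots in hits.items()}


def pleiotropy_flagged_snps(counts: Mapping[str, int], max_proteins_per_snp: int = 5) -> set[str]:
    """Variants associated with strictly more than ``max_proteins_per_snp``
    proteins (a count of exactly the threshold is retained)."""
    return {vid for vid, c in counts.items() if c > max_proteins_per_snp}


def region_filters(
    records: pd.DataFrame,
    annotation: Mapping[str, object],
    config: FilterConfig,
    pleiotropy_flagged: Iterable[str] = (),
) -> pd.DataFrame:
    """Apply the marginal (panel-free) filters to one protein's exposure table.

    Returns a copy with a ``drop_reason`` column; surviving rows have an
    empty reason.  Filters are applied in cascade order and each dropped SNP
    is labelled with the first filter it failed.
    """
    for key in ("gene", "chrom", "gene_start"):
        if key not in annotation:
            raise ConfigurationError(f"gene annotation missing field {key!r}")
    df = records.copy().reset_index(drop=True)
    reason = np.array([""] * len(df), dtype=object)
    flagged = set(pleiotropy_flagged)

    def mark(fail: np.ndarray, label: str) -> None:
        fail = fail & (reason == "")
        reason[fail] = label

    mark((df["pval"] >= config.p_exposure_max).to_numpy(), "pvalue_dropped")
    cis = (df["chrom"].astype(str) == str(annotation["chrom"])) & (
        (df["pos"] - int(annotation["gene_start"])).abs() <= config.cis_window
    )
    mark(~cis.to_numpy(), "cis_dropped")
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    mark((maf < config.maf_min).to_numpy(), "maf_dropped")
    mhc_chrom, mhc_start, mhc_end = config.mhc
    in_mhc = (df["chrom"].astype(str) == str(mhc_chrom)) & df["pos"].between(mhc_start, mhc_end)
    mark(in_mhc.to_numpy(), "mhc_dropped")
    f_stat = per_snp_f(df["beta"].to_numpy(), df["se"].to_numpy())
    mark(f_stat < config.f_min, "weak_dropped")
    mark(df["variant_id"].isin(flagged).to_numpy(), "pleiotropy_dropped")

    out = df.copy()
    out["f_stat"] = f_stat
    out["drop_reason"] = reason
    return out


def harmonize(
    exposure: Mapping[str, object],
    outcome: Mapping[str, object],
    band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedPair:
    """Harmonize one variant's outcome record onto the exposure effect allele.

    Handles allele swaps (outcome reports the other allele: flip the sign of
    beta and take 1−eaf), strand flips (outcome reports opposite-strand
    letters), and palindromic A/T / C/G variants, which carry no strand
    information in their letters: outside the ambiguous exposure-frequency
    ``band`` they are aligned by allele frequency, inside it they are dropped.
    Irreconcilable allele sets are dropped with reason.
    """
    if str(exposure["variant_id"]) != str(outcome["variant_id"]):
        raise ValueError(
            f"harmonize called on different variants "
            f"({exposure['variant_id']!r} vs {outcome['variant_id']!r})"
        )
    ea_x, oa_x = str(exposure["ea"]), str(exposure["oa"])
    ea_y, oa_y = str(outcome["ea"]), str(outcome["oa"])
    beta_out = float(outcome["beta"])
    eaf_out = float(outcome["eaf"])
    eaf_exp = float(exposure["eaf"])
    flags: set[str] = set()

    palindromic = _COMPLEMENT.get(ea_x) == oa_x
    if palindromic:
        if {ea_y, oa_y} != {ea_x, oa_x}:
            flags.add("allele_mismatch_dropped")
        elif band[0] <= eaf_exp <= band[1]:
            flags.add("palindromic_dropped")
        else:
            if ea_y != ea_x:  # letters swapped relative to exposure
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                flags.add("flipped")
            # letters cannot resolve strand: align by frequency
            if (eaf_exp - 0.5) * (eaf_out - 0.5) < 0:
                beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                flags.symmetric_difference_update({"flipped"})
    else:
        if {ea_y, oa_y} == {ea_x, oa_x}:
            pass
        elif {_COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y)} == {ea_x, oa_x}:
            ea_y, oa_y = _COMPLEMENT[ea_y], _COMPLEMENT[oa_y]  # strand flip only
        else:
            flags.add("allele_mismatch_dropped")
        if "allele_mismatch_dropped" not in flags and ea_y != ea_x:
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            flags.add("flipped")

    beta_exp, se_exp = float(exposure["beta"]), float(exposure["se"])
    n_exp, n_out = int(exposure["n"]), int(outcome["n"])
    pair = HarmonizedPair(
        variant_id=str(exposure["variant_id"]),
        beta_exp=beta_exp,
        se_exp=se_exp,
        eaf_exp=eaf_exp,
        n_exp=n_exp,
        beta_out=beta_out,
        se_out=float(outcome["se"]),
        eaf_out=eaf_out,
        n_out=n_out,
        f_stat=float(per_snp_f(beta_exp, se_exp)),
        flags=flags,
        chrom=str(exposure.get("chrom", "")),
        pos=int(exposure.get("pos", 0)),
        pval_exp=float(exposure.get("pval", np.nan)),
    )
    if not pair.dropped:
        pair.r2_exp = float(snp_r2(beta_exp, se_exp, n_exp))
        pair.r2_out = float(snp_r2(pair.beta_out, pair.se_out, n_out))
    return pair


def _pairs_frame(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": p.variant_id, "chrom": p.chrom, "pos": p.pos,
            "beta_exp": p.beta_exp, "se_exp": p.se_exp, "eaf_exp": p.eaf_exp,
            "n_exp": p.n_exp, "pval_exp": p.pval_exp,
            "beta_out": p.beta_out, "se_out": p.se_out, "eaf_out": p.eaf_out,
            "n_out": p.n_out, "f_stat": p.f_stat,
            "r2_exp": p.r2_exp, "r2_out": p.r2_out,
            "flipped": "flipped" in p.flags,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def harmonize_tables(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    band: tuple[float, float] = (0.42, 0.58),
    variant_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Harmonize all shared variants of two summary tables.

    Returns ``(pairs, audit)``: surviving harmonized pairs and dropped
    variants (unmatched in the outcome, irreconcilable alleles, ambiguous
    palindromic).
    """
    out_by_id = {str(r["variant_id"]): r for _, r in outcome.iterrows()}
    rows = exposure
    if variant_ids is not None:
        rows = exposure[exposure["variant_id"].isin(set(map(str, variant_ids)))]
    pairs: list[HarmonizedPair] = []
    audit: list[dict[str, str]] = []
    for _, exp_row in rows.iterrows():
        vid = str(exp_row["variant_id"])
        out_row = out_by_id.get(vid)
        if out_row is None:
            audit.append({"variant_id": vid, "drop_reason": "unmatched_dropped"})
            continue
        pair = harmonize(exp_row, out_row, band)
        if pair.dropped:
            audit.append({"variant_id": vid, "drop_reason": pair.drop_reason})
        else:
            pairs.append(pair)
    return _pairs_frame(pairs), pd.DataFrame(audit, columns=["variant_id", "drop_reason"])


def ld_clump(
    candidates: pd.DataFrame,
    panel: ReferencePanel,
    r2_max: float = 0.1,
    p_column: str = "pval_exp",
) -> tuple[list[str], list[str]]:
    """Greedy LD clumping: repeatedly keep the most significant remaining
    candidate and discard every other candidate correlated with it at
    ``r² >= r2_max`` in the reference panel.

    Ties on p-value break by (chrom, pos, variant_id).  Returns
    ``(kept, dropped)`` variant ids, the kept list sorted by position.
    """
    if candidates.empty:
        return [], []
    for vid in candidates["variant_id"]:
        if str(vid) not in panel._index:
            raise ValueError(f"clump candidate {vid!r} absent from reference panel")
        if panel.monomorphic[panel._index[str(vid)]]:
            raise ValueError(f"clump candidate {vid!r} is monomorphic in the panel")
    order = candidates.sort_values(
        by=[p_column, "chrom", "pos", "variant_id"], kind="mergesort"
    )
    remaining = [
        (str(r["variant_id"]), str(r["chrom"]), int(r["pos"])) for _, r in order.iterrows()
    ]
    kept: list[tuple[str, str, int]] = []
    dropped: list[str] = []
    while remaining:
        top = remaining.pop(0)
        kept.append(top)
        still = []
        for cand in remaining:
            if panel.r2(top[0], cand[0]) >= r2_max:
                dropped.append(cand[0])
            else:
                still.append(cand)
        remaining = still
    kept.sort(key=lambda t: (t[1], t[2], t[0]))
    return [t[0] for t in kept], dropped


def build_instrument_set(
    protein: str,
    gene: str,
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    annotations: pd.DataFrame,
    panel: ReferencePanel,
    config: FilterConfig | None = None,
    pleiotropy_flagged: Iterable[str] = (),
) -> InstrumentSet:
    """Run the full selection cascade for one protein.

    The audit and the surviving pairs partition the candidate SNP list; the
    set is eligible for MR when ``len(pairs) >= config.min_ivs``.
    """
    config = config or FilterConfig()
    ann = annotations[annotations["gene"] == gene]
    if ann.empty:
        raise ConfigurationError(f"no gene annotation for {gene!r}")
    annotation = ann.iloc[0].to_dict()

    filtered = region_filters(exposure, annotation, config, pleiotropy_flagged)
    audit_rows = filtered.loc[filtered["drop_reason"] != "", ["variant_id", "drop_reason"]]
    survivors = filtered[filtered["drop_reason"] == ""]

    pairs_df, harm_audit = harmonize_tables(survivors, outcome, config.palindromic_eaf_band)
    audit_rows = pd.concat([audit_rows, harm_audit], ignore_index=True)

    keep_mask = []
    for _, p in pairs_df.iterrows():
        res = steiger_filter(p["r2_exp"], p["r2_out"], p["n_exp"], p["n_out"], config.steiger_p)
        keep_mask.append(res.keep)
    steiger_dropped = pairs_df.loc[[not k for k in keep_mask], "variant_id"]
    audit_rows = pd.concat(
        [audit_rows, pd.DataFrame({"variant_id": steiger_dropped, "drop_reason": "steiger_dropped"})],
        ignore_index=True,
    )
    pairs_df = pairs_df[keep_mask].reset_index(drop=True)

    if len(pairs_df):
        kept_ids, clump_dropped = ld_clump(pairs_df, panel, config.clump_r2)
        audit_rows = pd.concat(
            [audit_rows, pd.DataFrame({"variant_id": clump_dropped, "drop_reason": "clump_dropped"})],
            ignore_index=True,
        )
        pairs_df = (
            pairs_df[pairs_df["variant_id"].isin(kept_ids)]
            .sort_values(["chrom", "pos", "variant_id"])
            .reset_index(drop=True)
        )
    audit = audit_rows.reset_index(drop=True)
    return InstrumentSet(protein=protein, gene=gene, pairs=pairs_df, audit=audit, min_ivs=config.min_ivs)
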