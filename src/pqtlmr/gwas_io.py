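"""Readers and writers for GWAS summary statistics, LD reference panels,
gene annotations, gene sets (GMT) and result tables.

All tabular formats are headered, tab-separated text.  Genomic coordinates
are 1-based and intervals are inclusive at both ends throughout the package.

Summary-statistic tables use the canonical column names

    variant_id, chrom, pos, ea, oa, eaf, beta, se, pval, n

where ``ea`` is the effect allele (the allele whose per-copy effect ``beta``
reports) and ``oa`` the other allele.  A *dialect* — a mapping from canonical
to file-specific column names — lets exports with arbitrary headers be read
without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUMMARY_COLUMNS",
    "ReferencePanel",
    "GwasIOError",
    "SummaryStatError",
    "read_summary_stats",
    "write_summary_stats",
    "read_reference_panel",
    "write_reference_panel",
    "read_gene_annotations",
    "write_gene_annotations",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
]

#: canonical summary-statistic columns, in file order
SUMMARY_COLUMNS = ["variant_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

_VALID_ALLELE = frozenset("ACGT")

# tolerance for the |z| vs p consistency check: warn when the reported
# p-value differs from the two-sided normal p by more than 10% (as a ratio)
_P_CONSISTENCY_RATIO = 1.10


class GwasIOError(ValueError):
    """Malformed or inconsistent input file."""


class SummaryStatError(GwasIOError):
    """A summary-statistic record violates the data model."""


def _resolve_columns(columns: Sequence[str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical names to the file's actual column names."""
    dialect = dict(dialect or {})
    mapping = {}
    for canon in SUMMARY_COLUMNS:
        name = dialect.get(canon, canon)
        if name not in columns:
            raise GwasIOError(
                f"required column {canon!r} (file column {name!r}) not found; "
                f"available: {list(columns)}"
            )
        mapping[canon] = name
    return mapping


def read_summary_stats(path: str | Path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read one GWAS summary-statistics table.

    Parameters
    ----------
    path
        Headered TSV file.
    dialect
        Optional mapping from canonical column names (``SUMMARY_COLUMNS``)
        to the names used in the file, e.g. ``{"pval": "P", "ea": "A1"}``.

    Returns
    -------
    pandas.DataFrame
        Canonical columns, rows in file order.  Raises on duplicate variant
        ids, non-positive standard errors, p-values outside (0, 1], allele
        strings outside {A,C,G,T}+ or effect allele equal to other allele.
        A reported p-value inconsistent with ``2*Phi(-|beta/se|)`` by more
        than 10% only triggers a warning (files may carry exact t-based or
        higher-precision p-values).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = _resolve_columns(raw.columns, dialect)
    df = pd.DataFrame({canon: raw[actual] for canon, actual in cols.items()})

    for col in ("pos", "n"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            line = int(np.flatnonzero(bad.isna())[0]) + 2  # +1 header, +1 one-based
            raise GwasIOError(f"{path.name}: unparseable {col!r} near line {line}") from exc
    for col in ("eaf", "beta", "se", "pval"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna())[0]) + 2
            raise GwasIOError(f"{path.name}: unparseable {col!r} near line {line}")
        df[col] = vals.astype(float)
    df["chrom"] = df["chrom"].astype(str)
    df["variant_id"] = df["variant_id"].astype(str)
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()

    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise SummaryStatError(f"{path.name}: duplicated variant_id {dup.iloc[0]!r}")
    _validate_summary_frame(df, source=path.name)
    return df


def _validate_summary_frame(df: pd.DataFrame, source: str = "<frame>") -> None:
    def _fail(mask: np.ndarray, message: str) -> None:
        if np.any(mask):
            vid = df["variant_id"].iloc[int(np.flatnonzero(mask)[0])]
            raise SummaryStatError(f"{source}: {message} (first offender {vid!r})")

    ok_allele = df["ea"].map(lambda a: bool(a) and set(a) <= _VALID_ALLELE) & df["oa"].map(
        lambda a: bool(a) and set(a) <= _VALID_ALLELE
    )
    _fail(~ok_allele.to_numpy(), "alleles must be non-empty A/C/G/T strings")
    _fail((df["ea"] == df["oa"]).to_numpy(), "effect allele equals other allele")
    _fail((df["se"] <= 0).to_numpy(), "se must be > 0")
    _fail(((df["eaf"] < 0) | (df["eaf"] > 1)).to_numpy(), "eaf outside [0, 1]")
    _fail(((df["pval"] <= 0) | (df["pval"] > 1)).to_numpy(), "pval outside (0, 1]")
    _fail((df["n"] <= 0).to_numpy(), "n must be positive")

    with np.errstate(divide="ignore"):
        p_norm = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    p_norm = np.clip(p_norm, 1e-300, 1.0)
    p_obs = np.clip(df["pval"].to_numpy(), 1e-300, 1.0)
    ratio = np.maximum(p_norm / p_obs, p_obs / p_norm)
    bad = ratio > _P_CONSISTENCY_RATIO
    if np.any(bad):
        ids = df["variant_id"].to_numpy()[bad][:3]
        warnings.warn(
            f"{source}: {int(bad.sum())} record(s) have p-values inconsistent with "
            f"|beta/se| under the normal approximation (e.g. {', '.join(ids)})",
            stacklevel=3,
        )


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical summary-statistics table (full float precision)."""
    df.to_csv(path, sep="\t", index=False, columns=SUMMARY_COLUMNS, float_format="%.17g")


@dataclass
class ReferencePanel:
    """Variant-by-sample genotype dosages used only for pairwise LD (r²).

    ``dosages`` has one row per variant in ``variant_ids`` order; values lie
    in [0, 2].  Monomorphic variants (zero dosage variance) are flagged and
    must not be used for r².
    """

    variant_ids: list[str]
    dosages: np.ndarray
    monomorphic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.variant_ids):
            raise GwasIOError("panel row count must equal number of variant_ids")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise GwasIOError("dosage values must lie in [0, 2]")
        if self.monomorphic is None:
            self.monomorphic = self.dosages.std(axis=1) == 0
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def sample_count(self) -> int:
        return self.dosages.shape[1]

    def row(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[self._index[variant_id]]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not present in reference panel") from None

    def r2(self, a: str, b: str) -> float:
        """Squared Pearson correlation between two variants' dosages."""
        for v in (a, b):
            if self.monomorphic[self._index[v]]:
                raise GwasIOError(f"variant {v!r} is monomorphic in the panel; r² undefined")
        r = np.corrcoef(self.row(a), self.row(b))[0, 1]
        return float(r * r)

    def subset(self, variant_ids: Sequence[str]) -> "ReferencePanel":
        idx = [self._index[v] for v in variant_ids]
        return ReferencePanel(list(variant_ids), self.dosages[idx], self.monomorphic[idx].copy())


def read_reference_panel(path: str | Path) -> ReferencePanel:
    """Read a reference panel: headered TSV, first column ``variant_id``,
    remaining columns one dosage per sample."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise GwasIOError(f"{path.name}: panel needs a variant_id column plus ≥1 sample")
    ids = df.iloc[:, 0].astype(str).tolist()
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    return ReferencePanel(ids, dosages)


def write_reference_panel(panel: ReferencePanel, path: str | Path) -> None:
    cols = [f"s{i}" for i in range(panel.sample_count)]
    out = pd.DataFrame(panel.dosages, columns=cols)
    out.insert(0, "variant_id", panel.variant_ids)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_annotations(path: str | Path) -> pd.DataFrame:
    """Read a 3-column gene annotation table: gene, chrom, gene_start (1-based bp)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    for col in ("gene", "chrom", "gene_start"):
        if col not in df.columns:
            raise GwasIOError(f"{path.name}: missing column {col!r}")
    df["gene_start"] = df["gene_start"].astype(np.int64)
    if (df["gene_start"] < 1).any():
        raise GwasIOError(f"{path.name}: gene_start must be ≥ 1")
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise GwasIOError(f"{path.name}: duplicated gene symbol {dup.iloc[0]!r}")
    return df[["gene", "chrom", "gene_start"]]


def write_gene_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=["gene", "chrom", "gene_start"])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: term, description, then ≥0 genes, tab-separated.

    Genes are de-duplicated per term; term order is preserved (dicts are
    insertion-ordered).
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GwasIOError(f"{path.name}: line {lineno} has fewer than 3 fields")
            term = fields[0]
            terms[term] = {g for g in fields[2:] if g}
    return terms


def write_gmt(terms: Mapping[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            fh.write("\t".join([term, description, *sorted(genes)]) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic result table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table (instrument sets, MR results, screen results)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
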