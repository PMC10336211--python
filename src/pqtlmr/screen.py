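"""Proteome-wide orchestration: discovery, replication and cross-trait summaries.

Discovery applies Bonferroni control over the number of tested exposures
(aptamer-level tests by default).  A discovered protein *replicates* on a
secondary outcome when the secondary IVW p-value is nominally significant
(p < 0.05) and the effect direction is consistent with the discovery effect
under a per-outcome sign convention: BMD-like outcomes expect the same sign,
fracture-like outcomes the opposite sign (higher BMD, lower fracture risk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gwas_io import ReferencePanel
from .instruments import (
    FilterConfig,
    build_instrument_set,
    pleiotropy_counts,
    pleiotropy_flagged_snps,
)
from .mr_core import MRResult, results_table, run_mr

__all__ = [
    "ScreenResult",
    "bonferroni_alpha",
    "discover",
    "replicate",
    "cross_trait_correlation",
    "run_screen",
]


@dataclass
class ScreenResult:
    """Discovery table plus (optional) replication annotations."""

    results: pd.DataFrame           # one row per protein: MRResult fields + discovered/direction
    bonferroni_alpha: float
    n_tests: int
    replication: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def discovered(self) -> list[str]:
        return self.results.loc[self.results["discovered"], "protein"].tolist()


def bonferroni_alpha(alpha_family: float, n_tests: int) -> float:
    """Per-test significance threshold controlling the family-wise error."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha_family < 1:
        raise ValueError("alpha_family must lie in (0, 1)")
    return alpha_family / n_tests


def discover(
    results: Sequence[MRResult] | pd.DataFrame,
    alpha_family: float = 0.05,
    n_tests: int | None = None,
) -> ScreenResult:
    """Flag proteins whose IVW p-value passes the Bonferroni threshold and
    label each discovery by effect direction.

    ``n_tests`` defaults to the number of tested exposures (aptamer-level
    correction); pass the number explicitly to correct over a larger family.
    """
    df = results if isinstance(results, pd.DataFrame) else results_table(list(results))
    df = df.copy()
    m = n_tests if n_tests is not None else len(df)
    if len(df) == 0:
        df["discovered"] = pd.Series(dtype=bool)
        df["direction"] = pd.Series(dtype=str)
        return ScreenResult(df, np.nan if m == 0 else bonferroni_alpha(alpha_family, max(m, 1)), m)
    alpha = bonferroni_alpha(alpha_family, m)
    df["discovered"] = df["p_ivw"] < alpha
    df["direction"] = np.where(df["beta_ivw"] >= 0, "positive", "negative")
    return ScreenResult(df, alpha, m)


def replicate(
    screen: ScreenResult,
    secondary: Mapping[str, Sequence[MRResult] | pd.DataFrame],
    direction_map: Mapping[str, int],
    alpha: float = 0.05,
) -> ScreenResult:
    """Replication of discovered proteins on secondary outcomes.

    ``direction_map`` gives the expected sign relation per outcome: +1 when
    the secondary effect should share the discovery sign (BMD-like traits),
    −1 when it should oppose it (fracture).  A protein replicates on an
    outcome when p < ``alpha`` and the sign relation holds; missing secondary
    results count as non-replicated for that outcome.
    """
    disc = screen.results[screen.results["discovered"]][["protein", "beta_ivw"]]
    rows = []
    for outcome, res in secondary.items():
        if outcome not in direction_map:
            raise ValueError(f"no direction convention for outcome {outcome!r}")
        expect = int(direction_map[outcome])
        if expect not in (-1, 1):
            raise ValueError("direction_map values must be +1 or -1")
        tab = res if isinstance(res, pd.DataFrame) else results_table(list(res))
        tab = tab.set_index("protein")
        for _, row in disc.iterrows():
            protein = row["protein"]
            if protein not in tab.index:
                rows.append(
                    {"protein": protein, "outcome": outcome, "beta": np.nan,
                     "p": np.nan, "replicated": False, "missing": True}
                )
                continue
            sec = tab.loc[protein]
            consistent = np.sign(sec["beta_ivw"]) * np.sign(row["beta_ivw"]) == expect
            rows.append(
                {
                    "protein": protein,
                    "outcome": outcome,
                    "beta": float(sec["beta_ivw"]),
                    "p": float(sec["p_ivw"]),
                    "replicated": bool(sec["p_ivw"] < alpha and consistent),
                    "missing": False,
                }
            )
    replication = pd.DataFrame(
        rows, columns=["protein", "outcome", "beta", "p", "replicated", "missing"]
    )
    results = screen.results.copy()
    if len(replication):
        any_rep = replication.groupby("protein")["replicated"].any()
        results["replicated_any"] = (
            results["protein"].map(any_rep).astype("boolean").fillna(False).astype(bool)
        )
        all_consistent = replication[~replication["missing"]].groupby("protein")["replicated"].all()
        results["direction_consistent"] = (
            results["protein"].map(all_consistent).astype("boolean").fillna(False).astype(bool)
        )
    else:
        results["replicated_any"] = False
        results["direction_consistent"] = False
    return ScreenResult(results, screen.bonferroni_alpha, screen.n_tests, replication)


def cross_trait_correlation(
    effects: Mapping[str, Mapping[str, float] | pd.Series],
    proteins: Sequence[str],
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-protein effect vectors across
    outcomes, restricted to ``proteins`` (typically the discovered set) and
    pairwise-complete; entries with fewer than ``min_shared`` shared proteins
    are NaN."""
    outcomes = list(effects)
    series = {o: pd.Series(dict(effects[o])).reindex(proteins) for o in outcomes}
    mat = pd.DataFrame(np.nan, index=outcomes, columns=outcomes, dtype=float)
    for i, a in enumerate(outcomes):
        for j, b in enumerate(outcomes):
            if j < i:
                continue
            both = pd.concat([series[a], series[b]], axis=1).dropna()
            if len(both) < min_shared:
                continue
            r = float(np.corrcoef(both.iloc[:, 0], both.iloc[:, 1])[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = r
    return mat


def run_screen(
    exposures: Mapping[str, pd.DataFrame],
    outcome: pd.DataFrame,
    panel: ReferencePanel,
    annotations: pd.DataFrame,
    gene_of: Mapping[str, str] | None = None,
    filter_config: FilterConfig | None = None,
    alpha_family: float = 0.05,
    n_tests: int | None = None,
    outcome_label: str = "outcome",
    n_boot: int = 1000,
    seed: int = 7_919,
) -> tuple[ScreenResult, list[MRResult], dict[str, int]]:
    """Full pipeline for one outcome: pleiotropy counting across all
    exposures, per-protein instrument selection, MR on every eligible set,
    Bonferroni discovery.

    ``gene_of`` maps each exposure label to its coding gene (defaults to a
    ``P<i>`` → ``GENE<i>`` convention matching the simulator).  Returns the
    screen result, the per-protein MR results and a per-stage count log.
    Bonferroni correction is over all exposures attempted (tested or not),
    mirroring an aptamer-level correction.
    """
    cfg = filter_config or FilterConfig()
    counts = pleiotropy_counts(exposures, cfg.p_exposure_max)
    flagged = pleiotropy_flagged_snps(counts, cfg.max_proteins_per_snp)
    results: list[MRResult] = []
    log = {"proteins": len(exposures), "eligible": 0, "ineligible": 0}
    for protein, exp_df in exposures.items():
        gene = gene_of[protein] if gene_of else protein.replace("P", "GENE", 1)
        iset = build_instrument_set(
            protein, gene, exp_df, outcome, annotations, panel, cfg, flagged
        )
        if not iset.eligible:
            log["ineligible"] += 1
            continue
        log["eligible"] += 1
        results.append(run_mr(iset, outcome_label, n_boot=n_boot, seed=seed))
    m = n_tests if n_tests is not None else len(exposures)
    screen = discover(results, alpha_family, n_tests=m)
    log["discovered"] = len(screen.discovered)
    return screen, results, log
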