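"""Over-representation analysis of discovered genes against gene sets.

One-sided hypergeometric tests (is the overlap between the hit list and a
term's gene set larger than chance within a stated gene universe?) with
Benjamini–Hochberg adjustment across the tested terms, plus a trivial
druggability-tier join.

The universe should normally be the coding genes of *all* proteins tested in
the MR screen, not the whole genome: the assay panel defines the sampling
frame and using it removes ascertainment bias from the enrichment.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_enrich", "druggability_join"]

ENRICHMENT_COLUMNS = [
    "term", "term_size", "hit_overlap", "universe_size", "hits_size", "p", "p_adjust",
]


def hypergeom_enrich(
    hits: Iterable[str],
    universe: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    min_term: int = 3,
    max_term: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` within ``universe``.

    Every term set is intersected with the universe first; terms whose
    intersected size falls outside [``min_term``, ``max_term``] are not
    tested.  ``p = P(X >= overlap)`` under
    hypergeometric(universe_size, term_size, hits_size); BH step-up adjusts
    over the tested terms only.  Rows are sorted by raw p (ties by term id).
    """
    hits = set(hits)
    universe = set(universe)
    stray = hits - universe
    if stray:
        raise ValueError(f"hits not contained in universe: {sorted(stray)[:10]}")
    rows = []
    for term, genes in terms.items():
        tset = set(genes) & universe
        if not min_term <= len(tset) <= max_term:
            continue
        overlap = len(tset & hits)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(tset), len(hits)))
        rows.append(
            {
                "term": term,
                "term_size": len(tset),
                "hit_overlap": overlap,
                "universe_size": len(universe),
                "hits_size": len(hits),
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if len(df):
        df["p_adjust"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["p_adjust"] = pd.Series(dtype=float)
    return df


def druggability_join(genes: Iterable[str], tiers: Mapping[str, str] | pd.DataFrame) -> pd.DataFrame:
    """Left-join a user-supplied gene → druggability-tier table onto the
    discovered genes; genes absent from the table are ``unclassified``."""
    if isinstance(tiers, pd.DataFrame):
        tiers = dict(zip(tiers["gene"].astype(str), tiers["tier"].astype(str)))
    genes = list(genes)
    return pd.DataFrame(
        {"gene": genes, "tier": [str(tiers.get(g, "unclassified")) for g in genes]}
    )
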