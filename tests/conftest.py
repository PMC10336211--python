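import numpy as np
import pandas as pd
import pytest

from pqtlmr.gwas_io import SUMMARY_COLUMNS, ReferencePanel
from pqtlmr.simulate import SimConfig, simulate_region


def make_stats(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical summary-stat frame from partial row dicts."""
    defaults = {
        "chrom": "1", "pos": 1_000_000, "ea": "A", "oa": "G", "eaf": 0.3,
        "beta": 0.1, "se": 0.02, "n": 10_000,
    }
    out = []
    for i, row in enumerate(rows):
        rec = {**defaults, "variant_id": f"rs{i}", **row}
        if "pval" not in rec:
            from scipy.stats import norm
            rec["pval"] = float(max(2 * norm.sf(abs(rec["beta"] / rec["se"])), 1e-300))
        out.append(rec)
    return pd.DataFrame(out)[SUMMARY_COLUMNS]


@pytest.fixture
def small_stats() -> pd.DataFrame:
    return make_stats(
        [
            {"variant_id": "rs1", "pos": 100, "beta": 0.5, "se": 0.05},
            {"variant_id": "rs2", "pos": 200, "beta": -0.2, "se": 0.04, "ea": "T", "oa": "C"},
            {"variant_id": "rs3", "pos": 300, "beta": 0.01, "se": 0.03},
        ]
    )


@pytest.fixture
def tiny_panel() -> ReferencePanel:
    rng = np.random.default_rng(0)
    dosages = rng.integers(0, 3, size=(5, 100)).astype(float)
    return ReferencePanel([f"rs{i}" for i in range(5)], dosages)


@pytest.fixture(scope="session")
def clean_region():
    """One LD-free region with 3 strong causal SNPs, θ = 0.3."""
    cfg = SimConfig(
        seed=11, snps_per_region=3, n_causal_snps=3, ld_rho=0.0,
        n_exposure=20_000, n_outcome=20_000, n_panel=500,
        causal_effect=0.3, palindromic_fraction=0.0,
        gamma_dist="fixed", gamma_sd=0.2,
    )
    return simulate_region(cfg, 0)
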