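"""Frozen Monte-Carlo study conditions for validating the pipeline.

Each function runs one pre-specified simulation study against the package's
own estimators and returns the summary numbers.  The generating conditions
(sample sizes, instrument counts, effect and pleiotropy sizes) are part of
the study design and are documented in the methods note; they are shared by
the test suite and the acceptance script so both measure the same thing.

Estimator-level studies (calibration, recovery, robustness, directionality)
use the ground-truth instruments of each simulated region — LD-free regions
whose causal SNPs are known — so they benchmark the estimators themselves;
the end-to-end study runs the full selection + MR + discovery pipeline with
no access to the truth until scoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .instruments import harmonize_tables, steiger_filter
from .mr_core import egger, ivw, steiger_direction, weighted_median
from .screen import run_screen
from .simulate import RegionData, SimConfig, simulate_region, simulate_reverse, simulate_screen

__all__ = [
    "truth_pairs",
    "null_calibration",
    "parameter_recovery",
    "weighted_median_robustness",
    "egger_intercept_power",
    "directionality",
    "end_to_end_screen",
]

_MOD = 2**31 - 1


def _rep_seed(base: int, tag: int, rep: int) -> int:
    """Deterministic per-replicate seed, decorrelated across scenarios."""
    return int((base * 1_000_003 + tag * 7_919 + rep) % _MOD)


def truth_pairs(region: RegionData) -> pd.DataFrame:
    """Harmonized exposure/outcome pairs for a region's ground-truth
    instruments (bypasses the selection cascade)."""
    pairs, _ = harmonize_tables(
        region.exposure, region.outcome, variant_ids=list(region.truth.causal_snps)
    )
    return pairs


def null_calibration(
    seed: int,
    n_reps_rejection: int = 200,
    n_reps_q: int = 500,
    pleiotropy: bool = False,
) -> dict[str, float]:
    """Type-I error and Cochran-Q calibration of IVW under the null.

    θ = 0, three independent instruments, 5,000 individuals per cohort.
    With ``pleiotropy=True`` the null holds on average but 40% of the
    instruments carry balanced direct effects (heterogeneity without bias).
    Returns the rejection rate at α = 0.05 over the first
    ``n_reps_rejection`` replicates and the mean Q (df = 2) over all
    ``n_reps_q``.
    """
    n_reps = max(n_reps_rejection, n_reps_q)
    rejected = 0
    q_stats = []
    for rep in range(n_reps):
        cfg = SimConfig(
            seed=_rep_seed(seed, 3, rep), snps_per_region=3, n_causal_snps=3,
            ld_rho=0.0, n_exposure=5_000, n_outcome=5_000, n_panel=200,
            causal_effect=0.0, palindromic_fraction=0.0,
            pleiotropy_mode="balanced" if pleiotropy else "none",
            pleiotropy_sd=0.25 if pleiotropy else 0.05,
            invalid_fraction=0.4 if pleiotropy else 0.0,
            gamma_dist="fixed" if pleiotropy else "halfnormal",
            gamma_sd=0.25 if pleiotropy else 0.15,
        )
        res = ivw(truth_pairs(simulate_region(cfg, 0)))
        if rep < n_reps_rejection:
            rejected += res.p < 0.05
        if rep < n_reps_q:
            q_stats.append(res.q_stat)
    return {
        "rejection_rate": rejected / n_reps_rejection,
        "q_mean": float(np.mean(q_stats)),
        "q_df": 2.0,
        "n_rejection": float(n_reps_rejection),
        "n_q": float(n_reps_q),
    }


def parameter_recovery(seed: int, n_reps: int = 100, theta: float = 0.3) -> dict[str, float]:
    """Median IVW / MR-Egger / weighted-median estimates under a clean causal
    model: θ = 0.3, three valid instruments of graded strength
    (γ = 0.1, 0.2, 0.3 — MR-Egger needs strength dispersion), 20,000 per
    cohort."""
    est = {"ivw": [], "egger": [], "wm": []}
    for rep in range(n_reps):
        cfg = SimConfig(
            seed=_rep_seed(seed, 4, rep), snps_per_region=3, n_causal_snps=3,
            ld_rho=0.0, n_exposure=20_000, n_outcome=20_000, n_panel=200,
            causal_effect=theta, palindromic_fraction=0.0,
            gamma_dist="ladder", gamma_sd=0.3,
        )
        pairs = truth_pairs(simulate_region(cfg, 0))
        est["ivw"].append(ivw(pairs).beta)
        est["egger"].append(egger(pairs).slope)
        est["wm"].append(weighted_median(pairs, n_boot=200, seed=rep).beta)
    return {
        "theta_true": theta,
        "ivw_median": float(np.median(est["ivw"])),
        "egger_median": float(np.median(est["egger"])),
        "wm_median": float(np.median(est["wm"])),
        "n_reps": float(n_reps),
    }


def weighted_median_robustness(seed: int, n_reps: int = 100, theta: float = 0.3) -> dict[str, float]:
    """Bias of IVW versus the weighted median when 40% of ten equal-strength
    instruments carry directional pleiotropy (α mean = SD = 0.25), with
    5,000 individuals per cohort.

    The valid instruments hold 60% of the weight, so the weighted median
    should stay near θ while IVW absorbs the directional bias.
    """
    iv_est, wm_est = [], []
    for rep in range(n_reps):
        cfg = SimConfig(
            seed=_rep_seed(seed, 5, rep), snps_per_region=10, n_causal_snps=10,
            ld_rho=0.0, n_exposure=5_000, n_outcome=5_000, n_panel=200,
            causal_effect=theta, gamma_dist="fixed", gamma_sd=0.25,
            pleiotropy_mode="directional", pleiotropy_sd=0.25,
            invalid_fraction=0.4, palindromic_fraction=0.0,
        )
        pairs = truth_pairs(simulate_region(cfg, 0))
        iv_est.append(ivw(pairs).beta)
        wm_est.append(weighted_median(pairs, n_boot=200, seed=rep).beta)
    ivw_bias = abs(float(np.mean(iv_est)) - theta)
    wm_bias = abs(float(np.mean(wm_est)) - theta)
    return {
        "ivw_bias": ivw_bias,
        "wm_bias": wm_bias,
        "wm_bias_over_ivw_bias": wm_bias / ivw_bias,
        "n_reps": float(n_reps),
    }


def egger_intercept_power(seed: int, n_reps: int = 100, theta: float = 0.3) -> dict[str, float]:
    """Rejection rate of the MR-Egger intercept test (α = 0.05) when every
    one of 30 instruments has a directional direct effect
    (α_j ~ N(0.05, 0.05²)), 20,000 per cohort."""
    hits = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            seed=_rep_seed(seed, 6, rep), snps_per_region=30, n_causal_snps=30,
            ld_rho=0.0, n_exposure=20_000, n_outcome=20_000, n_panel=200,
            causal_effect=theta, gamma_sd=0.2,
            pleiotropy_mode="directional", pleiotropy_sd=0.05,
            invalid_fraction=1.0, palindromic_fraction=0.0,
        )
        pairs = truth_pairs(simulate_region(cfg, 0))
        hits += egger(pairs).p_intercept < 0.05
    return {"intercept_rejection_rate": hits / n_reps, "n_reps": float(n_reps)}


def directionality(seed: int, n_reps_forward: int = 100, n_reps_reverse: int = 50) -> dict[str, float]:
    """Steiger behaviour on forward- and reverse-causation simulations.

    Forward: θ = 0.3, exposure n = 10,000, outcome n = 20,000 — the set-level
    direction should be "forward" with one-sided p < 0.05.  Reverse: the
    SNPs act on the outcome and the protein is downstream
    (reverse_effect = 0.5) — per-SNP Steiger filtering should drop the
    candidates and the set-level direction should be "reverse".
    """
    fwd_ok = 0
    for rep in range(n_reps_forward):
        cfg = SimConfig(
            seed=_rep_seed(seed, 7, rep), snps_per_region=3, n_causal_snps=3,
            ld_rho=0.0, n_exposure=10_000, n_outcome=20_000, n_panel=200,
            causal_effect=0.3, palindromic_fraction=0.0,
            gamma_dist="fixed", gamma_sd=0.15,
        )
        d = steiger_direction(truth_pairs(simulate_region(cfg, 0)))
        fwd_ok += d.direction == "forward" and d.p < 0.05
    dropped = 0
    total = 0
    rev_direction = 0
    for rep in range(n_reps_reverse):
        cfg = SimConfig(
            seed=_rep_seed(seed, 8, rep), snps_per_region=5, n_causal_snps=5,
            ld_rho=0.0, n_exposure=10_000, n_outcome=20_000, n_panel=200,
            reverse_effect=0.5, palindromic_fraction=0.0,
            gamma_dist="fixed", gamma_sd=0.15,
        )
        pairs = truth_pairs(simulate_reverse(cfg, 0))
        for _, p in pairs.iterrows():
            total += 1
            if not steiger_filter(p["r2_exp"], p["r2_out"], p["n_exp"], p["n_out"]).keep:
                dropped += 1
        rev_direction += steiger_direction(pairs).direction == "reverse"
    return {
        "forward_rate": fwd_ok / n_reps_forward,
        "reverse_drop_fraction": dropped / total,
        "reverse_direction_rate": rev_direction / n_reps_reverse,
        "n_forward": float(n_reps_forward),
        "n_reverse": float(n_reps_reverse),
    }


def screen_config(seed: int, causal_effect: float = 0.3, n_cohort: int = 20_000) -> SimConfig:
    """Generating conditions of the end-to-end screen study: five
    equal-strength, evenly spaced causal cis-SNPs per protein (γ = 0.15),
    moderate LD (ld_rho = 0.4) so clumping is non-trivial yet the kept
    instruments are effectively independent."""
    return SimConfig(
        seed=seed % _MOD, snps_per_region=30, n_causal_snps=5,
        gamma_dist="fixed", gamma_sd=0.15, ld_rho=0.4,
        causal_snp_placement="spaced", n_exposure=n_cohort,
        n_outcome=n_cohort, n_panel=2_000, causal_effect=causal_effect,
    )


def end_to_end_screen(seed: int, n_null: int = 20, n_causal: int = 5) -> dict[str, float]:
    """Full pipeline on a simulated screen: simulate → select → MR →
    Bonferroni discovery, scored against the planted truth."""
    data = simulate_screen(screen_config(seed), n_null=n_null, n_causal=n_causal)
    result, _, log = run_screen(
        data.exposures, data.outcome, data.panel, data.annotations,
        n_boot=200, seed=seed % _MOD,
    )
    causal = {t.protein for t in data.truths if t.theta_true != 0}
    discovered = set(result.discovered)
    sensitivity = len(discovered & causal) / len(causal) if causal else float("nan")
    return {
        "sensitivity": sensitivity,
        "false_discoveries": float(len(discovered - causal)),
        "n_proteins": float(n_null + n_causal),
        "n_eligible": float(log["eligible"]),
        "bonferroni_alpha": float(result.bonferroni_alpha),
    }
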