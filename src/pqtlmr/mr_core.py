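"""Two-sample MR estimators and sensitivity statistics for one instrument set.

Implements, on a table of harmonized exposure/outcome pairs:

* per-variant Wald ratios with first-order delta-method standard errors;
* inverse-variance-weighted (IVW) estimation as weighted regression of the
  outcome effects on the exposure effects through the origin (weights
  1/se_out²), with *multiplicative* random effects — the standard error is
  inflated, never deflated, by the residual scale sqrt(Q/(k−1));
* MR-Egger regression (weighted, with intercept), whose intercept estimates
  average directional pleiotropy; inference on t with k−2 df;
* the Bowden-style weighted median with a parametric-bootstrap standard
  error;
* Cochran's Q heterogeneity statistic (from the fixed-effect fit) and the
  Steiger directionality test comparing total variance explained in
  exposure versus outcome.

Pair tables are pandas DataFrames with (at least) the columns
``beta_exp, se_exp, beta_out, se_out`` plus ``r2_exp, r2_out, n_exp, n_out``
for directionality, as produced by :mod:`pqtlmr.instruments`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import InstrumentSet

__all__ = [
    "WaldEstimate",
    "MRResult",
    "wald_ratio",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "steiger_direction",
    "run_mr",
    "results_table",
]


class WaldEstimate(NamedTuple):
    """Per-variant causal estimate: ratio = beta_out/beta_exp with
    first-order SE se_out/|beta_exp| and inverse-variance weight."""

    variant_id: str
    ratio: float
    se_ratio: float
    weight: float


class IVWResult(NamedTuple):
    beta: float
    se: float
    p: float
    q_stat: float
    q_p: float
    sigma_scale: float


class EggerResult(NamedTuple):
    slope: float
    se_slope: float
    p_slope: float
    intercept: float
    se_intercept: float
    p_intercept: float


class WeightedMedianResult(NamedTuple):
    beta: float
    se: float
    p: float


class SteigerDirection(NamedTuple):
    direction: str  # "forward" | "reverse"
    p: float


@dataclass
class MRResult:
    """All estimates and sensitivity statistics for one protein-outcome pair."""

    protein: str
    outcome: str
    n_ivs: int
    beta_ivw: float
    se_ivw: float
    p_ivw: float
    beta_egger: float
    se_egger: float
    p_egger: float
    egger_intercept: float
    se_intercept: float
    p_intercept: float
    beta_wm: float
    se_wm: float
    p_wm: float
    q_stat: float
    q_df: int
    q_p: float
    steiger_direction: str
    steiger_p: float
    sigma_scale: float

    def as_dict(self) -> dict:
        return asdict(self)


def _columns(pairs: pd.DataFrame) -> tuple[np.ndarray, ...]:
    return (
        pairs["beta_exp"].to_numpy(float),
        pairs["se_exp"].to_numpy(float),
        pairs["beta_out"].to_numpy(float),
        pairs["se_out"].to_numpy(float),
    )


def wald_ratio(beta_exp: float, beta_out: float, se_out: float, variant_id: str = "") -> WaldEstimate:
    """Single-variant Wald ratio with first-order delta-method SE."""
    if beta_exp == 0:
        raise ValueError(f"degenerate instrument {variant_id!r}: beta_exp = 0")
    ratio = beta_out / beta_exp
    se_ratio = se_out / abs(beta_exp)
    return WaldEstimate(variant_id, float(ratio), float(se_ratio), float(1.0 / se_ratio**2))


def wald_ratios(pairs: pd.DataFrame) -> pd.DataFrame:
    """Wald ratios for every pair, for forest-style reporting."""
    bx, _, by, sy = _columns(pairs)
    if np.any(bx == 0):
        bad = pairs["variant_id"].to_numpy()[bx == 0][0]
        raise ValueError(f"degenerate instrument {bad!r}: beta_exp = 0")
    ratio = by / bx
    se = sy / np.abs(bx)
    return pd.DataFrame(
        {
            "variant_id": pairs["variant_id"],
            "ratio": ratio,
            "se_ratio": se,
            "weight": 1.0 / se**2,
        }
    )


def ivw(pairs: pd.DataFrame) -> IVWResult:
    """Random-effects IVW estimate.

    Weighted regression of beta_out on beta_exp through the origin with
    weights 1/se_out² (identical to the inverse-variance meta-analysis of
    first-order Wald ratios).  Cochran's Q comes from the fixed-effect fit;
    the SE is then inflated by ``sigma_scale = max(1, sqrt(Q/(k−1)))``
    (multiplicative random effects) and the p-value is two-sided normal.
    """
    bx, _, by, sy = _columns(pairs)
    k = len(bx)
    if k < 2:
        raise ValueError("IVW requires at least 2 instruments")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    if sxx <= 0:
        raise ValueError("all exposure effects are zero")
    beta = float(np.sum(w * bx * by) / sxx)
    se_fixed = float(np.sqrt(1.0 / sxx))
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))
    sigma_scale = max(1.0, float(np.sqrt(q / (k - 1))))
    se = se_fixed * sigma_scale
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta) / se), np.finfo(float).tiny, 1.0))
    return IVWResult(beta, se, p, q, q_p, sigma_scale)


def egger(pairs: pd.DataFrame) -> EggerResult:
    """MR-Egger regression: weighted regression of beta_out on beta_exp with
    a free intercept, after orienting every pair to beta_exp >= 0.

    SEs use the larger of the residual scale and 1 (never deflated);
    p-values come from t with k−2 df.
    """
    bx, _, by, sy = _columns(pairs)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = by * sw
    xtx = Xw.T @ Xw
    coef = np.linalg.solve(xtx, Xw.T @ yw)
    resid = yw - Xw @ coef
    sigma2 = float(resid @ resid) / (k - 2)
    scale = max(1.0, sigma2)
    cov = np.linalg.inv(xtx) * scale
    se = np.sqrt(np.diag(cov))
    tvals = coef / se
    pvals = np.clip(2.0 * stats.t.sf(np.abs(tvals), df=k - 2), np.finfo(float).tiny, 1.0)
    return EggerResult(
        slope=float(coef[1]), se_slope=float(se[1]), p_slope=float(pvals[1]),
        intercept=float(coef[0]), se_intercept=float(se[0]), p_intercept=float(pvals[0]),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Bowden-style weighted median: linear interpolation of the weighted
    empirical quantile function at 0.5."""
    order = np.argsort(ratios, kind="mergesort")
    b = ratios[order]
    w = weights[order]
    s = np.cumsum(w) - 0.5 * w
    s = s / np.sum(w)
    if s[0] >= 0.5:
        return float(b[0])
    if s[-1] <= 0.5:
        return float(b[-1])
    j = int(np.searchsorted(s, 0.5, side="right")) - 1
    if s[j] == 0.5:
        return float(b[j])
    frac = (0.5 - s[j]) / (s[j + 1] - s[j])
    return float(b[j] + frac * (b[j + 1] - b[j]))


def weighted_median(pairs: pd.DataFrame, n_boot: int = 1000, seed: int = 7_919) -> WeightedMedianResult:
    """Weighted-median causal estimate (consistent while valid instruments
    hold >50% of the weight), with a seeded parametric-bootstrap SE.

    Each bootstrap draw perturbs beta_exp and beta_out by their standard
    errors and recomputes the weighted median; the SE is the standard
    deviation across draws and the p-value is two-sided normal.
    """
    bx, sx, by, sy = _columns(pairs)
    if len(bx) < 3:
        raise ValueError("weighted median requires at least 3 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    ratios = by / bx
    se_ratio = sy / np.abs(bx)
    weights = 1.0 / se_ratio**2
    if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
        raise ValueError("nonpositive or non-finite weights")
    beta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = bx + sx * rng.standard_normal(len(bx))
        bys = by + sy * rng.standard_normal(len(by))
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        r = bys / bxs
        wgt = (np.abs(bxs) / sy) ** 2
        boots[i] = _weighted_median(r, wgt)
    se = float(np.std(boots, ddof=1))
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta) / se), np.finfo(float).tiny, 1.0))
    return WeightedMedianResult(float(beta), se, p)


def steiger_direction(pairs: pd.DataFrame) -> SteigerDirection:
    """Causal direction over the whole instrument set.

    Compares the total variance explained in exposure versus outcome
    (summed per-SNP r², capped at 1) through the two-sample Fisher-z
    statistic; ``forward`` iff the instruments explain more exposure
    variance.  One-sided p-value for the reported direction.
    """
    if pairs.empty:
        raise ValueError("steiger_direction needs a non-empty instrument set")
    r2x = float(np.clip(pairs["r2_exp"].sum(), 0.0, 1.0 - 1e-12))
    r2y = float(np.clip(pairs["r2_out"].sum(), 0.0, 1.0 - 1e-12))
    n_exp = float(np.median(pairs["n_exp"]))
    n_out = float(np.median(pairs["n_out"]))
    z = (np.arctanh(np.sqrt(r2x)) - np.arctanh(np.sqrt(r2y))) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    direction = "forward" if r2x > r2y else "reverse"
    p = float(stats.norm.sf(abs(z)))
    return SteigerDirection(direction, p)


def run_mr(
    instruments: InstrumentSet,
    outcome: str,
    n_boot: int = 1000,
    seed: int = 7_919,
) -> MRResult:
    """Run IVW, MR-Egger and the weighted median on one eligible instrument
    set (all on the identical pair list) and collect sensitivity statistics."""
    if not instruments.eligible:
        raise ValueError(
            f"instrument set for {instruments.protein!r} has "
            f"{len(instruments.pairs)} < {instruments.min_ivs} instruments"
        )
    pairs = instruments.pairs
    ivw_res = ivw(pairs)
    egger_res = egger(pairs)
    wm_res = weighted_median(pairs, n_boot=n_boot, seed=seed)
    direction = steiger_direction(pairs)
    k = len(pairs)
    return MRResult(
        protein=instruments.protein,
        outcome=outcome,
        n_ivs=k,
        beta_ivw=ivw_res.beta, se_ivw=ivw_res.se, p_ivw=ivw_res.p,
        beta_egger=egger_res.slope, se_egger=egger_res.se_slope, p_egger=egger_res.p_slope,
        egger_intercept=egger_res.intercept, se_intercept=egger_res.se_intercept,
        p_intercept=egger_res.p_intercept,
        beta_wm=wm_res.beta, se_wm=wm_res.se, p_wm=wm_res.p,
        q_stat=ivw_res.q_stat, q_df=k - 1, q_p=ivw_res.q_p,
        steiger_direction=direction.direction, steiger_p=direction.p,
        sigma_scale=ivw_res.sigma_scale,
    )


def results_table(results: list[MRResult]) -> pd.DataFrame:
    """Stack MRResults into one row-per-(protein, outcome) table."""
    return pd.DataFrame([r.as_dict() for r in results])
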