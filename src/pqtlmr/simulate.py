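"""Synthetic two-sample pQTL / outcome GWAS generator with known ground truth.

The generator emulates the statistical structure a proteome-wide MR screen
assumes, at desk scale:

* one *cis region* per protein: ``snps_per_region`` biallelic SNPs whose
  genotype dosages follow Hardy–Weinberg margins with AR(1)-style linkage
  disequilibrium (latent Gaussian haplotypes thresholded at the minor-allele
  frequency; the latent correlation is calibrated numerically so the realized
  dosage correlation between adjacent SNPs matches ``ld_rho`` wherever the
  two marginal frequencies allow it);
* a protein ``X = Σ_j γ_j G_j + ε`` with a configurable number of causal
  SNPs, standardized to unit variance, measured in an *exposure* cohort;
* an outcome ``Y = θ·X + Σ_{j∈invalid} α_j G_j + ε'`` measured in a disjoint
  *outcome* cohort (two-sample design holds by construction), standardized
  to unit variance, with optional balanced or directional pleiotropic direct
  effects on a fraction of the instruments;
* a third disjoint cohort forming the LD reference panel;
* marginal per-SNP summary statistics (beta, se, normal two-sided p, eaf, n)
  computed by simple least squares within each cohort, as GWAS software
  reports them.

Every dataset carries a :class:`SimTruth` record (true causal effect, the
identities of invalid and causal SNPs, reverse-causation flag) so each
pipeline stage can be checked against ground truth.  All randomness derives
from one integer seed via counter-based stream splitting: region ``i`` of a
multi-protein dataset is identical no matter how many other regions are
generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gwas_io import (
    ReferencePanel,
    write_gene_annotations,
    write_reference_panel,
    write_summary_stats,
    write_table,
)

__all__ = ["SimConfig", "SimTruth", "RegionData", "ScreenData", "simulate_region", "simulate_screen", "simulate_reverse"]


class SimulationError(ValueError):
    """Degenerate generating configuration (e.g. variance budget exceeded)."""


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic pQTL/outcome dataset.

    Traits are standardized to unit variance, so ``causal_effect`` is the
    true causal effect in outcome SDs per protein SD — directly comparable
    to the MR estimates.  Per-SNP causal effects on the protein are drawn
    half-normal, ``γ_j ~ |N(0, gamma_sd²)|``: the effect-allele orientation
    of a pQTL is arbitrary, so positive signs lose no generality while
    keeping directional pleiotropy scenarios well-defined.
    """

    n_proteins: int = 1
    snps_per_region: int = 30
    maf_range: tuple[float, float] = (0.05, 0.45)
    ld_rho: float = 0.5
    n_exposure: int = 20_000
    n_outcome: int = 20_000
    n_panel: int = 2_000
    causal_effect: float = 0.3
    n_causal_snps: int = 3
    gamma_sd: float = 0.15
    # halfnormal: gamma_j ~ |N(0, gamma_sd^2)|; fixed: all gamma_j = gamma_sd;
    # ladder: gamma_j = gamma_sd * (j+1)/k (deterministic spread of strengths,
    # needed for MR-Egger, whose slope is identified by strength dispersion)
    gamma_dist: str = "halfnormal"
    causal_snp_placement: str = "random"  # random | spaced (evenly spread across the region)
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.05
    invalid_fraction: float = 0.0
    reverse_effect: float = 0.0
    palindromic_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0 < lo <= hi < 0.5:
            raise SimulationError("maf_range must satisfy 0 < low <= high < 0.5")
        if not 0 <= self.ld_rho < 1:
            raise SimulationError("ld_rho must lie in [0, 1)")
        for name in ("n_exposure", "n_outcome", "n_panel"):
            if getattr(self, name) < 50:
                raise SimulationError(f"{name} must be >= 50")
        if not 0 <= self.invalid_fraction <= 1:
            raise SimulationError("invalid_fraction must lie in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise SimulationError("pleiotropy_mode must be none, balanced or directional")
        if not 1 <= self.n_causal_snps <= self.snps_per_region:
            raise SimulationError("n_causal_snps must lie in [1, snps_per_region]")
        if self.gamma_dist not in ("halfnormal", "fixed", "ladder"):
            raise SimulationError("gamma_dist must be halfnormal, fixed or ladder")
        if self.causal_snp_placement not in ("random", "spaced"):
            raise SimulationError("causal_snp_placement must be random or spaced")


@dataclass
class SimTruth:
    """Ground-truth labels attached to a simulated region."""

    protein: str
    theta_true: float
    invalid_snp_ids: set[str]
    reverse: bool
    causal_snps: dict[str, float] = field(default_factory=dict)  # variant_id -> gamma (or delta)


@dataclass
class RegionData:
    """One protein's simulated region: two GWAS tables, a panel, the truth."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    panel: ReferencePanel
    truth: SimTruth
    gene: str
    chrom: str
    gene_start: int

    @property
    def annotation(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": [self.gene], "chrom": [self.chrom], "gene_start": [self.gene_start]}
        )


@dataclass
class ScreenData:
    """A multi-protein dataset: per-protein exposure GWAS, one shared outcome
    GWAS, one reference panel, gene annotations and a truth table."""

    exposures: dict[str, pd.DataFrame]
    outcome: pd.DataFrame
    panel: ReferencePanel
    annotations: pd.DataFrame
    truths: list[SimTruth]

    @property
    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": [t.protein for t in self.truths],
                "theta_true": [t.theta_true for t in self.truths],
                "reverse": [t.reverse for t in self.truths],
                "n_invalid": [len(t.invalid_snp_ids) for t in self.truths],
            }
        )

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        (out_dir / "exposures").mkdir(parents=True, exist_ok=True)
        for protein, df in self.exposures.items():
            write_summary_stats(df, out_dir / "exposures" / f"{protein}.tsv")
        write_summary_stats(self.outcome, out_dir / "outcome.tsv")
        write_reference_panel(self.panel, out_dir / "panel.tsv")
        write_gene_annotations(self.annotations, out_dir / "genes.tsv")
        write_table(self.truth_table, out_dir / "truth.tsv")


# ---------------------------------------------------------------------------
# LD machinery: latent-Gaussian haplotypes with calibrated threshold correlation


def _bvn_cdf(t1: float, t2: float, rho: float) -> float:
    cov = [[1.0, rho], [rho, 1.0]]
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([t1, t2]))


def _binary_corr(rho: float, p1: float, p2: float, t1: float, t2: float) -> float:
    """Pearson correlation of two threshold indicators with latent corr rho."""
    cov = _bvn_cdf(t1, t2, rho) - p1 * p2
    return cov / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def _calibrate_latent_rho(mafs: np.ndarray, target: float) -> np.ndarray:
    """Latent AR(1) coefficients giving adjacent-dosage correlation ``target``.

    The Pearson correlation of two Bernoulli indicators is Fréchet-bounded;
    when the two marginal frequencies differ too much for ``target`` to be
    attainable the latent correlation is capped near 1 and the realized LD
    falls at the bound.
    """
    m = len(mafs)
    if m < 2 or target == 0.0:
        return np.zeros(max(m - 1, 0))
    thr = stats.norm.ppf(mafs)
    out = np.empty(m - 1)
    for j in range(m - 1):
        p1, p2, t1, t2 = mafs[j], mafs[j + 1], thr[j], thr[j + 1]

        def f(rho: float) -> float:
            return _binary_corr(rho, p1, p2, t1, t2) - target

        hi = 0.9995
        if f(hi) <= 0:  # target unattainable for this MAF pair
            out[j] = hi
        else:
            out[j] = optimize.brentq(f, 0.0, hi, xtol=1e-6)
    return out


def _haplotypes(rng: np.random.Generator, n: int, thr: np.ndarray, latent_rho: np.ndarray) -> np.ndarray:
    """n haplotypes over len(thr) SNPs; returns 0/1 allele matrix (n, m)."""
    m = len(thr)
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    for j in range(1, m):
        r = latent_rho[j - 1]
        z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    return (z < thr).astype(np.int8)


def _genotypes(rng: np.random.Generator, n: int, mafs: np.ndarray, latent_rho: np.ndarray) -> np.ndarray:
    thr = stats.norm.ppf(mafs)
    return (_haplotypes(rng, n, thr, latent_rho) + _haplotypes(rng, n, thr, latent_rho)).astype(np.int8)


def _dosage_cov(mafs: np.ndarray, latent_rho: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Theoretical dosage covariance among the SNPs in ``idx``."""
    thr = stats.norm.ppf(mafs)
    k = len(idx)
    cov = np.zeros((k, k))
    for a in range(k):
        ja = idx[a]
        cov[a, a] = 2.0 * mafs[ja] * (1 - mafs[ja])
        for b in range(a + 1, k):
            jb = idx[b]
            rho = float(np.prod(latent_rho[min(ja, jb):max(ja, jb)])) if len(latent_rho) else 0.0
            c = 2.0 * (_bvn_cdf(thr[ja], thr[jb], rho) - mafs[ja] * mafs[jb])
            cov[a, b] = cov[b, a] = c
    return cov


# ---------------------------------------------------------------------------
# Marginal association statistics

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _marginal_stats(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP simple-regression beta, se, normal two-sided p and eaf.

    Monomorphic columns get se = inf (callers drop them from output)."""
    n = len(y)
    Gf = G.astype(float)
    gm = Gf.mean(axis=0)
    Gc = Gf - gm
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", Gc, Gc)
    sxy = Gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(rss / (n - 2) / np.where(sxx > 0, sxx, np.nan))
    se = np.where(sxx > 0, se, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return beta, se, pval, gm / 2.0


@dataclass
class _Region:
    """Structural draws shared by all cohorts of one region."""

    variant_ids: list[str]
    chrom: str
    positions: np.ndarray
    mafs: np.ndarray
    latent_rho: np.ndarray
    ea: list[str]
    oa: list[str]
    causal_idx: np.ndarray
    gamma: np.ndarray
    invalid_idx: np.ndarray
    alpha: np.ndarray
    gene: str
    gene_start: int


_SNP_SPACING = 25_000
_REGION_BASE = 10_000_000


def _region_structure(config: SimConfig, protein_index: int) -> _Region:
    rng = np.random.default_rng([max(config.seed, 0), protein_index, 0])
    m = config.snps_per_region
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    latent_rho = _calibrate_latent_rho(mafs, config.ld_rho)
    chrom = str(1 + protein_index % 22)
    start = _REGION_BASE + (protein_index // 22) * 10_000_000
    positions = start + _SNP_SPACING * np.arange(m)
    gene_start = int(start + _SNP_SPACING * (m // 2))
    ea, oa = [], []
    for j in range(m):
        if rng.random() < config.palindromic_fraction:
            pair = _PALINDROMIC_PAIRS[rng.integers(len(_PALINDROMIC_PAIRS))]
        else:
            pair = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
        ea.append(pair[0])
        oa.append(pair[1])
    if config.causal_snp_placement == "spaced":
        # evenly spread causal SNPs: conditionally independent cis signals
        causal_idx = np.unique(np.round(np.linspace(0, m - 1, config.n_causal_snps)).astype(int))
    else:
        causal_idx = np.sort(rng.choice(m, size=config.n_causal_snps, replace=False))
    if config.gamma_dist == "fixed":
        gamma = np.full(config.n_causal_snps, config.gamma_sd)
    elif config.gamma_dist == "ladder":
        k = config.n_causal_snps
        gamma = config.gamma_sd * np.arange(1, k + 1) / k
    else:
        gamma = np.abs(rng.normal(0.0, config.gamma_sd, size=config.n_causal_snps))
    n_invalid = int(round(config.invalid_fraction * config.n_causal_snps))
    if config.pleiotropy_mode == "none" or n_invalid == 0:
        invalid_idx = np.array([], dtype=int)
        alpha = np.array([])
    else:
        pick = np.sort(rng.choice(config.n_causal_snps, size=n_invalid, replace=False))
        invalid_idx = causal_idx[pick]
        mean = config.pleiotropy_sd if config.pleiotropy_mode == "directional" else 0.0
        alpha = rng.normal(mean, config.pleiotropy_sd, size=n_invalid)
    vids = [f"rs{protein_index}_{j}" for j in range(m)]
    return _Region(
        vids, chrom, positions, mafs, latent_rho, ea, oa, causal_idx, gamma,
        invalid_idx, alpha, gene=f"GENE{protein_index}", gene_start=gene_start,
    )


def _protein_noise_sd(region: _Region) -> float:
    cov = _dosage_cov(region.mafs, region.latent_rho, region.causal_idx)
    var_g = float(region.gamma @ cov @ region.gamma)
    if var_g >= 1.0:
        raise SimulationError(
            f"genetic variance of protein {region.gene} is {var_g:.3f} >= 1; "
            "reduce gamma_sd or n_causal_snps"
        )
    return float(np.sqrt(1.0 - var_g))


def _direct_variance_terms(region: _Region, theta: float) -> float:
    """Var contribution of θ·X plus direct effects (traits unit-variance)."""
    total = theta * theta
    if len(region.invalid_idx):
        both = np.concatenate([region.causal_idx, region.invalid_idx])
        uniq, inv = np.unique(both, return_inverse=True)
        cov = _dosage_cov(region.mafs, region.latent_rho, uniq)
        kc = len(region.causal_idx)
        ci = inv[:kc]
        ii = inv[kc:]
        gam = np.zeros(len(uniq))
        gam[ci] += region.gamma
        alf = np.zeros(len(uniq))
        alf[ii] += region.alpha
        total += float(alf @ cov @ alf) + 2.0 * theta * float(gam @ cov @ alf)
    return total


def _protein_values(G: np.ndarray, region: _Region, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    return G[:, region.causal_idx].astype(float) @ region.gamma + rng.normal(0.0, noise_sd, size=G.shape[0])


def _summary_frame(region: _Region, G: np.ndarray, y: np.ndarray, n: int,
                   swap: np.ndarray | None = None, flip_strand: np.ndarray | None = None) -> pd.DataFrame:
    beta, se, pval, eaf = _marginal_stats(G, y)
    ea = list(region.ea)
    oa = list(region.oa)
    if swap is not None:  # report the other allele as effect allele
        for j in np.flatnonzero(swap):
            ea[j], oa[j] = oa[j], ea[j]
        beta = np.where(swap, -beta, beta)
        eaf = np.where(swap, 1.0 - eaf, eaf)
    if flip_strand is not None:  # report opposite-strand letters (same orientation)
        for j in np.flatnonzero(flip_strand):
            ea[j] = _COMPLEMENT[ea[j]]
            oa[j] = _COMPLEMENT[oa[j]]
    df = pd.DataFrame(
        {
            "variant_id": region.variant_ids,
            "chrom": region.chrom,
            "pos": region.positions,
            "ea": ea,
            "oa": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )
    return df[np.isfinite(df["se"])].reset_index(drop=True)


def _outcome_presentation(rng: np.random.Generator, region: _Region) -> tuple[np.ndarray, np.ndarray]:
    """How the outcome GWAS reports each SNP: possibly swapped effect/other
    allele and, for non-palindromic SNPs, possibly opposite-strand letters.
    Harmonization must undo both."""
    m = len(region.variant_ids)
    swap = rng.random(m) < 0.5
    palindromic = np.array([_COMPLEMENT[a] == b for a, b in zip(region.ea, region.oa)])
    flip_strand = (rng.random(m) < 0.25) & ~palindromic
    return swap, flip_strand


def simulate_region(config: SimConfig, protein_index: int = 0) -> RegionData:
    """Simulate one protein's cis region in three disjoint cohorts.

    Returns exposure and outcome summary statistics, an LD reference panel
    and the :class:`SimTruth` record.  Reproducible: the output depends only
    on ``(config, protein_index)``.
    """
    region = _region_structure(config, protein_index)
    noise_sd = _protein_noise_sd(region)
    theta = config.causal_effect
    explained = _direct_variance_terms(region, theta)
    if explained >= 1.0:
        raise SimulationError("outcome variance budget exceeded; reduce effect sizes")
    out_noise_sd = float(np.sqrt(1.0 - explained))
    seed = max(config.seed, 0)

    rng_exp = np.random.default_rng([seed, protein_index, 1])
    G_exp = _genotypes(rng_exp, config.n_exposure, region.mafs, region.latent_rho)
    x_exp = _protein_values(G_exp, region, noise_sd, rng_exp)
    exposure = _summary_frame(region, G_exp, x_exp, config.n_exposure)

    rng_out = np.random.default_rng([seed, protein_index, 2])
    G_out = _genotypes(rng_out, config.n_outcome, region.mafs, region.latent_rho)
    x_out = _protein_values(G_out, region, noise_sd, rng_out)
    y = theta * x_out
    if len(region.invalid_idx):
        y = y + G_out[:, region.invalid_idx].astype(float) @ region.alpha
    y = y + rng_out.normal(0.0, out_noise_sd, size=config.n_outcome)
    swap, flip_strand = _outcome_presentation(np.random.default_rng([seed, protein_index, 5]), region)
    outcome = _summary_frame(region, G_out, y, config.n_outcome, swap, flip_strand)

    rng_panel = np.random.default_rng([seed, protein_index, 3])
    panel = ReferencePanel(
        list(region.variant_ids),
        _genotypes(rng_panel, config.n_panel, region.mafs, region.latent_rho).astype(float).T,
    )
    truth = SimTruth(
        protein=f"P{protein_index}",
        theta_true=theta,
        invalid_snp_ids={region.variant_ids[j] for j in region.invalid_idx},
        reverse=False,
        causal_snps={region.variant_ids[j]: g for j, g in zip(region.causal_idx, region.gamma)},
    )
    return RegionData(exposure, outcome, panel, truth, region.gene, region.chrom, region.gene_start)


def simulate_reverse(config: SimConfig, protein_index: int = 0) -> RegionData:
    """Simulate a reverse-causation region: the SNPs act on the outcome and
    the protein is downstream, ``X = reverse_effect·Y + noise``.

    With ``reverse_effect = 0`` the exposure GWAS is pure noise (null region).
    """
    region = _region_structure(config, protein_index)
    delta = region.gamma  # direct SNP effects, here on the outcome
    out_noise_sd = _protein_noise_sd(region)
    r = config.reverse_effect
    if abs(r) >= 1.0:
        raise SimulationError("abs(reverse_effect) must be < 1 for unit-variance traits")
    x_noise_sd = float(np.sqrt(1.0 - r * r))
    seed = max(config.seed, 0)

    rng_exp = np.random.default_rng([seed, protein_index, 1])
    G_exp = _genotypes(rng_exp, config.n_exposure, region.mafs, region.latent_rho)
    y_exp = _protein_values(G_exp, region, out_noise_sd, rng_exp)  # outcome values
    x_exp = r * y_exp + rng_exp.normal(0.0, x_noise_sd, size=config.n_exposure)
    exposure = _summary_frame(region, G_exp, x_exp, config.n_exposure)

    rng_out = np.random.default_rng([seed, protein_index, 2])
    G_out = _genotypes(rng_out, config.n_outcome, region.mafs, region.latent_rho)
    y_out = _protein_values(G_out, region, out_noise_sd, rng_out)
    swap, flip_strand = _outcome_presentation(np.random.default_rng([seed, protein_index, 5]), region)
    outcome = _summary_frame(region, G_out, y_out, config.n_outcome, swap, flip_strand)

    rng_panel = np.random.default_rng([seed, protein_index, 3])
    panel = ReferencePanel(
        list(region.variant_ids),
        _genotypes(rng_panel, config.n_panel, region.mafs, region.latent_rho).astype(float).T,
    )
    truth = SimTruth(
        protein=f"P{protein_index}",
        theta_true=0.0,
        invalid_snp_ids=set(),
        reverse=True,
        causal_snps={region.variant_ids[j]: g for j, g in zip(region.causal_idx, delta)},
    )
    return RegionData(exposure, outcome, panel, truth, region.gene, region.chrom, region.gene_start)


def simulate_screen(
    config: SimConfig,
    n_null: int,
    n_causal: int,
    theta: Sequence[float] | None = None,
) -> ScreenData:
    """Simulate a multi-protein screen sharing one outcome GWAS.

    Proteins ``P0 … P{n_causal-1}`` are causal (true effect ``causal_effect``,
    or the entries of ``theta`` if given); the remaining ``n_null`` proteins
    have no effect on the outcome.  Regions are independent; the outcome
    trait sums every causal protein's contribution plus pleiotropic direct
    effects and noise, and its GWAS is computed in one shared cohort.
    """
    if n_null < 0 or n_causal < 0:
        raise SimulationError("protein counts must be >= 0")
    n_prot = n_null + n_causal
    if theta is None:
        thetas = np.array([config.causal_effect] * n_causal + [0.0] * n_null)
    else:
        if len(theta) != n_causal:
            raise SimulationError("theta must have one entry per causal protein")
        thetas = np.concatenate([np.asarray(theta, dtype=float), np.zeros(n_null)])
    seed = max(config.seed, 0)

    exposures: dict[str, pd.DataFrame] = {}
    truths: list[SimTruth] = []
    annotations = []
    panel_ids: list[str] = []
    panel_rows = []
    regions: list[_Region] = []
    G_out_all: list[np.ndarray] = []
    y_contrib = np.zeros(config.n_outcome)
    explained = 0.0

    for p in range(n_prot):
        region = _region_structure(config, p)
        regions.append(region)
        noise_sd = _protein_noise_sd(region)
        th = float(thetas[p])
        explained += _direct_variance_terms(region, th)

        rng_exp = np.random.default_rng([seed, p, 1])
        G_exp = _genotypes(rng_exp, config.n_exposure, region.mafs, region.latent_rho)
        x_exp = _protein_values(G_exp, region, noise_sd, rng_exp)
        protein = f"P{p}"
        exposures[protein] = _summary_frame(region, G_exp, x_exp, config.n_exposure)

        rng_out = np.random.default_rng([seed, p, 2])
        G_out = _genotypes(rng_out, config.n_outcome, region.mafs, region.latent_rho)
        x_out = _protein_values(G_out, region, noise_sd, rng_out)
        y_contrib += th * x_out
        if len(region.invalid_idx):
            y_contrib += G_out[:, region.invalid_idx].astype(float) @ region.alpha
        G_out_all.append(G_out)

        rng_panel = np.random.default_rng([seed, p, 3])
        panel_rows.append(_genotypes(rng_panel, config.n_panel, region.mafs, region.latent_rho).astype(float).T)
        panel_ids.extend(region.variant_ids)

        truths.append(
            SimTruth(
                protein=protein,
                theta_true=th,
                invalid_snp_ids={region.variant_ids[j] for j in region.invalid_idx},
                reverse=False,
                causal_snps={region.variant_ids[j]: g for j, g in zip(region.causal_idx, region.gamma)},
            )
        )
        annotations.append({"gene": region.gene, "chrom": region.chrom, "gene_start": region.gene_start})

    if explained >= 1.0:
        raise SimulationError("outcome variance budget exceeded across causal proteins")
    rng_y = np.random.default_rng([seed, 2**30 + 1])
    y = y_contrib + rng_y.normal(0.0, float(np.sqrt(1.0 - explained)), size=config.n_outcome)

    outcome_frames = []
    for p, (region, G_out) in enumerate(zip(regions, G_out_all)):
        swap, flip_strand = _outcome_presentation(np.random.default_rng([seed, p, 5]), region)
        outcome_frames.append(_summary_frame(region, G_out, y, config.n_outcome, swap, flip_strand))
    outcome = pd.concat(outcome_frames, ignore_index=True) if outcome_frames else pd.DataFrame(
        columns=["variant_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]
    )
    panel = (
        ReferencePanel(panel_ids, np.vstack(panel_rows))
        if panel_rows
        else ReferencePanel([], np.empty((0, config.n_panel)))
    )
    annotations_df = pd.DataFrame(annotations, columns=["gene", "chrom", "gene_start"])
    return ScreenData(exposures, outcome, panel, annotations_df, truths)
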