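"""The instrument-selection cascade, SNP by SNP.

Every candidate cis-SNP either survives to the instrument list or is dropped
with the first filter it failed — genome-wide significance, the ±1 Mb cis
window, minor-allele frequency, the MHC exclusion, instrument strength
(F < 10), cross-protein pleiotropy, harmonization (ambiguous palindromic
alleles), Steiger directionality, or LD clumping.  The audit plus the kept
list always partition the candidates."""

from pqtlmr import SimConfig, build_instrument_set, simulate_region

config = SimConfig(
    seed=3, snps_per_region=30, n_causal_snps=5, gamma_dist="fixed",
    gamma_sd=0.15, ld_rho=0.4, causal_snp_placement="spaced",
    n_exposure=20_000, n_outcome=20_000, n_panel=2_000, causal_effect=0.3,
)
region = simulate_region(config, protein_index=0)
iset = build_instrument_set(
    region.truth.protein, region.gene, region.exposure, region.outcome,
    region.annotation, region.panel,
)

print(f"protein {iset.protein} (gene {iset.gene}): "
      f"{iset.n_candidates} candidate SNPs → {len(iset.pairs)} instruments "
      f"({'eligible' if iset.eligible else 'ineligible'} for MR, needs ≥ {iset.min_ivs})\n")
print("drop reasons:")
print(iset.audit["drop_reason"].value_counts().to_string())
print("\nkept instruments (harmonized):")
cols = ["variant_id", "pos", "beta_exp", "se_exp", "beta_out", "se_out", "f_stat", "flipped"]
print(iset.pairs[cols].round(4).to_string(index=False))
print("\npvalue_dropped = not genome-wide significant for the protein;")
print("clump_dropped = in LD (r² ≥ 0.1) with a stronger kept SNP.")
print("'flipped' marks SNPs whose outcome effect was re-oriented onto the")
print("exposure effect allele during harmonization.")
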