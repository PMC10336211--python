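"""Selection cascade: per-SNP statistics, filters, harmonization, clumping,
Steiger filtering and the full instrument-set builder."""


import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pqtlmr.gwas_io import ReferencePanel
from pqtlmr.instruments import (
    ConfigurationError,
    FilterConfig,
    build_instrument_set,
    harmonize,
    harmonize_tables,
    ld_clump,
    per_snp_f,
    pleiotropy_counts,
    pleiotropy_flagged_snps,
    region_filters,
    snp_r2,
    steiger_filter,
)

from conftest import make_stats


class TestPerSnpF:
    def test_arithmetic(self):
        assert per_snp_f(0.5, 0.05) == pytest.approx(100.0)
        assert per_snp_f(0.1, 0.05) == pytest.approx(4.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            per_snp_f(0.1, 0.0)

    def test_f_is_squared_z_distribution_identity(self):
        # p from z (two-sided normal) equals p from F with (1, n-2) df as n grows
        z = 2.3
        p_z = 2 * stats.norm.sf(z)
        p_f = stats.f.sf(per_snp_f(z * 0.01, 0.01), 1, 10**6)
        assert p_f == pytest.approx(p_z, rel=1e-3)


class TestSnpR2:
    def test_zero_beta_zero_r2(self):
        assert snp_r2(0.0, 0.1, 100) == 0.0

    def test_half_r2_identity(self):
        # t^2 = n-2  =>  r^2 = 0.5
        n = 50
        t = np.sqrt(n - 2)
        assert snp_r2(t * 0.1, 0.1, n) == pytest.approx(0.5)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            snp_r2(0.1, 0.1, 2)

    def test_matches_individual_level_pearson_r2(self):
        # regression identity: summary-stat r2 equals squared correlation
        rng = np.random.default_rng(0)
        n = 2_000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        y = 0.2 * g + rng.standard_normal(n)
        gc, yc = g - g.mean(), y - y.mean()
        beta = gc @ yc / (gc @ gc)
        se = np.sqrt((yc @ yc - beta * (gc @ yc)) / (n - 2) / (gc @ gc))
        r2_summary = snp_r2(beta, se, n)
        r2_direct = np.corrcoef(g, y)[0, 1] ** 2
        assert r2_summary == pytest.approx(r2_direct, rel=1e-9)


class TestSteigerFilter:
    def test_equal_r2_is_dropped_at_half(self):
        res = steiger_filter(0.01, 0.01, 1_000, 1_000)
        assert res.p == pytest.approx(0.5) and not res.keep and res.z == pytest.approx(0.0)

    def test_strong_exposure_dominance_kept(self):
        res = steiger_filter(0.05, 1e-6, 35_000, 400_000)
        assert res.keep and res.p < 1e-10

    def test_swapping_sides_negates_z(self):
        a = steiger_filter(0.03, 0.001, 5_000, 20_000)
        b = steiger_filter(0.001, 0.03, 20_000, 5_000)
        assert a.z == pytest.approx(-b.z)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            steiger_filter(0.1, 0.01, 3, 100)


class TestPleiotropyCounts:
    def _tables(self, n_proteins, vid="rs1"):
        return {
            f"P{i}": make_stats([{"variant_id": vid, "beta": 0.5, "se": 0.05}])
            for i in range(n_proteins)
        }

    def test_six_proteins_flagged_everywhere(self):
        counts = pleiotropy_counts(self._tables(6))
        assert counts["rs1"] == 6
        assert pleiotropy_flagged_snps(counts, 5) == {"rs1"}

    def test_exactly_five_retained(self):
        # "more than five" is strict: a count of 5 survives
        counts = pleiotropy_counts(self._tables(5))
        assert pleiotropy_flagged_snps(counts, 5) == set()

    def test_empty_input(self):
        assert pleiotropy_counts({}) == {}

    def test_aptamers_collapse_to_unique_proteins(self):
        tables = self._tables(6)
        protein_of = {f"P{i}": "SAME" for i in range(6)}  # six aptamers, one target
        counts = pleiotropy_counts(tables, protein_of=protein_of)
        assert counts["rs1"] == 1


class TestRegionFilters:
    ANN = {"gene": "G", "chrom": "6", "gene_start": 30_000_000}

    def test_mhc_interval_dropped_inclusive(self):
        df = make_stats(
            [
                {"variant_id": "in_mhc", "chrom": "6", "pos": 32_900_000, "beta": 0.5, "se": 0.05},
                {"variant_id": "at_end", "chrom": "6", "pos": 33_448_354, "beta": 0.5, "se": 0.05},
                {"variant_id": "past_end", "chrom": "6", "pos": 33_448_355, "beta": 0.5, "se": 0.05},
            ]
        )
        # gene close enough that every variant is cis: the MHC filter decides
        out = region_filters(df, {**self.ANN, "gene_start": 32_800_000}, FilterConfig())
        reasons = dict(zip(out["variant_id"], out["drop_reason"]))
        assert reasons["in_mhc"] == "mhc_dropped"
        assert reasons["at_end"] == "mhc_dropped"
        assert reasons["past_end"] == ""

    def test_cis_window_boundary(self):
        cfg = FilterConfig(mhc=("22", 1, 2))  # park the MHC elsewhere
        df = make_stats(
            [
                {"variant_id": "cis", "chrom": "6", "pos": 30_999_999, "beta": 0.5, "se": 0.05},
                {"variant_id": "edge", "chrom": "6", "pos": 31_000_000, "beta": 0.5, "se": 0.05},
                {"variant_id": "trans", "chrom": "6", "pos": 31_000_001, "beta": 0.5, "se": 0.05},
                {"variant_id": "other_chr", "chrom": "7", "pos": 30_000_000, "beta": 0.5, "se": 0.05},
            ]
        )
        out = region_filters(df, self.ANN, cfg)
        reasons = dict(zip(out["variant_id"], out["drop_reason"]))
        assert reasons["cis"] == "" and reasons["edge"] == ""
        assert reasons["trans"] == "cis_dropped"
        assert reasons["other_chr"] == "cis_dropped"

    def test_rare_allele_dropped_by_maf(self):
        df = make_stats(
            [{"variant_id": "rare", "chrom": "6", "pos": 30_000_000, "eaf": 0.995,
              "beta": 0.5, "se": 0.05}]
        )
        out = region_filters(df, {**self.ANN, "gene_start": 30_000_000}, FilterConfig(mhc=("22", 1, 2)))
        assert out["drop_reason"].iloc[0] == "maf_dropped"

    def test_first_failing_filter_wins(self):
        # fails significance AND maf: the earlier filter names the drop
        df = make_stats(
            [{"variant_id": "multi", "chrom": "6", "pos": 30_000_000, "eaf": 0.999,
              "beta": 0.01, "se": 0.05}]
        )
        out = region_filters(df, self.ANN, FilterConfig(mhc=("22", 1, 2)))
        assert out["drop_reason"].iloc[0] == "pvalue_dropped"

    def test_weak_instrument_dropped(self):
        cfg = FilterConfig(p_exposure_max=0.5, mhc=("22", 1, 2))
        df = make_stats(
            [{"variant_id": "weak", "chrom": "6", "pos": 30_000_000, "beta": 0.1, "se": 0.05}]
        )
        out = region_filters(df, self.ANN, cfg)
        assert out["drop_reason"].iloc[0] == "weak_dropped"


class TestHarmonize:
    EXP = {"variant_id": "rs1", "ea": "A", "oa": "G", "eaf": 0.3, "beta": 0.5,
           "se": 0.05, "pval": 1e-20, "n": 10_000, "chrom": "1", "pos": 100}

    def _out(self, **kw):
        base = {"variant_id": "rs1", "ea": "A", "oa": "G", "eaf": 0.3, "beta": 0.1,
                "se": 0.02, "pval": 1e-6, "n": 50_000}
        return {**base, **kw}

    def test_identity_no_flags(self):
        pair = harmonize(self.EXP, self._out())
        assert pair.flags == set()
        assert pair.beta_out == 0.1 and pair.eaf_out == 0.3

    def test_allele_swap_flips_beta_and_eaf(self):
        pair = harmonize(self.EXP, self._out(ea="G", oa="A", eaf=0.7))
        assert "flipped" in pair.flags and not pair.dropped
        assert pair.beta_out == pytest.approx(-0.1)
        assert pair.eaf_out == pytest.approx(0.3)

    def test_strand_flip_resolved_without_beta_flip(self):
        # outcome reports opposite-strand letters, same orientation
        pair = harmonize(self.EXP, self._out(ea="T", oa="C"))
        assert not pair.dropped and "flipped" not in pair.flags
        assert pair.beta_out == pytest.approx(0.1)

    def test_ambiguous_palindromic_dropped(self):
        exp = {**self.EXP, "ea": "A", "oa": "T", "eaf": 0.50}
        pair = harmonize(exp, self._out(ea="A", oa="T", eaf=0.5))
        assert pair.drop_reason == "palindromic_dropped"

    def test_palindromic_outside_band_aligned_by_frequency(self):
        exp = {**self.EXP, "ea": "C", "oa": "G", "eaf": 0.1}
        # outcome frequency says the listed effect allele is the common one:
        # opposite orientation, so beta flips
        pair = harmonize(exp, self._out(ea="C", oa="G", eaf=0.9))
        assert not pair.dropped
        assert pair.beta_out == pytest.approx(-0.1)
        assert pair.eaf_out == pytest.approx(0.1)

    def test_irreconcilable_alleles_dropped(self):
        pair = harmonize(self.EXP, self._out(ea="A", oa="C"))
        assert pair.drop_reason == "allele_mismatch_dropped"

    def test_mismatched_ids_raise(self):
        with pytest.raises(ValueError, match="different variants"):
            harmonize(self.EXP, self._out(variant_id="rs2"))

    def test_f_stat_is_squared_z(self):
        pair = harmonize(self.EXP, self._out())
        assert pair.f_stat == pytest.approx((0.5 / 0.05) ** 2)


def _reference_clump(candidates: pd.DataFrame, panel: ReferencePanel, r2_max: float) -> list[str]:
    """Independent re-implementation of the greedy clumping rule."""
    rows = sorted(
        candidates.to_dict("records"),
        key=lambda r: (r["pval_exp"], str(r["chrom"]), int(r["pos"]), str(r["variant_id"])),
    )
    kept, removed = [], set()
    for row in rows:
        vid = str(row["variant_id"])
        if vid in removed:
            continue
        kept.append(vid)
        for other in rows:
            ov = str(other["variant_id"])
            if ov == vid or ov in removed or ov in kept:
                continue
            x, y = panel.row(vid), panel.row(ov)
            if np.corrcoef(x, y)[0, 1] ** 2 >= r2_max:
                removed.add(ov)
    return sorted(kept)


class TestLdClump:
    def _candidates(self, ids, pvals, pos=None):
        return pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": "1",
                "pos": pos if pos is not None else range(100, 100 + len(ids)),
                "pval_exp": pvals,
            }
        )

    def test_single_candidate_kept(self, tiny_panel):
        kept, dropped = ld_clump(self._candidates(["rs0"], [1e-8]), tiny_panel)
        assert kept == ["rs0"] and dropped == []

    def test_duplicated_variants_keep_most_significant(self):
        row = np.random.default_rng(1).integers(0, 3, 50).astype(float)
        panel = ReferencePanel(["a", "b", "c"], np.vstack([row, row, row]))
        kept, dropped = ld_clump(self._candidates(["a", "b", "c"], [1e-9, 1e-10, 1e-8]), panel)
        assert kept == ["b"] and set(dropped) == {"a", "c"}

    def test_missing_candidate_names_variant(self, tiny_panel):
        with pytest.raises(ValueError, match="rs99"):
            ld_clump(self._candidates(["rs99"], [1e-8]), tiny_panel)

    def test_matches_independent_reference_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m, n = 12, 120
            base = rng.integers(0, 3, size=(m, n)).astype(float)
            # induce correlation clusters by copying rows with noise
            for j in range(1, m):
                if rng.random() < 0.5:
                    base[j] = np.clip(base[j - 1] + rng.integers(-1, 2, n) * (rng.random(n) < 0.3), 0, 2)
            panel = ReferencePanel([f"v{j}" for j in range(m)], base)
            cands = self._candidates([f"v{j}" for j in range(m)], rng.uniform(1e-12, 1e-8, m))
            kept, _ = ld_clump(cands, panel, 0.1)
            assert sorted(kept) == _reference_clump(cands, panel, 0.1)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        m = 8
        dosages = rng.integers(0, 3, size=(m, 80)).astype(float)
        panel = ReferencePanel([f"v{j}" for j in range(m)], dosages)
        cands = self._candidates([f"v{j}" for j in range(m)], rng.uniform(1e-12, 1e-8, m))
        kept1, _ = ld_clump(cands, panel, 0.1)
        kept2, _ = ld_clump(cands.sample(frac=1, random_state=0), panel, 0.1)
        assert kept1 == kept2


class TestFilterConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("p_exposure_max: 1.0e-6\nmhc: ['6', 100, 200]\nmin_ivs: 2\n")
        cfg = FilterConfig.from_yaml(path)
        assert cfg.p_exposure_max == 1e-6 and cfg.mhc == ("6", 100, 200) and cfg.min_ivs == 2

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("nonsense: 1\n")
        with pytest.raises(ConfigurationError, match="nonsense"):
            FilterConfig.from_yaml(path)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            FilterConfig(clump_r2=0.0)


class TestBuildInstrumentSet:
    def test_clean_region_keeps_exactly_causal_snps(self, clean_region):
        rd = clean_region
        iset = build_instrument_set(
            rd.truth.protein, rd.gene, rd.exposure, rd.outcome, rd.annotation, rd.panel
        )
        assert iset.eligible
        assert set(iset.pairs["variant_id"]) == set(rd.truth.causal_snps)

    def test_audit_partitions_candidates(self, clean_region):
        rd = clean_region
        iset = build_instrument_set(
            rd.truth.protein, rd.gene, rd.exposure, rd.outcome, rd.annotation, rd.panel
        )
        assert len(iset.pairs) + len(iset.audit) == len(rd.exposure)
        assert not set(iset.pairs["variant_id"]) & set(iset.audit["variant_id"])

    def test_cascade_idempotent_on_survivors(self, clean_region):
        rd = clean_region
        iset = build_instrument_set(
            rd.truth.protein, rd.gene, rd.exposure, rd.outcome, rd.annotation, rd.panel
        )
        survivors = rd.exposure[rd.exposure["variant_id"].isin(iset.pairs["variant_id"])]
        again = build_instrument_set(
            rd.truth.protein, rd.gene, survivors, rd.outcome, rd.annotation, rd.panel
        )
        pd.testing.assert_frame_equal(
            iset.pairs.reset_index(drop=True), again.pairs.reset_index(drop=True)
        )
        assert len(again.audit) == 0

    def test_all_mhc_region_ineligible(self):
        ann = pd.DataFrame({"gene": ["HLAX"], "chrom": ["6"], "gene_start": [30_000_000]})
        exposure = make_stats(
            [
                {"variant_id": f"m{i}", "chrom": "6", "pos": 29_000_000 + i * 1000,
                 "beta": 0.5, "se": 0.05}
                for i in range(4)
            ]
        )
        outcome = exposure.assign(beta=0.01, se=0.02, n=50_000)
        panel = ReferencePanel(
            [f"m{i}" for i in range(4)],
            np.random.default_rng(0).integers(0, 3, size=(4, 50)).astype(float),
        )
        iset = build_instrument_set("P", "HLAX", exposure, outcome, ann, panel)
        assert not iset.eligible
        assert (iset.audit["drop_reason"] == "mhc_dropped").all()

    def test_unknown_gene_raises_configuration_error(self, clean_region):
        rd = clean_region
        with pytest.raises(ConfigurationError, match="NOPE"):
            build_instrument_set(
                rd.truth.protein, "NOPE", rd.exposure, rd.outcome, rd.annotation, rd.panel
            )

    def test_unmatched_outcome_variant_flagged(self, clean_region):
        rd = clean_region
        outcome = rd.outcome.iloc[1:]  # drop one variant from the outcome GWAS
        iset = build_instrument_set(
            rd.truth.protein, rd.gene, rd.exposure, outcome, rd.annotation, rd.panel
        )
        missing = set(rd.outcome["variant_id"]) - set(outcome["variant_id"])
        audit = dict(zip(iset.audit["variant_id"], iset.audit["drop_reason"]))
        assert all(audit.get(v) == "unmatched_dropped" for v in missing)


class TestHarmonizeTables:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_shuffled_outcome_orientation_recovers_effects(self, seed):
        """Random allele swaps/strand flips in the outcome table must be
        undone exactly by harmonization."""
        rng = np.random.default_rng(seed)
        exp = make_stats(
            [
                {"variant_id": f"rs{i}", "ea": ea, "oa": oa, "eaf": float(rng.uniform(0.1, 0.9)),
                 "beta": float(rng.normal(0, 0.2)) or 0.1, "se": 0.02}
                for i, (ea, oa) in enumerate([("A", "G"), ("T", "C"), ("G", "A"), ("A", "C")])
            ]
        )
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        out_rows = []
        for _, r in exp.iterrows():
            ea, oa, beta, eaf = r["ea"], r["oa"], 0.07, float(r["eaf"])
            if rng.random() < 0.5:
                ea, oa, beta, eaf = oa, ea, -beta, 1 - eaf
            if rng.random() < 0.5 and comp[ea] != oa:
                ea, oa = comp[ea], comp[oa]
            out_rows.append({"variant_id": r["variant_id"], "ea": ea, "oa": oa,
                             "eaf": eaf, "beta": beta, "se": 0.02})
        out = make_stats(out_rows)
        pairs, audit = harmonize_tables(exp, out)
        assert len(audit) == 0
        np.testing.assert_allclose(pairs["beta_out"], 0.07, rtol=1e-12)
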