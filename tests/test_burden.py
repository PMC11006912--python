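"""Consensus burden rule, LOF rule, and burden statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import equiburden as eq
from equiburden.impacts import DEFAULT_LOF_TERMS, ImpactClass, normalize_term

H, M, L, MOD = ImpactClass.HIGH, ImpactClass.MODERATE, ImpactClass.LOW, ImpactClass.MODIFIER


class TestClassifyBurden:
    @pytest.mark.parametrize(
        "se,ve,expected",
        [(H, H, True), (H, M, True), (M, H, True), (M, M, False), (L, H, False)],
    )
    def test_examples(self, se, ve, expected):
        assert eq.classify_burden(se, ve) is expected

    def test_all_16_pairs_match_membership_list(self):
        qualifying = {(H, H), (H, M), (M, H)}
        for se, ve in itertools.product(ImpactClass, repeat=2):
            assert eq.classify_burden(se, ve) == ((se, ve) in qualifying)


class TestClassifyLof:
    @pytest.mark.parametrize(
        "se,ve,expected",
        [
            ("frameshift_variant", "frameshift_variant", True),
            ("frameshift_variant", "inframe_deletion", False),
            ("missense_variant", "missense_variant", False),
            ("splice_acceptor_variant", "splice_donor_variant", True),
        ],
    )
    def test_examples(self, se, ve, expected):
        assert eq.classify_lof(se, ve) is expected

    def test_dialect_spellings_are_recognised(self):
        # the two annotators spell terms differently; membership is post-mapping
        assert eq.classify_lof("Frameshift", "frameshift_variant")
        assert eq.classify_lof("Splice acceptor", "splice_donor_variant")
        assert not eq.classify_lof("Transcript ablation", "frameshift_variant")

    def test_all_term_pairs_match_membership_oracle(self):
        vocab = [
            "frameshift_variant", "splice_acceptor_variant", "splice_donor_variant",
            "start_lost", "stop_lost", "stop_gained", "missense_variant",
            "inframe_deletion", "transcript_ablation", "exon_loss_variant",
            "Frameshift", "Splice donor", "Stop gained",
        ]
        for se, ve in itertools.product(vocab, repeat=2):
            oracle = (
                normalize_term(se) in DEFAULT_LOF_TERMS
                and normalize_term(ve) in DEFAULT_LOF_TERMS
            )
            assert eq.classify_lof(se, ve) == oracle


def _random_calls(rng, n):
    labels = [i.name for i in ImpactClass]
    return pd.DataFrame(
        {
            "snpeff_impact": rng.choice(labels, size=n),
            "vep_impact": rng.choice(labels, size=n),
        }
    )


class TestImpactCrosstab:
    def test_small_example(self):
        calls = pd.DataFrame(
            {
                "snpeff_impact": ["HIGH", "MODERATE", "LOW"],
                "vep_impact": ["HIGH", "HIGH", "LOW"],
            }
        )
        tab = eq.impact_crosstab(calls)
        assert tab.loc["HIGH", "HIGH"] == 1
        assert tab.loc["MODERATE", "HIGH"] == 1
        assert tab.loc["LOW", "LOW"] == 1
        assert tab.to_numpy().sum() == 3

    def test_empty_input_is_all_zero(self):
        tab = eq.impact_crosstab(pd.DataFrame(columns=["snpeff_impact", "vep_impact"]))
        assert (tab.to_numpy() == 0).all()

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(42)
        calls = _random_calls(rng, 500)
        tab = eq.impact_crosstab(calls)
        # independent oracle: direct pair counting
        for se in tab.index:
            for ve in tab.columns:
                expected = int(
                    ((calls["snpeff_impact"] == se) & (calls["vep_impact"] == ve)).sum()
                )
                assert tab.loc[se, ve] == expected
        assert tab.to_numpy().sum() == len(calls)


class TestSiteAlleleFrequency:
    def test_single_het_among_605(self):
        codes = np.zeros(605, dtype=np.int8)
        codes[0] = 1
        f = eq.site_allele_frequency(codes)
        assert f.alt_count == 1 and f.called_alleles == 1210
        assert f.vf == pytest.approx(1 / 1210)

    def test_one_hom_alt_of_ten(self):
        codes = np.zeros(10, dtype=np.int8)
        codes[3] = 2
        assert eq.site_allele_frequency(codes).vf == pytest.approx(0.10)

    def test_missing_shrinks_denominator(self):
        f = eq.site_allele_frequency(np.array([1, -1, 2, 0], dtype=np.int8))
        assert f.vf == pytest.approx(3 / 6)
        assert f.maf == pytest.approx(0.5)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            eq.site_allele_frequency(np.array([-1, -1], dtype=np.int8))


class TestPerSampleBurden:
    def test_counts_and_private(self, small_cohort):
        calls = eq.build_burden_calls(small_cohort)
        psb = eq.per_sample_burden(small_cohort, calls)
        m = small_cohort.genotype_matrix()
        # one sample checked against direct counting
        j = 5
        carried = m[:, j] >= 1
        assert psb.loc[j, "n_variants"] == int(carried.sum())
        sole = (m >= 1).sum(axis=1) == 1
        assert psb.loc[j, "n_private"] == int((carried & sole).sum())
        # structural invariants
        assert (psb["n_burden_hom"] <= psb["n_burden"]).all()
        assert (psb["n_lof_hom"] <= psb["n_lof"]).all()
        assert (psb["n_lof"] <= psb["n_burden"]).all()
        assert (psb["n_private"] <= psb["n_variants"]).all()

    def test_no_alt_sample_counts_zero(self, tmp_path):
        from conftest import ann, csq, metadata_for, write_vcf

        body = "\n".join(
            f"1\t{100+i}\t.\tG\tA\t.\t.\tANN={ann('A','stop_gained','HIGH')};CSQ={csq('A','stop_gained','HIGH')}\tGT\t0/1\t0/0"
            for i in range(3)
        )
        cohort = eq.read_cohort_vcf(write_vcf(tmp_path / "z.vcf", body), metadata_for(["S1", "S2"]))
        calls = eq.build_burden_calls(cohort)
        psb = eq.per_sample_burden(cohort, calls).set_index("sample_id")
        assert psb.loc["S1", "n_burden"] == 3
        assert psb.loc["S1", "n_private"] == 3
        assert (psb.loc["S2"] == 0).all()


class TestBurdenSummary:
    def test_single_burden_variant_fraction(self):
        calls = pd.DataFrame(
            {
                "variant_class": ["SNP"],
                "is_burden": [True],
                "is_lof": [True],
            }
        )
        freqs = pd.DataFrame({"vf": [0.01]})
        s = eq.burden_summary(calls, freqs)
        assert s["burden_fraction"] == 1.0
        assert s["n_burden"] == 1

    def test_fraction_and_split(self, small_cohort):
        calls = eq.build_burden_calls(small_cohort)
        freqs = eq.variant_frequencies(small_cohort)
        s = eq.burden_summary(calls, freqs)
        assert s["n_snp"] + s["n_indel"] == s["n_variants"]
        assert s["n_burden_snp"] + s["n_burden_indel"] == s["n_burden"]
        assert s["burden_fraction"] == pytest.approx(s["n_burden"] / s["n_variants"])

    def test_burden_vf_below_non_burden_vf(self, small_cohort):
        # purifying selection: deleterious sites are rarer than neutral ones
        calls = eq.build_burden_calls(small_cohort)
        freqs = eq.variant_frequencies(small_cohort)
        s = eq.burden_summary(calls, freqs)
        assert s["vf_burden"]["median"] < s["vf_non_burden"]["median"]


class TestTypeConcordance:
    def test_small_example(self):
        calls = pd.DataFrame(
            {
                "snpeff_term": ["frameshift_variant", "frameshift_variant"],
                "vep_term": ["frameshift_variant", "stop_gained"],
                "is_burden": [True, True],
                "type_concordant": [True, False],
            }
        )
        c = eq.type_concordance(calls)
        assert c["n_concordant"] == 1 and c["n_discordant"] == 1
        assert c["n_concordant"] + c["n_discordant"] == c["n_burden"]

    def test_conservation_on_cohort(self, small_cohort):
        calls = eq.build_burden_calls(small_cohort)
        c = eq.type_concordance(calls)
        assert c["n_concordant"] + c["n_discordant"] == int(calls["is_burden"].sum())
        assert c["pairs"]["count"].sum() == c["n_burden"]


class TestAggregateByGene:
    def test_median_of_three_variants(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["G1"] * 3,
                "hgnc_symbol": [None] * 3,
                "is_burden": [True] * 3,
                "is_lof": [False] * 3,
            }
        )
        freqs = pd.DataFrame({"vf": [0.001, 0.002, 0.003]})
        agg, unassigned = eq.aggregate_by_gene(calls, freqs)
        assert unassigned == 0
        assert agg.loc[0, "n_burden_variants"] == 3
        assert agg.loc[0, "median_vf"] == pytest.approx(0.002)

    def test_matches_group_and_summarize_oracle(self, small_cohort):
        calls = eq.build_burden_calls(small_cohort)
        freqs = eq.variant_frequencies(small_cohort)
        agg, unassigned = eq.aggregate_by_gene(calls, freqs)
        b = calls[calls["is_burden"]].copy()
        b["vf"] = freqs.loc[b.index, "vf"]
        # independent oracle: per-gene loops
        for gene, grp in b.dropna(subset=["gene_id"]).groupby("gene_id"):
            row = agg[agg["gene_id"] == gene].iloc[0]
            assert row["n_burden_variants"] == len(grp)
            assert row["n_lof_variants"] == int(grp["is_lof"].sum())
            assert row["max_vf"] == pytest.approx(grp["vf"].max())
            assert row["mean_vf"] == pytest.approx(grp["vf"].mean())
        # conservation: genes + unassigned = burden total
        assert agg["n_burden_variants"].sum() + unassigned == int(calls["is_burden"].sum())


class TestSelectGeneSets:
    def _agg(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "n_burden_variants", "mean_vf", "max_vf"]
        )

    def test_strict_count_threshold(self):
        agg = self._agg([("G6", 6, 0.01, 0.01), ("G5", 5, 0.01, 0.01)])
        multi, _ = eq.select_gene_sets(agg)
        assert multi == ["G6"]

    def test_any_mode_uses_single_high_frequency_variant(self):
        agg = self._agg([("G1", 1, 0.06, 0.06), ("G2", 1, 0.03, 0.04)])
        _, high = eq.select_gene_sets(agg, vf_mode="any")
        assert high == ["G1"]

    def test_mean_mode_switch(self):
        agg = self._agg([("G1", 2, 0.04, 0.08)])
        _, high_any = eq.select_gene_sets(agg, vf_mode="any")
        _, high_mean = eq.select_gene_sets(agg, vf_mode="mean")
        assert high_any == ["G1"] and high_mean == []

    def test_all_below_both_thresholds(self):
        agg = self._agg([("G1", 2, 0.01, 0.02)])
        multi, high = eq.select_gene_sets(agg)
        assert multi == [] and high == []


def test_lof_subset_of_burden_everywhere(small_cohort):
    calls = eq.build_burden_calls(small_cohort)
    assert (calls.loc[calls["is_lof"], "is_burden"]).all()


def test_crosstab_burden_total_identity(small_cohort):
    calls = eq.build_burden_calls(small_cohort)
    tab = eq.impact_crosstab(calls)
    assert eq.burden_total_from_crosstab(tab) == int(calls["is_burden"].sum())
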