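"""Annotated-VCF ingestion: parsing, decomposition, primary selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import equiburden as eq
from equiburden.impacts import ImpactClass, severity_rank
from equiburden.vcf_io import ConsequenceAnnotation

from conftest import ANN_FIELDS, ann, csq, metadata_for, write_vcf


class TestReadCohortVcf:
    def test_biallelic_snp_genotype_codes(self, tmp_path):
        body = f"1\t100\t.\tG\tA\t.\t.\tANN={ann('A','missense_variant','MODERATE')};CSQ={csq('A','missense_variant','MODERATE')}\tGT\t0/1\t1/1"
        path = write_vcf(tmp_path / "a.vcf", body)
        cohort = eq.read_cohort_vcf(path, metadata_for(["S1", "S2"]))
        assert len(cohort.records) == 1
        assert cohort.records[0].genotypes.codes.tolist() == [1, 2]

    def test_multiallelic_decomposed_per_alt(self, tmp_path):
        info = (
            f"ANN={ann('A','missense_variant','MODERATE')},{ann('T','stop_gained','HIGH')};"
            f"CSQ={csq('A','missense_variant','MODERATE')},{csq('T','stop_gained','HIGH')}"
        )
        body = f"1\t100\t.\tG\tA,T\t.\t.\t{info}\tGT\t1/2\t0/1"
        cohort = eq.read_cohort_vcf(
            write_vcf(tmp_path / "m.vcf", body), metadata_for(["S1", "S2"])
        )
        assert len(cohort.records) == 2
        rec_a = next(r for r in cohort.records if r.alt == "A")
        rec_t = next(r for r in cohort.records if r.alt == "T")
        assert rec_a.genotypes.codes.tolist() == [1, 1]
        assert rec_t.genotypes.codes.tolist() == [1, 0]
        # annotations routed per allele
        assert rec_a.snpeff_annotations[0].term == "missense_variant"
        assert rec_t.snpeff_annotations[0].term == "stop_gained"

    def test_decomposition_conserves_allele_dosage(self, tmp_path):
        # 3 samples at a triallelic site: dosage of each alt is preserved
        info = (
            f"ANN={ann('A','missense_variant','MODERATE')},{ann('T','stop_gained','HIGH')};"
            f"CSQ={csq('A','missense_variant','MODERATE')},{csq('T','stop_gained','HIGH')}"
        )
        body = f"1\t100\t.\tG\tA,T\t.\t.\t{info}\tGT\t1/1\t1/2\t2/2"
        cohort = eq.read_cohort_vcf(
            write_vcf(tmp_path / "d.vcf", body, samples=("S1", "S2", "S3")),
            metadata_for(["S1", "S2", "S3"]),
        )
        dosage = {
            r.alt: int((r.genotypes.codes == 1).sum() + 2 * (r.genotypes.codes == 2).sum())
            for r in cohort.records
        }
        assert dosage == {"A": 3, "T": 3}  # 1/1 + 1/2 -> A:3; 1/2 + 2/2 -> T:3

    def test_long_indel_excluded_and_counted(self, tmp_path):
        ref = "G" + "A" * 25
        body = f"1\t100\t.\t{ref}\tG\t.\t.\tANN={ann('G','frameshift_variant','HIGH')};CSQ={csq('G','frameshift_variant','HIGH')}\tGT\t0/1\t0/0"
        cohort = eq.read_cohort_vcf(write_vcf(tmp_path / "l.vcf", body), metadata_for(["S1", "S2"]))
        assert len(cohort.records) == 0
        assert cohort.n_excluded_long_indels == 1

    def test_half_call_treated_as_missing(self, tmp_path):
        body = f"1\t100\t.\tG\tA\t.\t.\tANN={ann('A','missense_variant','MODERATE')};CSQ={csq('A','missense_variant','MODERATE')}\tGT\t./1\t0/1"
        cohort = eq.read_cohort_vcf(write_vcf(tmp_path / "h.vcf", body), metadata_for(["S1", "S2"]))
        assert cohort.records[0].genotypes.codes.tolist() == [-1, 1]

    def test_missing_ann_header_is_fatal(self, tmp_path):
        from conftest import CSQ_HEADER

        path = tmp_path / "no_ann.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n" + CSQ_HEADER + "\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
        )
        with pytest.raises(eq.VcfFormatError, match="ANN"):
            eq.read_cohort_vcf(path, metadata_for(["S1"]))

    def test_sample_absent_from_metadata_is_fatal(self, tmp_path):
        body = f"1\t100\t.\tG\tA\t.\t.\tANN={ann('A','missense_variant','MODERATE')};CSQ={csq('A','missense_variant','MODERATE')}\tGT\t0/1\t1/1"
        path = write_vcf(tmp_path / "s.vcf", body)
        with pytest.raises(eq.VcfFormatError, match="S2"):
            eq.read_cohort_vcf(path, metadata_for(["S1"]))


class TestParseSnpeffAnn:
    def test_direct_field_mapping(self):
        text = "A|stop_gained|HIGH|GENE1|ENSECAG001|transcript|T1"
        (a,) = eq.parse_snpeff_ann(text, ANN_FIELDS)
        assert a.term == "stop_gained"
        assert a.impact is ImpactClass.HIGH
        assert a.gene_id == "ENSECAG001"
        assert a.hgnc_symbol == "GENE1"

    def test_blocks_get_sequential_ranks(self):
        text = (
            "A|stop_gained|HIGH|G1|E1|transcript|T1,"
            "A|missense_variant|MODERATE|G1|E1|transcript|T2"
        )
        anns = eq.parse_snpeff_ann(text, ANN_FIELDS)
        assert [a.rank_in_field for a in anns] == [0, 1]

    def test_compound_term_uses_first(self):
        text = "A|splice_donor_variant&intron_variant|HIGH|G1|E1|transcript|T1"
        (a,) = eq.parse_snpeff_ann(text, ANN_FIELDS)
        assert a.term == "splice_donor_variant"
        assert a.terms == ("splice_donor_variant", "intron_variant")

    def test_wrong_pipe_count_error_carries_block_index(self):
        text = "A|stop_gained|HIGH|G1|E1|transcript|T1,A|missense_variant|MODERATE"
        with pytest.raises(eq.AnnotationParseError) as err:
            eq.parse_snpeff_ann(text, ANN_FIELDS)
        assert err.value.block_index == 1


class TestParseVepCsq:
    DESC = "Allele|Consequence|IMPACT|SYMBOL|Gene"

    def test_columns_located_by_name(self):
        (a,) = eq.parse_vep_csq("A|missense_variant|MODERATE|MYOT|ENSECAG002", self.DESC)
        assert a.term == "missense_variant"
        assert a.impact is ImpactClass.MODERATE
        assert a.gene_id == "ENSECAG002"
        assert a.hgnc_symbol == "MYOT"

    def test_missing_impact_column_is_fatal(self):
        with pytest.raises(eq.VcfFormatError, match="IMPACT"):
            eq.parse_vep_csq("A|missense_variant", "Allele|Consequence")

    def test_short_block_error_carries_index(self):
        with pytest.raises(eq.AnnotationParseError) as err:
            eq.parse_vep_csq("A|missense_variant|MODERATE|MYOT|E2,A|stop_gained|HIGH", self.DESC)
        assert err.value.block_index == 1


def _mk(term, impact, rank):
    return ConsequenceAnnotation(
        annotator="snpeff", allele="A", terms=(term,), impact=impact, rank_in_field=rank
    )


class TestSelectPrimaryAnnotation:
    def test_most_severe_impact_wins(self):
        chosen = eq.select_primary_annotation(
            [_mk("missense_variant", ImpactClass.MODERATE, 0), _mk("stop_gained", ImpactClass.HIGH, 1)]
        )
        assert chosen.term == "stop_gained"

    def test_single_annotation_is_identity(self):
        a = _mk("missense_variant", ImpactClass.MODERATE, 0)
        assert eq.select_primary_annotation([a]) is a

    def test_custom_severity_table_breaks_impact_ties(self):
        table = {"frameshift_variant": 0, "stop_gained": 1}
        chosen = eq.select_primary_annotation(
            [_mk("stop_gained", ImpactClass.HIGH, 0), _mk("frameshift_variant", ImpactClass.HIGH, 1)],
            severity_table=table,
        )
        assert chosen.term == "frameshift_variant"

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            eq.select_primary_annotation([])

    @settings(max_examples=300, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(
                    ["stop_gained", "frameshift_variant", "missense_variant",
                     "synonymous_variant", "intron_variant", "made_up_term"]
                ),
                st.sampled_from(list(ImpactClass)),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_matches_bruteforce_oracle(self, pairs):
        anns = [_mk(t, i, r) for r, (t, i) in enumerate(pairs)]
        # independent oracle: explicit max-by-key over all annotations
        oracle = max(anns, key=lambda a: (int(a.impact), -severity_rank(a.term), -a.rank_in_field))
        assert eq.select_primary_annotation(anns) is oracle


class TestRoundTrip:
    def test_write_then_reread_is_lossless(self, small_cohort, tmp_path):
        out = tmp_path / "rt.vcf"
        eq.write_cohort_vcf(small_cohort, out)
        again = eq.read_cohort_vcf(out, small_cohort.metadata)
        assert len(again.records) == len(small_cohort.records)
        for a, b in zip(again.records, small_cohort.records):
            assert a == b

    def test_simulated_ann_csq_round_trip_through_parsers(self, small_sim, small_cohort):
        # generated labels survive the VCF text -> parser path without loss
        st = small_sim.site_table
        got = eq.primary_annotation_table(small_cohort)
        assert list(got["snpeff_term"]) == list(st["snpeff_term"])
        assert list(got["vep_impact"]) == list(st["vep_impact"])


def test_primary_annotation_table_shape(small_cohort):
    df = eq.primary_annotation_table(small_cohort)
    assert list(df.columns) == [
        "chrom", "pos", "ref", "alt",
        "snpeff_term", "snpeff_impact", "vep_term", "vep_impact", "gene_id",
    ]
    assert len(df) == len(small_cohort.records)
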