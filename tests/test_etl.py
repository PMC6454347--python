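"""MAF/VCF/clinical loading: dialect handling, skips, conservation."""

import pytest

from varcdm import schema
from varcdm.etl import (
    AnnotationConfig,
    MafFormatError,
    PanelDefinition,
    load_clinical,
    load_maf,
    load_vcf,
    read_maf,
    vcf_to_maf_coordinates,
)
from varcdm.schema import init_database, insert_records, validate_database
from varcdm.synthetic import table1_fixture

from conftest import MAF_HEADER, maf_line, make_cohort


def _variant_multiset(db):
    """Variant rows up to surrogate keys (for multiset comparisons)."""
    rows = db.fetch_table("variant_occurrence")
    gene_of = {r["target_gene_id"]: r["hgnc_symbol"]
               for r in db.fetch_table("target_gene")}
    person_of = {r["procedure_id"]: r["person_id"]
                 for r in db.fetch_table("procedure_occurrence")}
    return sorted(
        (person_of[r["procedure_id"]], gene_of[r["target_gene_id"]],
         r["hgvs_p"], r["variant_feature"], r["sequence_alteration"])
        for r in rows
    )


class TestReadMaf:
    def test_reads_three_records_and_skips_comments(self, tiny_maf):
        reader = read_maf(tiny_maf)
        records = list(reader)
        assert len(records) == 3
        assert reader.comments == ["#version 2.4"]
        assert records[0].hugo_symbol == "EGFR"
        assert records[0].read_depth == 200

    def test_column_matching_is_case_insensitive(self, tmp_path):
        path = tmp_path / "odd.maf"
        path.write_text(
            "HUGO_SYMBOL\tvariant_classification\tTumor_Sample_Barcode\n"
            "EGFR\tMissense_Mutation\tS1\n"
        )
        records = list(read_maf(path))
        assert records[0].hugo_symbol == "EGFR"

    def test_missing_mandatory_column_is_an_error(self, tmp_path):
        path = tmp_path / "broken.maf"
        path.write_text("Hugo_Symbol\tTumor_Sample_Barcode\nEGFR\tS1\n")
        with pytest.raises(MafFormatError, match="variant_classification"):
            read_maf(path)


class TestLoadMaf:
    @pytest.fixture
    def db(self, empty_db):
        make_cohort(empty_db, 3)
        return empty_db

    def test_mapped_features_and_expanded_hgvs(self, db, tiny_maf, small_panel):
        report = load_maf(db, read_maf(tiny_maf), small_panel,
                          {"S1": 1, "S2": 2})
        assert report.rows_read == 3
        assert report.rows_loaded == 3
        rows = db.fetch_table("variant_occurrence")
        stored = {(r["hgvs_p"], r["variant_feature"], r["sequence_alteration"])
                  for r in rows}
        assert ("p.Leu858Arg", "missense", "SNP") in stored
        assert ("p.Gly12Cys", "missense", "SNP") in stored
        assert ("p.Pro72ArgfsTer5", "frameshift", "deletion") in stored
        assert validate_database(db) == []

    def test_off_panel_gene_skipped_with_reason(self, db, tmp_path, small_panel):
        path = tmp_path / "m.maf"
        path.write_text("\n".join([
            MAF_HEADER,
            maf_line("TTN", "Missense_Mutation", "SNP", "p.A1V", "S1"),
            maf_line("EGFR", "Missense_Mutation", "SNP", "p.L858R", "S1"),
        ]) + "\n")
        report = load_maf(db, read_maf(path), small_panel, {"S1": 1})
        assert report.rows_loaded == 1
        assert report.skip_reasons == {"off_panel": 1}

    def test_unmapped_patient_skipped(self, db, tiny_maf, small_panel):
        report = load_maf(db, read_maf(tiny_maf), small_panel, {"S1": 1})
        assert report.skip_reasons.get("unmapped_patient") == 1
        assert report.rows_read == report.rows_loaded + report.rows_skipped

    def test_one_sample_per_patient(self, db, tmp_path, small_panel):
        path = tmp_path / "dup.maf"
        path.write_text("\n".join([
            MAF_HEADER,
            maf_line("EGFR", "Missense_Mutation", "SNP", "p.L858R", "S1b"),
            maf_line("KRAS", "Missense_Mutation", "SNP", "p.G12C", "S1a"),
            maf_line("TP53", "Missense_Mutation", "SNP", "p.R175H", "S1a"),
        ]) + "\n")
        # both barcodes belong to patient 1: lexicographically first wins
        report = load_maf(db, read_maf(path), small_panel,
                          {"S1a": 1, "S1b": 1})
        assert report.rows_loaded == 2
        assert report.skip_reasons == {"duplicate_sample": 1}

    def test_conservation_and_projection_commute(self, db, tmp_path, small_panel):
        """Loading then panel-filtering equals filtering the stream first."""
        lines = [MAF_HEADER]
        genes = ["EGFR", "TTN", "KRAS", "MUC16", "TP53", "BRAF", "OR4F5"]
        for i, g in enumerate(genes):
            lines.append(maf_line(g, "Missense_Mutation", "SNP",
                                  f"p.A{i + 10}V", "S1"))
        path = tmp_path / "mix.maf"
        path.write_text("\n".join(lines) + "\n")

        report = load_maf(db, read_maf(path), small_panel, {"S1": 1})
        assert report.rows_read == report.rows_loaded + report.rows_skipped
        assert report.rows_loaded == db.table_count("variant_occurrence")

        db2 = init_database(":memory:")
        make_cohort(db2, 3)
        panel_set = set(small_panel.genes)
        prefiltered = [r for r in read_maf(path) if r.hugo_symbol in panel_set]
        load_maf(db2, prefiltered, small_panel, {"S1": 1})
        assert _variant_multiset(db) == _variant_multiset(db2)


VCF_TEXT = """##fileformat=VCFv4.2
##INFO=<ID=ANN,Number=.,Type=String,Description="gene|consequence|hgvs_c|hgvs_p">
##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">
##contig=<ID=7>
##contig=<ID=12>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
7\t55259515\trs121434568\tT\tG\t60\tPASS\tANN=EGFR|missense_variant|c.2573T>G|p.L858R;DP=433
12\t100\t.\tAT\tA\t50\t.\tANN=KRAS|frameshift_variant|c.35del|;DP=120
7\t200\t.\tG\tA\t10\tq10\tANN=EGFR|missense_variant||p.A2V;DP=5
"""


class TestLoadVcf:
    @pytest.fixture
    def vcf_path(self, tmp_path):
        path = tmp_path / "sample.vcf"
        path.write_text(VCF_TEXT)
        return path

    def test_pass_records_loaded_filter_failed_skipped(self, empty_db,
                                                       vcf_path, small_panel):
        make_cohort(empty_db, 1)
        report = load_vcf(empty_db, vcf_path, small_panel, person_id=1)
        assert report.rows_loaded == 2
        assert report.skip_reasons == {"filter_failed": 1}
        rows = empty_db.fetch_table("variant_occurrence")
        snv = next(r for r in rows if r["hgvs_p"] == "p.Leu858Arg")
        assert snv["read_depth"] == 433
        assert snv["rs_id"] == "rs121434568"
        assert (snv["genomic_start"], snv["genomic_end"]) == (55259515, 55259515)
        deletion = next(r for r in rows if r["sequence_alteration"] == "deletion")
        assert (deletion["genomic_start"], deletion["genomic_end"]) == (101, 101)
        assert validate_database(empty_db) == []

    def test_missing_annotation_subfields_rejected(self, empty_db, vcf_path,
                                                   small_panel):
        make_cohort(empty_db, 1)
        with pytest.raises(MafFormatError, match="consequence"):
            load_vcf(empty_db, vcf_path, small_panel, person_id=1,
                     annotation=AnnotationConfig(subfields=("gene",)))


@pytest.mark.parametrize("pos,ref,alt,expected", [
    # hand-converted VCF -> 1-based-inclusive cases
    (100, "AT", "A", (101, 101, "deletion")),
    (100, "ATTC", "A", (101, 103, "deletion")),
    (100, "A", "AT", (100, 101, "insertion")),
    (100, "A", "AGGG", (100, 101, "insertion")),
    (100, "C", "T", (100, 100, "SNP")),
    (100, "CA", "TG", (100, 101, "MNP")),
])
def test_vcf_indel_coordinate_conversion(pos, ref, alt, expected):
    assert vcf_to_maf_coordinates(pos, ref, alt) == expected


class TestLoadClinical:
    def test_table1_fixture_round_trips_through_csv(self, tmp_path):
        source = table1_fixture("ausom_like")
        dump_dir = tmp_path / "dump"
        schema.dump_csv(source, dump_dir)
        db = init_database(":memory:")
        report = load_clinical(db, {
            "person": dump_dir / "person.tsv",
            "condition_occurrence": dump_dir / "condition_occurrence.tsv",
        })
        assert db.table_count("person") == 114
        assert db.table_count("condition_occurrence") == 114
        assert report.rows_read == report.rows_loaded + report.rows_skipped

    def test_invalid_rows_skipped_with_reason(self, tmp_path):
        person_tsv = tmp_path / "person.tsv"
        person_tsv.write_text(
            "person_id\tgender\tage_years\trace\n"
            "1\tmale\t63\t\n"
            "2\tfemale\t-3\t\n"     # impossible age
            "3\tdroid\t40\t\n"      # vocabulary violation
        )
        db = init_database(":memory:")
        report = load_clinical(db, {"person": person_tsv})
        assert report.rows_loaded == 1
        assert report.skip_reasons == {"invariant_violation": 2}

    def test_empty_condition_file_is_fine(self, tmp_path):
        cond = tmp_path / "condition_occurrence.tsv"
        cond.write_text("condition_id\tperson_id\tcondition_name\t"
                        "condition_type\tstage\n")
        db = init_database(":memory:")
        report = load_clinical(db, {"condition_occurrence": cond})
        assert report.rows_read == 0
        assert report.rows_loaded == 0
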