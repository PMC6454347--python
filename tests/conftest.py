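"""Shared fixtures: tiny in-memory cohorts and text-format variant files."""

from __future__ import annotations

import pytest

from varcdm import schema
from varcdm.etl import PanelDefinition
from varcdm.schema import (
    CohortDB,
    PersonRecord,
    init_database,
    insert_records,
)


@pytest.fixture
def empty_db() -> CohortDB:
    db = init_database(":memory:")
    yield db
    db.close()


@pytest.fixture
def small_panel() -> PanelDefinition:
    return PanelDefinition(
        genes=["EGFR", "KRAS", "TP53", "BRAF", "PIK3CA"],
        test_name="mini_panel",
    )


def make_cohort(db: CohortDB, n_patients: int) -> None:
    """Persons 1..n with procedure and target specimen of the same id."""
    insert_records(db, "person", [
        PersonRecord(person_id=i, gender="male" if i % 2 else "female",
                     age_years=50 + i)
        for i in range(1, n_patients + 1)
    ])
    insert_records(db, "procedure_occurrence", [
        schema.ProcedureRecord(procedure_id=i, person_id=i)
        for i in range(1, n_patients + 1)
    ])
    insert_records(db, "specimen", [
        schema.SpecimenRecord(specimen_id=i, person_id=i, specimen_role="target")
        for i in range(1, n_patients + 1)
    ])


@pytest.fixture
def cohort_db(empty_db, small_panel) -> CohortDB:
    """Ten patients with the mini panel registered; no variants yet."""
    from varcdm.etl import register_panel

    make_cohort(empty_db, 10)
    _, gene_ids = register_panel(empty_db, small_panel)
    empty_db.gene_ids = gene_ids  # convenience for tests
    return empty_db


def add_variant(db: CohortDB, person_id: int, gene: str, *,
                hgvs_p: str | None = None,
                feature: str = "missense",
                alteration: str = "SNP") -> int:
    """Insert one variant for a patient; returns the new id."""
    vid = db.max_id("variant_occurrence") + 1
    insert_records(db, "variant_occurrence", [
        schema.VariantOccurrenceRecord(
            variant_occurrence_id=vid,
            procedure_id=person_id,
            specimen_id_target=person_id,
            target_gene_id=db.gene_ids[gene],
            hgvs_p=hgvs_p,
            sequence_alteration=alteration,
            variant_feature=feature,
        )
    ])
    return vid


MAF_HEADER = (
    "Hugo_Symbol\tVariant_Classification\tVariant_Type\tHGVSp_Short\t"
    "Chromosome\tStart_Position\tEnd_Position\tdbSNP_RS\t"
    "Tumor_Sample_Barcode\tt_depth"
)


def maf_line(gene: str, classification: str, vtype: str, hgvs_p: str,
             barcode: str, start: int = 100, end: int = 100,
             depth: int = 200) -> str:
    return (f"{gene}\t{classification}\t{vtype}\t{hgvs_p}\t1\t{start}\t{end}"
            f"\t\t{barcode}\t{depth}")


@pytest.fixture
def tiny_maf(tmp_path):
    """Three-record MAF with a comment line; two patients, panel genes."""
    lines = [
        "#version 2.4",
        MAF_HEADER,
        maf_line("EGFR", "Missense_Mutation", "SNP", "p.L858R", "S1"),
        maf_line("KRAS", "Missense_Mutation", "SNP", "p.G12C", "S2"),
        maf_line("TP53", "Frame_Shift_Del", "DEL", "p.P72Rfs*5", "S1"),
    ]
    path = tmp_path / "tiny.maf"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
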