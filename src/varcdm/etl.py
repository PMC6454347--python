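"""ETL: MAF, annotated VCF and clinical CSV -> validated cohort database.

The loaders share one internal convention: 1-based inclusive genomic
coordinates (the MAF convention); VCF-style indel coordinates are
converted on the way in.  Panel restriction — keeping only variants in the
genes a targeted test covers — happens here, mirroring how a
whole-exome cohort is made comparable to a gene-panel cohort.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping

from . import schema
from .nomenclature import (
    FeatureMapping,
    HgncTable,
    HgvsParseError,
    UnknownGeneError,
    expand_protein_hgvs,
    load_default_feature_mapping,
    load_default_hgnc,
    map_consequence,
    normalize_gene_symbol,
)
from .schema import CohortDB, insert_records

logger = logging.getLogger(__name__)

__all__ = [
    "MafRecord",
    "MafFormatError",
    "PanelDefinition",
    "LoadReport",
    "AnnotationConfig",
    "read_maf",
    "load_maf",
    "load_vcf",
    "load_clinical",
    "register_panel",
    "load_default_panel",
]


class MafFormatError(ValueError):
    """Input file violates the expected dialect (e.g. missing columns)."""


@dataclass
class MafRecord:
    """One somatic variant call from a MAF row (cBioPortal/TCGA dialect)."""

    hugo_symbol: str
    variant_classification: str
    tumor_sample_barcode: str
    variant_type: str = ""
    hgvs_p_short: str = ""
    hgvs_c: str = ""
    chromosome: str = ""
    start: int | None = None
    end: int | None = None
    dbsnp_rs: str = ""
    read_depth: int | None = None


@dataclass
class PanelDefinition:
    """A targeted test: metadata plus the ordered list of HGNC symbols."""

    genes: list[str]
    test_name: str = "panel"
    test_version: str = "1.0"
    sequencing_device: str | None = None
    analytical_tools: str | None = None
    reference_databases: str | None = None
    reference_genome_build: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelDefinition":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(
            genes=list(raw["genes"]),
            test_name=raw.get("test_name", "panel"),
            test_version=raw.get("test_version", "1.0"),
            sequencing_device=raw.get("sequencing_device"),
            analytical_tools=raw.get("analytical_tools"),
            reference_databases=raw.get("reference_databases"),
            reference_genome_build=raw.get("reference_genome_build"),
        )

    def canonical_genes(self, hgnc: HgncTable) -> list[tuple[str, str]]:
        """Canonicalized (symbol, hgnc_id) pairs; duplicates after
        canonicalization are an error."""
        seen: dict[str, str] = {}
        out: list[tuple[str, str]] = []
        for symbol in self.genes:
            canonical, hgnc_id = normalize_gene_symbol(symbol, hgnc)
            if canonical in seen:
                raise ValueError(
                    f"panel genes {seen[canonical]!r} and {symbol!r} both "
                    f"canonicalize to {canonical!r}"
                )
            seen[canonical] = symbol
            out.append((canonical, hgnc_id))
        return out


def load_default_panel() -> PanelDefinition:
    """The bundled 49-gene lung-cancer panel."""
    from importlib import resources

    ref = resources.files("varcdm.assets").joinpath("panel_49.json")
    with resources.as_file(ref) as path:
        return PanelDefinition.from_json(path)


@dataclass
class LoadReport:
    """Accounting for one load: every input row is either loaded or
    skipped with a reason, so rows_read == rows_loaded + rows_skipped."""

    rows_read: int = 0
    rows_loaded: int = 0
    skip_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def rows_skipped(self) -> int:
        return sum(self.skip_reasons.values())

    def skip(self, reason: str) -> None:
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows_read": self.rows_read,
                "rows_loaded": self.rows_loaded,
                "rows_skipped": self.rows_skipped,
                "skip_reasons": dict(sorted(self.skip_reasons.items())),
            },
            sort_keys=True,
        )


# --- MAF --------------------------------------------------------------------

_MAF_COLUMNS = {
    "hugo_symbol": "hugo_symbol",
    "variant_classification": "variant_classification",
    "variant_type": "variant_type",
    "hgvsp_short": "hgvs_p_short",
    "hgvsp": "hgvs_p_short",
    "hgvsc": "hgvs_c",
    "chromosome": "chromosome",
    "start_position": "start",
    "end_position": "end",
    "dbsnp_rs": "dbsnp_rs",
    "tumor_sample_barcode": "tumor_sample_barcode",
    "t_depth": "read_depth",
}
_MAF_MANDATORY = ("hugo_symbol", "variant_classification", "tumor_sample_barcode")


class MafReader:
    """Streaming MAF reader: iterate to get :class:`MafRecord` objects;
    ``comments`` holds the '#' header lines seen before the column row."""

    def __init__(self, path: str | Path):
        self.path = str(path)
        self.comments: list[str] = []
        self._fh = open(path, encoding="utf-8", newline="")
        header: list[str] | None = None
        for line in self._fh:
            if line.startswith("#"):
                self.comments.append(line.rstrip("\n"))
                continue
            header = line.rstrip("\n").split("\t")
            break
        if header is None:
            self._fh.close()
            raise MafFormatError(f"{path}: no column header found")
        self.columns = header
        self._index: dict[str, int] = {}
        for i, name in enumerate(header):
            key = name.strip().lower()
            if key in _MAF_COLUMNS and _MAF_COLUMNS[key] not in self._index:
                self._index[_MAF_COLUMNS[key]] = i
        missing = [
            m for m in _MAF_MANDATORY
            if _MAF_COLUMNS.get(m, m) not in self._index
        ]
        if missing:
            self._fh.close()
            raise MafFormatError(
                f"{path}: missing mandatory MAF columns: {', '.join(sorted(missing))}"
            )

    def _get(self, row: list[str], field_name: str) -> str:
        i = self._index.get(field_name)
        if i is None or i >= len(row):
            return ""
        return row[i].strip()

    def __iter__(self) -> Iterator[MafRecord]:
        for line in self._fh:
            if not line.strip() or line.startswith("#"):
                continue
            row = line.rstrip("\n").split("\t")
            barcode = self._get(row, "tumor_sample_barcode")
            if not barcode:
                raise MafFormatError(f"{self.path}: empty Tumor_Sample_Barcode")

            def opt_int(name: str) -> int | None:
                raw = self._get(row, name)
                try:
                    return int(raw) if raw else None
                except ValueError:
                    return None

            yield MafRecord(
                hugo_symbol=self._get(row, "hugo_symbol"),
                variant_classification=self._get(row, "variant_classification"),
                tumor_sample_barcode=barcode,
                variant_type=self._get(row, "variant_type"),
                hgvs_p_short=self._get(row, "hgvs_p_short"),
                hgvs_c=self._get(row, "hgvs_c"),
                chromosome=self._get(row, "chromosome"),
                start=opt_int("start"),
                end=opt_int("end"),
                dbsnp_rs=self._get(row, "dbsnp_rs"),
                read_depth=opt_int("read_depth"),
            )
        self._fh.close()

    def close(self) -> None:
        self._fh.close()


def read_maf(path: str | Path) -> MafReader:
    """Open a MAF file for streaming.  Column matching is case-insensitive
    over the canonical MAF column set; '#' comment lines are skipped.
    Raises :class:`MafFormatError` when a mandatory column is absent."""
    return MafReader(path)


def register_panel(
    db: CohortDB,
    panel: PanelDefinition,
    hgnc: HgncTable | None = None,
    site_name: str = "site",
    id_base: int = 0,
) -> tuple[int, dict[str, int]]:
    """Create care_site, genomic_test and target_gene rows for ``panel``.

    ``id_base`` floors the allocated surrogate keys, letting databases
    built independently keep disjoint key spaces.  Returns
    ``(genomic_test_id, canonical symbol -> target_gene_id)``.
    """
    hgnc = hgnc or load_default_hgnc()
    care_site_id = max(db.max_id("care_site"), id_base) + 1
    insert_records(db, "care_site", [
        schema.CareSiteRecord(care_site_id=care_site_id, site_name=site_name)
    ])
    genomic_test_id = max(db.max_id("genomic_test"), id_base) + 1
    insert_records(db, "genomic_test", [
        schema.GenomicTestRecord(
            genomic_test_id=genomic_test_id,
            care_site_id=care_site_id,
            test_name=panel.test_name,
            test_version=panel.test_version,
            sequencing_device=panel.sequencing_device,
            analytical_tools=panel.analytical_tools,
            reference_databases=panel.reference_databases,
            reference_genome_build=panel.reference_genome_build,
        )
    ])
    base = max(db.max_id("target_gene"), id_base)
    gene_ids: dict[str, int] = {}
    rows = []
    for i, (canonical, hgnc_id) in enumerate(panel.canonical_genes(hgnc), start=1):
        gene_ids[canonical] = base + i
        rows.append(schema.TargetGeneRecord(
            target_gene_id=base + i,
            genomic_test_id=genomic_test_id,
            hgnc_symbol=canonical,
            hgnc_id=hgnc_id,
        ))
    insert_records(db, "target_gene", rows)
    return genomic_test_id, gene_ids


def _ensure_patient_context(
    db: CohortDB,
    person_id: int,
    test_name: str,
    cache: dict[int, tuple[int, int]],
) -> tuple[int, int]:
    """Find or create the procedure and target-specimen rows for a patient.
    Returns (procedure_id, specimen_id_target)."""
    if person_id in cache:
        return cache[person_id]
    row = db.conn.execute(
        "SELECT procedure_id FROM procedure_occurrence WHERE person_id = ? "
        "ORDER BY procedure_id LIMIT 1", (person_id,)
    ).fetchone()
    if row:
        procedure_id = row[0]
    else:
        procedure_id = db.max_id("procedure_occurrence") + 1
        insert_records(db, "procedure_occurrence", [
            schema.ProcedureRecord(
                procedure_id=procedure_id,
                person_id=person_id,
                acquisition_method="biopsy",
                genomic_test_name=test_name,
            )
        ])
    row = db.conn.execute(
        "SELECT specimen_id FROM specimen WHERE person_id = ? AND "
        "specimen_role = 'target' ORDER BY collection_date, specimen_id LIMIT 1",
        (person_id,),
    ).fetchone()
    if row:
        specimen_id = row[0]
    else:
        specimen_id = db.max_id("specimen") + 1
        insert_records(db, "specimen", [
            schema.SpecimenRecord(
                specimen_id=specimen_id,
                person_id=person_id,
                specimen_role="target",
                specimen_type="tumor tissue",
            )
        ])
    cache[person_id] = (procedure_id, specimen_id)
    return procedure_id, specimen_id


def _choose_samples(
    barcodes_by_person: Mapping[int, set[str]],
    collection_dates: Mapping[str, str] | None = None,
) -> dict[int, str]:
    """One sample per patient: earliest specimen collection date wins,
    ties (and missing dates) broken lexicographically on the barcode."""
    dates = collection_dates or {}
    chosen: dict[int, str] = {}
    for person_id, barcodes in barcodes_by_person.items():
        chosen[person_id] = min(
            barcodes, key=lambda b: (dates.get(b, "9999-12-31"), b)
        )
    return chosen


def load_maf(
    db: CohortDB,
    records: Iterable[MafRecord],
    panel: PanelDefinition,
    patient_of_sample: Mapping[str, int],
    hgnc: HgncTable | None = None,
    mapping: FeatureMapping | None = None,
    collection_dates: Mapping[str, str] | None = None,
    site_name: str = "site",
) -> LoadReport:
    """Load MAF records into the database, restricted to ``panel``.

    Per record: the gene symbol is canonicalized and must be on the panel
    (otherwise skipped as ``off_panel``); the sample barcode must map to a
    known patient (``unmapped_patient``); only one sample per patient is
    kept (``duplicate_sample``); protein HGVS is expanded to three-letter
    form (unparseable -> ``bad_hgvs``); the consequence term is mapped to
    the controlled variant_feature vocabulary.  The batch is all-or-nothing
    at the database level.
    """
    hgnc = hgnc or load_default_hgnc()
    mapping = mapping or load_default_feature_mapping()
    _, gene_ids = register_panel(db, panel, hgnc, site_name=site_name)
    report = LoadReport()

    staged = list(records)
    report.rows_read = len(staged)

    barcodes_by_person: dict[int, set[str]] = {}
    for rec in staged:
        person = patient_of_sample.get(rec.tumor_sample_barcode)
        if person is not None:
            barcodes_by_person.setdefault(person, set()).add(rec.tumor_sample_barcode)
    chosen = _choose_samples(barcodes_by_person, collection_dates)
    chosen_barcodes = set(chosen.values())

    context_cache: dict[int, tuple[int, int]] = {}
    rows: list[schema.VariantOccurrenceRecord] = []
    next_id = db.max_id("variant_occurrence") + 1
    for rec in staged:
        person = patient_of_sample.get(rec.tumor_sample_barcode)
        if person is None:
            report.skip("unmapped_patient")
            continue
        if rec.tumor_sample_barcode not in chosen_barcodes:
            report.skip("duplicate_sample")
            continue
        try:
            canonical, _hgnc_id = normalize_gene_symbol(rec.hugo_symbol, hgnc)
        except UnknownGeneError:
            report.skip("off_panel")
            continue
        if canonical not in gene_ids:
            report.skip("off_panel")
            continue
        hgvs_p = None
        if rec.hgvs_p_short:
            try:
                hgvs_p = expand_protein_hgvs(rec.hgvs_p_short)
            except HgvsParseError:
                report.skip("bad_hgvs")
                continue
        feature, alteration_hint = map_consequence(rec.variant_classification, mapping)
        alteration = mapping.map_structural(rec.variant_type) or alteration_hint or "SNP"
        procedure_id, specimen_id = _ensure_patient_context(
            db, person, panel.test_name, context_cache
        )
        rows.append(schema.VariantOccurrenceRecord(
            variant_occurrence_id=next_id,
            procedure_id=procedure_id,
            specimen_id_target=specimen_id,
            target_gene_id=gene_ids[canonical],
            rs_id=rec.dbsnp_rs or None,
            hgvs_c=rec.hgvs_c or None,
            hgvs_p=hgvs_p,
            read_depth=rec.read_depth,
            sequence_alteration=alteration,
            variant_feature=feature,
            genomic_start=rec.start,
            genomic_end=rec.end,
        ))
        next_id += 1
    report.rows_loaded = insert_records(db, "variant_occurrence", rows)
    logger.info("MAF load: %s", report.to_json())
    return report


# --- VCF --------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    """Where and how per-ALT consequence annotation lives in a VCF.

    ``info_field`` names the INFO key (e.g. ANN or CSQ); ``subfields``
    gives the pipe-separated sub-field order and must contain ``gene``,
    ``consequence`` and (optionally) ``hgvs_c``/``hgvs_p``.
    """

    info_field: str = "ANN"
    subfields: tuple[str, ...] = ("gene", "consequence", "hgvs_c", "hgvs_p")
    separator: str = "|"

    def parse_entry(self, entry: str) -> dict[str, str]:
        parts = entry.split(self.separator)
        return {
            name: (parts[i].strip() if i < len(parts) else "")
            for i, name in enumerate(self.subfields)
        }


def vcf_to_maf_coordinates(pos: int, ref: str, alt: str) -> tuple[int, int, str]:
    """Convert one VCF allele to 1-based-inclusive coordinates plus the
    structural class.

    The shared leading base is stripped first.  Deletions span the deleted
    bases; insertions get start = base before and end = base after the
    inserted sequence (the MAF convention).
    """
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    trimmed_ref, trimmed_alt = ref[k:], alt[k:]
    if len(trimmed_ref) == len(trimmed_alt):
        if len(trimmed_ref) == 0:
            raise ValueError(f"REF and ALT identical at pos {pos}")
        start = pos + k
        end = start + len(trimmed_ref) - 1
        return start, end, ("SNP" if len(trimmed_ref) == 1 else "MNP")
    if len(trimmed_ref) > len(trimmed_alt):  # deletion
        start = pos + k + len(trimmed_alt)
        end = pos + len(ref) - 1
        return start, end, "deletion"
    # insertion: anchor on the base before the inserted run
    start = pos + k - 1
    return start, start + 1, "insertion"


def load_vcf(
    db: CohortDB,
    path: str | Path,
    panel: PanelDefinition,
    person_id: int,
    annotation: AnnotationConfig | None = None,
    hgnc: HgncTable | None = None,
    mapping: FeatureMapping | None = None,
    site_name: str = "site",
) -> LoadReport:
    """Load one patient's annotated VCF, restricted to ``panel``.

    One variant_occurrence per ALT allele whose FILTER is PASS or '.';
    rows failing FILTER are skipped (``filter_failed``), alleles without a
    usable annotation entry as ``bad_annotation``, off-panel genes as
    ``off_panel``.  Read depth is taken from INFO/DP when present.
    """
    from cyvcf2 import VCF  # deferred: only VCF loads need it

    annotation = annotation or AnnotationConfig()
    hgnc = hgnc or load_default_hgnc()
    mapping = mapping or load_default_feature_mapping()
    if "gene" not in annotation.subfields or "consequence" not in annotation.subfields:
        raise MafFormatError(
            "annotation subfields must include 'gene' and 'consequence'"
        )

    _, gene_ids = register_panel(db, panel, hgnc, site_name=site_name)
    report = LoadReport()
    context_cache: dict[int, tuple[int, int]] = {}
    rows: list[schema.VariantOccurrenceRecord] = []
    next_id = db.max_id("variant_occurrence") + 1

    vcf = VCF(str(path))
    for variant in vcf:
        for alt_index, alt in enumerate(variant.ALT):
            report.rows_read += 1
            if variant.FILTER not in (None, "PASS", "."):
                report.skip("filter_failed")
                continue
            raw = variant.INFO.get(annotation.info_field)
            if raw is None:
                report.skip("bad_annotation")
                continue
            entries = str(raw).split(",")
            entry = entries[alt_index] if alt_index < len(entries) else entries[0]
            fields = annotation.parse_entry(entry)
            gene_symbol = fields.get("gene", "")
            if not gene_symbol or not fields.get("consequence"):
                report.skip("bad_annotation")
                continue
            try:
                canonical, _ = normalize_gene_symbol(gene_symbol, hgnc)
            except UnknownGeneError:
                report.skip("off_panel")
                continue
            if canonical not in gene_ids:
                report.skip("off_panel")
                continue
            hgvs_p = None
            if fields.get("hgvs_p"):
                try:
                    hgvs_p = expand_protein_hgvs(fields["hgvs_p"])
                except HgvsParseError:
                    report.skip("bad_hgvs")
                    continue
            try:
                start, end, alteration = vcf_to_maf_coordinates(
                    variant.POS, variant.REF, alt
                )
            except ValueError:
                report.skip("bad_allele")
                continue
            feature, _hint = map_consequence(fields["consequence"], mapping)
            depth = variant.INFO.get("DP")
            procedure_id, specimen_id = _ensure_patient_context(
                db, person_id, panel.test_name, context_cache
            )
            rows.append(schema.VariantOccurrenceRecord(
                variant_occurrence_id=next_id,
                procedure_id=procedure_id,
                specimen_id_target=specimen_id,
                target_gene_id=gene_ids[canonical],
                rs_id=variant.ID,
                hgvs_c=fields.get("hgvs_c") or None,
                hgvs_p=hgvs_p,
                read_depth=int(depth) if depth is not None else None,
                sequence_alteration=alteration,
                variant_feature=feature,
                genomic_start=start,
                genomic_end=end,
            ))
            next_id += 1
    report.rows_loaded = insert_records(db, "variant_occurrence", rows)
    logger.info("VCF load: %s", report.to_json())
    return report


# --- clinical CSVs ----------------------------------------------------------

_CLINICAL_TABLES = (
    "person", "care_site", "condition_occurrence",
    "procedure_occurrence", "specimen",
)


def load_clinical(db: CohortDB, tables: Mapping[str, str | Path]) -> LoadReport:
    """Load the five clinical tables from dump-format TSV files.

    ``tables`` maps table name -> path; tables may be omitted.  Rows that
    violate an invariant (bad vocabulary, implausible age, unresolvable
    foreign key) are skipped with reason ``invariant_violation``.
    """
    report = LoadReport()
    for table in _CLINICAL_TABLES:
        if table not in tables:
            continue
        rows = schema.read_table_csv(tables[table], table)
        report.rows_read += len(rows)
        good: list[dict[str, Any]] = []
        for i, row in enumerate(rows):
            try:
                schema._validate_row(table, i, row)
            except schema.InsertError:
                report.skip("invariant_violation")
                continue
            good.append(row)
        # insert one-by-one so FK failures skip just the bad row
        for row in good:
            try:
                report.rows_loaded += insert_records(db, table, [row])
            except schema.InsertError:
                report.skip("invariant_violation")
    logger.info("clinical load: %s", report.to_json())
    return report
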