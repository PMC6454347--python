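"""Relational core: create, populate, validate and dump the cohort database.

The model links four genomic tables (genomic_test, target_gene,
variant_occurrence, variant_annotation) to five OMOP-style clinical tables
(person, condition_occurrence, procedure_occurrence, specimen, care_site).
The backing store is a single-file SQLite database with foreign keys
enforced; the DDL ships as a versioned text asset.  Controlled
vocabularies are string-coded; a mapping hook to real OMOP concept_ids is
left to downstream integration.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass, field, fields as dc_fields, is_dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from .nomenclature import (
    SEQUENCE_ALTERATIONS,
    VARIANT_FEATURES,
    HgvsParseError,
    parse_protein_hgvs,
)

__all__ = [
    "SCHEMA_VERSION",
    "TABLE_ORDER",
    "CohortDB",
    "Violation",
    "SchemaError",
    "InsertError",
    "init_database",
    "open_database",
    "insert_records",
    "validate_database",
    "dump_csv",
    "load_csv",
    "PersonRecord",
    "ConditionRecord",
    "ProcedureRecord",
    "SpecimenRecord",
    "CareSiteRecord",
    "GenomicTestRecord",
    "TargetGeneRecord",
    "VariantOccurrenceRecord",
    "VariantAnnotationRecord",
]

SCHEMA_VERSION = "1.0"

#: deterministic table ordering used by validation, dumps and exports
TABLE_ORDER = (
    "person",
    "care_site",
    "condition_occurrence",
    "procedure_occurrence",
    "specimen",
    "genomic_test",
    "target_gene",
    "variant_occurrence",
    "variant_annotation",
)

GENDERS = ("male", "female", "unknown")
STAGES = ("I", "II", "III", "IV", "unknown")
SPECIMEN_ROLES = ("target", "reference")
VARIANT_ORIGINS = ("somatic", "germline", "unknown")


class SchemaError(RuntimeError):
    """Database file is missing, already initialized, or not this schema."""


class InsertError(ValueError):
    """A row failed validation; names the row index and offending field."""

    def __init__(self, table: str, row_index: int, field_name: str, message: str):
        super().__init__(
            f"{table} row {row_index}: field {field_name!r}: {message}"
        )
        self.table = table
        self.row_index = row_index
        self.field = field_name


@dataclass(frozen=True)
class Violation:
    """One integrity violation found by :func:`validate_database`."""

    table: str
    row_key: int
    rule: str
    message: str


# --- record dataclasses -----------------------------------------------------

@dataclass
class PersonRecord:
    person_id: int
    gender: str = "unknown"
    age_years: int | None = None
    race: str | None = None


@dataclass
class ConditionRecord:
    condition_id: int
    person_id: int
    condition_name: str
    condition_type: str | None = "primary condition"
    stage: str | None = "unknown"


@dataclass
class ProcedureRecord:
    procedure_id: int
    person_id: int
    acquisition_method: str | None = None
    genomic_test_name: str | None = None


@dataclass
class SpecimenRecord:
    specimen_id: int
    person_id: int
    specimen_role: str = "target"
    specimen_type: str | None = None
    collection_date: str | None = None
    anatomic_site: str | None = None


@dataclass
class CareSiteRecord:
    care_site_id: int
    site_name: str | None = None


@dataclass
class GenomicTestRecord:
    genomic_test_id: int
    care_site_id: int
    test_name: str | None = None
    test_version: str | None = None
    sequencing_device: str | None = None
    analytical_tools: str | None = None
    reference_databases: str | None = None
    reference_genome_build: str | None = None


@dataclass
class TargetGeneRecord:
    target_gene_id: int
    genomic_test_id: int
    hgnc_symbol: str = ""
    hgnc_id: str | None = None


@dataclass
class VariantOccurrenceRecord:
    variant_occurrence_id: int
    procedure_id: int
    specimen_id_target: int
    target_gene_id: int
    specimen_id_reference: int | None = None
    reference_sequence: str | None = None
    rs_id: str | None = None
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    read_depth: int | None = None
    exon_number: int | None = None
    sequence_alteration: str = "SNP"
    variant_feature: str = "other"
    genomic_start: int | None = None
    genomic_end: int | None = None


@dataclass
class VariantAnnotationRecord:
    variant_annotation_id: int
    variant_occurrence_id: int
    annotation_db_name: str | None = None
    annotation_db_version: str | None = None
    variant_origin: str | None = "unknown"
    pathogenicity: str | None = None
    allele_frequency: float | None = None
    medication: str | None = None


RECORD_TYPES = {
    "person": PersonRecord,
    "care_site": CareSiteRecord,
    "condition_occurrence": ConditionRecord,
    "procedure_occurrence": ProcedureRecord,
    "specimen": SpecimenRecord,
    "genomic_test": GenomicTestRecord,
    "target_gene": TargetGeneRecord,
    "variant_occurrence": VariantOccurrenceRecord,
    "variant_annotation": VariantAnnotationRecord,
}

_PRIMARY_KEYS = {
    "person": "person_id",
    "care_site": "care_site_id",
    "condition_occurrence": "condition_id",
    "procedure_occurrence": "procedure_id",
    "specimen": "specimen_id",
    "genomic_test": "genomic_test_id",
    "target_gene": "target_gene_id",
    "variant_occurrence": "variant_occurrence_id",
    "variant_annotation": "variant_annotation_id",
}

# column -> (referenced table, referenced column); applied per table
_FOREIGN_KEYS: dict[str, dict[str, tuple[str, str]]] = {
    "condition_occurrence": {"person_id": ("person", "person_id")},
    "procedure_occurrence": {"person_id": ("person", "person_id")},
    "specimen": {"person_id": ("person", "person_id")},
    "genomic_test": {"care_site_id": ("care_site", "care_site_id")},
    "target_gene": {"genomic_test_id": ("genomic_test", "genomic_test_id")},
    "variant_occurrence": {
        "procedure_id": ("procedure_occurrence", "procedure_id"),
        "specimen_id_target": ("specimen", "specimen_id"),
        "specimen_id_reference": ("specimen", "specimen_id"),
        "target_gene_id": ("target_gene", "target_gene_id"),
    },
    "variant_annotation": {
        "variant_occurrence_id": ("variant_occurrence", "variant_occurrence_id"),
    },
}

_NULLABLE_FKS = {("variant_occurrence", "specimen_id_reference")}

_ENUMS: dict[str, dict[str, tuple[str, ...]]] = {
    "person": {"gender": GENDERS},
    "condition_occurrence": {"stage": STAGES},
    "specimen": {"specimen_role": SPECIMEN_ROLES},
    "variant_occurrence": {
        "sequence_alteration": SEQUENCE_ALTERATIONS,
        "variant_feature": VARIANT_FEATURES,
    },
    "variant_annotation": {"variant_origin": VARIANT_ORIGINS},
}

_INT_COLUMNS = {
    "age_years", "read_depth", "exon_number", "genomic_start", "genomic_end",
}


class CohortDB:
    """Handle to a populated cohort database.

    Thin wrapper over a :mod:`sqlite3` connection; all package operations
    accept this handle.  Use :func:`init_database` to create and
    :func:`open_database` to reopen.
    """

    def __init__(self, conn: sqlite3.Connection, path: str):
        self.conn = conn
        self.path = path
        self.conn.execute("PRAGMA foreign_keys = ON")

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "CohortDB":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def table_count(self, table: str) -> int:
        _require_table(table)
        return self.conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def max_id(self, table: str) -> int:
        """Largest primary key in ``table`` (0 when empty); used by loaders
        to allocate fresh surrogate keys."""
        _require_table(table)
        pk = _PRIMARY_KEYS[table]
        row = self.conn.execute(f"SELECT MAX({pk}) FROM {table}").fetchone()
        return row[0] or 0

    def fetch_table(self, table: str) -> list[dict[str, Any]]:
        _require_table(table)
        cols = _columns(table)
        pk = _PRIMARY_KEYS[table]
        rows = self.conn.execute(
            f"SELECT {', '.join(cols)} FROM {table} ORDER BY {pk}"
        ).fetchall()
        return [dict(zip(cols, row)) for row in rows]


def _require_table(table: str) -> None:
    if table not in RECORD_TYPES:
        raise KeyError(f"unknown table {table!r}; expected one of {TABLE_ORDER}")


def _columns(table: str) -> list[str]:
    return [f.name for f in dc_fields(RECORD_TYPES[table])]


def _ddl() -> str:
    return resources.files("varcdm.assets").joinpath("schema.sql").read_text("utf-8")


def init_database(path: str | Path, overwrite: bool = False) -> CohortDB:
    """Create an empty cohort database at ``path``.

    ``path`` may be ``":memory:"`` for an in-process database.  An existing
    file is refused unless ``overwrite`` is set; a foreign file that is not
    a cohort database is always refused.
    """
    path = str(path)
    if path != ":memory:":
        p = Path(path)
        if p.exists():
            if not overwrite:
                raise SchemaError(
                    f"{path} already exists; pass overwrite=True to replace it"
                )
            if p.stat().st_size > 0 and not _is_cohort_db_file(p):
                raise SchemaError(f"{path} exists and is not a cohort database")
            p.unlink()
    conn = sqlite3.connect(path)
    conn.executescript(_ddl())
    conn.execute("PRAGMA user_version = 1")
    conn.commit()
    return CohortDB(conn, path)


def _is_cohort_db_file(p: Path) -> bool:
    try:
        with open(p, "rb") as fh:
            if fh.read(16) != b"SQLite format 3\x00":
                return False
        conn = sqlite3.connect(str(p))
        try:
            names = {
                r[0] for r in conn.execute(
                    "SELECT name FROM sqlite_master WHERE type='table'"
                )
            }
        finally:
            conn.close()
        return set(TABLE_ORDER) <= names
    except OSError:
        return False


def open_database(path: str | Path) -> CohortDB:
    """Reopen an existing cohort database."""
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"{path} does not exist")
    if not _is_cohort_db_file(p):
        raise SchemaError(f"{path} is not a cohort database")
    return CohortDB(sqlite3.connect(str(p)), str(p))


def _as_dict(row: Any, table: str, index: int) -> dict[str, Any]:
    if is_dataclass(row) and not isinstance(row, type):
        return asdict(row)
    if isinstance(row, Mapping):
        cols = set(_columns(table))
        extra = set(row) - cols
        if extra:
            raise InsertError(table, index, sorted(extra)[0], "unknown column")
        return {c: row.get(c) for c in _columns(table)}
    raise InsertError(table, index, "<row>", f"unsupported row type {type(row).__name__}")


def _validate_row(table: str, index: int, row: dict[str, Any]) -> None:
    for col, allowed in _ENUMS.get(table, {}).items():
        value = row.get(col)
        if value is not None and value not in allowed:
            raise InsertError(
                table, index, col,
                f"value {value!r} not in controlled vocabulary {allowed}",
            )
    for col in _INT_COLUMNS & set(row):
        value = row[col]
        if value is not None and not isinstance(value, int):
            raise InsertError(table, index, col, f"expected integer, got {value!r}")
    if table == "person":
        age = row.get("age_years")
        if age is not None and not (0 <= age < 150):
            raise InsertError(table, index, "age_years", f"implausible age {age!r}")
    if table == "variant_occurrence":
        hgvs_p = row.get("hgvs_p")
        if hgvs_p:
            try:
                change = parse_protein_hgvs(hgvs_p)
            except HgvsParseError as exc:
                raise InsertError(table, index, "hgvs_p", str(exc)) from exc
            if change.is_wildcard:
                raise InsertError(
                    table, index, "hgvs_p",
                    "wildcard Xaa is a query pattern, not an observation",
                )
        start, end = row.get("genomic_start"), row.get("genomic_end")
        if start is not None and end is not None and end < start:
            raise InsertError(table, index, "genomic_end", "end before start")
    if table == "variant_annotation":
        af = row.get("allele_frequency")
        if af is not None and not (0.0 <= af <= 1.0):
            raise InsertError(table, index, "allele_frequency",
                              f"{af!r} outside [0, 1]")


def insert_records(db: CohortDB, table: str, rows: Iterable[Any]) -> int:
    """Insert ``rows`` (dataclass records or mappings) into ``table``.

    All-or-nothing: the batch is validated row by row (controlled
    vocabularies, HGVS re-parse, plausibility checks) and committed in one
    transaction; any database constraint failure rolls the whole batch
    back.  Returns the number of rows inserted.
    """
    _require_table(table)
    cols = _columns(table)
    pk = _PRIMARY_KEYS[table]
    dicts: list[dict[str, Any]] = []
    seen_keys: set[Any] = set()
    seen_unique: set[Any] = set()
    for i, row in enumerate(rows):
        d = _as_dict(row, table, i)
        _validate_row(table, i, d)
        key = d.get(pk)
        if key in seen_keys:
            raise InsertError(table, i, pk, f"duplicate key {key!r} in batch")
        seen_keys.add(key)
        if table == "target_gene":
            uniq = (d.get("genomic_test_id"), d.get("hgnc_symbol"))
            if uniq in seen_unique:
                raise InsertError(table, i, "hgnc_symbol",
                                  f"duplicate (genomic_test_id, hgnc_symbol) {uniq!r} in batch")
            seen_unique.add(uniq)
        dicts.append(d)
    if not dicts:
        return 0
    placeholders = ", ".join("?" for _ in cols)
    sql = f"INSERT INTO {table} ({', '.join(cols)}) VALUES ({placeholders})"
    values = [tuple(d[c] for c in cols) for d in dicts]
    try:
        with db.conn:  # transaction scope
            db.conn.executemany(sql, values)
    except sqlite3.IntegrityError as exc:
        # pin down the offending row for the error message
        msg = str(exc)
        for i, v in enumerate(values):
            try:
                db.conn.execute("BEGIN")
                db.conn.execute(sql, v)
            except sqlite3.IntegrityError as row_exc:
                db.conn.execute("ROLLBACK")
                field_name = _guess_constraint_field(table, str(row_exc))
                raise InsertError(table, i, field_name, str(row_exc)) from exc
            else:
                db.conn.execute("ROLLBACK")
        raise InsertError(table, 0, "<batch>", msg) from exc
    return len(dicts)


def _guess_constraint_field(table: str, message: str) -> str:
    for col in _columns(table):
        if col in message:
            return col
    if "FOREIGN KEY" in message:
        return ",".join(_FOREIGN_KEYS.get(table, {}))
    return "<unknown>"


def validate_database(db: CohortDB) -> list[Violation]:
    """Enumerate every integrity violation in the database.

    Checks primary-key uniqueness, foreign-key resolvability, controlled
    vocabularies, value-range invariants, specimen-role consistency and
    HGVS re-parseability.  Returns violations ordered deterministically by
    table (schema order) then row key; an empty list means the database is
    consistent.  Violations are data, not exceptions: the function itself
    never raises on bad content.
    """
    out: list[Violation] = []
    conn = db.conn
    for table in TABLE_ORDER:
        pk = _PRIMARY_KEYS[table]
        found: list[Violation] = []
        # duplicate primary keys can only appear via rowid tricks; still check
        for (key, n) in conn.execute(
            f"SELECT {pk}, COUNT(*) FROM {table} GROUP BY {pk} HAVING COUNT(*) > 1"
        ):
            found.append(Violation(table, key, "unique_key", f"{pk}={key} occurs {n} times"))
        for col, (ref_table, ref_col) in _FOREIGN_KEYS.get(table, {}).items():
            for (key,) in conn.execute(
                f"SELECT t.{pk} FROM {table} t "
                f"LEFT JOIN {ref_table} r ON t.{col} = r.{ref_col} "
                f"WHERE t.{col} IS NOT NULL AND r.{ref_col} IS NULL"
            ):
                found.append(Violation(
                    table, key, "foreign_key",
                    f"{col} does not resolve in {ref_table}",
                ))
        for col, allowed in _ENUMS.get(table, {}).items():
            qmarks = ", ".join("?" for _ in allowed)
            for (key, value) in conn.execute(
                f"SELECT {pk}, {col} FROM {table} "
                f"WHERE {col} IS NOT NULL AND {col} NOT IN ({qmarks})",
                allowed,
            ):
                found.append(Violation(
                    table, key, "vocabulary",
                    f"{col}={value!r} not in {allowed}",
                ))
        if table == "person":
            for (key, age) in conn.execute(
                "SELECT person_id, age_years FROM person "
                "WHERE age_years IS NOT NULL AND (age_years < 0 OR age_years >= 150)"
            ):
                found.append(Violation(table, key, "age_range", f"age_years={age}"))
        if table == "specimen":
            pass  # role vocabulary covered above
        if table == "variant_occurrence":
            for (key, hgvs_p) in conn.execute(
                "SELECT variant_occurrence_id, hgvs_p FROM variant_occurrence "
                "WHERE hgvs_p IS NOT NULL AND hgvs_p != '' "
                "ORDER BY variant_occurrence_id"
            ):
                try:
                    change = parse_protein_hgvs(hgvs_p)
                except HgvsParseError as exc:
                    found.append(Violation(table, key, "hgvs_p_parse", str(exc)))
                else:
                    if change.is_wildcard:
                        found.append(Violation(
                            table, key, "hgvs_p_wildcard",
                            "stored hgvs_p contains query wildcard Xaa",
                        ))
            for (key,) in conn.execute(
                "SELECT v.variant_occurrence_id FROM variant_occurrence v "
                "JOIN specimen s ON v.specimen_id_target = s.specimen_id "
                "WHERE s.specimen_role != 'target'"
            ):
                found.append(Violation(
                    table, key, "specimen_role",
                    "specimen_id_target refers to a non-target specimen",
                ))
            for (key,) in conn.execute(
                "SELECT variant_occurrence_id FROM variant_occurrence "
                "WHERE genomic_start IS NOT NULL AND genomic_end IS NOT NULL "
                "AND genomic_end < genomic_start"
            ):
                found.append(Violation(table, key, "coordinates", "genomic_end < genomic_start"))
        if table == "variant_annotation":
            for (key, af) in conn.execute(
                "SELECT variant_annotation_id, allele_frequency FROM variant_annotation "
                "WHERE allele_frequency IS NOT NULL "
                "AND (allele_frequency < 0 OR allele_frequency > 1)"
            ):
                found.append(Violation(table, key, "allele_frequency", f"{af} outside [0, 1]"))
        found.sort(key=lambda v: (v.row_key, v.rule))
        out.extend(found)
    return out


# --- CSV dump / load --------------------------------------------------------

_NULL = ""


def dump_csv(db: CohortDB, directory: str | Path) -> dict[str, Path]:
    """Write one UTF-8 tab-separated file per table (header = field names,
    empty string encodes NULL).  Returns table -> file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for table in TABLE_ORDER:
        cols = _columns(table)
        path = directory / f"{table}.tsv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(cols)
            for row in db.fetch_table(table):
                writer.writerow([_NULL if row[c] is None else row[c] for c in cols])
        written[table] = path
    return written


def load_csv(db: CohortDB, directory: str | Path) -> dict[str, int]:
    """Load per-table TSV files produced by :func:`dump_csv` (missing files
    are skipped).  Returns table -> rows inserted."""
    directory = Path(directory)
    counts: dict[str, int] = {}
    for table in TABLE_ORDER:
        path = directory / f"{table}.tsv"
        if not path.exists():
            continue
        rows = read_table_csv(path, table)
        counts[table] = insert_records(db, table, rows)
    return counts


def read_table_csv(path: str | Path, table: str) -> list[dict[str, Any]]:
    """Parse one dump-format TSV into typed row dictionaries."""
    _require_table(table)
    types = {f.name: f.type for f in dc_fields(RECORD_TYPES[table])}
    rows: list[dict[str, Any]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for raw in reader:
            row: dict[str, Any] = {}
            for col, value in raw.items():
                if col not in types:
                    continue
                if value == _NULL or value is None:
                    row[col] = None
                elif "int" in str(types[col]):
                    row[col] = int(value)
                elif "float" in str(types[col]):
                    row[col] = float(value)
                else:
                    row[col] = value
            rows.append(row)
    return rows
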