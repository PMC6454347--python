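-- varcdm relational schema, version 1.0
-- Four genomic tables (genomic_test, target_gene, variant_occurrence,
-- variant_annotation) linked to five OMOP-style clinical tables
-- (person, condition_occurrence, procedure_occurrence, specimen, care_site).
-- Controlled vocabularies are string-coded; coordinates are 1-based inclusive.

CREATE TABLE person (
    person_id   INTEGER PRIMARY KEY,
    gender      TEXT NOT NULL CHECK (gender IN ('male', 'female', 'unknown')),
    age_years   INTEGER CHECK (age_years IS NULL OR (age_years >= 0 AND age_years < 150)),
    race        TEXT
);

CREATE TABLE care_site (
    care_site_id INTEGER PRIMARY KEY,
    site_name    TEXT
);

CREATE TABLE condition_occurrence (
    condition_id   INTEGER PRIMARY KEY,
    person_id      INTEGER NOT NULL REFERENCES person (person_id),
    condition_name TEXT NOT NULL,
    condition_type TEXT,
    stage          TEXT CHECK (stage IS NULL OR stage IN ('I', 'II', 'III', 'IV', 'unknown'))
);

CREATE TABLE procedure_occurrence (
    procedure_id       INTEGER PRIMARY KEY,
    person_id          INTEGER NOT NULL REFERENCES person (person_id),
    acquisition_method TEXT,
    genomic_test_name  TEXT
);

CREATE TABLE specimen (
    specimen_id     INTEGER PRIMARY KEY,
    person_id       INTEGER NOT NULL REFERENCES person (person_id),
    specimen_role   TEXT NOT NULL CHECK (specimen_role IN ('target', 'reference')),
    specimen_type   TEXT,
    collection_date TEXT,
    anatomic_site   TEXT
);

CREATE TABLE genomic_test (
    genomic_test_id        INTEGER PRIMARY KEY,
    care_site_id           INTEGER NOT NULL REFERENCES care_site (care_site_id),
    test_name              TEXT,
    test_version           TEXT,
    sequencing_device      TEXT,
    analytical_tools       TEXT,
    reference_databases    TEXT,
    reference_genome_build TEXT
);

CREATE TABLE target_gene (
    target_gene_id  INTEGER PRIMARY KEY,
    genomic_test_id INTEGER NOT NULL REFERENCES genomic_test (genomic_test_id),
    hgnc_symbol     TEXT NOT NULL,
    hgnc_id         TEXT,
    UNIQUE (genomic_test_id, hgnc_symbol)
);

CREATE TABLE variant_occurrence (
    variant_occurrence_id INTEGER PRIMARY KEY,
    procedure_id          INTEGER NOT NULL REFERENCES procedure_occurrence (procedure_id),
    specimen_id_target    INTEGER NOT NULL REFERENCES specimen (specimen_id),
    specimen_id_reference INTEGER REFERENCES specimen (specimen_id),
    target_gene_id        INTEGER NOT NULL REFERENCES target_gene (target_gene_id),
    reference_sequence    TEXT,
    rs_id                 TEXT,
    hgvs_c                TEXT,
    hgvs_p                TEXT,
    read_depth            INTEGER CHECK (read_depth IS NULL OR read_depth >= 0),
    exon_number           INTEGER CHECK (exon_number IS NULL OR exon_number >= 1),
    sequence_alteration   TEXT NOT NULL CHECK (sequence_alteration IN
                              ('SNP', 'insertion', 'deletion', 'MNP', 'CNV', 'translocation')),
    variant_feature       TEXT NOT NULL CHECK (variant_feature IN
                              ('missense', 'nonsense', 'frameshift', 'inframe',
                               'splice', 'synonymous', 'intron', 'other')),
    genomic_start         INTEGER,
    genomic_end           INTEGER,
    CHECK (genomic_start IS NULL OR genomic_end IS NULL OR genomic_end >= genomic_start)
);

CREATE TABLE variant_annotation (
    variant_annotation_id INTEGER PRIMARY KEY,
    variant_occurrence_id INTEGER NOT NULL REFERENCES variant_occurrence (variant_occurrence_id),
    annotation_db_name    TEXT,
    annotation_db_version TEXT,
    variant_origin        TEXT CHECK (variant_origin IS NULL OR
                                      variant_origin IN ('somatic', 'germline', 'unknown')),
    pathogenicity         TEXT,
    allele_frequency      REAL CHECK (allele_frequency IS NULL OR
                                      (allele_frequency >= 0.0 AND allele_frequency <= 1.0)),
    medication            TEXT
);

CREATE INDEX idx_variant_occurrence_gene ON variant_occurrence (target_gene_id);
CREATE INDEX idx_variant_occurrence_proc ON variant_occurrence (procedure_id);
CREATE INDEX idx_specimen_person ON specimen (person_id);
CREATE INDEX idx_condition_person ON condition_occurrence (person_id);
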