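"""Cohort analytics over a populated cohort database.

Implements the descriptive summaries a site shares in a distributed
research network: demographics, per-gene variant frequencies, variant-type
proportions, actionable-mutation frequencies, waterfall matrices, ad-hoc
gene/HGVS queries, privacy-preserving aggregate export and two-site
comparison with chi-squared tests.  Everything a site exports is
aggregate-only: counts and denominators, never patient-level rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

from scipy.stats import chi2 as _chi2_dist

from .nomenclature import (
    SEQUENCE_ALTERATIONS,
    VARIANT_FEATURES,
    HgncTable,
    ProteinChange,
    UnknownGeneError,
    expand_protein_hgvs,
    load_default_hgnc,
    matches_pattern,
    normalize_gene_symbol,
    parse_protein_hgvs,
)
from .schema import SCHEMA_VERSION, CohortDB

logger = logging.getLogger(__name__)

__all__ = [
    "PROTEIN_ALTERING_FEATURES",
    "WATERFALL_PRIORITY",
    "AGE_BINS",
    "DemographicRow",
    "GeneFrequencyRow",
    "ActionableRegistry",
    "WaterfallMatrix",
    "cohort_demographics",
    "gene_variant_frequency",
    "top_gene_union",
    "variant_type_proportions",
    "actionable_frequency",
    "waterfall_matrix",
    "query_variant",
    "export_aggregate",
    "merge_aggregates",
    "chi_squared_2x2",
    "compare_aggregates",
    "round_half_up",
    "load_default_registry",
]

#: protein-altering variant_feature classes (waterfall/frequency filter)
PROTEIN_ALTERING_FEATURES = ("missense", "nonsense", "frameshift", "inframe", "splice")

#: most-deleterious-first cell priority for the waterfall matrix
WATERFALL_PRIORITY = (
    "nonsense", "frameshift", "splice", "inframe",
    "missense", "synonymous", "intron", "other",
)

AGE_BINS = ("<=49", "50-59", "60-69", "70-79", ">=80", "unknown")


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention of printed clinical
    tables), not banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _age_bin(age: int | None) -> str:
    if age is None:
        return "unknown"
    if age <= 49:
        return "<=49"
    if age <= 59:
        return "50-59"
    if age <= 69:
        return "60-69"
    if age <= 79:
        return "70-79"
    return ">=80"


@dataclass(frozen=True)
class DemographicRow:
    group: str          # age | gender | pathology | stage
    category: str
    count: int
    percent: float      # of cohort N, half-up to one decimal


@dataclass(frozen=True)
class GeneFrequencyRow:
    hgnc_symbol: str
    n_patients_with_variant: int
    n_patients_total: int
    frequency: float


def _cohort_n(db: CohortDB) -> int:
    return db.conn.execute("SELECT COUNT(*) FROM person").fetchone()[0]


def _require_cohort(db: CohortDB) -> int:
    n = _cohort_n(db)
    if n == 0:
        raise ValueError("empty_cohort")
    return n


def _condition_of_person(db: CohortDB) -> dict[int, str]:
    """First-listed condition name per patient."""
    out: dict[int, str] = {}
    for person_id, name in db.conn.execute(
        "SELECT person_id, condition_name FROM condition_occurrence "
        "ORDER BY condition_id"
    ):
        out.setdefault(person_id, name)
    return out


def cohort_demographics(db: CohortDB) -> list[DemographicRow]:
    """Demographic summary over the full cohort.

    Ages are binned <=49 / 50-59 / 60-69 / 70-79 / >=80 / unknown;
    percentages are 100*count/N over the full cohort (unknowns included in
    the denominator), rounded half-up to one decimal.  Raises
    ``ValueError("empty_cohort")`` on an empty person table.
    """
    n = _require_cohort(db)
    rows: list[DemographicRow] = []

    age_counts = {b: 0 for b in AGE_BINS}
    gender_counts = {"male": 0, "female": 0, "unknown": 0}
    for age, gender in db.conn.execute("SELECT age_years, gender FROM person"):
        age_counts[_age_bin(age)] += 1
        gender_counts[gender] += 1
    for category in AGE_BINS:
        c = age_counts[category]
        rows.append(DemographicRow("age", category, c, round_half_up(100 * c / n, 1)))
    for category in ("male", "female", "unknown"):
        c = gender_counts[category]
        rows.append(DemographicRow("gender", category, c, round_half_up(100 * c / n, 1)))

    condition = _condition_of_person(db)
    pathology_counts: dict[str, int] = {}
    for name in condition.values():
        pathology_counts[name] = pathology_counts.get(name, 0) + 1
    unknown_path = n - len(condition)
    if unknown_path:
        pathology_counts["unknown"] = unknown_path
    for category in sorted(pathology_counts, key=lambda k: (-pathology_counts[k], k)):
        c = pathology_counts[category]
        rows.append(DemographicRow("pathology", category, c, round_half_up(100 * c / n, 1)))

    stage_by_person: dict[int, str] = {}
    for person_id, stage in db.conn.execute(
        "SELECT person_id, stage FROM condition_occurrence ORDER BY condition_id"
    ):
        stage_by_person.setdefault(person_id, stage or "unknown")
    stage_counts = {s: 0 for s in ("I", "II", "III", "IV", "unknown")}
    for stage in stage_by_person.values():
        stage_counts[stage] += 1
    stage_counts["unknown"] += n - len(stage_by_person)
    for category in ("I", "II", "III", "IV", "unknown"):
        c = stage_counts[category]
        rows.append(DemographicRow("stage", category, c, round_half_up(100 * c / n, 1)))
    return rows


_VARIANT_PERSON_SQL = (
    "SELECT g.hgnc_symbol, p.person_id, v.variant_feature, v.hgvs_p, "
    "v.sequence_alteration "
    "FROM variant_occurrence v "
    "JOIN target_gene g ON v.target_gene_id = g.target_gene_id "
    "JOIN procedure_occurrence p ON v.procedure_id = p.procedure_id "
)


def gene_variant_frequency(
    db: CohortDB, protein_altering_only: bool = False
) -> list[GeneFrequencyRow]:
    """Fraction of patients with >=1 variant per panel gene.

    The denominator is the full cohort (patients with no variants
    included); each patient counts at most once per gene.  With
    ``protein_altering_only`` set, only missense/nonsense/frameshift/
    inframe/splice variants count.  Rows cover every panel gene (zero
    counts included), ordered by frequency descending then symbol.
    """
    n = _require_cohort(db)
    panel_genes = [
        row[0] for row in db.conn.execute(
            "SELECT DISTINCT hgnc_symbol FROM target_gene ORDER BY hgnc_symbol"
        )
    ]
    where = ""
    params: tuple = ()
    if protein_altering_only:
        qmarks = ", ".join("?" for _ in PROTEIN_ALTERING_FEATURES)
        where = f"WHERE v.variant_feature IN ({qmarks})"
        params = PROTEIN_ALTERING_FEATURES
    counts = dict(db.conn.execute(
        f"SELECT g.hgnc_symbol, COUNT(DISTINCT p.person_id) "
        f"FROM variant_occurrence v "
        f"JOIN target_gene g ON v.target_gene_id = g.target_gene_id "
        f"JOIN procedure_occurrence p ON v.procedure_id = p.procedure_id "
        f"{where} GROUP BY g.hgnc_symbol",
        params,
    ))
    rows = [
        GeneFrequencyRow(gene, counts.get(gene, 0), n, counts.get(gene, 0) / n)
        for gene in panel_genes
    ]
    rows.sort(key=lambda r: (-r.frequency, r.hgnc_symbol))
    return rows


def top_gene_union(
    a: Sequence[GeneFrequencyRow], b: Sequence[GeneFrequencyRow], k: int
) -> list[str]:
    """Union of the top-``k`` genes (by frequency, ties alphabetical) of
    two frequency tables, ordered by the max frequency across tables,
    descending, ties alphabetical."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not a or not b:
        raise ValueError("both frequency tables must be non-empty")

    def top_k(table: Sequence[GeneFrequencyRow]) -> list[str]:
        ordered = sorted(table, key=lambda r: (-r.frequency, r.hgnc_symbol))
        return [r.hgnc_symbol for r in ordered[:k]]

    union = set(top_k(a)) | set(top_k(b))
    freq = {r.hgnc_symbol: r.frequency for r in b}
    for r in a:
        freq[r.hgnc_symbol] = max(freq.get(r.hgnc_symbol, 0.0), r.frequency)
    return sorted(union, key=lambda g: (-freq.get(g, 0.0), g))


def variant_type_proportions(
    db: CohortDB, level: str = "sequence_alteration"
) -> list[tuple[str, int, float]]:
    """Counts and proportions of variant *rows* (not patients) by
    structural class (``sequence_alteration``) or protein-functional class
    (``variant_feature``).  Proportions sum to 1."""
    if level not in ("sequence_alteration", "variant_feature"):
        raise ValueError(f"unknown level {level!r}")
    vocabulary = SEQUENCE_ALTERATIONS if level == "sequence_alteration" else VARIANT_FEATURES
    counts = dict(db.conn.execute(
        f"SELECT {level}, COUNT(*) FROM variant_occurrence GROUP BY {level}"
    ))
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no variants loaded")
    return [
        (t, counts.get(t, 0), counts.get(t, 0) / total)
        for t in vocabulary
    ]


class ActionableRegistry:
    """Gene -> HGVS protein patterns defining actionable-mutation classes.

    Patterns may use the ``Xaa`` wildcard to group codon-level classes
    (e.g. ``p.Gly12Xaa`` for KRAS codon 12).  All genes are canonicalized
    and all patterns parsed at construction.
    """

    def __init__(self, patterns: Mapping[str, Iterable[str]],
                 hgnc: HgncTable | None = None, version: str = "custom"):
        hgnc = hgnc or load_default_hgnc()
        self.version = version
        self.patterns: dict[str, list[ProteinChange]] = {}
        self.pattern_text: dict[str, list[str]] = {}
        for gene, exprs in patterns.items():
            canonical, _ = normalize_gene_symbol(gene, hgnc)
            parsed = [parse_protein_hgvs(expand_protein_hgvs(e)) for e in exprs]
            self.patterns[canonical] = parsed
            self.pattern_text[canonical] = [str(p) for p in parsed]

    @classmethod
    def from_json(cls, path: str | Path,
                  hgnc: HgncTable | None = None) -> "ActionableRegistry":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(raw["patterns"], hgnc, raw.get("version", "custom"))

    def genes(self) -> list[str]:
        return sorted(self.patterns)


def load_default_registry() -> ActionableRegistry:
    """The bundled NSCLC actionable-mutation registry (EGFR, KRAS, BRAF,
    NRAS, PIK3CA)."""
    from importlib import resources

    ref = resources.files("varcdm.assets").joinpath("actionable_registry.json")
    with resources.as_file(ref) as path:
        return ActionableRegistry.from_json(path)


@dataclass(frozen=True)
class ActionableRow:
    gene: str
    pattern: str        # formatted pattern, or "any" for the gene level
    condition: str      # "all" or a condition name
    n_patients: int
    n_total: int
    frequency: float


def _patient_changes(db: CohortDB, gene: str) -> dict[int, list[ProteinChange]]:
    """Parsed protein changes per patient for one gene."""
    out: dict[int, list[ProteinChange]] = {}
    for person_id, hgvs_p in db.conn.execute(
        "SELECT p.person_id, v.hgvs_p FROM variant_occurrence v "
        "JOIN target_gene g ON v.target_gene_id = g.target_gene_id "
        "JOIN procedure_occurrence p ON v.procedure_id = p.procedure_id "
        "WHERE g.hgnc_symbol = ? AND v.hgvs_p IS NOT NULL", (gene,)
    ):
        try:
            out.setdefault(person_id, []).append(parse_protein_hgvs(hgvs_p))
        except Exception:  # stored rows are pre-validated; belt and braces
            continue
    return out


def actionable_frequency(
    db: CohortDB,
    registry: ActionableRegistry,
    stratify_by_condition: bool = False,
) -> list[ActionableRow]:
    """Patient frequencies of actionable-mutation patterns.

    A patient counts once per pattern, and once per gene across that
    gene's patterns.  Registry genes absent from the loaded panel produce
    a warning, not an error.  With ``stratify_by_condition``, rows are
    additionally computed per condition name with condition-specific
    denominators.
    """
    n = _require_cohort(db)
    panel = {
        row[0] for row in db.conn.execute("SELECT DISTINCT hgnc_symbol FROM target_gene")
    }
    condition = _condition_of_person(db)
    strata: list[tuple[str, set[int] | None, int]] = [("all", None, n)]
    if stratify_by_condition:
        by_name: dict[str, set[int]] = {}
        for person_id, name in condition.items():
            by_name.setdefault(name, set()).add(person_id)
        for name in sorted(by_name):
            strata.append((name, by_name[name], len(by_name[name])))

    rows: list[ActionableRow] = []
    for gene in registry.genes():
        if gene not in panel:
            logger.warning("registry gene %s is not on the loaded panel", gene)
        changes = _patient_changes(db, gene)
        pattern_hits: list[set[int]] = []
        for pattern in registry.patterns[gene]:
            hits = {
                person for person, observed in changes.items()
                if any(matches_pattern(o, pattern) for o in observed)
            }
            pattern_hits.append(hits)
        gene_hits = set().union(*pattern_hits) if pattern_hits else set()
        for label, members, denom in strata:
            if denom == 0:
                continue
            sub = gene_hits if members is None else gene_hits & members
            rows.append(ActionableRow(gene, "any", label, len(sub), denom,
                                      len(sub) / denom))
            for text, hits in zip(registry.pattern_text[gene], pattern_hits):
                sub = hits if members is None else hits & members
                rows.append(ActionableRow(gene, text, label, len(sub), denom,
                                          len(sub) / denom))
    return rows


@dataclass
class WaterfallMatrix:
    """Patient-by-gene mutation landscape.

    ``genes`` are ordered by variant frequency (descending); ``patients``
    by hierarchical presence/absence in that gene order (memo-sort), so the
    characteristic staircase is deterministic.  Each cell holds the single
    highest-priority variant_feature among that patient's variants in that
    gene, or ``None``.
    """

    genes: list[str]
    patients: list[int]
    cells: dict[tuple[str, int], str | None]
    gene_frequencies: dict[str, float]
    clinical: dict[int, dict[str, Any]]  # per-patient age / gender / condition

    def cell(self, gene: str, person_id: int) -> str | None:
        return self.cells.get((gene, person_id))

    def to_frame(self):
        """The matrix as a pandas DataFrame (genes x patients)."""
        import pandas as pd

        return pd.DataFrame(
            [[self.cells.get((g, p)) for p in self.patients] for g in self.genes],
            index=self.genes,
            columns=self.patients,
        )


_PRIORITY_RANK = {f: i for i, f in enumerate(WATERFALL_PRIORITY)}


def waterfall_matrix(
    db: CohortDB,
    genes: Sequence[str] | None = None,
    protein_altering_only: bool = False,
    top_n: int = 10,
) -> WaterfallMatrix:
    """Build the waterfall matrix for ``genes`` (default: the cohort's
    top-``top_n`` genes by variant frequency).

    Cell priority is most-deleterious-first: nonsense > frameshift >
    splice > inframe > missense > synonymous > intron > other.  Patients
    with no variants appear as all-``None`` columns.
    """
    _require_cohort(db)
    freq_rows = gene_variant_frequency(db, protein_altering_only=protein_altering_only)
    freq = {r.hgnc_symbol: r.frequency for r in freq_rows}
    if genes is None:
        genes = [r.hgnc_symbol for r in freq_rows[:top_n]]
    else:
        genes = sorted(genes, key=lambda g: (-freq.get(g, 0.0), g))

    feature_filter = ""
    params: list = []
    if protein_altering_only:
        qmarks = ", ".join("?" for _ in PROTEIN_ALTERING_FEATURES)
        feature_filter = f"AND v.variant_feature IN ({qmarks})"
        params = list(PROTEIN_ALTERING_FEATURES)

    cells: dict[tuple[str, int], str | None] = {}
    for gene, person_id, feature in db.conn.execute(
        "SELECT g.hgnc_symbol, p.person_id, v.variant_feature "
        "FROM variant_occurrence v "
        "JOIN target_gene g ON v.target_gene_id = g.target_gene_id "
        "JOIN procedure_occurrence p ON v.procedure_id = p.procedure_id "
        f"WHERE g.hgnc_symbol IN ({', '.join('?' for _ in genes)}) "
        f"{feature_filter}",
        list(genes) + params,
    ):
        key = (gene, person_id)
        current = cells.get(key)
        if current is None or _PRIORITY_RANK[feature] < _PRIORITY_RANK[current]:
            cells[key] = feature

    patients = [r[0] for r in db.conn.execute("SELECT person_id FROM person")]
    # memo-sort: presence-pattern in gene order, mutated-first, ties by id
    patients.sort(key=lambda p: tuple(
        0 if (g, p) in cells else 1 for g in genes
    ) + (p,))

    condition = _condition_of_person(db)
    clinical = {}
    for person_id, age, gender in db.conn.execute(
        "SELECT person_id, age_years, gender FROM person"
    ):
        clinical[person_id] = {
            "age": age, "gender": gender,
            "condition": condition.get(person_id, "unknown"),
        }
    return WaterfallMatrix(
        genes=list(genes),
        patients=patients,
        cells=cells,
        gene_frequencies={g: freq.get(g, 0.0) for g in genes},
        clinical=clinical,
    )


def query_variant(
    db: CohortDB,
    gene: str,
    hgvs_pattern: str | None = None,
    hgnc: HgncTable | None = None,
) -> tuple[int, int, float]:
    """Proportion of patients carrying a given mutation.

    With a null pattern, any variant in the gene counts; otherwise the
    stored protein changes are matched against the (possibly wildcard)
    pattern.  Returns ``(n_patients, N, frequency)``.
    """
    hgnc = hgnc or load_default_hgnc()
    canonical, _ = normalize_gene_symbol(gene, hgnc)
    n = _require_cohort(db)
    if hgvs_pattern is None:
        count = db.conn.execute(
            "SELECT COUNT(DISTINCT p.person_id) FROM variant_occurrence v "
            "JOIN target_gene g ON v.target_gene_id = g.target_gene_id "
            "JOIN procedure_occurrence p ON v.procedure_id = p.procedure_id "
            "WHERE g.hgnc_symbol = ?", (canonical,)
        ).fetchone()[0]
        return count, n, count / n
    pattern = parse_protein_hgvs(expand_protein_hgvs(hgvs_pattern))
    changes = _patient_changes(db, canonical)
    count = sum(
        1 for observed in changes.values()
        if any(matches_pattern(o, pattern) for o in observed)
    )
    return count, n, count / n


# --- aggregate export and comparison ---------------------------------------

def export_aggregate(
    db: CohortDB,
    site_label: str,
    suppression_k: int = 0,
    registry: ActionableRegistry | None = None,
) -> dict[str, Any]:
    """Patient-level-free summary of a cohort database.

    Contains only counts and denominators: demographics, per-gene patient
    counts, variant-type counts at both levels, actionable-pattern counts
    overall and per condition, and the panel gene list.  With
    ``suppression_k`` > 0, any count strictly between 0 and k is masked as
    the string ``"<k"`` to reduce re-identification risk.  Keys serialize
    deterministically (sorted).
    """
    n = _require_cohort(db)
    registry = registry or load_default_registry()

    demographics: dict[str, dict[str, int]] = {}
    for row in cohort_demographics(db):
        demographics.setdefault(row.group, {})[row.category] = row.count

    gene_counts = {
        r.hgnc_symbol: r.n_patients_with_variant for r in gene_variant_frequency(db)
    }
    try:
        alterations = {t: c for t, c, _ in variant_type_proportions(db, "sequence_alteration")}
        features = {t: c for t, c, _ in variant_type_proportions(db, "variant_feature")}
    except ValueError:  # no variants loaded
        alterations = {t: 0 for t in SEQUENCE_ALTERATIONS}
        features = {t: 0 for t in VARIANT_FEATURES}

    actionable: dict[str, dict[str, Any]] = {}
    for row in actionable_frequency(db, registry, stratify_by_condition=True):
        actionable.setdefault(row.condition, {}).setdefault(row.gene, {})[row.pattern] = row.n_patients
    condition_n = {"all": n}
    for person_id, name in _condition_of_person(db).items():
        condition_n[name] = condition_n.get(name, 0) + 1

    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "registry_version": registry.version,
        "site": site_label,
        "n_patients": n,
        "demographics": demographics,
        "gene_patient_counts": gene_counts,
        "sequence_alteration_counts": alterations,
        "variant_feature_counts": features,
        "actionable_patient_counts": actionable,
        "condition_n": condition_n,
        "panel_genes": sorted({
            r[0] for r in db.conn.execute("SELECT DISTINCT hgnc_symbol FROM target_gene")
        }),
        "suppression_k": suppression_k,
    }
    if suppression_k > 0:
        report = _suppress(report, suppression_k)
    return report


_UNSUPPRESSED_KEYS = {"n_patients", "suppression_k"}


def _suppress(node: Any, k: int, key: str | None = None) -> Any:
    if isinstance(node, dict):
        return {kk: (vv if kk in _UNSUPPRESSED_KEYS else _suppress(vv, k, kk))
                for kk, vv in node.items()}
    if isinstance(node, bool):
        return node
    if isinstance(node, int) and 0 < node < k:
        return f"<{k}"
    return node


def aggregate_to_json(report: Mapping[str, Any]) -> str:
    """Deterministic JSON serialization of an aggregate report."""
    return json.dumps(report, sort_keys=True, indent=2)


def merge_aggregates(x: Mapping[str, Any], y: Mapping[str, Any]) -> dict[str, Any]:
    """Element-wise sum of two unsuppressed aggregate reports from
    disjoint cohorts on the same panel (multi-site pooling)."""
    if x["schema_version"] != y["schema_version"]:
        raise ValueError("schema version mismatch")
    if x["panel_genes"] != y["panel_genes"]:
        raise ValueError("panel mismatch")
    if x.get("suppression_k") or y.get("suppression_k"):
        raise ValueError("cannot merge suppressed reports")

    def add(a: Any, b: Any) -> Any:
        if isinstance(a, dict) or isinstance(b, dict):
            a = a if isinstance(a, dict) else {}
            b = b if isinstance(b, dict) else {}
            return {k: add(a.get(k, 0), b.get(k, 0)) for k in set(a) | set(b)}
        if isinstance(a, (int, float)) and isinstance(b, (int, float)):
            return a + b
        return a if a == b else f"{a}+{b}"

    out = dict(x)
    out["site"] = f"{x['site']}+{y['site']}"
    for key in (
        "n_patients", "demographics", "gene_patient_counts",
        "sequence_alteration_counts", "variant_feature_counts",
        "actionable_patient_counts", "condition_n",
    ):
        out[key] = add(x[key], y[key])
    return out


def chi_squared_2x2(a: int, n1: int, b: int, n2: int) -> tuple[float, float, int]:
    """Pearson chi-squared (no continuity correction) comparing a/n1
    against b/n2.

    The 2x2 table is [[a, n1-a], [b, n2-b]]; the statistic is
    N*(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) and the p-value is the df=1
    upper tail.  A table with an empty margin (all successes or all
    failures pooled) is degenerate and raises ``ValueError``.
    """
    if not (0 <= a <= n1 and 0 <= b <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError("counts must satisfy 0 <= a <= n1, 0 <= b <= n2, n1,n2 > 0")
    c, d = n1 - a, n2 - b
    n = n1 + n2
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("degenerate 2x2 table: an outcome margin is zero")
    statistic = n * (a * d - c * b) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p_value = float(_chi2_dist.sf(statistic, 1))
    return float(statistic), p_value, 1


@dataclass(frozen=True)
class ComparisonRow:
    item: str
    count_x: int
    n_x: int
    count_y: int
    n_y: int
    freq_x: float
    freq_y: float
    ratio: float | None     # freq_x / freq_y, half-up to 2 decimals
    chi2: float | None
    p_value: float | None
    significant: bool | None  # p < 0.05
    note: str = ""


def compare_aggregates(
    x: Mapping[str, Any],
    y: Mapping[str, Any],
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> list[ComparisonRow]:
    """Item-by-item comparison of two sites' aggregate reports.

    Items are per-gene patient counts, actionable-pattern patient counts
    (denominator: cohort N) and variant-type counts at both levels
    (denominator: total variant rows).  Each comparable item gets a
    frequency ratio (2 decimals, half-up) and a Pearson chi-squared test;
    the significance threshold is ``alpha`` (0.05 by default, matching
    standard practice; an optional Bonferroni correction over the emitted
    tests is off by default).  Suppressed cells and zero denominators are
    refused/skipped with a note.
    """
    if x["schema_version"] != y["schema_version"]:
        raise ValueError("schema version mismatch between reports")
    if x["panel_genes"] != y["panel_genes"]:
        raise ValueError("panel mismatch between reports")

    items: list[tuple[str, Any, int, Any, int]] = []
    n_x, n_y = x["n_patients"], y["n_patients"]
    for gene in x["panel_genes"]:
        items.append((
            f"gene:{gene}",
            x["gene_patient_counts"].get(gene, 0), n_x,
            y["gene_patient_counts"].get(gene, 0), n_y,
        ))
    act_x = x["actionable_patient_counts"].get("all", {})
    act_y = y["actionable_patient_counts"].get("all", {})
    for gene in sorted(set(act_x) | set(act_y)):
        patterns = sorted(set(act_x.get(gene, {})) | set(act_y.get(gene, {})))
        for pattern in patterns:
            items.append((
                f"actionable:{gene}:{pattern}",
                act_x.get(gene, {}).get(pattern, 0), n_x,
                act_y.get(gene, {}).get(pattern, 0), n_y,
            ))
    for level_key, label in (
        ("sequence_alteration_counts", "alteration"),
        ("variant_feature_counts", "feature"),
    ):
        totals = (sum(v for v in x[level_key].values() if isinstance(v, int)),
                  sum(v for v in y[level_key].values() if isinstance(v, int)))
        for t in sorted(x[level_key]):
            items.append((
                f"{label}:{t}",
                x[level_key].get(t, 0), totals[0],
                y[level_key].get(t, 0), totals[1],
            ))

    usable = []
    skipped = []
    for item, a, na, b, nb in items:
        if isinstance(a, str) or isinstance(b, str):
            raise ValueError(f"suppressed cell in compared item {item!r}")
        if na == 0 or nb == 0:
            skipped.append(ComparisonRow(item, a, na, b, nb, 0.0, 0.0,
                                         None, None, None, None,
                                         note="zero denominator; skipped"))
            continue
        usable.append((item, a, na, b, nb))

    threshold = alpha / len(usable) if (bonferroni and usable) else alpha
    rows: list[ComparisonRow] = []
    for item, a, na, b, nb in usable:
        fx, fy = a / na, b / nb
        ratio = round_half_up(fx / fy, 2) if fy > 0 else None
        try:
            stat, p, _df = chi_squared_2x2(a, na, b, nb)
            rows.append(ComparisonRow(item, a, na, b, nb, fx, fy, ratio,
                                      stat, p, p < threshold))
        except ValueError:
            rows.append(ComparisonRow(item, a, na, b, nb, fx, fy, ratio,
                                      None, None, None,
                                      note="degenerate table; no test"))
    rows.extend(skipped)
    return rows
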