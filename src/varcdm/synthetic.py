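"""Self-contained synthetic cohorts for development and testing.

Two kinds of fixtures: (1) clinically exact cohorts whose demographic
margins reproduce the published two-cohort description (a 114-patient
panel site and a 1060-patient whole-exome site restricted to the same
49-gene panel); (2) stochastic variant cohorts with configurable per-gene
and per-pattern per-patient probabilities, used for parameter-recovery
and two-site-comparison studies.  Everything is seeded and deterministic.

The generator emulates the *marginal* statistics of real cohorts (gene
frequencies, hotspot-pattern frequencies, variant-type mixes); it does not
model mutational signatures, positional hotspot clustering beyond the
configured patterns, or co-mutation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import schema
from .etl import PanelDefinition, load_default_panel, register_panel
from .nomenclature import THREE_TO_ONE, load_default_hgnc, parse_protein_hgvs
from .schema import (
    CohortDB,
    CareSiteRecord,
    ConditionRecord,
    PersonRecord,
    ProcedureRecord,
    SpecimenRecord,
    VariantOccurrenceRecord,
    init_database,
    insert_records,
)

__all__ = [
    "CohortSpec",
    "table1_fixture",
    "generate_cohort",
    "two_site_fixture",
    "pool_databases",
    "AUSOM_LIKE_DEMOGRAPHICS",
    "TCGA_LIKE_DEMOGRAPHICS",
]

#: standard 20 residues (three-letter), used for substitution draws
_RESIDUES = sorted(set(THREE_TO_ONE) - {"Ter", "Xaa", "Sec"})

# Exact demographic margins of the two published cohorts:
# category lists are (label, count) in table order.
AUSOM_LIKE_DEMOGRAPHICS = {
    "n": 114,
    "age": [("<=49", 7), ("50-59", 26), ("60-69", 41), ("70-79", 35),
            (">=80", 5), ("unknown", 0)],
    "gender": [("male", 64), ("female", 50), ("unknown", 0)],
    "pathology": [("lung adenocarcinoma", 92), ("lung squamous cell carcinoma", 22)],
    "stage": [("I", 78), ("II", 16), ("III", 18), ("IV", 0), ("unknown", 2)],
}
TCGA_LIKE_DEMOGRAPHICS = {
    "n": 1060,
    "age": [("<=49", 44), ("50-59", 163), ("60-69", 310), ("70-79", 317),
            (">=80", 56), ("unknown", 170)],
    "gender": [("male", 628), ("female", 429), ("unknown", 3)],
    "pathology": [("lung adenocarcinoma", 603), ("lung squamous cell carcinoma", 457)],
    "stage": [("I", 526), ("II", 286), ("III", 184), ("IV", 36), ("unknown", 28)],
}

_AGE_REPRESENTATIVE = {
    "<=49": 45, "50-59": 55, "60-69": 65, "70-79": 75, ">=80": 85,
    "unknown": None,
}


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic cohort.

    ``gene_probs`` is the per-patient probability of carrying >=1 variant
    in a gene; ``pattern_probs`` maps (gene, HGVS pattern) to the
    per-patient probability of carrying that specific (possibly
    wildcarded) mutation.  A mutated patient-gene receives 1 +
    Poisson(``extra_variant_rate``) variants with features/alterations
    drawn from the weight tables.
    """

    n_patients: int
    seed: int = 0
    panel: PanelDefinition | None = None
    demographics: Mapping | None = None          # exact-count table as above
    gene_probs: Mapping[str, float] = field(default_factory=dict)
    pattern_probs: Mapping[tuple[str, str], float] = field(default_factory=dict)
    feature_weights: Mapping[str, float] = field(default_factory=lambda: {
        "missense": 0.60, "nonsense": 0.08, "frameshift": 0.08,
        "inframe": 0.04, "splice": 0.05, "synonymous": 0.10,
        "intron": 0.04, "other": 0.01,
    })
    alteration_weights: Mapping[str, float] = field(default_factory=lambda: {
        "SNP": 0.88, "insertion": 0.04, "deletion": 0.06, "MNP": 0.02,
    })
    extra_variant_rate: float = 0.3              # Poisson rate of extra variants
    id_offset: int = 0                           # shift all surrogate keys
    site_name: str = "synthetic"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name, weights in (("feature_weights", self.feature_weights),
                              ("alteration_weights", self.alteration_weights)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} must be non-negative")
        for p in list(self.gene_probs.values()) + list(self.pattern_probs.values()):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        panel = self.panel or load_default_panel()
        panel_genes = set(panel.genes)
        for gene in self.gene_probs:
            if gene not in panel_genes:
                raise ValueError(f"gene_probs gene {gene!r} absent from panel")
        for gene, _pattern in self.pattern_probs:
            if gene not in panel_genes:
                raise ValueError(f"pattern_probs gene {gene!r} absent from panel")


def _load_clinical_tables(
    db: CohortDB, demographics: Mapping, id_offset: int, site_name: str
) -> None:
    """Insert person + condition rows matching the exact category counts.

    Each margin (age, gender, pathology, stage) is assigned independently
    in blocks over person ids; only the margins are contractual.
    """
    n = demographics["n"]

    def assign(category_counts) -> list:
        out = []
        for label, count in category_counts:
            out.extend([label] * count)
        if len(out) != n:
            raise ValueError("demographic counts do not sum to cohort N")
        return out

    ages = assign(demographics["age"])
    genders = assign(demographics["gender"])
    pathologies = assign(demographics["pathology"])
    stages = assign(demographics["stage"])

    persons, conditions = [], []
    for i in range(n):
        pid = id_offset + i + 1
        persons.append(PersonRecord(
            person_id=pid,
            gender=genders[i],
            age_years=_AGE_REPRESENTATIVE[ages[i]],
        ))
        conditions.append(ConditionRecord(
            condition_id=pid,
            person_id=pid,
            condition_name=pathologies[i],
            condition_type="primary condition",
            stage=stages[i],
        ))
    insert_records(db, "person", persons)
    insert_records(db, "condition_occurrence", conditions)


def table1_fixture(site: str = "ausom_like", path: str = ":memory:") -> CohortDB:
    """Clinical-tables-only cohort with the exact published margins.

    ``site`` is ``ausom_like`` (N=114 panel cohort) or ``tcga_like``
    (N=1060 whole-exome cohort).  Person ids are deterministic (1..N).
    """
    demographics = {
        "ausom_like": AUSOM_LIKE_DEMOGRAPHICS,
        "tcga_like": TCGA_LIKE_DEMOGRAPHICS,
    }.get(site)
    if demographics is None:
        raise ValueError(f"unknown site {site!r}; expected ausom_like or tcga_like")
    db = init_database(path, overwrite=True)
    _load_clinical_tables(db, demographics, id_offset=0, site_name=site)
    return db


def _default_demographics(n: int) -> Mapping:
    """A plausible NSCLC demographic split for an arbitrary cohort size."""
    def scaled(pairs):
        counts = [int(round(n * w)) for _, w in pairs]
        counts[0] += n - sum(counts)   # absorb rounding drift in first bin
        return [(label, c) for (label, _), c in zip(pairs, counts)]

    return {
        "n": n,
        "age": scaled([("<=49", 0.05), ("50-59", 0.18), ("60-69", 0.33),
                       ("70-79", 0.32), (">=80", 0.06), ("unknown", 0.06)]),
        "gender": scaled([("male", 0.58), ("female", 0.42), ("unknown", 0.0)]),
        "pathology": scaled([("lung adenocarcinoma", 0.60),
                             ("lung squamous cell carcinoma", 0.40)]),
        "stage": scaled([("I", 0.50), ("II", 0.25), ("III", 0.17),
                         ("IV", 0.04), ("unknown", 0.04)]),
    }


def _instantiate_pattern(pattern_text: str, rng: np.random.Generator) -> str:
    """Turn a registry pattern into a concrete observation: a wildcard is
    replaced uniformly by one of the 19 residues differing from the
    reference; literal patterns pass through."""
    change = parse_protein_hgvs(pattern_text)
    if not change.is_wildcard:
        return pattern_text
    candidates = [r for r in _RESIDUES if r != change.ref_residue]
    alt = candidates[int(rng.integers(len(candidates)))]
    return f"p.{change.ref_residue}{change.position}{alt}"


def _feature_of_concrete(hgvs_p: str) -> str:
    change = parse_protein_hgvs(hgvs_p)
    if change.kind == "substitution":
        return "nonsense" if change.alt_residue == "Ter" else "missense"
    if change.kind == "frameshift":
        return "frameshift"
    if change.kind in ("deletion", "insertion", "duplication", "delins"):
        return "inframe"
    return "synonymous"


def _random_hgvs(feature: str, rng: np.random.Generator) -> str | None:
    """A parseable protein expression consistent with ``feature`` (or None
    for features with no protein-level description)."""
    pos = int(rng.integers(30, 900))
    ref = _RESIDUES[int(rng.integers(len(_RESIDUES)))]
    if feature == "missense":
        alt = _RESIDUES[int(rng.integers(len(_RESIDUES) - 1))]
        if alt == ref:
            alt = _RESIDUES[-1] if ref != _RESIDUES[-1] else _RESIDUES[0]
        return f"p.{ref}{pos}{alt}"
    if feature == "nonsense":
        return f"p.{ref}{pos}Ter"
    if feature == "frameshift":
        alt = _RESIDUES[int(rng.integers(len(_RESIDUES)))]
        return f"p.{ref}{pos}{alt}fsTer{int(rng.integers(2, 40))}"
    if feature == "inframe":
        end_ref = _RESIDUES[int(rng.integers(len(_RESIDUES)))]
        return f"p.{ref}{pos}_{end_ref}{pos + 2}del"
    if feature == "synonymous":
        return f"p.{ref}{pos}="
    return None  # splice / intron / other: DNA-level only


def generate_cohort(spec: CohortSpec, path: str = ":memory:") -> CohortDB:
    """Generate a full cohort database from ``spec``.

    Per patient, each gene mutates independently with its configured
    probability; mutated patient-genes get 1 + Poisson extra variants with
    features and structural classes drawn from the weight tables
    (frameshift/inframe variants force an indel class; CNV/translocation
    draws carry no protein-level change).  Pattern carriers additionally
    receive the configured hotspot mutation, wildcards instantiated
    uniformly.  Deterministic for a fixed seed; the result passes
    database validation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel or load_default_panel()
    hgnc = load_default_hgnc()

    db = init_database(path, overwrite=True)
    demographics = spec.demographics or _default_demographics(spec.n_patients)
    if demographics["n"] != spec.n_patients:
        raise ValueError("demographics N does not match n_patients")
    _load_clinical_tables(db, demographics, spec.id_offset, spec.site_name)
    _, gene_ids = register_panel(db, panel, hgnc, site_name=spec.site_name,
                                 id_base=spec.id_offset)

    off = spec.id_offset
    n = spec.n_patients
    procedures, specimens = [], []
    for i in range(n):
        pid = off + i + 1
        procedures.append(ProcedureRecord(
            procedure_id=pid, person_id=pid,
            acquisition_method="biopsy", genomic_test_name=panel.test_name,
        ))
        specimens.append(SpecimenRecord(
            specimen_id=pid, person_id=pid, specimen_role="target",
            specimen_type="tumor tissue", collection_date="2018-01-01",
        ))
        specimens.append(SpecimenRecord(
            specimen_id=off + n + i + 1, person_id=pid, specimen_role="reference",
            specimen_type="blood", collection_date="2018-01-01",
        ))
    insert_records(db, "procedure_occurrence", procedures)
    insert_records(db, "specimen", specimens)

    features = sorted(spec.feature_weights)
    feature_p = np.array([spec.feature_weights[f] for f in features])
    alterations = sorted(spec.alteration_weights)
    alteration_p = np.array([spec.alteration_weights[a] for a in alterations])
    panel_genes = [g for g in panel.genes]
    patterns = sorted(spec.pattern_probs.items())

    variants: list[VariantOccurrenceRecord] = []
    vid = off  # variant ids share the offset namespace
    for i in range(n):
        pid = off + i + 1
        for gene in panel_genes:
            p = spec.gene_probs.get(gene, 0.0)
            if p <= 0.0 or rng.random() >= p:
                continue
            k = 1 + int(rng.poisson(spec.extra_variant_rate))
            for _ in range(k):
                feature = features[int(rng.choice(len(features), p=feature_p))]
                alteration = alterations[int(rng.choice(len(alterations), p=alteration_p))]
                if feature in ("frameshift", "inframe"):
                    alteration = "deletion" if rng.random() < 0.5 else "insertion"
                hgvs_p = _random_hgvs(feature, rng)
                if alteration in ("CNV", "translocation"):
                    feature, hgvs_p = "other", None
                vid += 1
                variants.append(VariantOccurrenceRecord(
                    variant_occurrence_id=vid,
                    procedure_id=pid,
                    specimen_id_target=pid,
                    specimen_id_reference=off + n + i + 1,
                    target_gene_id=gene_ids[gene],
                    hgvs_p=hgvs_p,
                    read_depth=int(rng.integers(50, 2000)),
                    sequence_alteration=alteration,
                    variant_feature=feature,
                ))
        for (gene, pattern_text), p in patterns:
            if p <= 0.0 or rng.random() >= p:
                continue
            concrete = _instantiate_pattern(pattern_text, rng)
            vid += 1
            variants.append(VariantOccurrenceRecord(
                variant_occurrence_id=vid,
                procedure_id=pid,
                specimen_id_target=pid,
                specimen_id_reference=off + n + i + 1,
                target_gene_id=gene_ids[gene],
                hgvs_p=concrete,
                read_depth=int(rng.integers(50, 2000)),
                sequence_alteration="SNP",
                variant_feature=_feature_of_concrete(concrete),
            ))
    insert_records(db, "variant_occurrence", variants)
    return db


# --- the two-site study conditions -----------------------------------------

# Site A emulates a clinical panel cohort of Asian NSCLC patients: very
# high per-gene variant frequencies (the panel reports intronic and
# synonymous calls), EGFR-driven, with CNV/translocation calls enabled.
# EGFR background set so that background ∪ hotspot patterns ≈ 0.895:
# 1 - (1-0.870)(1-0.175)(1-0.018) ≈ 0.895
SITE_A_GENE_PROBS = {
    "EGFR": 0.870, "TP53": 0.85, "APC": 0.82, "NOTCH1": 0.80, "ATM": 0.79,
    "BRCA2": 0.78, "RET": 0.77, "ALK": 0.76, "MET": 0.76, "ROS1": 0.75,
    "KRAS": 0.30, "PIK3CA": 0.35, "BRAF": 0.25, "NRAS": 0.20, "STK11": 0.30,
}
SITE_A_PATTERN_PROBS = {
    ("EGFR", "p.Leu858Arg"): 0.175,
    ("EGFR", "p.Thr790Met"): 0.018,
    ("KRAS", "p.Gly12Xaa"): 0.085,
    ("KRAS", "p.Gly13Xaa"): 0.012,
    ("BRAF", "p.Val600Glu"): 0.020,
    ("NRAS", "p.Gln61Xaa"): 0.010,
    ("PIK3CA", "p.Glu542Lys"): 0.010,
    ("PIK3CA", "p.Glu545Lys"): 0.015,
    ("PIK3CA", "p.His1047Arg"): 0.010,
}
# intron + synonymous dominate: background weight 0.88 so that after
# hotspot-pattern injection and CNV/translocation reclassification the
# realized row proportion lands near 0.83; SNPs > 80% of rows
SITE_A_FEATURE_WEIGHTS = {
    "missense": 0.075, "nonsense": 0.005, "frameshift": 0.02, "inframe": 0.005,
    "splice": 0.005, "synonymous": 0.40, "intron": 0.48, "other": 0.01,
}
SITE_A_ALTERATION_WEIGHTS = {
    "SNP": 0.85, "insertion": 0.05, "deletion": 0.05, "MNP": 0.02,
    "CNV": 0.02, "translocation": 0.01,
}

# Site B emulates a research whole-exome cohort restricted to the same
# panel: somatic coding calls only (missense-dominated, 0.73), SNP/INDEL
# only, TP53 the only gene above 25%, KRAS-driven actionable profile.
# EGFR/KRAS backgrounds set so background ∪ patterns lands at the
# intended gene-level frequencies (~0.115 for EGFR, ~0.24 for KRAS); the
# two sites' top-10 gene sets overlap in five genes (TP53, EGFR, MET,
# APC, ATM), so their union profiles 15 genes.
SITE_B_GENE_PROBS = {
    "TP53": 0.56, "KRAS": 0.060, "KEAP1": 0.17, "STK11": 0.15, "EGFR": 0.089,
    "NF1": 0.12, "PIK3CA": 0.12, "MET": 0.11, "APC": 0.105, "ATM": 0.10,
    "PTEN": 0.06, "RB1": 0.05, "NRAS": 0.04, "CDKN2A": 0.04, "BRAF": 0.03,
}
SITE_B_PATTERN_PROBS = {
    ("EGFR", "p.Leu858Arg"): 0.0264,   # 0.175 / 6.64
    ("EGFR", "p.Thr790Met"): 0.002,
    ("KRAS", "p.Gly12Xaa"): 0.172,     # 0.085 * 2.02
    ("KRAS", "p.Gly13Xaa"): 0.024,
    ("BRAF", "p.Val600Glu"): 0.020,
    ("NRAS", "p.Gln61Xaa"): 0.010,
    ("PIK3CA", "p.Glu542Lys"): 0.020,
    ("PIK3CA", "p.Glu545Lys"): 0.020,
    ("PIK3CA", "p.His1047Arg"): 0.010,
}
# missense background 0.70 so the realized proportion including injected
# hotspot substitutions lands near 0.73
SITE_B_FEATURE_WEIGHTS = {
    "missense": 0.70, "nonsense": 0.08, "frameshift": 0.06, "inframe": 0.02,
    "splice": 0.05, "synonymous": 0.06, "intron": 0.02, "other": 0.01,
}
SITE_B_ALTERATION_WEIGHTS = {"SNP": 0.90, "insertion": 0.04, "deletion": 0.06}

#: person/key-id offset separating the two sites so their databases pool
SITE_B_ID_OFFSET = 1_000_000


def two_site_fixture(seed: int = 0) -> tuple[CohortDB, CohortDB]:
    """The two-site study conditions: a 114-patient panel cohort (site A,
    CNV/translocation enabled) and a 1060-patient whole-exome-restricted
    cohort (site B, SNP/INDEL only), sharing the 49-gene panel.  Surrogate
    keys are disjoint so the two databases can be pooled."""
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    spec_a = CohortSpec(
        n_patients=114, seed=seed_a,
        demographics=AUSOM_LIKE_DEMOGRAPHICS,
        gene_probs=SITE_A_GENE_PROBS,
        pattern_probs=SITE_A_PATTERN_PROBS,
        feature_weights=SITE_A_FEATURE_WEIGHTS,
        alteration_weights=SITE_A_ALTERATION_WEIGHTS,
        site_name="site_a",
    )
    spec_b = CohortSpec(
        n_patients=1060, seed=seed_b,
        demographics=TCGA_LIKE_DEMOGRAPHICS,
        gene_probs=SITE_B_GENE_PROBS,
        pattern_probs=SITE_B_PATTERN_PROBS,
        feature_weights=SITE_B_FEATURE_WEIGHTS,
        alteration_weights=SITE_B_ALTERATION_WEIGHTS,
        id_offset=SITE_B_ID_OFFSET,
        site_name="site_b",
    )
    return generate_cohort(spec_a), generate_cohort(spec_b)


def pool_databases(dbs: Sequence[CohortDB], path: str = ":memory:") -> CohortDB:
    """Union of several cohort databases with disjoint surrogate keys
    (e.g. the two-site fixture) into one database."""
    pooled = init_database(path, overwrite=True)
    for table in schema.TABLE_ORDER:
        for db in dbs:
            rows = db.fetch_table(table)
            if rows:
                insert_records(pooled, table, rows)
    return pooled
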