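"""Cohort analytics: frequencies, actionable profiling, waterfall,
aggregate export/comparison, chi-squared."""

import json

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from varcdm import profiler
from varcdm.profiler import (
    ActionableRegistry,
    GeneFrequencyRow,
    actionable_frequency,
    chi_squared_2x2,
    cohort_demographics,
    compare_aggregates,
    export_aggregate,
    gene_variant_frequency,
    load_default_registry,
    merge_aggregates,
    query_variant,
    round_half_up,
    top_gene_union,
    variant_type_proportions,
    waterfall_matrix,
)
from varcdm.schema import init_database
from varcdm.synthetic import (
    CohortSpec,
    generate_cohort,
    pool_databases,
    table1_fixture,
    two_site_fixture,
)

from conftest import add_variant


class TestDemographics:
    def test_published_margin_percentages(self):
        ausom = {(r.group, r.category): (r.count, r.percent)
                 for r in cohort_demographics(table1_fixture("ausom_like"))}
        assert ausom[("pathology", "lung adenocarcinoma")] == (92, 80.7)
        assert ausom[("gender", "male")] == (64, 56.1)
        assert ausom[("stage", "I")] == (78, 68.4)
        tcga = {(r.group, r.category): (r.count, r.percent)
                for r in cohort_demographics(table1_fixture("tcga_like"))}
        assert tcga[("age", "unknown")] == (170, 16.0)
        assert tcga[("stage", "IV")] == (36, 3.4)
        assert tcga[("pathology", "lung squamous cell carcinoma")] == (457, 43.1)

    def test_groups_sum_to_cohort_n(self):
        rows = cohort_demographics(table1_fixture("ausom_like"))
        for group in ("age", "gender", "pathology", "stage"):
            assert sum(r.count for r in rows if r.group == group) == 114

    def test_single_patient_cohort(self, empty_db):
        from varcdm.schema import PersonRecord, insert_records

        insert_records(empty_db, "person",
                       [PersonRecord(person_id=1, gender="male")])
        rows = cohort_demographics(empty_db)
        male = next(r for r in rows if r.group == "gender" and r.category == "male")
        assert (male.count, male.percent) == (1, 100.0)

    def test_empty_cohort_is_an_error(self, empty_db):
        with pytest.raises(ValueError, match="empty_cohort"):
            cohort_demographics(empty_db)


def test_round_half_up_matches_printed_table_convention():
    assert round_half_up(100 * 92 / 114, 1) == 80.7
    assert round_half_up(0.05, 1) == 0.1     # ties go up, not to even
    assert round_half_up(6.635, 2) == 6.64


class TestGeneFrequency:
    def test_patient_counts_once_per_gene(self, cohort_db):
        for _ in range(4):  # four distinct TP53 missense calls, one patient
            add_variant(cohort_db, 1, "TP53")
        for pid in (1, 2, 3):
            add_variant(cohort_db, pid, "EGFR")
        rows = {r.hgnc_symbol: r for r in gene_variant_frequency(cohort_db)}
        assert rows["TP53"].n_patients_with_variant == 1
        assert rows["EGFR"] == GeneFrequencyRow("EGFR", 3, 10, 0.3)

    def test_protein_altering_filter(self, cohort_db):
        add_variant(cohort_db, 1, "EGFR", feature="intron")
        add_variant(cohort_db, 2, "EGFR", feature="synonymous")
        add_variant(cohort_db, 3, "EGFR", feature="missense")
        all_rows = {r.hgnc_symbol: r for r in gene_variant_frequency(cohort_db)}
        pa_rows = {r.hgnc_symbol: r
                   for r in gene_variant_frequency(cohort_db, True)}
        assert all_rows["EGFR"].n_patients_with_variant == 3
        assert pa_rows["EGFR"].n_patients_with_variant == 1

    def test_binomial_parameter_recovery(self):
        """A cohort drawn with EGFR per-patient probability 0.895 recovers
        that frequency within 3 binomial standard errors."""
        p, n = 0.895, 1000
        se = np.sqrt(p * (1 - p) / n)
        db = generate_cohort(CohortSpec(
            n_patients=n, seed=11, gene_probs={"EGFR": p},
        ))
        row = next(r for r in gene_variant_frequency(db)
                   if r.hgnc_symbol == "EGFR")
        assert abs(row.frequency - p) < 3 * se


class TestTopGeneUnion:
    def _table(self, pairs):
        return [GeneFrequencyRow(g, int(100 * f), 100, f) for g, f in pairs]

    def test_identical_tables_give_their_top_k(self):
        t = self._table([("A", 0.9), ("B", 0.8), ("C", 0.7), ("D", 0.6)])
        assert top_gene_union(t, t, 3) == ["A", "B", "C"]

    def test_disjoint_tops_concatenate(self):
        a = self._table([("A", 0.9), ("B", 0.8)] + [(f"X{i}", 0.01) for i in range(5)])
        b = self._table([("C", 0.7), ("D", 0.6)] + [(f"X{i}", 0.01) for i in range(5)])
        assert top_gene_union(a, b, 2) == ["A", "B", "C", "D"]

    def test_partial_overlap_yields_union(self):
        """Top-10 sets overlapping in 5 genes give a 15-gene union."""
        shared = [(f"S{i}", 0.9 - i * 0.01) for i in range(5)]
        a = self._table(shared + [(f"A{i}", 0.5 - i * 0.01) for i in range(5)]
                        + [("Z", 0.001)])
        b = self._table(shared + [(f"B{i}", 0.4 - i * 0.01) for i in range(5)]
                        + [("Z", 0.001)])
        union = top_gene_union(a, b, 10)
        assert len(union) == 15
        assert union[:5] == [f"S{i}" for i in range(5)]

    def test_k_below_one_rejected(self):
        t = self._table([("A", 0.5)])
        with pytest.raises(ValueError):
            top_gene_union(t, t, 0)


class TestVariantTypeProportions:
    def test_proportions_over_variant_rows(self, cohort_db):
        for i in range(1, 9):
            add_variant(cohort_db, (i % 10) + 1, "EGFR", alteration="SNP")
        add_variant(cohort_db, 1, "KRAS", alteration="insertion",
                    feature="frameshift")
        add_variant(cohort_db, 2, "TP53", alteration="deletion",
                    feature="frameshift")
        table = dict((t, p) for t, _c, p in
                     variant_type_proportions(cohort_db, "sequence_alteration"))
        assert table["SNP"] == 0.8
        assert abs(sum(table.values()) - 1.0) < 1e-9

    def test_single_variant_is_proportion_one(self, cohort_db):
        add_variant(cohort_db, 1, "EGFR", feature="missense")
        table = dict((t, p) for t, _c, p in
                     variant_type_proportions(cohort_db, "variant_feature"))
        assert table["missense"] == 1.0

    def test_multinomial_weight_recovery(self):
        """Variant features drawn with missense weight 0.73 recover that
        proportion within 3 multinomial standard errors."""
        weights = {"missense": 0.73, "nonsense": 0.05, "frameshift": 0.05,
                   "inframe": 0.03, "splice": 0.04, "synonymous": 0.06,
                   "intron": 0.03, "other": 0.01}
        db = generate_cohort(CohortSpec(
            n_patients=400, seed=5,
            gene_probs={g: 0.6 for g in ("EGFR", "KRAS", "TP53", "BRAF",
                                         "PIK3CA", "ALK", "MET", "RET",
                                         "ATM", "APC")},
            feature_weights=weights,
            extra_variant_rate=1.0,
        ))
        table = {t: (c, p) for t, c, p in
                 variant_type_proportions(db, "variant_feature")}
        total = sum(c for c, _ in table.values())
        assert total > 3000
        se = np.sqrt(0.73 * 0.27 / total)
        assert abs(table["missense"][1] - 0.73) < 3 * se

    def test_no_variants_is_an_error(self, cohort_db):
        with pytest.raises(ValueError, match="no variants"):
            variant_type_proportions(cohort_db)


class TestActionable:
    def test_wildcard_groups_codon_substitutions(self, cohort_db):
        add_variant(cohort_db, 1, "KRAS", hgvs_p="p.Gly12Cys")
        add_variant(cohort_db, 2, "KRAS", hgvs_p="p.Gly12Asp")
        add_variant(cohort_db, 3, "KRAS", hgvs_p="p.Gly13Asp")
        registry = ActionableRegistry({"KRAS": ["p.Gly12Xaa"]})
        rows = {(r.gene, r.pattern): r.n_patients
                for r in actionable_frequency(cohort_db, registry)}
        assert rows[("KRAS", "p.Gly12Xaa")] == 2
        assert rows[("KRAS", "any")] == 2

    def test_patient_counts_once_per_gene_across_patterns(self, cohort_db):
        add_variant(cohort_db, 1, "EGFR", hgvs_p="p.Leu858Arg")
        add_variant(cohort_db, 1, "EGFR", hgvs_p="p.Thr790Met")
        registry = ActionableRegistry(
            {"EGFR": ["p.Leu858Arg", "p.Thr790Met"]})
        rows = {(r.gene, r.pattern): r.n_patients
                for r in actionable_frequency(cohort_db, registry)}
        assert rows[("EGFR", "any")] == 1
        assert rows[("EGFR", "p.Leu858Arg")] == 1
        assert rows[("EGFR", "p.Thr790Met")] == 1

    def test_empty_registry_gives_empty_table(self, cohort_db):
        add_variant(cohort_db, 1, "EGFR", hgvs_p="p.Leu858Arg")
        assert actionable_frequency(cohort_db, ActionableRegistry({})) == []

    def test_condition_stratification_uses_condition_denominators(self, cohort_db):
        from varcdm.schema import ConditionRecord, insert_records

        insert_records(cohort_db, "condition_occurrence", [
            ConditionRecord(condition_id=i, person_id=i,
                            condition_name=("lung adenocarcinoma" if i <= 6
                                            else "lung squamous cell carcinoma"))
            for i in range(1, 11)
        ])
        add_variant(cohort_db, 1, "EGFR", hgvs_p="p.Leu858Arg")
        add_variant(cohort_db, 7, "EGFR", hgvs_p="p.Leu858Arg")
        registry = ActionableRegistry({"EGFR": ["p.Leu858Arg"]})
        rows = actionable_frequency(cohort_db, registry,
                                    stratify_by_condition=True)
        luad = next(r for r in rows if r.condition == "lung adenocarcinoma"
                    and r.pattern == "p.Leu858Arg")
        assert (luad.n_patients, luad.n_total) == (1, 6)


class TestWaterfall:
    def test_cell_holds_highest_priority_feature(self, cohort_db):
        add_variant(cohort_db, 1, "TP53", feature="missense")
        add_variant(cohort_db, 1, "TP53", feature="nonsense")
        matrix = waterfall_matrix(cohort_db, genes=["TP53"])
        assert matrix.cell("TP53", 1) == "nonsense"

    def test_priority_is_stable_under_lower_priority_additions(self, cohort_db):
        add_variant(cohort_db, 1, "TP53", feature="nonsense")
        before = waterfall_matrix(cohort_db, genes=["TP53"]).cell("TP53", 1)
        for feature in ("missense", "synonymous", "intron", "other"):
            add_variant(cohort_db, 1, "TP53", feature=feature)
        after = waterfall_matrix(cohort_db, genes=["TP53"]).cell("TP53", 1)
        assert before == after == "nonsense"

    def test_genes_ordered_by_descending_frequency(self, cohort_db):
        for pid in range(1, 7):
            add_variant(cohort_db, pid, "TP53")
        for pid in range(1, 4):
            add_variant(cohort_db, pid, "EGFR")
        add_variant(cohort_db, 1, "KRAS")
        matrix = waterfall_matrix(cohort_db, genes=["KRAS", "EGFR", "TP53"])
        assert matrix.genes == ["TP53", "EGFR", "KRAS"]
        assert matrix.gene_frequencies["TP53"] == 0.6

    def test_memo_sort_puts_mutated_patients_first(self, cohort_db):
        add_variant(cohort_db, 5, "TP53")
        add_variant(cohort_db, 9, "TP53")
        add_variant(cohort_db, 9, "EGFR")
        matrix = waterfall_matrix(cohort_db, genes=["TP53", "EGFR"])
        assert matrix.patients[:2] == [9, 5]  # 9 mutated in both genes
        # patients with no variants appear as all-none columns
        assert matrix.cell("TP53", matrix.patients[-1]) is None

    def test_requested_gene_with_no_variants_is_all_none(self, cohort_db):
        add_variant(cohort_db, 1, "TP53")
        matrix = waterfall_matrix(cohort_db, genes=["TP53", "BRAF"])
        assert matrix.gene_frequencies["BRAF"] == 0.0
        assert all(matrix.cell("BRAF", p) is None for p in matrix.patients)


class TestQueryVariant:
    def test_literal_query_counts_carriers(self, cohort_db):
        add_variant(cohort_db, 1, "EGFR", hgvs_p="p.Leu858Arg")
        add_variant(cohort_db, 2, "EGFR", hgvs_p="p.Leu858Arg")
        add_variant(cohort_db, 3, "EGFR", hgvs_p="p.Thr790Met")
        assert query_variant(cohort_db, "EGFR", "p.Leu858Arg") == (2, 10, 0.2)

    def test_null_pattern_dominates_any_specialization(self, cohort_db):
        add_variant(cohort_db, 1, "EGFR", hgvs_p="p.Leu858Arg")
        add_variant(cohort_db, 2, "EGFR", hgvs_p="p.Thr790Met")
        add_variant(cohort_db, 3, "EGFR", feature="intron")
        n_any, _, _ = query_variant(cohort_db, "EGFR")
        for pattern in ("p.Leu858Arg", "p.Thr790Met", "p.Gly12Xaa"):
            n_pat, _, _ = query_variant(cohort_db, "EGFR", pattern)
            assert n_pat <= n_any

    def test_wildcard_query_equals_brute_force_scan(self, cohort_db):
        observed = {1: "p.Gly12Cys", 2: "p.Gly12Asp", 3: "p.Gly12Cys",
                    4: "p.Gly13Asp", 5: "p.Gly12Ter"}
        for pid, hgvs in observed.items():
            add_variant(cohort_db, pid, "KRAS", hgvs_p=hgvs)
        add_variant(cohort_db, 1, "KRAS", hgvs_p="p.Gly12Val")  # same patient
        # independent oracle: count distinct carriers of any codon-12
        # single-residue substitution by scanning the raw strings
        carriers = {pid for pid, h in observed.items()
                    if h.startswith("p.Gly12") and not h.endswith(("fs", "del"))}
        n, total, freq = query_variant(cohort_db, "KRAS", "p.Gly12Xaa")
        assert n == len(carriers)
        assert freq == n / total

    def test_one_letter_query_pattern_is_expanded(self, cohort_db):
        add_variant(cohort_db, 1, "EGFR", hgvs_p="p.Leu858Arg")
        assert query_variant(cohort_db, "EGFR", "p.L858R")[0] == 1


class TestAggregateExport:
    def test_report_contains_no_patient_identifiers(self):
        db = generate_cohort(CohortSpec(
            n_patients=7, seed=3, gene_probs={"EGFR": 1.0},
        ))
        report = export_aggregate(db, "site_x")
        text = json.dumps(report)
        assert "person_id" not in text
        assert "specimen_id" not in text
        # no list/dict anywhere has per-patient cardinality under a
        # patient-keyed name; every leaf is a count, label or version
        assert report["n_patients"] == 7

    def test_suppression_masks_small_counts(self, cohort_db):
        add_variant(cohort_db, 1, "EGFR", hgvs_p="p.Leu858Arg")
        report = export_aggregate(cohort_db, "s", suppression_k=5)
        assert report["gene_patient_counts"]["EGFR"] == "<5"
        assert report["n_patients"] == 10  # denominators stay visible
        raw = export_aggregate(cohort_db, "s", suppression_k=0)
        assert raw["gene_patient_counts"]["EGFR"] == 1

    def test_pooled_export_equals_summed_exports(self):
        """Aggregation homomorphism on a small disjoint two-cohort pair."""
        db_a = generate_cohort(CohortSpec(
            n_patients=30, seed=1, gene_probs={"EGFR": 0.5, "TP53": 0.3}))
        db_b = generate_cohort(CohortSpec(
            n_patients=40, seed=2, gene_probs={"EGFR": 0.2, "KRAS": 0.4},
            id_offset=1000))
        merged = merge_aggregates(export_aggregate(db_a, "A"),
                                  export_aggregate(db_b, "B"))
        pooled = export_aggregate(pool_databases([db_a, db_b]), "A+B")
        for key in ("n_patients", "demographics", "gene_patient_counts",
                    "sequence_alteration_counts", "variant_feature_counts",
                    "actionable_patient_counts", "condition_n"):
            assert merged[key] == pooled[key], key


class TestChiSquared:
    def test_worked_case_equals_closed_form(self):
        stat, p, df = chi_squared_2x2(30, 100, 10, 100)
        assert stat == pytest.approx(12.5, abs=1e-12)
        assert df == 1
        assert p < 0.001

    def test_identical_proportions_give_zero(self):
        stat, p, _ = chi_squared_2x2(10, 100, 10, 100)
        assert stat == 0
        assert p == 1

    def test_symmetric_under_group_swap(self):
        s1, _, _ = chi_squared_2x2(17, 114, 43, 1060)
        s2, _, _ = chi_squared_2x2(43, 1060, 17, 114)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_squared_2x2(0, 50, 0, 60)
        with pytest.raises(ValueError, match="degenerate"):
            chi_squared_2x2(50, 50, 60, 60)

    def test_agrees_with_scipy_on_random_tables(self):
        """Cross-check against scipy's Pearson test (no continuity
        correction) on 1000 random 2x2 tables."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            n1, n2 = rng.integers(2, 500, size=2)
            a, b = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            if (a + b) == 0 or (a + b) == (n1 + n2):
                continue
            stat, p, _ = chi_squared_2x2(int(a), int(n1), int(b), int(n2))
            ref = chi2_contingency(
                [[a, n1 - a], [b, n2 - b]], correction=False)
            assert stat == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)
            checked += 1


class TestCompareAggregates:
    def _reports(self, count_x, count_y, n=100):
        db_x = generate_cohort(CohortSpec(n_patients=n, seed=1))
        db_y = generate_cohort(CohortSpec(n_patients=n, seed=2))
        x = export_aggregate(db_x, "X")
        y = export_aggregate(db_y, "Y")
        x["gene_patient_counts"]["EGFR"] = count_x
        y["gene_patient_counts"]["EGFR"] = count_y
        return x, y

    def test_ratio_reported_to_two_decimals(self):
        x, y = self._reports(20, 10)
        rows = {r.item: r for r in compare_aggregates(x, y)}
        assert rows["gene:EGFR"].ratio == 2.00
        assert rows["gene:EGFR"].chi2 is not None

    def test_identical_reports_give_unit_ratios_and_zero_statistics(self):
        db = generate_cohort(CohortSpec(
            n_patients=50, seed=9, gene_probs={"EGFR": 0.4, "TP53": 0.5}))
        x = export_aggregate(db, "X")
        rows = compare_aggregates(x, dict(x))
        for r in rows:
            if r.chi2 is not None and r.count_x > 0:
                assert r.ratio == 1.00
                assert r.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_suppressed_cells_refuse_comparison(self):
        db = generate_cohort(CohortSpec(
            n_patients=50, seed=9, gene_probs={"EGFR": 0.05}))
        x = export_aggregate(db, "X", suppression_k=5)
        y = export_aggregate(db, "Y")
        with pytest.raises(ValueError, match="suppressed"):
            compare_aggregates(x, y)

    def test_schema_version_mismatch_rejected(self):
        x, y = self._reports(10, 10)
        y["schema_version"] = "0.0"
        with pytest.raises(ValueError, match="schema version"):
            compare_aggregates(x, y)


def test_two_site_ratio_recovers_configured_separation():
    """The two-site study conditions put the EGFR hotspot about 6-7x
    higher at the panel site; a single draw lands in that vicinity."""
    a, b = two_site_fixture(seed=123)
    fa = query_variant(a, "EGFR", "p.Leu858Arg")[2]
    fb = query_variant(b, "EGFR", "p.Leu858Arg")[2]
    assert fb > 0
    assert 3.0 < fa / fb < 12.0  # wide band: site A has only 114 patients
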