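"""Profile a synthetic cohort: demographics, gene frequencies, variant
types, waterfall.

Generates a 200-patient cohort with configured per-gene mutation
probabilities, then runs the descriptive analytics a site would share.
The waterfall figure is written next to this script's working directory
under example_output/.
"""

from pathlib import Path

from varcdm import CohortSpec, generate_cohort
from varcdm.profiler import (
    cohort_demographics, gene_variant_frequency, variant_type_proportions,
    waterfall_matrix,
)
from varcdm.plotting import plot_waterfall

db = generate_cohort(CohortSpec(
    n_patients=200, seed=42,
    gene_probs={"TP53": 0.55, "EGFR": 0.30, "KRAS": 0.25, "STK11": 0.15,
                "KEAP1": 0.12, "BRAF": 0.08},
    pattern_probs={("EGFR", "p.Leu858Arg"): 0.12,
                   ("KRAS", "p.Gly12Xaa"): 0.18},
))

print("== demographics ==")
for row in cohort_demographics(db):
    if row.group in ("gender", "pathology"):
        print(f"  {row.group:9s} {row.category:28s} {row.count:4d} ({row.percent}%)")

print("== top genes by patient frequency ==")
for row in gene_variant_frequency(db)[:6]:
    print(f"  {row.hgnc_symbol:8s} {row.n_patients_with_variant:4d}/"
          f"{row.n_patients_total} = {row.frequency:.3f}")
# a patient counts once per gene no matter how many calls it carries

print("== variant features (proportion of variant rows) ==")
for feature, count, proportion in variant_type_proportions(db, "variant_feature"):
    if count:
        print(f"  {feature:11s} {count:5d}  {proportion:.3f}")

matrix = waterfall_matrix(db, top_n=6)
print("== waterfall ==")
print("  gene order (frequency desc):", matrix.genes)
print("  first five patient columns:", matrix.patients[:5])
# columns are memo-sorted: patients mutated in the most frequent genes
# come first, producing the characteristic staircase.

out = Path("example_output")
out.mkdir(exist_ok=True)
print("figure:", plot_waterfall(matrix, out / "waterfall.png",
                                title="synthetic cohort (n=200)"))
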