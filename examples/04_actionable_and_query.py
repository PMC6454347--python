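"""Actionable-mutation profiling and wildcard HGVS queries.

The actionable registry maps genes to protein-level patterns; the
three-letter wildcard residue Xaa groups all substitutions at a codon
(p.Gly12Xaa = any KRAS codon-12 substitution), the way codon-level
actionable classes are reported for NSCLC.
"""

from varcdm import CohortSpec, generate_cohort
from varcdm.profiler import (
    ActionableRegistry, actionable_frequency, load_default_registry,
    query_variant,
)

db = generate_cohort(CohortSpec(
    n_patients=500, seed=7,
    gene_probs={"EGFR": 0.25, "KRAS": 0.10, "BRAF": 0.06},
    pattern_probs={
        ("EGFR", "p.Leu858Arg"): 0.15,
        ("EGFR", "p.Thr790Met"): 0.02,
        ("KRAS", "p.Gly12Xaa"): 0.20,   # wildcard: drawn substitutions vary
        ("BRAF", "p.Val600Glu"): 0.04,
    },
))

registry = load_default_registry()  # EGFR/KRAS/BRAF/NRAS/PIK3CA defaults
print("== actionable mutation frequencies ==")
for row in actionable_frequency(db, registry):
    if row.n_patients:
        print(f"  {row.gene:7s} {row.pattern:14s} {row.n_patients:3d}/"
              f"{row.n_total} = {row.frequency:.3f}")
# 'any' rows deduplicate patients across a gene's patterns: a patient
# with both p.Leu858Arg and p.Thr790Met counts once for EGFR.

print("== ad-hoc queries ==")
for gene, pattern in [("EGFR", "p.Leu858Arg"), ("EGFR", None),
                      ("KRAS", "p.Gly12Xaa"), ("KRAS", "p.G12C")]:
    n, total, freq = query_variant(db, gene, pattern)
    print(f"  {gene:5s} {str(pattern):14s} -> {n:3d}/{total} = {freq:.3f}")
# the null pattern counts any variant in the gene, so it always
# dominates every specialization; one-letter queries are expanded
# (p.G12C -> p.Gly12Cys) before matching.
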