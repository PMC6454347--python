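"""Load a MAF file into the model with panel restriction.

Writes a five-record MAF to a temporary directory, maps its tumor sample
barcodes to patients, and loads it against a three-gene panel.  The load
report accounts for every input row: loaded, off-panel, or duplicate
sample.
"""

import tempfile
from pathlib import Path

from varcdm import init_database, insert_records, read_maf, load_maf
from varcdm.etl import PanelDefinition
from varcdm.schema import PersonRecord

MAF = """\
#version 2.4
Hugo_Symbol\tVariant_Classification\tVariant_Type\tHGVSp_Short\tChromosome\tStart_Position\tEnd_Position\tTumor_Sample_Barcode\tt_depth
EGFR\tMissense_Mutation\tSNP\tp.L858R\t7\t55259515\t55259515\tTCGA-01\t433
TP53\tNonsense_Mutation\tSNP\tp.R342*\t17\t7574003\t7574003\tTCGA-01\t510
TTN\tMissense_Mutation\tSNP\tp.A100V\t2\t179400000\t179400000\tTCGA-01\t95
KRAS\tMissense_Mutation\tSNP\tp.G12C\t12\t25398285\t25398285\tTCGA-02\t377
EGFR\tIn_Frame_Del\tDEL\tp.E746_A750del\t7\t55242465\t55242479\tTCGA-02\t610
"""

with tempfile.TemporaryDirectory() as tmp:
    maf_path = Path(tmp) / "cohort.maf"
    maf_path.write_text(MAF)

    db = init_database(":memory:")
    insert_records(db, "person", [
        PersonRecord(person_id=1, gender="female", age_years=58),
        PersonRecord(person_id=2, gender="male", age_years=66),
    ])
    panel = PanelDefinition(genes=["EGFR", "KRAS", "TP53"], test_name="demo")
    report = load_maf(db, read_maf(maf_path), panel,
                      patient_of_sample={"TCGA-01": 1, "TCGA-02": 2})

    print("load report:", report.to_json())
    # rows_read=5, rows_loaded=4, one skip: TTN is off-panel.

    for row in db.fetch_table("variant_occurrence"):
        print(row["hgvs_p"], row["variant_feature"], row["sequence_alteration"])
    # protein HGVS is stored expanded to three-letter form
    # (p.L858R -> p.Leu858Arg, p.E746_A750del -> p.Glu746_Ala750del),
    # and MAF classifications map onto the controlled two-level
    # variant taxonomy (In_Frame_Del -> inframe / deletion).
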