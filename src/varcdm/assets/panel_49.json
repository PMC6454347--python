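{
  "test_name": "LungCancerPanel49",
  "test_version": "1.0",
  "sequencing_device": "Ion Torrent S5",
  "analytical_tools": "Torrent Suite 5.8",
  "reference_databases": "dbSNP151;COSMIC v86;ClinVar 2018-08",
  "reference_genome_build": "GRCh37",
  "genes": [
    "ABL1", "AKT1", "ALK", "APC", "ATM", "BRAF", "BRCA1", "BRCA2", "CDH1",
    "CDKN2A", "CSF1R", "CTNNB1", "DDR2", "EGFR", "ERBB2", "ERBB4", "ESR1",
    "EZH2", "FBXW7", "FGFR1", "FGFR2", "FGFR3", "FLT3", "GNAQ", "GNAS",
    "HRAS", "IDH1", "IDH2", "JAK2", "JAK3", "KEAP1", "KIT", "KRAS",
    "MAP2K1", "MET", "MLH1", "NF1", "NOTCH1", "NRAS", "PDGFRA", "PIK3CA",
    "PTEN", "PTPN11", "RB1", "RET", "ROS1", "SMAD4", "STK11", "TP53"
  ]
}
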