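{
  "_comment": "Default MAF-dialect mapping. 'consequence' maps Variant_Classification terms to (variant_feature, optional sequence_alteration hint); 'structural' maps Variant_Type terms to sequence_alteration. Unlisted terms map to 'other' with a warning.",
  "version": "1.0",
  "consequence": {
    "Missense_Mutation": ["missense", null],
    "Nonsense_Mutation": ["nonsense", null],
    "Nonstop_Mutation": ["missense", null],
    "Frame_Shift_Del": ["frameshift", "deletion"],
    "Frame_Shift_Ins": ["frameshift", "insertion"],
    "In_Frame_Del": ["inframe", "deletion"],
    "In_Frame_Ins": ["inframe", "insertion"],
    "Splice_Site": ["splice", null],
    "Splice_Region": ["splice", null],
    "Silent": ["synonymous", null],
    "Intron": ["intron", null],
    "3'UTR": ["other", null],
    "5'UTR": ["other", null],
    "3'Flank": ["other", null],
    "5'Flank": ["other", null],
    "IGR": ["other", null],
    "RNA": ["other", null],
    "Translation_Start_Site": ["other", null],
    "Targeted_Region": ["other", null],
    "missense_variant": ["missense", null],
    "stop_gained": ["nonsense", null],
    "stop_lost": ["missense", null],
    "frameshift_variant": ["frameshift", null],
    "inframe_deletion": ["inframe", "deletion"],
    "inframe_insertion": ["inframe", "insertion"],
    "splice_acceptor_variant": ["splice", null],
    "splice_donor_variant": ["splice", null],
    "splice_region_variant": ["splice", null],
    "synonymous_variant": ["synonymous", null],
    "intron_variant": ["intron", null],
    "start_lost": ["other", null],
    "5_prime_UTR_variant": ["other", null],
    "3_prime_UTR_variant": ["other", null],
    "upstream_gene_variant": ["other", null],
    "downstream_gene_variant": ["other", null],
    "intergenic_variant": ["other", null]
  },
  "structural": {
    "SNP": "SNP",
    "SNV": "SNP",
    "INS": "insertion",
    "DEL": "deletion",
    "DNP": "MNP",
    "TNP": "MNP",
    "ONP": "MNP",
    "MNP": "MNP",
    "CNV": "CNV",
    "AMPLIFICATION": "CNV",
    "TRANSLOCATION": "translocation",
    "FUSION": "translocation"
  }
}
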