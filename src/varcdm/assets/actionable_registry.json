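{
  "_comment": "Default actionable-mutation registry for NSCLC targeted-therapy genes. EGFR and KRAS patterns follow the published clinical guidance directly; BRAF, NRAS and PIK3CA entries are conventional hotspot defaults bundled for completeness and freely editable.",
  "version": "1.0",
  "patterns": {
    "EGFR": ["p.Leu858Arg", "p.Thr790Met"],
    "KRAS": ["p.Gly12Xaa", "p.Gly13Xaa"],
    "BRAF": ["p.Val600Glu"],
    "NRAS": ["p.Gln61Xaa"],
    "PIK3CA": ["p.Glu542Lys", "p.Glu545Lys", "p.His1047Arg"]
  }
}
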