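# Loline (LOL) cluster, 11 genes.  The first committed intermediate,
# 1-acetamidopyrrolizidine (AcAP), needs five genes simultaneously
# (lolC/F/D/T/U); the remaining six cluster genes are modelled as one
# downstream block for each end product (N-formylloline, N-acetylloline) --
# finer granularity does not change any producibility call on data where the
# AcAP gate already fails, and can be overridden in a custom model file.
# Lolines are insect-active but not toxic to livestock.
name: LOL
steps:
  - product: AcAP
    precursor: null
    required_genes: [lolC, lolF, lolD, lolT, lolU]
    notes: 1-acetamidopyrrolizidine; five-gene all-of gate
  - product: NFL
    precursor: AcAP
    required_genes: [lolA, lolO, lolP, lolE, lolN, lolM]
    notes: N-formylloline
  - product: NAL
    precursor: AcAP
    required_genes: [lolA, lolO, lolP, lolE, lolN, lolM]
    notes: N-acetylloline
terminal_products: [NFL, NAL]
toxic_products: []
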