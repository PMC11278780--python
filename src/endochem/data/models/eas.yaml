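# Ergot-alkaloid (EAS) cluster, 14 genes.  Gating is the coarsest assignment
# consistent with the knockout literature: the early core builds chanoclavine I,
# the middle block oxidises it to D-lysergic acid, and three parallel terminal
# branches release ergovaline (lpsA/lpsB/easH), ergonovine (lpsC) and lysergic
# acid alpha-hydroxyacetamide (easO/easP downstream of ergonovine).
name: EAS
steps:
  - product: CC
    precursor: null
    required_genes: [dmaW, easF, easC, easE]
    notes: chanoclavine I, early pathway core
  - product: D-LC
    precursor: CC
    required_genes: [easD, easA, easG, cloA]
    notes: D-lysergic acid
  - product: ERV
    precursor: D-LC
    required_genes: [lpsA, lpsB, easH]
    notes: ergovaline via the two-module lysergyl peptide synthetase
  - product: EN
    precursor: D-LC
    required_genes: [lpsC]
    notes: ergonovine; terminal branch
  - product: LAH
    precursor: EN
    required_genes: [easO, easP]
    notes: lysergic acid alpha-hydroxyacetamide
terminal_products: [ERV, LAH]
toxic_products: [CC, D-LC, ERV, EN, LAH]
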