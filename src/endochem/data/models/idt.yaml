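# Indole-diterpene (IDT/LTM) cluster, 11 genes.  Linear backbone:
# paspaline -> paxilline -> terpendole K -> lolitrem B, with the five-gene
# core (idtG/B/M/C/S) committed to paspaline and two-gene gates at every
# later step.
name: IDT
steps:
  - product: PAS
    precursor: null
    required_genes: [idtG, idtB, idtM, idtC, idtS]
    notes: paspaline, first stable indole-diterpene
  - product: PAX
    precursor: PAS
    required_genes: [idtP, idtQ]
    notes: paxilline
  - product: TDK
    precursor: PAX
    required_genes: [idtF, idtK]
    notes: terpendole K
  - product: LTM-B
    precursor: TDK
    required_genes: [idtE, idtJ]
    notes: lolitrem B, pathway end product
terminal_products: [LTM-B]
toxic_products: [PAS, PAX, TDK, LTM-B]
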