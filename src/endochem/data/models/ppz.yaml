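# Peramine (pyrrolopyrazine) pathway: a single multi-domain NRPS gene (ppzA,
# formerly perA) assayed as seven domain segments plus the reductase (R)
# domain.  The full-length allele (ppzA-1, R present) releases peramine; the
# truncated allele (ppzA-2, dR = R-domain deletion) stalls one enzymatic step
# earlier and releases pyrrolopyrazine-1,4-diones instead.
name: PPZ
steps:
  - product: PER
    precursor: null
    required_genes: [ppzA-A1, ppzA-T1, ppzA-C, ppzA-A2, ppzA-M, ppzA-T2, ppzA-R]
    notes: full-length ppzA (allele ppzA-1)
  - product: PPZ-dione
    precursor: null
    required_genes: [ppzA-A1, ppzA-T1, ppzA-C, ppzA-A2, ppzA-M, ppzA-T2, ppzA-dR]
    notes: R-domain deletion allele (ppzA-2); diketopiperazine release
terminal_products: [PER, PPZ-dione]
toxic_products: []
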