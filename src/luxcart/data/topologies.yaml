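# Catalog of downstream gene-neighborhood patterns for convergent double
# luxR-luxR-luxI loci. Each pattern is the ordered list of product tokens
# expected immediately downstream of the luxI member, reading away from the
# luxR pair. "X" matches exactly one gene annotated as a hypothetical protein.
#
# Only the fully described topology "T" (phyH - X - virB1 - virB2 - virB3) is
# pre-populated. The named variants T1..T6 exist in the literature only as
# figure-level drawings; encode them here from your own inspection before use.
patterns:
  - label: T
    downstream: [phyH, X, virB1, virB2, virB3]
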