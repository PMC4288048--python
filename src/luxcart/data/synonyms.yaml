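# Product-label synonym map used when matching annotation strings against
# neighborhood-pattern tokens. Matching is case-insensitive after trimming;
# a token matches when the (normalized) product label equals the token itself
# or any listed synonym. The special token "X" matches hypothetical proteins.
phyH:
  - phytanoyl dioxygenase
  - phytanoly dioxygenase
  - phytanoyl-CoA dioxygenase
  - phytanoyl-coa dioxygenase family protein
virB1:
  - type IV secretion system protein VirB1
virB2:
  - type IV secretion system protein VirB2
virB3:
  - type IV secretion system protein VirB3
lcmT:
  - isoprenylcysteine carboxyl methyltransferase
metB:
  - cystathionine gamma-synthase
X:
  - hypothetical protein
  - conserved hypothetical protein
  - uncharacterized protein
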