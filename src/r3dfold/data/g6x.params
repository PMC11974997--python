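# Default parameters for the pseudoknot-layer grammar: a small nested-pair
# grammar in the G6 family, extended with a distinct unpaired-emission
# nonterminal (U).  Used for folding layers >= 1, where only the layer's
# covarying pairs and their immediate stacking neighbors may pair.
grammar G6X
start S
dist unp 0.25 0.25 0.25 0.25
pairtable wc 0.009 0.009 0.009 0.17 0.009 0.009 0.24 0.009 0.009 0.24 0.009 0.045 0.17 0.009 0.045 0.009
pairtable wcs 0.007 0.007 0.007 0.16 0.007 0.007 0.27 0.007 0.007 0.27 0.007 0.035 0.16 0.007 0.035 0.007
nt S
  rule 0.8 | nt:L nt:S
  rule 0.2 |
nt L
  rule 0.4 pair=wc | nt:F
  rule 0.6 | nt:U
nt U
  rule 1.0 | emit:unp
nt F
  rule 0.55 pair=wcs | nt:F
  rule 0.25 | nt:L nt:L nt:S
  rule 0.15 | nt:U
  rule 0.05 |
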