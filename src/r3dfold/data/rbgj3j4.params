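# Default parameters for the 12-nonterminal base folding grammar.
# Hand-curated: Watson-Crick/wobble-favoring pair emissions with a sharper
# stacked-pair table, geometric loop-length rules, and the generic hairpin
# probability pinned at 0.3475.  Retrainable with the counting trainer.
grammar RBGJ3J4
start S
dist unp 0.3 0.2 0.22 0.28
dist hloop 0.32 0.18 0.21 0.29
pairtable init 0.009 0.009 0.009 0.17 0.009 0.009 0.24 0.009 0.009 0.24 0.009 0.045 0.17 0.009 0.045 0.009
pairtable stack 0.007 0.007 0.007 0.16 0.007 0.007 0.27 0.007 0.007 0.27 0.007 0.035 0.16 0.007 0.035 0.007
nt S
  rule 0.15 | emit:unp nt:S
  rule 0.35 | nt:F0 nt:S
  rule 0.5 |
nt F0
  rule 0.85 pair=init | nt:F5
  rule 0.15 pair=init | nt:P
nt F5
  rule 0.75 pair=stack | nt:F5
  rule 0.25 pair=stack | nt:P
nt P
  rule 0.3475 tag=HL_generic | nt:G
  rule 0.1 tag=BL_generic | nt:B nt:F0
  rule 0.1 tag=BL_generic | nt:F0 nt:B
  rule 0.25 tag=IL_generic | nt:I nt:F0 nt:I
  rule 0.1 | nt:J3
  rule 0.05 | nt:J4
  rule 0.0525 | nt:BB nt:BB nt:BB nt:M
nt G
  rule 0.75 | emit:hloop nt:G
  rule 0.25 | emit:hloop
nt B
  rule 0.6 | emit:unp nt:B
  rule 0.4 | emit:unp
nt I
  rule 0.5 | emit:unp nt:I
  rule 0.5 | emit:unp
nt J3
  rule 1.0 tag=J3_generic | nt:BB nt:BT
nt J4
  rule 1.0 tag=J4_generic | nt:BB nt:BB nt:BT
nt M
  rule 0.35 | nt:BB nt:M
  rule 0.65 | nt:BT
nt BB
  rule 0.3 | emit:unp nt:BB
  rule 0.7 tag=BS_generic | nt:F0
nt BT
  rule 0.3 | nt:BT emit:unp
  rule 0.7 | nt:BB
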