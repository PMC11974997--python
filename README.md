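# r3dfold

Covariation-constrained RNA folding with joint 3D-motif annotation.

Structural RNAs fold into double helices connected by loops and junctions,
and those non-helical linkers recur as short **RNA 3D motifs** — GNRA-type
tetraloops, K-turns, loop E, C-loops, junction motifs — held together by
non-Watson-Crick interactions.  `r3dfold` predicts, from a multiple
sequence alignment, one consensus structure containing the nested helices,
the pseudoknotted/tertiary layers **and** the 3D motifs, in a single
maximum-probability parse of one stochastic context-free grammar (SCFG).
It is written for RNA bioinformaticians who work from Stockholm seed
alignments (the Rfam format) and want motif calls that come with an
explicit statement of their evolutionary support.

## The model

1. **Covariation framing.**  Every eligible column pair gets an
   APC-corrected mutual-information score; significance is judged against
   an empirical null built by permuting each column's residues
   independently across sequences (which preserves base composition but
   destroys covariation).  Pairs with E ≤ 0.05 are *positive* (they must
   pair), strongly variable pairs with no covariation tendency are
   *negative* (they may not pair).  A pre-computed pair list (e.g. from a
   dedicated covariation program) can be supplied instead.

2. **Layer decomposition.**  Positive pairs are split into ordered layers,
   each a maximum-cardinality mutually nested subset (weighted
   Nussinov-style dynamic programming), until every positive pair is
   placed.  Crossing pairs and base triplets land in layers ≥ 1.

3. **Layer 0 — joint helices + motifs.**  A 12-nonterminal base grammar
   (helix stacking, hairpins, bulges, internal loops, explicit 3-way and
   4-way junctions, generic higher-order multiloops) is extended with one
   sub-grammar per motif variant.  A loop class with generic probability
   *p* and motif fraction *f* keeps *p (1 − f)* on its generic rule and
   spreads *p f* equally over the class's motifs (for the default
   parameters: generic hairpin 0.3475 → 0.2085 generic + 0.1390 over 15
   hairpin motifs = 0.0093 each).  Motif segments are scored by short
   profile HMMs built from IUPAC consensus strings (off-consensus
   residues at 10⁻⁴; expected emitted length k + min(0.1 k, 1.5)).
   Constrained CYK — positives forced, negatives forbidden — returns the
   maximum-probability derivation in O(L³ · M) for M nonterminals
   (12 + 96 = 108 with the full shipped library).

4. **Layers ≥ 1 — pseudoknots and tertiary pairs.**  Each further layer
   is folded with a small G6-family grammar in which only that layer's
   positive pairs and their immediate stacking neighbors may pair.

5. **Support flags.**  A motif has *covariation support* when at least
   one helix bounding its hosting loop contains a positive pair.

The shipped motif library (`src/r3dfold/data/motifs.r3d`, a curated,
editable text file) describes 51 motifs across six architectures — hairpin
(HL), bulge (BL), internal loop (IL), 3-way (J3) and 4-way (J4) junction,
and branch segment (BS) — which compile to 96 variant models after
accounting for the topological variants of multi-strand motifs (2 for
BL/IL, 3 for J3, 4 for J4).

## Worked example

Generate a synthetic 50-sequence alignment with a planted GNRA tetraloop
and a planted K-turn whose closing helices covary, then fold it:

```python
import warnings; warnings.filterwarnings("ignore")
from r3dfold import (CovariationConfig, PipelineConfig, fold_alignment,
                     load_default_descriptors)
from r3dfold.synthetic import generate, prototype_descriptors, prototype_spec

descriptors = prototype_descriptors(load_default_descriptors())
aln, truth = generate(prototype_spec(seed=0, descriptors=descriptors))
config = PipelineConfig(covariation=CovariationConfig(seed=0, n_null_shuffles=100))
result = fold_alignment(aln, descriptors, config)

print(result.structure.wuss)
print(result.motif_table().to_string(index=False))
print(f"layer-0 log probability: {result.logprob:.2f}")
```

prints

```
<<.<<<....>>>..>><<<<..<<<<......>>>>.....>>>>
 motif  variant  first_col  last_col                                              segments  logprob  covariation_support
  GNRA        0          7        10                               L1:7-7;loop:8-8;R1:9-10  -3.9110                 True
K-turn        0         22        42 outL:-;loopL:-;inL:22-23;inR:38-39;loopR:40-42;outR:- -35.1711                 True
layer-0 log probability: -93.90
```

The WUSS string is the consensus structure (angle brackets nested helices;
pseudoknot layers would appear as `Aa`, `Bb`, …).  Both planted motifs are
recovered at their exact planted coordinates (1-based columns): the GNRA
tetraloop fills the hairpin loop at columns 7–10, and the K-turn occupies
the internal loop at columns 22–42 (its GA/AG non-Watson-Crick segments at
22–23 and 38–39, the RNN bulge at 40–42, with the held inner helix in
between).  `covariation_support = True` records that each motif's bounding
helices contain significantly covarying pairs, and `logprob` is each
placement's contribution to the parse.

The same run is available from the shell:

```sh
r3dfold fold alignment.sto --out-prefix out        # Stockholm + TSV + JSON
r3dfold covary alignment.sto                       # pair classification only
r3dfold shuffle alignment.sto --out control.sto    # column-shuffle control
r3dfold validate-motifs                            # lint the motif library
r3dfold train annotated1.sto annotated2.sto        # counting trainer
```

`r3dfold validate-motifs` prints `51 motifs, 96 variant models`.

## Documentation

`docs/methods.md` describes the model, its parameters and defaults, the
synthetic-data generator, numerical choices and known limitations.
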