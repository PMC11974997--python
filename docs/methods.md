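# Methods

This note documents the models implemented in `r3dfold`, the parameters
that matter, the synthetic data the tests rely on, and the choices made
where the design was genuinely open.

## Covariation classification

**Statistic.**  For columns *i*, *j* the score is the weighted mutual
information (log base 2, gap-containing rows excluded, IUPAC ambiguity
codes spread fractionally over their residue sets) minus the
average-product correction APC(i, j) = m<sub>i</sub> m<sub>j</sub> / m,
where m<sub>i</sub> is the mean MI of pairs involving *i* and m the
overall mean.  The APC means are taken over pairs of *variable* eligible
columns only: a constant column has MI exactly zero with everything, and
letting it dilute the background mean would inflate the correction
applied to informative pairs.  Columns with gap fraction ≥ 0.5 are never
scored (profile columns dominated by gaps carry no pairing signal).

**Null and E-values.**  The null is empirical: each of
`n_null_shuffles` (default 200) column-wise permutations of the
alignment — every column's residues permuted independently across
sequences, preserving per-column composition — is rescored, and all
eligible pairs' corrected scores are pooled.  The E-value of a score is
the pooled count of null scores at or above it divided by the number of
shuffles, i.e. the expected per-alignment count of null pairs scoring as
high.  Positives require E ≤ `evalue_threshold` (default 0.05).

**Negatives.**  The package uses a calibrated proxy for covariation
power: power = 1 − exp(−λ · min(subs<sub>i</sub>, subs<sub>j</sub>)) with
λ = 0.5 and subs<sub>c</sub> the weighted minority-residue count of
column *c*.  A pair is negative only when (a) it is not positive, (b)
power ≥ 0.95, and (c) its E-value is at least 1.0 — the score is no
better than what the null produces at least once per alignment.
Condition (c) matters: without it, genuinely covarying pairs that
narrowly miss significance would be forbidden from pairing, which is the
opposite of what a negative constraint is meant to express (variability
with *no* covariation tendency).

**Power and sample size.**  With the empirical shuffle null, the MI
sampling bias at small depth (roughly 0.5–0.8 bits at 10–12 sequences
under Henikoff weighting) overlaps the corrected signal of even a
perfectly covarying pair, so the classifier is effectively powered from
about 25–30 sequences upward.  Below that, supply constraints externally
(`load_external_pairs` / `--pairs`).

**Sequence weighting.**  Henikoff position-based weights by default
(gaps counted as a residue type, weights normalized to sum to the number
of sequences); `none` gives exact unweighted counts for toy inputs.

## Layer decomposition

Positive pairs are split into ordered layers; each layer is a
maximum-cardinality mutually nested subset of the remaining pairs, found
by Nussinov-style dynamic programming on the participating columns (each
pair weight 1).  Ties break toward the lexicographically smallest sorted
pair list, which makes the cascade deterministic.  A column may appear
in different layers (base triplets) but at most once per layer.  The
cascade uses at most one layer per remaining pair and every layer is
non-empty; layer sizes are non-increasing.

## Grammars

**Base grammar (12 nonterminals).**  `S` (external loop), `F0` (helix
entry pair), `F5` (stacked pair continuation, with its own 16-entry
emission table), `P` (loop selector), `G`/`B`/`I` (geometric hairpin /
bulge / internal-loop runs), `J3` and `J4` (explicit 3-way and 4-way
junctions), `M` (≥ 5-way multiloop recursion) and the branch roles `BB`
(optional 5′ unpaired run + helix) and `BT` (last branch, optional 3′
unpaired run).  Junction arity is encoded structurally — `J3 → BB BT`
(two inner helices), `J4 → BB BB BT`, `P → BB BB BB M` for five-way and
higher — so the grammar is unambiguous: a given (sequence, structure,
motif annotation) has exactly one derivation, verified by exhaustive
enumeration on sampled strings.  Hairpin loops require at least one
unpaired column; a forced pair with an empty interior is reported as
"no valid structure".

**Parameters.**  The shipped defaults
(`src/r3dfold/data/rbgj3j4.params`, a plain-text, retrainable format)
are hand-curated: Watson-Crick/wobble-favoring pair emissions with a
sharper stacked table, geometric loop-length rules, and the generic
hairpin-loop probability pinned at 0.3475 so the motif-prior arithmetic
is reproducible.  `train_by_counting` re-estimates every rule
probability and emission table from structure-annotated Stockholm files:
each structure is parsed with its pairs forced (the unambiguous grammar
makes the derivation unique), usage counts are accumulated, and
Laplace-smoothed (pseudocount 1) frequencies become the new parameters.

**Motif integration.**  For loop class *c* with generic probability
p<sub>c</sub> and curated fraction f<sub>c</sub> (defaults HL 0.4,
BL 0.4, IL 0.5, J3 0.2, J4 0.2, BS 0.2), the generic rule keeps
p<sub>c</sub>(1 − f<sub>c</sub>); the class mass p<sub>c</sub>f<sub>c</sub>
is divided equally among the class's motifs (maximum entropy) and each
motif's share equally among its topological variants.  Class probability
is conserved to 1e-9.  Hosts: HL/BL/IL variants attach at `P`, junction
motifs at `J3`/`J4`, branch segments at `BB`.  Closing Watson-Crick
pairs always come from the base grammar, never from motif models.

**Pseudoknot-layer grammar.**  A small G6-family nested-pair grammar
with a distinct unpaired-emission nonterminal (4 nonterminals:
`S`, `L`, `U`, `F`).  The classic ambiguity of `F → L S` is removed by
requiring two or more units (`F → L L S`), with separate productions for
a lone unpaired column and an empty interior.  In layers ≥ 1 only the
layer's positive pairs and their immediate stacking neighbors
(i∓1, j±1) are pair-eligible, and the layer's positives are forced.

## Parsing machinery

Grammars are parsed over *column profiles*: the emission score of a
column with residue distribution f under table e is Σ<sub>x</sub>
f(x) log e(x) (expected log-probability; pair emissions analogous over
the 16-entry table), with the gap mass removed from f by
renormalization.  Multi-atom productions are binarized internally into
anonymous chart symbols, keeping CYK and inside O(L³ · rules); the
official nonterminal count (12 base + one per motif variant) refers to
the un-binarized grammar.  Same-span dependencies (unary rules, splits
with a nullable side) are topologically ordered at compile time.
Constraints enter as emission masks: a forced column cannot be emitted
unpaired or mispaired, so every forced pair appears in any finite-score
derivation.  Traceback ties break to the first rule in declaration
order, then the smallest split point, making outputs byte-reproducible.

Motif segment spans are scored by the profile HMM *forward* probability
(insertion/deletion paths marginalized) in both the max and sum parses;
a derivation is therefore a parse tree with segment spans, not an HMM
path, which is the level at which unambiguity holds and placements are
reported.  The brute-force enumerator used as the test oracle applies
the same convention, works directly on the un-binarized grammar, and is
guarded at 12 columns.

## Segment profile HMMs

A consensus of length k compiles to k match transitions (emission on
transition): residues outside the position's IUPAC set get probability
10⁻⁴ each, residues inside share the remainder equally.  Each of the
k + 1 junctions carries a geometric insert loop with parameter α, and
each match may be deleted with δ = 0.01.  α is solved analytically so
the expected emitted length is exactly k + min(0.1 k, 1.5) (0.1 for an
empty consensus), deletion loss included:
(k + 1) α/(1 − α) = min(0.1 k, 1.5) + k δ.  Empty segments are real
k = 0 models, so insertions remain possible where the consensus has no
residues (e.g. coaxially stacked junction strands).

## Motif library

`src/r3dfold/data/motifs.r3d` is a curated plain-text library of 51
motifs (15 HL, 4 BL, 17 IL, 6 J3, 4 J4, 5 BS) in the documented one-line
dialect (`NAME TYPE role=CONSENSUS ...`, `-` for an empty segment).
With the per-architecture variant multiplicities (HL 1, BL 2, IL 2,
J3 3, J4 4, BS 1) it compiles to 96 variant models.  Variants of
multi-strand motifs are generated by rotating the strand order around
the loop so each bounding helix once plays the enclosing role.  The
consensus strings are literature-grounded for the well-characterized
motifs (GNRA, UNCG, K-turn, loop E, …) and plausible placeholders for
the rarer ones; the library is a text file precisely so users can
replace or extend it, and `r3dfold validate-motifs` lints any
replacement.

## Pipeline and support flags

Layer 0 is folded with the motif-extended grammar under: layer-0
positives forced; negatives and positives of other layers forbidden
(each positive pair is realized in exactly one layer).  Every further
layer is folded with the pseudoknot-layer grammar under its whitelist.
The hosting loop of a motif placement is the loop closed by the smallest
pair enclosing its span; its bounding helices are that closing helix
plus every child helix of the loop (1 for HL, 2 for BL/IL, 3 for J3,
4 for J4, all multiloop helices for BS).  A placement is
covariation-supported when any bounding helix contains a positive pair.
Motif reports use 1-based, closed column coordinates; internal
coordinates are 0-based.

## Synthetic data

The generator draws sequences from a common ancestor on a star
phylogeny.  Planted helix columns co-mutate: with probability
`covariation_rate` a sequence resamples a Watson-Crick/wobble pair
(compensatory double substitution).  Background substitutions
(default rate 0.12 per column per sequence) apply to *all* columns —
helix positions included, producing the occasional mismatched pair real
families show; planted motif columns mutate at a reduced 0.05.  A
separate `helix_mutation_rate` exists for clean-signal fixtures.  The
column-shuffle control permutes each column independently under a seed,
preserving composition exactly.

What this does and does not emulate: compensatory pairs on a star tree
produce the covariation signal a significance test needs, but real
alignments have phylogenetic correlation between sequences, indels, and
non-independent sites; passing tests on these fixtures demonstrates the
machinery (constraint propagation, motif placement, null calibration),
not performance on real family alignments.

**Benchmark conditions.**  The with/without-covariation comparison uses
a 46-column, 50-sequence fixture with a planted GNRA tetraloop (4-pair
closing helix) and a planted K-turn (4-pair outer and inner helices),
`covariation_rate` 0.6.  Pairs are classified on the alignment and the
first sequence is folded twice — once constrained by that
classification, once unconstrained — mirroring how a single-sequence
prediction is framed by family-level covariation.  Folding the *profile*
unconstrained is not a meaningful ablation: profile emissions see only
column marginals, and a strongly covarying helix column looks like
noise without its constraint — which is the method's premise.  The
null-calibration check folds 50 column-shuffled copies of the same
fixture and counts covariation-supported motif calls against twice the
E-value expectation.  Oracle-equivalence and unambiguity checks run at
≤ 10 columns, where exhaustive enumeration is feasible; the ablation and
null checks use the two-motif (GNRA + K-turn) library so each of the
~90 constituent folds stays under a second.

## Numerical choices

- Log-space throughout; −∞ is the IEEE value, and emission tables with
  exact zeros are handled by masking (a column with mass on a
  zero-probability residue scores −∞, not NaN).
- Chart and traceback tie-breaks are deterministic (first rule, smallest
  split); identical inputs and seed give byte-identical outputs.
- Every shuffle and null permutation derives its generator from
  (seed, replicate index), so results are reproducible and independent
  of evaluation order.
- Grammar text serialization uses `repr(float)` and round-trips
  bit-identically.

## Known limitations

- The covariation stage is a self-contained stand-in for a dedicated
  phylogenetic covariation analysis; it underestimates significance at
  low sequence depth (see above) and external pair lists are the
  recommended input when a stronger analysis is available.
- WUSS rendering draws each column once: when base triplets place one
  column in two layers, the later layer's pair is omitted from the
  string (structure objects retain it; Stockholm round-trips are
  lossless only for column-disjoint layers).
- The counting trainer uses layer-0 (nested) structure only.
- Motif consensus strings for rarely characterized motifs are
  placeholders; per-motif emission training from annotated examples is
  out of scope.
- CYK cost grows linearly with the number of motif variants; with all
  96 variants, alignments of a few hundred columns take minutes in this
  pure-Python implementation.
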