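# Methods

## The model

The package treats the conserved 75-nt archaeal tRNA core as the product of
a two-step generative mechanism: ligation of three 31-nt minihelices
(7-nt acceptor strand + 17-nt microhelix + 7-nt acceptor strand) into a
93-nt precursor, then one 9-nt deletion inside each of the two internal
14-nt acceptor-stem junctions (93 − 18 = 75). Each deletion leaves a 5-nt
relic; which 9 of the 14 junction nucleotides go is encoded in a
`LigationPlan`. The default plan keeps the last 5 nt of junction 1 (the
downstream unit's 5' stem positions 3–7, landing at core 25–29) and the
first 5 nt of junction 2 (the upstream unit's 3' stem positions 1–5,
landing at 47–51), matching the coordinate alignments the model asserts
(25–29 against acceptor positions 3–7; 47–51 against 69–73). Alternative
plans (deletion-window offsets 1–6 per junction) are accepted as
configuration. The order of events is fixed as ligate → delete; the true
historical order is unknowable and nothing downstream depends on it.

Snapback replication is modeled minimally: each round appends the exact
reverse complement of the 3'-terminal 31-nt unit (the ligated complementary
primer plus templated extension), so round r yields a concatemer of r + 1
units. Copying is deterministic by default; a per-base substitution rate
with a seeded generator is available for drift experiments.

## Segmentation

Segmentation maps one sequence onto the seven-segment scheme without any
multiple alignment. Anchors come first: the 5' and 3' acceptor stems are
the outermost 7 nt, and the T-arm microhelix is the 17 nt adjacent to the
3' stem (the model admits no variable region between them). The anticodon
microhelix is then located in the remaining interior by a greedy fold: every
17-nt window is scored as a 5-7-5 hairpin (Watson–Crick pair = 1, G:T
wobble = 0.5, maximum 5), windows scoring below 2.5 are discarded, and the
surviving candidates are ranked lexicographically by

1. V region within the 0–9 nt envelope of the model (simple or modestly
   inserted V loops outrank Type II-like interpretations),
2. hairpin score, discounted by 0.75 per nucleotide the implied V region
   falls below 5 (V deletions beyond 1 nt are off-model; a candidate
   implying one is almost always a shifted false fold),
3. pairing capacity of the flanking relics (the last ≤5 nt of the implied D
   region against the first ≤5 nt of the implied V region) — in the
   generative model these are two halves of a once-paired junction, so the
   true window tends to retain more of this complementarity than a shifted
   one,
4. smaller start position.

The D-region length then falls out as everything between the 5' stem and
the chosen window (intact = 22 nt; anything shorter is a deletion, assigned
to the D-arm microhelix because the relic is fixed adjacent to the
anticodon stem), and the V region as everything between that window and the
T arm. A D region that can only be explained as longer than 22 nt is a
model violation and raises an error rather than being silently truncated —
including when an over-length candidate folds strictly better than every
admissible one. When a dot-bracket structure line accompanies the sequence,
windows are scored by the annotated pairs instead of sequence
complementarity, which pins hairpins exactly and makes violations such as
an expanded D arm detectable unambiguously.

3'-CCA handling: CCA (or a partial CA/A suffix) is stripped before
segmentation whenever stripping yields the better-scoring segmentation, so
results are invariant to its presence. The internal alphabet is DNA-style
(U→T); tRNAdb modified-nucleoside codes map to parent bases (5→C, P→T,
1→A, Y→A), and the ambiguous code O is rejected in strict mode or mapped to
N in lenient mode, where N columns are excluded from profile statistics.

Known limitation: a core sequence can by chance contain a second perfectly
folding, in-envelope 17-nt window (observed in ~0.2% of cores built from
uniformly random stems). Such inputs are not uniquely decodable by any
sequence-only method; the tie-break chain picks one interpretation
deterministically. Likewise, when substitutions break two or more pairs of
the true anticodon stem, a shifted window may outrank it; at the default
synthetic substitution rate this affects under 1.5% of records, roughly
half of which are reported as segmentation failures rather than
mis-segmented.

## Profiles

Segmented tRNAs are stacked on core coordinates: short segments are
left-aligned with trailing gap counts (so D deletions appear as gaps inside
positions 8–24), and V-loop insertions beyond the 5-column range are
excluded from core columns. Frequencies are taken over non-gap
observations, with the gap fraction reported separately. Information
content is the standard logo quantity, 2 − H bits per column; the
small-sample correction e(n) = 3/(2 ln2 · n) is off by default and
available as a flag, and all-gap columns are reported as missing (NaN).
Consensus calls the top letter where its frequency reaches the threshold
(default 0.5; ties resolve alphabetically), N otherwise, and '−' on all-gap
columns; segment-vs-segment identity compares consensus letters in
parallel, dropping N/X/'−' positions from the denominator and reporting the
denominator used.

## Structural overlay

Backbone selections default to six atoms per residue (P, O5', C5', C4',
C3', O3'); a P-only set is available. Superposition is the closed-form
Kabsch solution (SVD of the cross-covariance of the centered point sets,
with the determinant sign correction so reflections are never returned),
with ordinal point correspondence — stem on stem, loop on loop. Inputs with
fewer than 3 points or effectively collinear geometry are rejected because
the rotation is not determined. Residues missing any atom of the set in
either arm are dropped pairwise from both selections and reported. The
test suite checks the implementation against an independent brute-force
oracle (Euler-angle grid search plus Nelder–Mead refinement) to within
0.01 Å on random point sets. Superposing the two arms of a real yeast
tRNA-Phe structure requires a user-supplied PDB file (with explicit residue
ranges, since that structure's D-loop deletion shifts its numbering); no
structure is downloaded or bundled.

## Synthetic data

The sequence generator draws i.i.d. descendants of the assembled 75-nt
ancestral core. Defaults mirror the archaeal survey the model is tested
against: 500 records; D-deletion probability 0.8, so the expected
intact-D-loop fraction is 20%; deletion lengths uniform on 1–9 nt
(contiguous, confined to the D-arm microhelix — the 9-nt ceiling matches
the junction-deletion scale of the model, and observed D-loop deletions are
a few nucleotides); V-insertion probability 0.1 with lengths uniform on
1–4 nt, confined to the V region; per-position substitution rate 0.05,
reflecting the high conservation of the archaeal core. Substitutions spare
the three anticodon positions by default, since each anticodon marks its
own lineage; a flag lifts this. All randomness flows through one
`numpy.random.default_rng(seed)`, and a fixed seed reproduces the FASTA and
truth table byte for byte.

What the generator does not emulate: phylogenetic correlation between
records (draws are i.i.d., not a coalescent), anticodon diversity,
position-specific substitution biases (e.g. the adenosine enrichment that
disrupts D/V pairing in real archaeal loops), compensatory stem mutations,
and modified-nucleoside codes. Passing tests therefore demonstrate that the
pipeline recovers known truth under idealized archaeal-like variation, not
that it is robust to every feature of database tRNAs.

The coordinate generator writes an idealized stem-loop backbone (helical
strands with A-form-like rise 2.8 Å and twist 32.7°, an arc closing the
loop, six atoms per residue at fixed local offsets) with optional per-atom
Gaussian noise. It exists to exercise PDB reading and superposition
end-to-end with known ground truth, not to model nucleic-acid geometry.

## Problem sizes and numerical choices

Tests run the survey condition at n = 500 (one seeded draw shared across
the suite), rate-monotonicity checks at n = 200, and profile round-trips at
n = 25–120; the ligation property tests cover 150+ random unit triples, and
oracle-equivalence checks use 10-point sets with a 15° grid before
refinement. Floating-point tolerances: 1e-9 for rigid-invariance checks,
2e-3 Å when comparing structures written through 3-decimal PDB coordinates,
0.01 Å for oracle equivalence. Binomial acceptance bands are ±3σ.
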