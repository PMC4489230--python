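# Methods

## Model

tcscore scores an existing multiple sequence alignment; it never re-aligns
the input (beyond building internal evidence).  The unit of evidence is the
**residue-pair library**: a set of cross-sequence residue pairs
(sequence, 1-based ungapped position) with weights in (0, 1].  Libraries may
contain mutually incompatible pairs; that incompatibility is precisely what
the score measures.  Duplicate pairs merge by maximum weight, so library
merging is commutative, associative and idempotent.

### Default library: pair-HMM posteriors

Every unordered sequence pair is decoded with a 3-state pair HMM
(Match, InsertX, InsertY; no InsertX↔InsertY transitions).  Forward–backward
runs in log space (numba kernels), so sequences of several thousand residues
neither overflow nor underflow.  The posterior that residue i of x aligns
residue j of y is P(M at (i,j) | x, y); pairs with posterior **strictly
greater than 0.9** enter the library with the raw posterior as weight.  This
keeps the optimal alignment plus high-scoring suboptimal ones.  Cost is
O(N²L²) — the dominant step.

Parameters are artifact constants, serialisable to versioned JSON
(`PairHmmParams.to_json/from_json`):

* match emissions: joint probabilities p_ab ∝ q_a·q_b·2^(S_ab/2) from
  BLOSUM62 log-odds S and published background frequencies q, renormalised;
  one ambiguity bucket `X` (background 5·10⁻⁴, odds ratio 1) absorbs
  non-standard symbols;
* insert emissions: the background vector q;
* gap open δ = 0.012, gap extend ε = 0.886, init (0.976, 0.012, 0.012) —
  in the range used by probabilistic consistency aligners; the model is
  deliberately the single-gap-class (3-state) variant.

Nucleotide input is accepted with an identity-biased ACGT(+N) emission table
(δ = 0.02, ε = 0.85) but only the protein mode is validated; a warning is
logged.

### Fast consensus library (proxy-MSA mode)

Three deterministic progressive aligners (profile–profile Gotoh over an NJ
guide tree built from pairwise identity distances) re-align the ungapped
sequences under distinct settings — BLOSUM62 −11/−1, BLOSUM45 −13/−2,
PAM250 −14/−2 — and every residue pair aligned in any proxy MSA enters the
library with weight = supporting aligners / total aligners.  The mode is
defined by this agreement rule, not by the specific aligners: any callable
`backend(names, seqs) -> Alignment` can be plugged in, and a backend that
mutates residues or reorders sequences is rejected.  With a single backend
all weights are 1.

## The pair score

For an aligned pair (x_i, y_j) of the target MSA, with w(·,·) the library
weight (0 when absent) and z ranging over residues of third sequences:

    num = w(x_i, y_j) + Σ_z min(w(x_i, z), w(z, y_j))
    den = w(x_i, y_j) + Σ_z max(w(x_i, z), w(z, y_j)) + C

C is the total weight of links of x_i to positions of y other than j, and
of y_j to positions of x other than i — direct conflicts.  PairTCS =
num/den, or 0 when den = 0 (least-trust convention for unsupported
residues).  Each intermediate contributes once to the denominator (its
larger link), so the score is 1 exactly when all evidence agrees, strictly
decreases when either residue gains an unmatched link, and is symmetric.
An alternative normaliser — the plain sum of all weights involving either
residue — was rejected because it caps a perfectly supported N-sequence
alignment at (N−1)/(2N−3) (0.6 at N = 4) instead of 1, which contradicts
the score's intended reading (maximum display score for a fully consistent
alignment) and makes the 0–9 scale uninterpretable.

Derived scores are unweighted means: ResidueTCS over the residue's column
partners; ColumnTCS over a column's residue pairs; SequenceTCS over a
sequence's residues; AlignmentTCS over **all residues** (not the mean of
SequenceTCS values — with unequal ungapped lengths the residue-level mean is
authoritative).  Residues alone in their column, and columns with fewer
than two residues, score 0; gap cells carry no score.  Pair scores are
computed only for pairs actually aligned in the MSA, keeping scoring
O(L·N²) on top of the library.

## Scaling, filtering, weighting, replicates

The display/filter scale is `scale_to_0_9(s) = min(9, floor(10·s + 1e-9))`;
the epsilon keeps exact decimals stored as binary floats in their intended
bin (0.7·10 = 6.999… would otherwise floor to 6) while 0.39999 still maps
to 3.

* **Column filter** (default): drop columns with scaled ColumnTCS < 4; with
  `keep_empty_columns` they are blanked to all-gap instead (coordinates
  preserved).  Removing every column raises unless empty columns are kept.
* **Residue masking**: replace low-scoring residues by gaps (deleting them
  would desynchronise rows); columns left empty are then dropped unless
  `keep_empty_columns`.
* **tcs_weighted**: each column is emitted scaled-score times; a real-valued
  duplication count is impossible, so the 0–9 integer is the multiplier and
  0 means omitted.
* **Bootstrap replicates**: each replicate draws L columns i.i.d. with
  replacement, probability ∝ scaled column score (raw [0,1] weights behind
  a flag); default count 100.  The RNG is numpy's default generator
  (PCG64); the seed is stored in the ReplicateSet and in the CLI's
  `<input>.run.json` sidecar — Phylip itself cannot carry comment headers
  without breaking downstream parsers, so provenance lives in the sidecar.

## Reports

score_ascii: `SCORE=` line (AlignmentTCS × 1000, half-away-from-zero
rounding), one 0–100 value per sequence (SequenceTCS × 100, absolute scale
so values are comparable across runs), then 60-column blocks in which every
residue is its 0–9 digit (gaps `-`) over a `cons` line of scaled column
scores.  score_html is the same content as a standalone page with a 10-bin
colour ramp from blue (#0000b3, bin 0) to dark pink (#c71585, bin 9); the
exact hex values are artifact constants.  sp_ascii lists every aligned pair
(names, 1-based positions, 1-based column, score to 4 decimals) and is
emitted only on request; it requires pair retention at scoring time.

## I/O

Readers: CLUSTAL, FASTA, MSF, Phylip (strict/relaxed, interleaved/
sequential) and Nexus, with format sniffing by unambiguous magic first
(Nexus → CLUSTAL → MSF → Phylip header → FASTA).  Residues are upper-cased;
`.` and `~` gap dialects become `-`.  Writers: CLUSTAL, FASTA, Phylip —
relaxed Phylip by default (whitespace-delimited names; tree programs accept
it), strict 10-character names behind a switch that raises on truncation
collisions.  Nexus and MSF are read-only.  Bootstrap replicates are written
as multi-dataset sequential Phylip (one `N L` header per dataset).  Columns
and residue positions are 1-based in all user-facing output.  Libraries
serialise to the T-Coffee plain-text format (integer weights =
round(100·w), so round-tripping quantises to 1/100).

## Synthetic families

`simulate_family` mutates a random ancestor independently along a star tree:
per-site substitutions at the given rate, deletions/insertions each at half
the indel rate with geometric lengths (default mean 2).  Insertions are
sequence-private columns, so true column homology is known by construction.
Defaults (8 sequences, ancestor 120, substitution 0.1, indel 0.02) give
families in the comfortable range for consistency scoring.  The generator
emulates none of: rate heterogeneity across sites, realistic phylogenies,
or conservation structure — passing tests demonstrate the scoring machinery
and its monotone response to misalignment, not performance on real protein
families.  `corrupt_alignment` destroys homology in a column window by
per-row random cyclic shifts, preserving composition; the test suite
asserts the *direction* of the score response (corrupted columns score
lower in ≥ 19 of 20 seeds), not its magnitude.

## Numerical and design notes

* Forward–backward and Gotoh DP are numba kernels; Gotoh ties break
  deterministically match > gap-in-second > gap-in-first, so the proxy
  aligners are reproducible bit-for-bit.
* Timing-sensitive checks (the O(L²) scaling of library construction) use
  best-of-3 timings on lengths 200–800 at N = 2 and assert a log–log slope
  of 2 ± 0.5.
* The CLI's default seed is fixed (42) and recorded, so default runs are
  byte-reproducible; `--seed random` opts out.
* Degenerate inputs: empty libraries score everything 0; an all-gap column
  scores 0 and is never sampled into replicates; filtering that removes
  every column raises rather than emitting an empty file.

## Limitations

Scores are relative consistency, not calibrated probabilities of structural
correctness; no local (Smith–Waterman) library entries; HMM parameters are
fixed constants, not trained on the input; the proxy aligners are simple
progressive methods — adequate as agreement probes, not competitive MSA
tools; nucleotide mode is unvalidated.
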