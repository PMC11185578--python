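# Methods

## The seeding model

A *seed* of a length-n window is a length-k **subsequence** (not substring)
of the window, selected as the minimum of a total order over all length-k
strings.  Two length-n strings at edit distance e always share a common
subsequence of length n − e, so for k well below n a few edits cannot
destroy every candidate seed — this is what makes subsequence seeds
sensitive on error-prone reads where long k-mers fail.  Precision comes
from choosing k large in absolute terms: unrelated strings essentially
never share a length-24 subsequence that both select as their minimum.

### Pivot-split score functions

The package defines k orders at once.  Order i scores a string
z = z₁…z_k by splitting it at its *pivot* character z_i:

* a forward recurrence scores the suffix z_{i+1}…z_k left-to-right,
* a reverse recurrence scores the reversed prefix z_{i−1}…z₁,
* pivot tables combine the two halves and the pivot character.

Each recurrence carries a pair (ψ, ω): ψ is a residue mod d accumulated
from the C tables, and ω is an integer accumulated from A-table magnitudes
with data-dependent ±1 signs from the B tables, where the row used at each
step depends on the residue of the current prefix.  The comparison is
asymmetric by construction: ψ ascending, then ω **descending**.  The
interleaving of modular classes and sign flips de-correlates the ranks of
similar strings, which is what gives the order its locality-sensitive
behaviour; because all k orders share the forward/reverse recurrences they
are not independent, but they behave nearly independently in practice (the
collision-probability curves below show the boost from pooling them).

### The sliding-window dynamic program

For a sequence X of length N the DP fills, for every span (start, length ≤ n)
of X, the extreme ω values of length-l subsequences per residue class
(`Fmin/Fmax` for the forward functions, `Rmin/Rmax` for the reverse ones,
O(Nnkd) subproblems).  A window/order optimum is then assembled by
enumerating the pivot position b: the prefix is a reverse subproblem of
span [w, w+b−1), the suffix a forward subproblem of [w+b, w+n); the
feasible residue classes of the two sides are scanned for the minimal
combined ψ, and the B-table signs of the pivot decide whether the min or
max table supplies each side's ω.  Spans are shared between overlapping
windows, which is the source of the asymptotic advantage over seeding each
window separately.  Subproblems with no feasible subsequence are tracked
with explicit boolean masks rather than sentinel arithmetic; masked value
entries hold a canonical 0 so that all engines produce bit-identical
arrays.

Three engines fill the tables: a scalar Python transcription of the
recurrences (the readable reference), a numpy engine that processes the
residue axis as whole arrays, and a numba-compiled element-wise kernel
(the production default).  The test suite asserts bit-identity of all
three; the compiled kernel is what makes simulation-scale workloads
(tens of thousands of windows) practical on one CPU.

Residue optimisation is a direct scan over feasible class pairs (with an
early exit on the smallest achievable residue); at d ≤ 32 this costs at
most ~10³ operations per (window, order, pivot) and is not worth a cleverer
algorithm.  d is capped at 32 and ω magnitudes are bounded by
(2k+1)·max|A|, asserted to fit comfortably in int64 for k ≤ 64.

### Determinism and tie-breaking

The order comparison can tie across *distinct* candidate subsequences —
frequently so for small d (at k=6, d=5 roughly a percent of window/order
optima are tied, often through repeated embeddings of the same string).
Seeds must be deterministic, and the brute-force oracle must agree with
the DP exactly, so a total tie rule is fixed and implemented identically
in both: smallest (ψ, −ω), then smallest pivot position, then smallest
prefix residue class, then leftmost-packed prefix and suffix positions.
For ties among embeddings of the same string this provably selects the
leftmost embedding.  The DP realizes the rule in the traceback by
preferring, at every step, the value-consistent decision that packs
positions left.

With reverse-complement-symmetric tables an extra layer is needed: a fixed
left-leaning rule is not equivariant under reverse complement, so a tied
window and its reverse complement could resolve to non-corresponding
seeds.  Windows are therefore canonically oriented — a window whose
reverse complement is strictly lexicographically smaller than itself uses
the mirrored rule (largest pivot, suffix residue class first, right-packed
positions).  The mirror of the forward rule applied to revcomp(w) is
exactly the flipped rule applied to w, so tied argmins still correspond
and strand-neutral matching loses nothing.  The only residual exception is
an exactly palindromic window (w = revcomp(w)) whose optimum is tied
across different strings between mirrored orders; such windows are
vanishingly rare (probability 4^(−n/2) per window before conditioning on a
tie) and would at worst cost one seed-match.

### Reverse-complement-symmetric tables

The constraints pair table rows i and k−i+1 through the complement map:
the reverse tables are the complement-relabelled forward tables, and the
pivot rows satisfy CP/AP mirroring with the two BP sign components
swapped.  One half of each constrained pair is drawn randomly, the other
derived; for odd k the middle row constrains symbols only against their
complements, so the construction never conflicts.  Under these constraints
the score of z under order i equals the score of revcomp(z) under order
k−i+1 — checked exhaustively over all 4⁶ strings in the tests — and hence
a window and its reverse complement produce corresponding seed sets.

### Variants and repeats

* Repeats: t ≤ k orders per window, evenly spaced over [1, k] (the middle
  order for t=1).  For rc-symmetric tables the selection is closed under
  i ↦ k+1−i by taking the union with its mirror — this can exceed t (e.g.
  t=1 with even k yields two orders); symmetry of the selection was judged
  more important than an exact count, since strand folding pairs order i
  with k+1−i.
* Windowed variant: a verbatim leading substring of length k0 (default
  k/2) concatenated with each subsequence seed of the following window;
  positions cover both parts, scores are the subsequence part's.
* Match keys: plain mode pairs (order index, seed string); rc mode folds
  the order index to min(i, k+1−i) and the string to
  min(seed, revcomp(seed)).

## Synthetic data

The generators emulate the statistical structure of the evaluation, not a
sequencer:

* uniform random DNA backgrounds;
* exact edit-distance categories: exactly e edits applied to a length-n
  string, accepted only when the true edit distance (edlib) equals e,
  retried up to 1,000 times — categorization by *exact* distance is what
  makes the collision curves interpretable;
* per-position error model: substitution / insertion / deletion with
  probability r/3 each, with the edit transcript recorded; the
  ground-truth alignment is the set of matched and substituted coordinate
  pairs (indels have no partner);
* read sets: fixed-length reads sampled uniformly from a random genome,
  mutated at rate r; ground-truth overlaps are interval overlaps ≥ 15 bp.

What these do **not** model: real base-composition bias, genomic repeats,
length-varying reads, or instrument-specific error profiles (no
homopolymer-length errors, no quality structure).  Passing tests therefore
demonstrate algorithmic correctness and the qualitative sensitivity/
precision behaviour of the seeds, not performance on any particular
instrument's data.

A truth-classified seed match counts a character pair as correct only if
the exact (pos_a, pos_b) pair is in the truth alignment; a match is true
when strictly more than half of its pairs are correct.  Coverage spans use
the full matched extent (first to last position, closed) on each sequence,
and proportions pool both sequences' characters.  Whether coverage should
count one side or both is a convention; pooling both is used throughout.

## Problem sizes and defaults

* Collision curves: window n=30, seed k=24, d ∈ {11, 31}, repeat counts
  t ∈ {1, k}, edit-distance categories 0–6, 2,000 pairs per category in
  the test suite (500 in the acceptance script).  These are desk-scale
  replicates of the study conditions; the larger canonical simulation uses
  100,000 pairs per category, which only narrows the binomial intervals.
* Oracle cross-checks: N=20 sequences over the grid n ∈ {8,10,12},
  k ∈ {4,5,6}, d ∈ {3,5,8}, where brute-force enumeration (≤ C(12,6)=924
  candidates per window) is exact and fast.
* Pairwise matching demo: L=20,000 at r=0.1 with n=20, k=16, d=15, t=5;
  overlap demo: 60 reads of 1 kb from a 20 kb genome.  Both chosen so a
  full run stays in minutes on one core while leaving the metrics stable.
* Memory: the driver processes long sequences in overlapping blocks of 64
  windows (exact, since a window depends only on its own n characters),
  bounding live DP memory at O(block · n · k · d) regardless of N.

## Known limitations

* The O(d) bit-parallel residue optimisation and hardware SIMD are not
  implemented; the compiled element-wise kernel with an early-exit residue
  scan is fast enough at d ≤ 32 by a wide margin for the package's scope.
* Non-ACGT symbols: lowercase is folded to uppercase; windows containing
  any other symbol (e.g. N) emit no seeds and are counted in the log.
  Scores are undefined off-alphabet, and skipping mirrors common seeding
  practice.
* The rc-symmetric variant is defined only for the DNA alphabet (the
  complement map is built in); protein or degenerate alphabets are
  rejected.
* Chaining, high-frequency-seed filtering and alignment verification are
  deliberately out of scope: the metrics evaluate raw seeds.
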