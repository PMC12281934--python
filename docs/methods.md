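# Methods

## Problem and approach

Prokaryotic taxa are delineated in practice by 16S rRNA gene identity
thresholds. `ribobound` derives such thresholds from a dataset of type
strains, one near-full-length 16S sequence per strain plus a seven-rank
lineage: it aligns every pair of sequences, aggregates within-taxon
identities per rank, and summarizes each rank's *minimum within-taxon
identity* distribution by its 5th and 95th percentiles. The resulting
per-rank intervals overlap, and the package treats that overlap as the
object of interest: classification returns all consistent ranks, never
a forced unique rank.

## Filtering

A strain is retained iff its sequence length is in [1,100, 1,750] and
it has at most 9 characters outside {A, C, G, T}, and no rank name
contains a placeholder marker (`No-Family`, `No-Order`, `No-Class`;
substring semantics, with an exact-match mode available). Ambiguity is
counted after canonicalization (upper case, U→T), so case and RNA
spelling never count as ambiguous. Each removed strain gets exactly one
reason, attributed in the fixed order short → long → ambiguous
characters → taxonomy, which makes reports reproducible and the
conservation identity `n_input = n_retained + Σ removals` checkable.
The ambiguity cutoff is exposed as a parameter (`max_ambiguous = 9`,
i.e. "ten or more ambiguous characters are removed") rather than
hard-coded, since it is a pragmatic, not principled, choice.

## Pairwise alignment and identity

Alignment is an exact three-state (Gotoh) dynamic program, end-to-end
global with terminal gaps penalized. Scores: match 2, mismatch −1, gap
open −10, gap extend −0.5. A maximal gap run of length *k* costs
`gap_open + (k−1)·gap_extend` — the first gap character is priced at
the opening score. Alignment libraries differ across versions on
whether the first gap character costs `open` or `open + extend`; this
package fixes the former and documents it, because the published
quantity is the identity, which is insensitive to this convention in
almost all pairs. The kernel is a numba-compiled float64 DP with a
full pointer matrix; traceback is deterministic, preferring a
match/mismatch column over a gap in the second sequence over a gap in
the first, and gap opening over extension on ties. Co-optimal
alignments can differ in identity by fractions of a point; only the
deterministic choice is surfaced, and the test suite bounds the
order-dependence at 0.5 percentage points.

Identity is gap-excluded: `100 · matches / (matches + mismatches)`,
i.e. columns containing a gap are in neither numerator nor
denominator. ("Total characters in alignment" could count columns or
characters; the two readings give the same ratio once gap positions
are excluded, so columns are used.) If every column has a gap —
impossible for optimal alignments of non-empty sequences — the value
is flagged undefined (NaN) rather than 0. Ambiguity codes match only
on exact equality and otherwise score as mismatches; the ≤9 ambiguous
characters allowed per sequence bound their influence at about 0.6%
of a 1,400 bp alignment.

The all-vs-all step lays out the C(n, 2) unordered pairs in a canonical
order (sorted strain IDs), splits them into `n_chunks` batches, and
optionally processes batches in threads (the kernel releases the GIL).
Chunk and worker counts only affect scheduling: results are bit-for-bit
identical for any setting, which the suite asserts.

Correctness of the aligner rests on two independent routes: exhaustive
enumeration of all global alignments for short sequences (the test
oracle, also rerun by the acceptance script), and score agreement with
Biopython's `PairwiseAligner` under the same scoring on longer,
indel-bearing pairs.

## Boundary statistics

Within-taxon membership at a rank groups strains by the name at that
rank; for species this naturally pools subspecies type strains, the
only source of within-species pairs in a one-sequence-per-strain
registry. Taxa with a single member carry no pairwise information and
are omitted. Per-taxon minima keep outliers (e.g. a species whose two
members share only ~90% identity): robustness is delegated entirely to
the 5th/95th percentiles, computed with linear interpolation between
order statistics at `h = (n−1)·p` (numpy's default, R's type 7).
Quantile conventions shift boundaries by tenths of a percent, hence
the explicit choice, the independent sort-and-interpolate oracle in
the tests, and an unrounded plus 1-decimal-rounded column in the
output table.

`classify_identity(v)` returns every rank whose interval contains `v`,
plus two flags: `above_species_range` (consistent with *same* species:
at or above the species lower boundary and above every other rank's
upper boundary) and `below_all`. Richer decision logic is deliberately
left to the caller. A published reference table for prokaryotes
(species 97.2–100, genus 90.1–99.0, family 80.1–94.1, order 72.9–90.0,
class 72.2–86.3, phylum 69.6–83.6) ships as a constant for classifying
real data; recomputing it requires the full registry dataset (~19,600
strains, ~191 million alignments), which is outside this package's
scope, so those values are recorded, not derived, and the test suite
checks only their internal consistency and the classifications they
imply. Analyses restricted to bacteria or archaea are a grouping
parameter (domain subset before aggregation), not separate code paths.

## Relative evolutionary divergence

On a rooted tree with branch lengths, `red(root) = 0` and for node *n*
with parent RED *p*, branch *d* and mean parent-to-descendant-leaf
distance *u*: `red(n) = p + (d/u)(1 − p)`, evaluated in preorder after
a postorder pass accumulating leaf distances. Leaves land at exactly 1
(`d = u`), and RED is non-decreasing along any root-to-leaf path. The
degenerate `u = 0` (an all-zero-length subtree) takes the recursion's
limit `red(n) = p`, with a warning. Trees are used exactly as
supplied — no rerooting.

Per-taxon minimum MRCA-RED is computed at the MRCA of the whole taxon:
since RED is monotone toward the leaves and the set-MRCA is an
ancestor of every pairwise MRCA (and equals one of them), the set-MRCA
RED equals the minimum over pairs; the tests verify this against a
brute-force pairwise minimum. MRCA queries walk parent pointers after
depth equalization, checked against an ancestor-set-intersection
oracle. Cross-database comparison uses a concordance filter (exact
lineage equality from phylum to species after whitespace trimming) and
a generic predicate filter on metadata tables, defaulting to
registry-typed, representative entries.

## Synthetic data

The generator produces the structure the analysis assumes, not a
facsimile of real data:

- **Tree**: pure-birth (Yule) topology, all lineages extended to the
  present and node times rescaled so every root-to-leaf distance is 1.
  Real reference trees are not ultrametric; the pipeline itself never
  assumes ultrametricity — the clock is only what makes depth cuts
  induce clean nested ranks.
- **Ranks**: each rank is cut at a fixed height above the leaves
  (defaults 0.02, 0.15, 0.35, 0.55, 0.75, 0.9 for species → phylum);
  taxa are the clades hanging below the first edge crossing the cut,
  so nesting is guaranteed by construction. Labels are synthetic
  tokens (s0007, g03, p01).
- **Sequences**: Jukes–Cantor evolution, 1,400 bp by default
  (mid-range for a near-full-length 16S gene), substitution rate 0.2
  per site per unit height. JC is the minimal model with a closed-form
  identity curve, `E[identity] = 25 + 75·e^{−4·rate·D/3}` at path
  length *D*; with the default cuts this spans roughly 71–99%
  expected within-rank minimum identity, qualitatively matching the
  70–100% range seen across real prokaryotic ranks. No indels are
  simulated (gap handling is exercised by the alignment tests and the
  planted length outliers); rate heterogeneity, GC skew and the
  conserved/variable-region structure of real 16S genes are likewise
  not modeled. Passing tests therefore validate the *machinery* —
  alignment, aggregation, percentiles, RED — under known truth, not
  the empirical boundary values of real data.
- **Planted violations**: optional injection of N-runs and
  length outliers with the affected strain IDs recorded, so filter
  reports can be compared against planted counts exactly.

All randomness derives from one integer seed (separate child streams
for topology, sequences, injection); equal configs give byte-identical
files.

## Numerical and design choices

- Scores are float64 in the DP; the default half-integer scheme is
  exact in floating point, and the returned alignment's score is
  re-derivable column-by-column to 1e-9 (asserted in tests).
- The identity matrix stores float64 values; the pairs file renders 4
  decimals, and reading it back is accepted to that precision.
- `join_dataset` drops and counts unmatched records instead of
  raising, because registries routinely list strains without deposited
  sequences; the join report makes the loss explicit.
- Pipeline manifests record versions, parameters, input digests and
  per-stage counts but no timestamps, so a rerun with identical inputs
  is byte-identical — the determinism contract the suite enforces.
- Problem sizes in the tests: the shared benchmark uses 60 leaves, the
  end-to-end validation 200 leaves × 1,400 bp (19,900 alignments,
  about three minutes), rerun determinism additionally at 30 leaves;
  these sizes make every distributional check well-populated (each
  rank has multiple multi-member taxa) while keeping the suite quick.

## Known limitations

- Identity among co-optimal alignments is convention-dependent at the
  sub-percent level; only the deterministic traceback is reported.
- The boundary classifier takes a single identity value; choosing
  *which* value to use against a multi-member taxon (best hit vs
  minimum) is left to the caller.
- Species-level boundaries hinge on subspecies type strains, which are
  few in real registries; synthetic benchmarks can populate this rank
  arbitrarily well and therefore overstate how well-determined the
  real species boundary is.
- The full-scale reference boundary table is shipped as data, not
  recomputed; applying the pipeline to a current registry snapshot
  requires the user to supply the downloaded inputs.
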