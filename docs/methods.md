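# Methods

This note documents the model, the conventions and defaults chosen where
more than one reasonable option existed, what the synthetic data does and
does not emulate, and the known limitations.

## Substitution counting

A multi-structure alignment (one gapped FASTA row per structure plus
superposed Cα traces; the format a Mustang-style aligner emits) defines
residue correspondences per column. For every unordered structure pair
and column:

* both residues present and Cα–Cα distance ≤ cutoff → one increment of
  the symmetric amino-acid cell (a, b);
* both present but further apart → the correspondence is not trusted:
  one increment of (a, gap) **and** one of (b, gap);
* exactly one present → one increment of (a, gap);
* neither present → nothing.

Whether a failed distance test should charge one or two gap increments is
a genuine ambiguity; we charge one per residue (both sides lose their
partner) and keep the per-category event counters on the result so the
accounting is auditable: substitution events + distance failures +
one-sided columns = total events. A structure is never paired with
itself, and each unordered pair is counted once.

`'X'` residues (non-standard types, e.g. MSE) occupy alignment columns
but contribute to no count cell — a 21-class table has no unknown class —
and excluded events are tallied separately.

Coordinates are used exactly as given: the package never superposes
structures, so inputs must already share a frame. The cutoff is the
single physical parameter; defaults are 3 Å for mainly-α and mainly-β
classes and 4 Å for α/β, and the sweep machinery rebuilds matrices over
any cutoff grid. In our synthetic studies the z-score differences across
cutoffs in the 1–8 Å range are small once training data is plentiful
(a tight cutoff mostly subsamples correspondences at random), so the
cutoff matters most when families are few or superposition error is
large.

## Normalization and aggregation

Each count C(a,b) is divided by the number of times *a* was replaced by
anything other than *b* — conserved positions and gap assignments
included, so the denominator is the full 21-class row sum minus C(a,b)
itself. A zero denominator yields 0 (logged). The raw ratio matrix is
asymmetric; since the combination anchor is symmetric the final matrix
must be too, and we symmetrize by the arithmetic mean (M + Mᵀ)/2 —
order-independent and ratio-preserving on average. The gap column is
normalized by the same rule and carried as metadata (it does not enter
alignment scoring, whose gap costs come from the affine penalties).

Homology-level matrices are normalized first, then summed into the
topology matrix, then the 20×20 block is scaled to maximum 1 (gap row by
the same factor). Normalize-then-sum keeps one large family from
dominating a topology purely by pair count. All-zero sums are returned
as-is with a warning.

## Combination and export

Combined = anchor + x·topology, element-wise over the 20 standard
residues; anchor cells outside the 20 (B, Z, X, *) pass through
unchanged. The working form is real-valued. Integer export exists only
for interoperability: the `psiblast` profile rounds the working values
(equivalent to scaling by 100 and dividing back down), the
`scaled100` profile multiplies by 100 before rounding, optionally
clamping large entries. The discrimination z-score is invariant under any
consistent positive rescaling of matrix and gap penalties (tested at
k = 100), so the choice of export profile can never change an evaluation
result — which is also why evaluation always uses the real-valued form
with gap penalties 10/1.

## Alignment

Global Needleman–Wunsch with affine gaps, implemented as the three-state
Gotoh recursion (the horizontal in-row dependency is solved by a prefix
max, so rows are fully vectorized). The default gap convention charges a
run of length k with open + k·extend — the first gapped position pays
both — with the alternative open-inclusive convention
(open + (k−1)·extend) selectable, since published descriptions of NW
implementations rarely pin this down. Terminal gaps are penalized
(true global alignment); a semi-global score with free end gaps is
available. State switches between the two gap directions are allowed, so
the optimum agrees with exhaustive enumeration over all alignments,
which the tests verify on hundreds of random small instances, alongside
a cross-check against Biopython's PairwiseAligner on longer sequences.
Traceback ties prefer diagonal, then up, then left, making output
deterministic.

## Evaluation

Each topology contributes one structurally similar pair (S, S′); cross
scores are S against every other topology's S′ (per-query population, as
the pair enumeration implies). z uses the sample (n−1) standard
deviation, and the similar pair's own score is excluded from the cross
population — exclusion makes z a clean outlier statistic; both choices
are configurable. Zero cross-score spread makes z undefined: reported as
NA, never silently dropped.

Percent improvement compares the best combined z with the best generic z
using |z_generic| in the denominator so that negative baselines still
yield a meaningful sign. A topology counts as "improved" only when the
best combined z beats **every** supplied generic matrix.

Three aggregation conventions are reported because they answer different
questions: per-(cutoff, weight, class) mean z over all topologies; the
same restricted to improved topologies (the subset the class-average
weight curves are taken over); and per cutoff the class mean of each
topology's best z relative to the anchor mean, the statistic cutoff
curves track. Weight 0 reproduces the anchor exactly, so every ratio
curve starts at 1 by construction.

## Synthetic families

The generator emulates the statistical structure the pipeline consumes,
not protein physics. Each family descends from a uniform-random ancestor:
descendants substitute each site with probability 0.3, replacements drawn
uniformly except for planted preferred pairs enriched 5×; sites are
deleted at rate 0.03 (deletion-only indels keep the ancestor frame as the
alignment); all structures share an ideal α-helix backbone (rise 1.5 Å,
100° turn, radius 2.3 Å — textbook constants) with independent Gaussian
coordinate jitter of σ = 0.5 Å standing in for superposition error.
Under that jitter the pairwise Cα distance is ~0.71·chi(3): essentially
all true correspondences survive a 3 Å cutoff and under half survive
1 Å. Held-out test pairs are two extra descendants at divergence 0.7
(identity ≈ 10–15 %, always checked against the 30 % ceiling) drawn from
an RNG stream disjoint from the training stream, so train/test
separation is structural. Same spec and seed give bit-identical output.

The benchmark defaults are 10 topologies × 12 homology-level families ×
4 structures of length 120. Twelve families per topology reflects that
real fold-level matrices aggregate many homology families, and matters
statistically: single-family counts are clustered (one mutated
descendant pairs against every sibling), so planted-preference recovery
is unreliable below ~6 aggregated families and saturates near certainty
by 12.

What passing these tests shows: the pipeline recovers planted
fold-specific substitution preferences from noisy superpositions and
converts them into combined matrices that measurably improve held-out
discrimination (typically 50–100 % of synthetic topologies improve, with
class-mean z-ratio curves peaking between weights 10 and 30). What it
does not show: performance on real CATH structures, whose substitution
preferences, gap structure, contact geometry (β-sheets in particular)
and family-size distributions are far richer than the generator's.

## Numerical choices and degenerate inputs

Scores use float64 throughout; −1e30 serves as the unreachable-state
sentinel so arithmetic stays finite. Traceback compares against the
recursion values with a 1e-9 tolerance. Empty-vs-empty alignment scores
0; empty-vs-length-k scores −(open + k·extend). Zero normalization
denominators produce zeros, all-zero topology matrices are preserved
(not rescaled), and per-cell failures in a sweep are recorded in an
errors table while the sweep continues.

## Limitations

* Architecture-level matrices, pseudocount smoothing and log-odds
  conversion are deliberately out of scope.
* Local alignment is not implemented; the evaluation protocol is purely
  global.
* The PDB reader handles Cα-trace extraction (first model, chosen or
  first chain) — not mmCIF, altloc arithmetic or insertion-code logic.
* VT-family anchors are consumed as NCBI-format files if supplied;
  only BLOSUM62 ships built-in (via Biopython).
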