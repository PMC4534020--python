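# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `wgpmap`.  Coordinates are 0-based and half-open
internally; AGP and GFF3 exports convert to 1-based inclusive, BED stays
0-based half-open, and each exported file states its convention in a header
comment.

## Synthetic data model

The simulator (`wgpmap.simgen`) generates every input the analysis consumes,
with a recorded ground truth.  One master seed drives everything; each
component derives its child generator as
`SeedSequence(seed, spawn_key=(k,))` with fixed keys (0 chromosome,
1 library, 2 tags, 3 RH panel, 4 deletion panel, 5 markers), so identical
seeds give byte-identical outputs and components are independently
reproducible.

**Chromosome.**  A linear chromosome of length `L` with a centromere
boundary splitting short (S) and long (L) arms.  Gene positions are sampled
per arm with linear intensity `1 + g*t` in the relative distance `t` from
the centromere (inverse-CDF sampling); `g = 0` is uniform and `g > 0`
reproduces the telomere-increasing gene density seen in large cereal
chromosomes.  An optional NOR-like interval and repeat profile are carried
as annotations.

**BAC library.**  Clone count ~ Poisson(coverage × L / insert mean); insert
lengths are normal around 130 kb (truncated at 20 kb).  A fraction
`1 - purity` of clones is foreign (flow-sorting contamination), drawn on one
of three foreign chromosomes of the same length.  Defaults follow the
arm-sorted libraries the pipeline emulates: 130 kb inserts, purity 0.85-0.92,
coverage ~9-18x.

**WGP tags.**  Tags are integer site IDs on a fixed lattice with spacing
`insert_mean / mean_tags_per_bac` (~6.3 kb at the defaults), so a clone
carries the sites inside its interval and overlapping clones share exactly
the sites of their overlap; real sequence tags map onto this abstraction by
any exact-match dictionary.  Each tag drops out independently (default 2%).
Foreign chromosomes use disjoint site universes except for a configurable 2%
of "shared-repeat" sites that collide with target IDs, which keeps the
contamination screen non-trivial.  Default 20.6 tags per clone.

**RH panel.**  Per line, break positions follow a Poisson process (default
mean 8 breaks per chromosome) and every fragment is retained independently
with probability `r` (default 0.25); adjacent retained fragments merge, so a
line's `n_breaks` counts observable interior boundaries.  The per-line
break-count distribution of real gamma-irradiated panels is not identifiable
from the published material; Poisson is a modelling choice and is flagged as
such in the run configuration (`break_distribution`).  Default panel size
355 lines.

**Deletion panel.**  21 terminal-deletion lines over 18 distinct breakpoints
(6 on S, 12 on L), each line retaining everything proximal to its breakpoint
on one arm plus the whole other arm.

**Markers and orthologs.**  Markers are drawn from gene positions first
(genic) and topped up uniformly (ISBP-like).  Syntenic genes get reference
positions colinear with their chromosome position (scale 0.1), modified
inside declared inversion/translocation blocks; a configurable nonsyntenic
fraction (default 477/2015) gets an off-chromosome link or none.

What the simulator does *not* emulate: sequencing errors below the tag level,
pooled-BAC deconvolution artefacts, locus-specific retention gradients along
the chromosome, segmental duplications, or marker genotyping error (exposed
as `error_rate` but defaulting to 0).  Passing tests therefore demonstrate
the correctness of the algorithms under the stated statistical model, not
robustness to every artefact of real libraries.

## Fingerprint assembly

The Sulston score with tolerance 0 is
`q = 1 - (1 - 1/G)^n_H`, `S = P(Binomial(n_L, q) >= m)`, evaluated via a
gammaln/logsumexp tail sum in log10 space so cut-offs far below the
double-precision floor remain comparable.  `G` (the "gel length") defaults
to the number of distinct tags observed in the dataset, matching how the
per-arm values were derived in practice; the CB unit defaults to the tag
lattice spacing.

Clustering is single linkage over clone pairs sharing at least one tag
(inverted tag index), which makes the partition independent of input order;
ties everywhere break on `bac_id`.

The consensus-band map is a greedy seriation: seed at the clone with the
most tags, repeatedly attach the unplaced clone with the largest number of
already-placed tags, appending its new tags on the side indicated by the
mean coordinate of its placed overlap.  A clone's CB interval is the span of
its tag coordinates.  This is deliberately simple; it is exact on noise-free
tiling data (estimated contig sizes land within 2 CB units per member of the
true span, tested) and adequate for end-window logic on noisy data.

A member is **Questionable** when fewer than 50% of its tags fall inside its
placement window `[cb_start, cb_start + 1.5 * n_tags)`.  FPC's internal
definition is not published; this rule reproduces the function of the DQer
screen (flagging clones incompatible with their placement) with a testable
criterion.  The 1.5 factor allows for interleaved tags contributed by
neighbours that the clone itself dropped.

Stepwise assembly starts at 1e-75, relaxes the cut-off by 5 orders of
magnitude per round ("increase by 1e-5 per step" is read as exponent += 5,
configurable), admits only merges whose joining clones lie within
`from_end = 12` tag units of a contig end (singletons always qualify), and
after each round re-assembles contigs with >10% Q clones at a cut-off
`dq_step * step_exponent` (=15) orders more stringent, capped at the initial
cut-off, iterating at most 5 times before warning.  The final cut-off
balances the three quantities practitioners balance — Q-contigs, contig
count and coverage: among rounds whose cumulative size lies within ±15% of
the coverage target it minimises first the Q-contig count and then the
contig count, remaining ties toward the more stringent exponent; if no round
is in band, the closest round is used.  The pipeline's default coverage
target is the cumulative size of the most relaxed (converged) round: a
fragmented mid-assembly systematically overestimates assembled content by
double-counting the overlap tags of clones split across neighbouring
contigs, so the converged size is the natural data-driven estimate of
assemblable content (foreign material included, since screening runs after
cut-off selection).

The MTP is the greedy furthest-reach interval cover with a ≥1-tag overlap
constraint between consecutive picks, which is minimal for interval inputs
(verified against exhaustive enumeration up to 12 members); CB coverage gaps
produce per-component paths with a warning.

## Contamination screen

"More than four" is read strictly (difference ≥ 5) and "more than 66%"
strictly (> 0.66); both are configurable.  Clones with no assigned tags are
*indeterminate*: they count in a contig's denominator but never as foreign.
The redundancy rule eliminates a contig with fewer than 3 members when ≥80%
of its tags occur in a single larger retained contig; the thresholds are
package defaults, as the source analyses describe the clone-depth criterion
only qualitatively.

## RH mapping

The equal-retention haploid model gives cell probabilities
`P(11) = r(1-θ) + r²θ`, `P(10) = P(01) = rθ(1-r)`,
`P(00) = (1-θ)(1-r) + (1-r)²θ`.  `r` has the closed-form marginal estimate
`(2n11 + n10 + n01) / 2N`; `θ` is found by bounded scalar optimisation
(the all-pairs path solves the equivalent score quadratic in closed form and
is tested to agree with the scalar optimiser to 1e-5).  The LOD compares
against independence (θ = 1) with `r` re-fit, which has the same closed
form, so LOD ≥ 0 by construction.  Missing calls are dropped pairwise.

Distances use the Haldane-analog metric `d = -100 ln(1-θ)` cR, additive
under the Markov multipoint model.  Total map lengths are therefore
internally consistent but not numerically comparable with maps produced by
other engines whose internals differ.

Grouping takes the AND of LOD ≥ 4.0 and d ≤ 100 cR (the published
description does not specify the engine's exact semantics; AND is the
conservative reading).  Markers agreeing on every shared informative line
(≥1) collapse transitively into loci before ordering.

The multipoint likelihood is a two-state (retained/absent) forward algorithm
per line: initial `P(retained) = r`, transitions persist with `1-θ_i` or
re-draw retention with probability `r`, observation error `ε` flips a call
(default 0), missing calls marginalise to emission 1.  With complete data
and `ε = 0` the hidden states are observed and the likelihood decomposes
into an initial term plus one precomputable term per locus adjacency, making
an order evaluation O(k); the search uses that fast path when valid and the
forward algorithm otherwise.  The chain satisfies detailed balance, so
reversing an order never changes its likelihood — orientation is fixed by
convention (lexicographically smaller terminal locus first).

The order search is greedy chaining from the strongest two-point pair,
ML insertion of remaining loci (most-linked first), then repeated 2-opt
segment reversals and a width-5 permutation ripple until no improvement
(cap 20 passes).  Adjacent θ are re-estimated from the cached two-point
table on the final order.  On simulated 40-locus groups with 355 lines the
true order or its reversal is recovered in ≥90% of panels, and the search
never returns an order less likely than the truth (both tested).

Obligate breaks are adjacent 1↔0 transitions per line after dropping missing
calls, summed over lines; bin scope restricts to the loci between a bin's
distal and proximal markers.  Deletion bins group loci by their presence
pattern across the deletion lines.  Terminal deletions alone cannot separate
the two pericentromeric segments (both are present in every line), but the
arm identity of each marker is known from the arm-specific libraries, so an
optional arm label per locus splits that pattern at the centromere — this is
how 18 breakpoints yield 20 bins (7 + 13).  Bins are named deterministically
by index and by the deletion line whose breakpoint separates them from their
map neighbour.

## Integration

Contigs are placed at the median locus of their anchored markers (robust to
one mis-anchored marker; even counts take the more distal middle locus).
Orientation is the sign of the Spearman correlation between members' CB
coordinates and their markers' cR positions and requires two distinct loci —
contigs with markers at a single locus stay unoriented.  A contig is
chimeric when its marker cR positions split into clusters more than 50 cR
apart (the gap is a package default; the source analyses give none); it is
split at the largest CB gap between members carrying markers of the two
clusters, members inherited by CB side, children re-assembled.  Three or
more clusters split at the largest gap only, with a warning.  Co-located
contigs with syntenic genes are ranked by median reference position;
link-free contigs keep a stable rank after them.

## Comparative step

Gene markers are de-duplicated greedily at 98% identity (longest
representative, ties by id) from either a precomputed cluster table or a
pairwise identity function — the package never runs a homology search
itself; external search results enter as plug-in tables.  Genes on external
sequence contigs transfer to a BAC contig only through unique exact tag
hits, and a sequence contig hit by tags of non-co-located BAC contigs is
discarded entirely (gene counts are conserved across
assigned/discarded/unassigned, tested).

Rearrangement detection segments the reference-position sequence of ordered
syntenic links into maximal monotone runs, skipping up to one interrupting
outlier per 10 consumed genes (real ortholog tables are noisy; configurable).
A run of ≥3 genes against the dominant direction (weighted by run length) is
an inversion; a single whole-span descending run is likewise an inversion,
since the reference is canonically oriented ascending.  A run whose median
reference position deviates by more than 5 Mb from the linear colinear fit
through the dominant-direction genes is a translocation; both conditions
together give "translocation (inversion)".  The 5 Mb displacement threshold
is absolute, so it — unlike the block boundaries — is not invariant to
rescaling reference coordinates.

## Problem sizes and tolerances

The test suite and the acceptance script run the full pipeline on a 40 Mb
two-arm chromosome (9x coverage, 85% purity, 200 markers, 355 RH lines),
which preserves every statistical feature that matters — tags per clone,
clone overlap depth, breaks per line relative to marker spacing,
breakpoint-to-bin geometry — at a desk-scale problem size; this is the
package's reference configuration for validation.  Scalar optimisation uses
`xatol = 1e-8`; θ estimates below 1e-6 snap to 0; probabilities are clipped
to [1e-9, 1 - 1e-9] where logs are taken.  Degenerate inputs (empty
fingerprint sets, zero informative lines, zero-size contigs, unplaced region
endpoints) raise typed errors rather than propagating NaNs, and quantities
undefined at zero breaks are reported as undefined rather than infinite.

## Known limitations

- The CB consensus is a seriation heuristic, not a constraint solver; on
  heavily contaminated or chimeric clone sets its coordinates are
  approximate (the Q-clone screen exists precisely to flag those members).
- The equal-retention RH model ignores retention gradients (e.g. elevated
  retention near selected markers or centromeres) present in real panels.
- Centiray lengths are engine-specific (see above) and should be compared
  only within maps produced by this package.
- The translocation call depends on a linear colinear fit and an absolute
  displacement threshold; complex nested rearrangements collapse onto the
  largest-gap structure with warnings rather than a full breakpoint graph.
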