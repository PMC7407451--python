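# Methods

This note documents the models and procedures the package implements, the
parameters that matter, and the choices made where the design was open.

## Protokaryotype arms and fusion inference

The protokaryotype identifier system assigns every salmonid chromosome arm
to one of 50 universal labels, `PK 01.1` … `PK 25.2`: 25 pre-duplication
chromosomes, each with two post-duplication homeologous descendants.  A
homology table maps each PK arm to the linkage-group arm carrying it in
each species.  Cells follow a small grammar: an LG stem plus an optional
arm tag (`a`/`b` for the two arms of a metacentric, `p`/`q` for arm-named
assemblies, plus a trailing `c` on chromosomes assembled in three pieces),
optional `^` (weak evidence) and `*` (uncertainty) flags, `or`-joined
alternatives, and the literals `not identified` and `missing`.  The arm tag
is part of the arm address, not the LG identity: fusion detection keys on
the LG stem, so `Cart08a` and `Cart08b` are the two arms of one fused
chromosome.

A **fusion** is a linkage group carrying ≥ 2 distinct PK arms in one
species.  Two ambiguity policies are exposed:

- `inclusive` (default) keeps weak and ambiguous assignments and
  provisionally takes the *first* alternative of an `or` cell.  This is the
  counting rule under which the bundled coregonine table yields 8, 7 and 6
  fusions for cisco, European whitefish and lake whitefish.
- `strict` discards every flagged or alternative-bearing cell, as a
  sensitivity analysis.  Under it the two best-supported coregonine
  fusions, PK 05.1–06.1 and PK 10.2–24.1, remain present in all three
  species, while weakly evidenced fusions (and the unresolved
  PK 11.1–21.1 question in lake whitefish) drop out.  The package reports
  both policies and asserts neither for contested fusions.

`missing` and `not identified` are distinct statuses but both are excluded
from fusion counting.  An LG listed with three or more arms produces a
single multi-arm fusion record; its pairwise decomposition feeds the
shared-fusion analysis.  Because a single status enum cannot represent
cells flagged both weak and uncertain (`^*`), assignments store the two
flags independently and derive a status (uncertainty dominates); this is
what makes parse → format → parse an exact identity.

Linkage-map summaries aggregate per-LG records; LGs with zero loci for the
requested sex are absent from that sex's map and are excluded before
totals and means are taken (the bundled female cisco map spans 38 of 40
LGs).  Printed comparisons use round-half-even at the printed precision.

## Length-weighted median similarity

Each homeolog pair is summarized by the median percent identity of its
filtered alignment blocks, weighted by aligned length: the smallest
identity *v* such that blocks with identity ≤ *v* carry at least half the
total aligned length.  This equals the plain median of the multiset where
each block's identity is repeated `length` times; the test suite enforces
that equivalence against a literal expansion oracle.  With an even total
weight split the **lower** median is returned by default — reproducible and
exactly matched by the oracle — with a `midpoint` convention available.
Filtering keeps blocks with identity ≥ 75 % and length ≥ 1,000 bp, both
bounds inclusive (the identity filter is an inclusive range).  Block length
is the aligned-column count when the aligner reports one (the denominator
of the LASTZ `identity` fraction) and the query span otherwise; whether gap
columns count is aligner-dependent, so both behaviors are reachable and
neither is asserted.

Blocks are resolved to PK pairs through a chromosome-name → PK-arm map;
blocks whose endpoints are not the two arms of one PK (multi-arm fusion
contamination, gene-family hits) are excluded and logged rather than
silently pooled — pooling across non-homeologous arms is a known way to
blur a tetrasomic signal.

Within a species, pairs are ranked by descending weighted median (rank 1 =
most similar); across species, PKs are ordered by mean rank over the
species in which they are ranked.  All rank ties break by ascending PK
number, for determinism.

## Extreme-anchored kNN classification

Homeolog pairs occupy a continuum from freely recombining (tetrasomic,
high identity) to fully rediploidized (disomic).  Rather than a fixed
identity cutoff, the classifier anchors the two classes on each species'
own extremes: the 4 highest-median pairs are tetrasomic exemplars, the 4
lowest disomic exemplars (ties at either cut break by PK number; building
anchors requires ≥ 9 pairs so anchors never exhaust the panel).  Every
other pair is labeled by majority vote of its k nearest anchors, distance
being absolute difference of weighted medians.  The feature is
deliberately one-dimensional — classification uses the median similarity
only; alignment-level distributions feed only the class-contrast test.

Determinism rules: anchor distance ties resolve by a stable sort on
(distance, anchor PK); an even vote split falls to the **disomic** class
and is flagged — tetrasomy is the positive claim, so ties are called
conservatively.  With 4 anchors per class and k = 5, a winning vote is
necessarily 3/5 or 4/5 (five odd neighbors from a pool of only four per
class), so 0.8 is the best attainable support and 0.6 marks an
intermediate; at k = 8 every query sees all anchors and receives the
documented 4/4 tie behavior.

**Choosing k.**  k ∈ {1..10} is scored by stratified 10-fold
cross-validation repeated 100 times, and the largest k attaining the
maximal mean accuracy is selected, with the full (k, accuracy) table
always reported.  Only 8 of 25 pairs carry labels a priori, so the CV
needs a label source; two modes are provided:

- `provisional` (default): every pair receives a provisional label from
  the nearer anchor-class median (one-nearest-class-centroid), and CV runs
  over all 25 pairs, each test fold classified by its k nearest neighbors
  among the training-fold pairs.  This permits genuine 10-fold CV on a
  25-pair panel.
- `anchors_only`: CV over the 8 anchors alone, folds capped at the
  minority class size.

If a class has fewer members than folds, the fold count is reduced to the
minority size and logged.  Fold shuffles are drawn from per-repeat
substreams of one master seed, so extending `n_repeats` never perturbs
earlier repeats, and the selection is invariant to input order.  Under
clean class separation every k ties at accuracy 1 and the rule returns
k = 10 — the largest-k tie rule is reported as such rather than asserting
any particular k; classification voting then caps k at the 8 available
anchors.

**Class contrast.**  A two-sided Wilcoxon rank-sum test compares pooled
alignment identities between predicted classes at α = 0.01: exact null
enumeration when n ≤ 20 and the pooled sample is tie-free, tie-corrected
normal approximation with continuity correction otherwise (the reported
statistic is the rank sum of the first group).  The exact branch is
verified in tests against full enumeration over rank assignments.

## Duplicated-marker support

In gynogenetic haploid crosses, markers in residually tetrasomic regions
can be mapped at both paralogous positions.  A both-paralog marker whose
two placements resolve (through the arm map) to the two arms of one PK
contributes one unit of support to that homeolog pair.  Markers mapped at
a single paralog cannot identify an arm pair; they are excluded from
support counts and reported separately.  Markers placed twice on one LG
are excluded with a warning, and markers on LGs outside the arm map are
skipped and logged.  Support counts key on PK pairs rather than raw LG
pairs so they compare directly across species.  The high/low split
defaults to 10 markers — sitting with wide margin between the
tens-of-markers regime of tetrasomic pairs and the 1–6 markers typical of
disomic pairs — with an inclusive boundary.

The upstream identification of duplicated loci from haploid segregation
ratios belongs to the genotyping stage and is out of scope; the interface
accepts already-called placements.

Marker pairing between two linkage maps goes through an intermediate
reference genome: anchors of map A, processed in (contig, position) order,
greedily take their nearest unpaired map-B anchor on the same contig
within `max_gap` (default 10 Mbp).  Greedy nearest pairing — not optimal
bipartite matching — mirrors the reference map-comparison behavior at this
scale; no marker is reused and pairing never crosses contigs.

## Synthetic data: what it emulates and what it does not

The generators produce panels of 25 homeolog pairs, 8 of them tetrasomic
(by default the set recurrently classified tetrasomic from genome
analyses: PK 01, 02, 09, 11, 20, 22, 23, 25).

**Substitution model.**  Equal-rates single-parameter substitution, no
indels: the simplest model with a closed-form identity expectation,
E[identity] = ¼ + ¾·e^(−8d/3) for per-lineage divergence d, which the
tests use as an independent oracle (each lineage's sites are drawn from
the exact transition distribution, equivalent to accumulating Poissonian
substitutions).  No indels means copies stay positionally aligned and no
aligner is needed; windowed identity over non-overlapping windows (default
1 kb, final partial window dropped) stands in for aligner output.

**Residual tetrasomy.**  Homeologous exchange is modeled as whole-tract
copy-over applied after divergence: tract count ~ Poisson(`exchange_rate`),
lengths ~ geometric(1/`tract_mean`), positions uniform, direction by fair
coin per tract.  This approximates ongoing homeologous recombination
without generation-by-generation simulation; covered sites become
identical regardless of direction.

**Default parameters** (`SimConfig`): 100 kb arms (a desk-scale stand-in
for ~50 Mb chromosome arms), `subst_rate_per_site = 0.0654` putting
disomic identity at ≈ 88 %, and `exchange_rate = 150` tracts of mean 1 kb,
covering 1 − e^(−1.5) ≈ 78 % of the arm and putting tetrasomic identity at
≈ 97 %.  Many short tracts rather than few long ones are used because the
covered fraction — hence the identity — then varies little between
tetrasomic pairs (sd ≈ 0.6 points), keeping the two regimes separated the
way the well-characterized tetrasomic/disomic contrast is in real genome
comparisons.  All generators derive per-object streams from one master
seed and are byte-reproducible.

**What passing tests do not show.**  The simulator has no indels, no
rearrangements, no assembly collapse of duplicated regions, no
gene-family paralogy, uniform base composition, and a sharp two-class
truth; real genomes blur all of these (intermediate pairs, multi-arm
fusions contaminating alignments, collapsed duplications).  Recovery of
planted labels under the default separation therefore validates the
pipeline's mechanics — filtering, weighted medians, anchoring, voting —
not the empirical difficulty of classifying borderline pairs in real
assemblies.

## Numerical and scale choices

- Weighted medians are computed on exact cumulative sums; no floating
  interpolation unless the midpoint convention is requested.
- Printed-value comparisons round half-even at the printed precision.
- CV accuracies are compared with a 1e-12 tolerance before taking the
  largest tied k.
- End-to-end recovery and calibration checks run 100 panels of 25 × 100 kb
  pairs and 50 disomic replicates of 100 kb respectively — sizes chosen so
  Monte-Carlo error is small relative to the effects being measured while
  the whole suite stays quick on one CPU.
- Degenerate inputs fail loudly: empty block lists, empty groups, empty
  LG subsets, k outside 1..8 for classification, conflicting planted
  fusions, and oversize windows all raise with context.

## Known limitations

- Fusion inference sees only what the homology table encodes; arms lost to
  `not identified` cells silently reduce fusion counts, which is why both
  ambiguity policies are reported.
- The provisional-label CV mode scores k against labels that are
  themselves derived from the anchors; it selects a stable k but is not an
  unbiased accuracy estimate.
- Greedy marker pairing is order-dependent by design and can differ from
  optimal matching when anchors cluster tightly.
- The Wilcoxon exact branch requires tie-free data; percent identities
  from windowed counts tie frequently, so real-scale contrasts almost
  always use the tie-corrected approximation.
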