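# Methods

`barcodiv` implements the analytical core of a rapid, tree-based biodiversity
assessment workflow for DNA-barcode surveys: condition and group unidentified
barcode sequences, delimit species on single-locus trees, attach taxonomy to
queries from their placement among tagged references, and extrapolate total
species richness from the delimited inventory. A survey simulator with
complete ground truth makes every stage testable at desk scale. This note
records the models, the numerical choices, and their limits.

## Units and conventions

All branch lengths and ages are expected substitutions per site; the
coalescent scale `theta` is in the same unit (a random within-species pair
coalesces `theta/2` back in time on average). Node supports are stored on
[0, 1]; Newick input carrying percentages (any value above 1) is divided by
100 on parsing, and emission defaults to the unit scale so round-trips never
rescale twice. Alignment coordinates are 0-based half-open. Every stochastic
routine takes an explicit seed and uses numpy's PCG64 generator, so results
are reproducible across platforms.

## Sequence conditioning

Distances: p-distance, Jukes–Cantor and Kimura 2-parameter, with gap, `N`
and ambiguity positions excluded from the comparison (they never count as
match or mismatch). JC/K2P corrections that are undefined (p ≥ 3/4, or
non-positive Kimura logs) return an infinite saturation sentinel which tree
building refuses to consume silently.

Global alignment uses the three-state affine-gap recursion (match +1,
mismatch −1, gap open −4, gap extend −1; the opening penalty covers the
first gap position). Rows are vectorised; the within-row horizontal-gap
recursion is a prefix-maximum scan, so the dynamic programme is O(L) numpy
operations per row. Multiple alignment is progressive: UPGMA guide tree on
k-mer distances (k = 8), profile columns as base-frequency vectors, and the
column–column score the expected pairwise score, which reduces exactly to
the scalar scheme for single sequences. Removing gap columns from any output
row recovers the input — the aligner never drops residues.

Re-orientation keeps or reverse-complements each query according to the
smaller best p-distance to any reference (alignment is attempted only
against the few references sharing the most k-mers with either strand);
equal strand scores flag the query as ambiguous and leave it unchanged.
End-trimming projects each query onto a full-length marker exemplar through
pairwise alignment and removes positions outside the exemplar's span;
post-trim fragments shorter than 100 bp (configurable) are dropped with a
warning. Dereplication collapses exact duplicates only — "population data"
is read as identical haplotypes — with the lexicographically smallest id as
representative.

Two alignment regimes serve different divergence levels.  Within a query
group (bounded by the clustering threshold) the de-novo progressive aligner
is reliable.  Across groups — the all-query tree that threshold delimitation
needs — positional homology from progressive profile merging degrades once
pairwise identity approaches 50%, so that alignment is instead pinned to the
marker exemplar's coordinate system (``anchor_align``: every sequence
pairwise-aligned to the anchor and projected into its columns, insertions
opening shared padding blocks).  Both trimming and anchor projection use a
gap-parsimony guard for length-conserved markers: an equal-length pair keeps
its gap-free positional alignment unless the affine-gap optimum gains more
than 0.25 per column, the empirical separatrix between chance relocations at
high divergence (up to ~0.11 per column) and true compensating indels
(~0.5 per column).

Query grouping is single-linkage clustering at a divergence threshold
(default p-distance 0.05; the workflow this follows leaves the threshold to
the operator). Reference recruitment into a group requires both a local
screen (shared distinct-k-mer fraction ≥ 0.2 at k = 8) and a global
p-distance ≤ 0.10 to at least one member; both criteria are logged per
reference, and a group recruiting nothing is flagged unidentifiable rather
than sent to tree building. For large distance matrices the same k-mer
screen can short-circuit alignment of pairs that cannot fall below any
clustering threshold; such pairs are recorded at distance 1.

## Trees

Neighbor joining (via scikit-bio, negative length estimates clamped to 0)
gives unrooted group trees; UPGMA (scipy average linkage, node age = cluster
distance / 2) gives the rooted ultrametric trees that threshold delimitation
requires. Supports come from nonparametric bootstrap over alignment columns;
an edge's support is the fraction of replicate trees containing its
(unrooted, canonically encoded) bipartition. Rooting ("secondary
polarisation") is midpoint by default — implemented directly, since the
longest-pair midpoint can coincide with an internal node, a case library
rerooting mishandles — or by outgroup, rooting on the edge above the
smallest clade containing all outgroup tips (with a warning when that clade
contains ingroup tips). Re-rooting re-attaches supports by bipartition
identity and never changes tip-to-tip path lengths.

A UPGMA tree built from an alignment snaps node ages below the marker's
distance resolution — half of one substitution per site, 1/(2L) — to zero.
Ages in that range are measurement noise (p-distances are quantised at 1/L),
and leaving them positive seeds spurious near-zero waiting intervals that
threshold models over-fit; with the snap, such pairs behave like the exact
duplicates they statistically are. Ultrametricity is checked as the maximum
absolute deviation of root-to-tip depths from their mean, tolerance 1e-6 of
tree height by default.

## Species delimitation

### Mixed Yule-coalescent threshold model

On an ultrametric tree with n tips, the n−1 inter-node intervals are
extracted oldest-first (coincident ages collapse into one interval). A
threshold age T classifies nodes older than T as diversification events;
edges crossing T subtend the delimited entities. The combined event rate in
interval i is

    b_i = lambda1 * n_d,i^p1 + lambda2 * sum_j [ n_j,i (n_j,i − 1) ]^p2

with `n_d,i` the number of species-level lineages (total lineages above T,
the constant number of entities below), `n_j,i` the lineages of entity j,
and entities with a single lineage contributing nothing. Each interval of
length x_i contributes `ln b_i − b_i x_i`; the null model is a single
process `b_i = lambda [n_i(n_i−1)]^p` over the whole tree. Candidate
thresholds are the midpoints between consecutive distinct node ages plus one
below the shallowest node (every tip its own entity) and one above the root
(a single entity).

Maximisation exploits the structure of the likelihood: at fixed exponents
(p1, p2) the problem is concave in the two rates, solved by a projected
Newton ascent with backtracking (bounds lambda ∈ [1e-8, 1e6]); the outer
search over (p1, p2) ∈ [0, 10]² is a batched hierarchical grid (11×11
refined twice around the incumbent, all grid points solved simultaneously by
a vectorised Newton) followed by a Nelder-Mead polish. This replaces a
generic 4-parameter multistart: profiling removes the rate–exponent ridge
that multistarts existed to survive, and the scheme is deterministic and
verified against dense-grid scans. Extra seeded polish starts remain
available (`n_starts`).

The likelihood-ratio statistic 2(logL − logL0) is referred to chi-square
with 3 degrees of freedom (five mixed-model parameters against two),
the convention of the threshold-model literature; the approximation is
rough — under single-population simulations the test runs mildly liberal
(empirical size around 0.1 at a nominal 0.05 in the acceptance suite's
200-replicate study). The confidence range of entity counts is the span of
entity counts over candidate thresholds within 2 log-likelihood units of the
optimum; the point estimate is always contained. "Entities" include
singletons; "clusters" are entities with ≥ 2 sampled tips.

### Poisson tree processes

For non-ultrametric trees, a delimitation is an antichain of species-root
nodes covering all tips. Branches strictly inside a species are the
coalescent class; all others — including the stem branch subtending each
species root, which ends at the speciation-to-coalescence transition — are
the speciation class. Each class is exponential with its maximum-likelihood
rate (count / total length); a delimitation leaving one class empty is
scored with the single-class model so all candidates are comparable.
Zero-length branches count as 1e-9; identical haplotypes should be
dereplicated first (the pipeline does), since a cluster of zero-length
branches otherwise rewards unbounded rates. `exact` mode enumerates every
antichain (≤ 12 tips); `greedy` mode takes the better of two deterministic
hill climbs, from the all-singletons and from the single-species
delimitations, merging (collapsing any internal node, absorbing the species
roots beneath it) or splitting one node per step, ties broken towards fewer
species. Single-start hill climbing stalls in local optima on trees without
clean two-class structure; the two-start variant agrees with exhaustive
enumeration on 98 of 100 random 8-tip trees in the acceptance suite.

## Taxonomic assignment

Given a polarised tree containing a query and taxonomically tagged
references, ancestors of the query are scanned tip-to-root:

* STRICT takes the least inclusive ancestor with support ≥ 0.70 (default),
  at least two reference tips, and references on at least two child
  subtrees — the query must be bracketed, not merely adjacent — and reports
  the rank-by-rank unanimous prefix of that clade's reference lineages.
  Scanning least-inclusive qualifying clades is equivalent to the
  "most inclusive supported clade" reading for a unanimity criterion, since
  enlarging a clade can only shorten the unanimous prefix.
* LIBERAL takes the nearest reference-bearing ancestor regardless of
  support and reports the majority lineage (strictly more than half at each
  rank, lineages lacking the rank abstaining); a single sister reference
  contributes its full lineage.

Strict is a prefix of liberal by construction (unanimity over a superset of
the liberal clade's references cannot descend further than their majority),
and the bracketing condition is what yields the anti-false-positive
behaviour: a query whose own genus is absent from the library resolves to
the correct family instead of adopting its nearest neighbour's genus. Both
criteria, the support bar and the majority fraction are configurable.

## Richness

Incidence-based estimators on the species-by-event matrix: Chao2
(`S_obs + ((m−1)/m) Q1²/(2 Q2)`, switching to the bias-corrected
`S_obs + ((m−1)/m) Q1(Q1−1)/(2(Q2+1))` when there are no doubletons, with
the standard asymptotic variance), first- and second-order jackknife; Chao1
on abundances. ACE/ICE are deliberately out of scope. Accumulation curves
use the closed-form hypergeometric rarefaction
`E[S_t] = Σ_i [1 − C(m−Y_i, t)/C(m, t)]`, with a seeded permutation mode as
a cross-check. Completeness is S_obs / S_hat; reporting all estimators
yields the customary min–max interval. Estimates are cross-checked against
vegan's `specpool` in the test suite.

## Morphospecies comparison

Each molecular group is classified against the morphospecies labels as
match (exact set equality), split (strictly inside one morphospecies),
lump (union of ≥ 2 complete morphospecies) or mixed (no clean containment —
a class required for totality, since noisy partitions straddle). Global
agreement is the adjusted Rand index (scikit-learn; a brute-force
pair-counting oracle lives in the tests).

## Survey simulator

The generator composes: a Yule species tree conditioned on n species
(backward construction, uniformly random joins, waiting time exp(rate·k)
with k lineages, so the expected root age is Σ_{k=2..n} 1/(rate·k)); a
censored multispecies coalescent within species branches (rate
pairs·2/theta, survivors entering the parent population — lineage sorting
can be made incomplete on purpose, monophyly is not forced); sequence
evolution under JC or K2P (rate matrix scaled to one expected substitution
per unit length, exact transition probabilities via matrix exponential) with
optional indels (Poisson events, geometric lengths of mean 3, insertions and
deletions equally likely) tracked through a column registry so the true
alignment is retained; ranked taxonomies by cutting the species tree at
fixed fractions of its height (genera at 0.5, families at 0.85 — genera
nest within families by construction); sampling events with per-species
Bernoulli occupancy (`detection`) and uniform allocation of individuals to
occupied events, with an optional geometric abundance distribution; and
morphospecies labels corrupted by lumping a species into a congener's label
with probability `morph_lump` and splitting a species into two labels with
probability `morph_split`.

Default study conditions — 10 species, rate 5 (mean height ≈ 0.39), theta
0.01 (within-to-between depth ratio ≈ 0.02), 5 individuals per species,
830 bp K2P barcode with kappa 4, no indels, 10 events at detection 0.5,
5% morphospecies error — emulate a tropical leaf-beetle-style cox1 survey
in which species are well separated but individual species pairs can still
be recent. What the simulator does not emulate: rate variation among sites
and lineages, selection, migration or hybridisation, PCR/sequencing error,
contamination, and uneven taxon sampling; passing tests therefore certify
the algorithms and their calibration on clock-like, neutrally coalescing
data, not performance on every real dataset.

## Pipeline

The orchestrated run validates its configuration before touching data
(unknown keys rejected, paths checked), then: load → orient → trim →
dereplicate → cluster → per-group recruitment, alignment, bootstrapped tree
(seeded), midpoint rooting, assignment → anchor-guided all-query alignment →
UPGMA → threshold delimitation (or NJ + PTP) → entity-by-event incidence →
accumulation and richness → morphospecies comparison when labels are
present. Every artifact is plain text and listed in a manifest with SHA-256
checksums; all randomness funnels through the single run seed, so same-seed
runs are byte-identical. Stage failures keep partial outputs under a
`.partial` suffix.

## Problem sizes in the test and acceptance suites

The oracle and property tests run at 4–12 tips where exhaustive enumeration
(all alignments, all antichains, all event subsets, dense threshold-exponent
grids) is exact. Calibration and recovery studies use 50 surveys at the
default conditions, 200 single-population null simulations of 20 samples,
and an end-to-end run at 30 species × 10 individuals; these sizes give the
Monte-Carlo checks three-standard-error resolution while keeping a full run
of the suite on one CPU comfortably inside half an hour.

## Known limitations

* GMYC here is single-threshold; surveys whose speciation–coalescent
  boundary varies strongly across clades need the multiple-threshold
  extension, which is out of scope.
* The chi-square(3) reference distribution for the LR test is a convention,
  not an exact null; bootstrap calibration would be better and is not
  implemented.
* Distance trees (NJ/UPGMA) stand in for likelihood tree search; externally
  computed support-annotated trees can be imported instead, and that is the
  recommended route for publication-grade analyses.
* PTP on trees containing many sub-resolution branch lengths over-splits by
  construction; dereplicate, and read its counts as haplotype-cluster upper
  bounds on shallow data.
* The assignment criteria assume the reference taxonomy is internally
  consistent (no rank gaps, no synonyms); no name reconciliation is done.
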