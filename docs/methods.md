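# Methods

This note documents the models and procedures implemented in `mrpforge`,
the defaults and their units, what the synthetic-data generator does and
does not emulate, and the numerical and design choices made where the
problem left room.

## Matrix representation with parsimony

Source trees contribute topological information only. Baum–Ragan additive
binary coding turns each internal node of a source tree into one character:
descendants `1`, other sampled taxa `0`, unsampled taxa `-`. The root node
(constant `1` over sampled taxa) and trivial singletons are omitted — they
cannot affect a parsimony search. An unrooted source is coded per
non-trivial split with an arbitrary fixed polarity. A rooted binary source
with n leaves therefore yields exactly n − 2 characters, an unrooted one
n − 3.

Admixture plots are population × cluster proportion tables (rows must sum
to 1 within 1e-6; violations are rejected, never silently renormalized).
Coding is thresholded presence: membership ≥ `present_threshold` (default
0.10, i.e. the "less than 10% is neglected" rule) codes `1`, otherwise
`0`. An optional borderline band (default off; when enabled,
[threshold − 0.05, threshold + 0.05)) codes `?`. The crisp rule is the
default because "borderline" has no canonical quantitative definition;
per-individual heterogeneity inside one population is below the resolution
of a population-level Q-matrix, so callers mark such cells `?` in the
input if needed. Plots can also be viewed through their implied MP tree
(`implied_admixture_tree`), but merging always uses the coded matrix
directly: the implied tree is a lossy summary, the matrix is not.

`?` (unknown) and `-` (inapplicable) are distinguished in storage and
serialization but both behave as fully missing (any state) in
optimization, the standard parsimony treatment.

## Rooting and weighting

Rooting is expressed through a hypothetical all-zero outgroup `ALL0`.
Characters from sources treated as rooted under the active scheme score it
`0`; all other characters score it `?`, so unrooted sources constrain
grouping but not polarity. This is the standard practice; scoring them `0`
instead would let unrooted sources vote on the root, which they cannot
justify. The four rooting schemes (A–D) and four weighting schemes (1–4)
are described in the README; the weight factor is 1,000 and weights are
integer multipliers inside the weighted Fitch step count, so a 1:1,000
ratio means one upweighted step outweighs any realistic number of
downweighted ones. `deactivate=True` replaces the low class's weight 1
with 0 (characters ignored entirely), which exists to verify that the
1:1,000 ratio is already effectively decisive.

When a parameter set treats no source as rooted (possible under scheme D
if no source carries a hominin outgroup), the position of `ALL0` is
arbitrary and the rooted consensus degenerates while the unrooted topology
remains meaningful; consumers should compare such cells unrooted.

## Parsimony engine

Characters are binary with missing data, so Fitch state sets fit two bits
and scoring is vectorized across characters. Two scorers coexist and are
cross-checked in the tests: a fast intersection/union Fitch pass for the
fully resolved trees visited during search, and a per-state Sankoff
dynamic program for the public scorer, exact on hard polytomies. Scores
are invariant under rerooting.

The search is random-addition stepwise insertion (ties in insertion cost
broken by a seeded uniform choice) followed by first-improvement branch
swapping under NNI, SPR or TBR, with an optional parsimony ratchet
(iterations of: upweight a random quarter of the informative characters
×4, swap, restore, swap). After the replicates, the search walks the
equal-score plateau breadth-first so the returned MP set is complete up to
`max_trees_retained` (default 1,000; hitting the cap flags the result
truncated rather than failing). Desk-scale defaults are 100 addition
replicates (large analyses historically used 10,000; that is a
configuration option, not a different code path) and TBR swapping.
Uninformative characters contribute a constant, topology-independent step
count and are folded into an additive offset.

`exhaustive_search` enumerates all (2n−5)!! unrooted binary topologies by
recursive edge addition (refusing n > 10) and is the optimality oracle:
the heuristic can tie it but never beat it, and any heuristic score below
the exhaustive optimum is a bug by definition.

## Consensus, SPR distance, anticonsensus, CI/RI

Strict consensus keeps clades present in every input; semistrict
(combinable components) keeps clades contradicted by none, assembled
greedily by frequency then size (deterministic order) when uncontradicted
clades are mutually incompatible; frequency-difference keeps clades
strictly more frequent than every incompatible rival. Unrooted inputs are
oriented away from the lexicographically smallest leaf so clade operations
coincide with split operations.

SPR distance is exact (breadth-first search through the SPR graph) for up
to 8 leaves and binary inputs; above that a greedy agreement-set upper
bound is used: strip the leaf whose removal most reduces the
Robinson–Foulds distance of the restrictions until the trees agree — each
stripped leaf can be regrafted with one SPR move, so the count is a valid
upper bound, and it is flagged approximate. Unresolved inputs are refined
against each other's compatible splits first and always flagged
approximate. The similarity percentage is 100 × (1 − d/(n−3)); the
normalization is this package's own convention, so published similarity
ranges should be compared qualitatively, not digit by digit.

Character fit uses the classical indices for a binary character on a
reference tree: observed steps s (Fitch), minimum m = 1, maximum
g = count of the rarer observed state (star-tree steps), CI = m/s,
RI = (g−s)/(g−m), and the floor CI_min = 1/N for a character scored `1` in
N taxa, which makes CI values comparable across families of different
sizes. Characters constant among scored taxa are reported but excluded
from the ensemble indices (Σm/Σs and (Σg−Σs)/(Σg−Σm)).

## Sensitivity grid and wildcards

`run_sensitivity` runs code → merge → root → weight → search → consensus
for each of the 16 cells, deriving cell i's seed as `seed + i` so the
whole grid is reproducible from one integer.

Wildcard identification is a greedy prune-and-measure variant of
iterative positional-congruence reduction: candidates are single taxa plus
cherries appearing in at least one MP tree; the node gain of a candidate
is the resolved-node count of the strict consensus of the pruned trees
minus that of the unpruned consensus restricted to the same leaves (this
is never negative). The candidate with the largest gain is pruned while
the gain is ≥ `min_gain` (default 1) and ≥ 4 leaves remain; ties prefer
the smaller candidate, then lexicographic order, so a lone rogue is never
shadowed by a cherry containing it. Exclusion is recommended when a
candidate's maximum gain across parameter sets reaches
`exclusion_threshold` (default 5 nodes). Alternative attachment positions
are reported as the distinct sister groups of the candidate across the MP
trees. Node gain is measured on the strict consensus, matching the pruned
strict consensus used for inspection.

## Linguistic constraints

Constrained supertrees append the classification characters to the
scheme-A-rooted merged matrix at the constraint weight factor (default
1,000), also upweighting language-tree partitions; they are soft
constraints, not hard backbones — fidelity to the weighting mechanism is
the point, and it keeps one search engine. Pairs of classification
characters whose `1`-sets properly overlap are reported as warnings before
the search; the search itself resolves the conflict in favour of whatever
heavier-compatible combination scores best.

`group_status` classifies a named group on a possibly unresolved tree as
monophyletic (some node's leaf set equals the group), otherwise
paraphyletic-or-unresolved when the group's indicator character attains at
most one step minimized over resolutions of polytomies (the group is
convex: compatible with monophyly or paraphyly), otherwise polyphyletic.
The convexity formalization is this package's; it reproduces the verbal
white/gray/black classification and is exercised against brute-force
enumeration in the tests.

## Synthetic scenarios

The generator emulates the structure of a compiled literature dataset:

* a Yule (uniform random-split) rooted binary true tree over populations
  `P001…`;
* ~40 sources by default with a partition census dominated by genetic
  trees (6 genomic, 6 autosomal, 6 Y, 6 mtDNA, 5 HLA, 2 classical), a
  minority of language trees (3) and ~15% admixture plots (6), mirroring
  the leverage the weighting schemes have on real compilations;
* each source tree samples a fraction of the taxa (default 0.5) and is
  perturbed by a number of random NNI moves (default 1). NNI count is the
  noise unit because the method is purely topological — there are no
  branch lengths to scale an error by. Y/mtDNA/genomic sources are always
  rooted, others rooted with probability 0.5, and 30% of rooted sources
  are flagged as carrying a hominin outgroup;
* admixture plots cut the true tree into K clades and draw each
  population's row from a Dirichlet centred on its clade indicator
  (concentration `alpha`, default 200 — visibly noisy but decisively
  assigned; 1e6–1e7 is the crisp limit used in identity tests), with
  planted admixed populations centred on a 50/50 two-cluster mixture;
* classifications assign families to clades of the truth, reassign a
  `misfit_rate` fraction to wrong families (gene–language discordance) and
  score designated language-shift taxa `?`;
* planted rogues are reattached at a random position in every source tree
  that samples them, erasing any consistent placement signal.

Every scenario records a manifest from which it regenerates
bit-identically.

What passing tests on these scenarios show — and what they do not: the
generator plants topological conflict, partial overlap, admixture noise
and rogues, so it exercises coding, weighting, search, consensus,
stability and constraint machinery under controlled truth. It does not
model ascertainment differences between markers, correlated errors among
publications from shared samples, reticulate history beyond flat admixture
rows, or curation artefacts; recovery rates here are upper bounds on what
equally noisy real compilations would give.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which each property is non-trivial: identity and
recovery checks use 10–30 taxa with 2–4 addition replicates and SPR
swapping; oracle comparisons use 8 taxa where the exhaustive enumerator is
exact; the full grid runs on 10–20-taxon scenarios. Determinism is
end-to-end: every stochastic step consumes a `numpy` generator seeded from
one integer, reports are serialized with sorted keys and fixed float
formatting, and rerunning any analysis with the same configuration and
seed reproduces byte-identical files.

Known limitations: exact SPR distance is exponential and therefore capped
at 8 leaves; TBR neighborhoods are enumerated without the dedicated
edge-reuse optimizations of specialized parsimony programs, so very large
matrices will want fewer replicates; wildcard detection is greedy and can
in principle miss a jointly-unstable pair whose individual gains are zero,
although the candidate set (taxa plus observed cherries) covers the cases
reported in practice.
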