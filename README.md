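# mrpforge

Supertree synthesis of human-population phylogenies by **matrix
representation with parsimony (MRP)**, combining heterogeneous published
source trees with STRUCTURE/ADMIXTURE-style ancestry plots, mapping the
robustness of the result over a weighting × rooting sensitivity grid,
pruning unstable "wildcard" taxa, and measuring how well linguistic
classifications fit the genetic signal.

## Who this is for

Population geneticists and phylogeneticists who want a reproducible,
scriptable pipeline for combining many partially overlapping published
trees — genome-wide, autosomal, Y-chromosomal, mtDNA, HLA, classical
polymorphism and language trees — plus admixture plots into one composite
phylogeny, and for interrogating how sensitive that composite is to
analytical choices. Because compiled collections of published trees are
rarely redistributable, the package ships a first-class synthetic-scenario
generator with known ground truth, so every stage of the pipeline is
testable end to end.

## The method

**Coding.** Each source tree is converted to a partial matrix of additive
binary characters (Baum–Ragan coding): for every internal node, taxa
descended from it are scored `1`, other taxa sampled by that source `0`,
and unsampled taxa `-` (inapplicable). An admixture plot (a Q-matrix of
per-population ancestry proportions over K clusters) contributes one
character per cluster: membership ≥ 10% codes `1`, below codes `0`, and an
optional borderline band codes `?`.

**Rooting and weighting.** The partial matrices are merged over the union
of taxa and a hypothetical all-zero outgroup `ALL0` is appended: characters
from sources treated as rooted score it `0`, all others `?`. Four rooting
schemes (A: all rooted sources and plots; B: rooted trees only; C: rooted
genetic/genomic trees only; D: only sources with great-ape/archaic-hominin
outgroups) cross four weighting schemes (1: equal; 2: trees ×1,000 over
plots; 3: genetic trees ×1,000 over language trees and plots; 4: genomic
trees ×1,000 over everything) to give 16 parameter sets `1.A` … `4.D`.

**Search.** The merged matrix is analysed by weighted Fitch maximum
parsimony: random-addition-sequence stepwise insertion followed by
NNI/SPR/TBR hill climbing with an optional parsimony ratchet, pooling all
equally most-parsimonious trees; an exhaustive enumerator over all
(2n−5)!! unrooted topologies serves as the optimality oracle at small n.
Results are summarized as strict / semistrict / frequency-difference
consensus trees, compared across parameter sets by SPR distance and
"anticonsensus" (positively incompatible clades).

**Wildcards.** Taxa whose position wanders among the MP trees are found by
greedy prune-and-measure: prune the candidate (taxon or cherry) whose
removal gains the most resolved nodes in the strict consensus, repeat, and
recommend exclusion for candidates gaining ≥ 5 nodes.

**Linguistics.** Language families enter either as characters *fitted*
onto the supertree — per-family consistency and retention indices
CI = m/s, RI = (g−s)/(g−m), compared with the floor CI_min = 1/N for a
family scored in N populations — or as soft *constraints*, upweighted
×1,000 so fully scored families become monophyletic while `?`-scored
language-shift populations follow the genetic signal.

## Worked example

```python
from mrpforge import (generate_scenario, run_sensitivity, SearchConfig,
                      spr_distance, fit_classification)
from mrpforge.trees import rf_distance

scenario = generate_scenario(n_taxa=20, seed=42, keep_fraction=0.6, n_nni=1)
print(f"{len(scenario.sources)} sources over {scenario.true_tree.n_leaves} populations")

cells = run_sensitivity(
    scenario.sources,
    search_cfg=SearchConfig(n_addition_replicates=3, swap="spr", seed=42))
for label in ("1.A", "2.A", "4.D"):
    cell = cells[label]
    rf = rf_distance(cell.strict.unroot(), scenario.true_tree.unroot())
    print(f"{label}: score={cell.search.best_score} "
          f"mp_trees={len(cell.search.mp_trees)} "
          f"strict_nodes={cell.strict.n_informative_nodes()} rf_to_truth={rf}")

sim = spr_distance(cells["1.A"].strict, cells["4.D"].strict)
print(f"1.A vs 4.D: d_spr={sim.d_spr} similarity={sim.similarity_pct:.1f}%")

fit = fit_classification(cells["1.A"].strict, scenario.classification_matrix)
print(f"linguistic ensemble CI = {fit['ensemble_ci']:.3f}")
```

prints

```
40 sources over 20 populations
1.A: score=390 mp_trees=1 strict_nodes=18 rf_to_truth=0
2.A: score=367023 mp_trees=1 strict_nodes=18 rf_to_truth=0
4.D: score=67326 mp_trees=1 strict_nodes=18 rf_to_truth=2
1.A vs 4.D: d_spr=1 similarity=94.1%
linguistic ensemble CI = 1.000
```

Forty noisy, 60%-overlapping sources recover the 20-population truth
exactly under equal weights (`1.A`: Robinson–Foulds distance 0, a single
fully resolved MP tree). The weighted cells report much larger scores
because tree characters carry weight 1,000. The genomic-only cell `4.D`
differs from the truth by one rearrangement (SPR distance 1, 94%
similar). The clade-derived language classification fits the recovered
supertree perfectly here (ensemble CI = 1); with planted gene–language
discordance it drops well below 1.

A command-line interface mirrors the library (`forge simulate`, `forge
search`, `forge sensitivity`, `forge wildcards`, `forge run-all`,
`forge fit`).

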