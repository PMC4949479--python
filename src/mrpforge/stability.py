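"""Sensitivity grid and wildcard-taxon identification.

The robustness of a supertree is mapped over a 4 x 4 grid of analytical
assumptions: four partition-weighting schemes crossed with four rooting
treatments, giving sixteen parameter sets labelled ``1.A`` ... ``4.D``.
Each cell re-codes, re-weights, re-roots and re-searches the merged matrix.

Wildcard (rogue) taxa are populations whose position wanders among the
equally most-parsimonious trees, collapsing the strict consensus.  They are
found by a greedy prune-and-measure procedure: for every candidate (single
taxon or cherry appearing in at least one MP tree), measure how many
resolved consensus nodes are gained by pruning it from every tree; prune
the best candidate and repeat.  Candidates whose gain reaches the exclusion
threshold (five nodes by default) are recommended for exclusion from the
dataset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .consensus_compare import semistrict_consensus, strict_consensus
from .errors import ValidationError
from .matrix_rep import (AdmixtureCodingConfig, OUTGROUP, apply_rooting,
                         apply_weights, build_merged_matrix)
from .parsimony import SearchConfig, SearchResult, heuristic_search
from .trees import Topology


@dataclass(frozen=True)
class ParameterSet:
    """One cell of the weighting x rooting sensitivity grid."""

    weighting: int          # 1..4
    rooting: str            # "A".."D"

    @property
    def label(self) -> str:
        return f"{self.weighting}.{self.rooting}"


def build_parameter_grid() -> list[ParameterSet]:
    """The full 16-cell grid, deterministic order 1.A, 1.B, ..., 4.D."""
    return [ParameterSet(w, r)
            for w, r in itertools.product((1, 2, 3, 4), "ABCD")]


@dataclass(frozen=True)
class CellResult:
    """Search outcome and consensus summaries for one parameter set."""

    label: str
    search: SearchResult
    mp_rooted: tuple[Topology, ...]   # MP trees rooted by the outgroup
    strict: Topology
    semistrict: Topology


def run_sensitivity(sources, grid=None, search_cfg: SearchConfig | None = None,
                    admixture_cfg: AdmixtureCodingConfig | None = None,
                    weight_factor: int = 1000, deactivate: bool = False,
                    universe=None) -> dict[str, CellResult]:
    """Code -> merge -> root -> weight -> search -> consensus per grid cell.

    Deterministic given the search seed: cell *i* of the grid derives its
    seed as ``search_cfg.seed + i``.
    """
    sources = list(sources)
    if grid is None:
        grid = build_parameter_grid()
    if not grid:
        raise ValidationError("empty parameter grid")
    if search_cfg is None:
        search_cfg = SearchConfig()
    base = build_merged_matrix(sources, admixture_cfg, universe)
    results: dict[str, CellResult] = {}
    for i, cell in enumerate(grid):
        try:
            rooted = apply_rooting(base, sources, cell.rooting)
            weighted = apply_weights(rooted, cell.weighting,
                                     factor=weight_factor,
                                     deactivate=deactivate)
            cfg = SearchConfig(
                n_addition_replicates=search_cfg.n_addition_replicates,
                swap=search_cfg.swap,
                ratchet_iterations=search_cfg.ratchet_iterations,
                seed=search_cfg.seed + i,
                max_trees_retained=search_cfg.max_trees_retained,
                exhaustive_limit=search_cfg.exhaustive_limit)
            res = heuristic_search(weighted, cfg)
            mp_rooted = tuple(t.root_at_leaf(OUTGROUP) for t in res.mp_trees)
            results[cell.label] = CellResult(
                cell.label, res, mp_rooted,
                strict_consensus(mp_rooted),
                semistrict_consensus(mp_rooted))
        except Exception as exc:
            raise type(exc)(f"[parameter set {cell.label}] {exc}") from exc
    return results


# ---------------------------------------------------------------------------
# wildcards

@dataclass
class WildcardRecord:
    """One pruned candidate within a single MP-tree set."""

    taxa: frozenset
    node_gain: int
    alternative_positions: tuple[tuple[str, ...], ...]


@dataclass
class WildcardReport:
    """Aggregated instability of one candidate across parameter sets."""

    taxa: frozenset
    flagged_sets: list[str] = field(default_factory=list)
    node_gain: dict[str, int] = field(default_factory=dict)
    alternative_positions: tuple[tuple[str, ...], ...] = ()
    exclusion_threshold: int = 5

    @property
    def max_gain(self) -> int:
        return max(self.node_gain.values(), default=0)

    @property
    def exclude(self) -> bool:
        return self.max_gain >= self.exclusion_threshold


def pruned_strict_consensus(trees, prune) -> Topology:
    """Strict consensus after removing ``prune`` from every input tree."""
    trees = list(trees)
    prune = frozenset(prune)
    if not trees:
        raise ValidationError("no input trees")
    remaining = trees[0].leaves - prune
    if len(remaining) < 3:
        raise ValidationError("pruning would leave fewer than 3 leaves")
    if not prune:
        return strict_consensus(trees)
    return strict_consensus([t.prune(prune) for t in trees])


def _candidates(trees) -> list[frozenset]:
    """Single taxa plus cherries appearing in at least one tree."""
    leaves = trees[0].leaves
    cands = {frozenset((t,)) for t in leaves}
    for tree in trees:
        for c in tree.clades():
            if len(c) == 2:
                cands.add(c)
    # smaller candidates first: on equal gain a single taxon is pruned in
    # preference to a cherry containing it, then lexicographic
    return sorted(cands, key=lambda c: (len(c), tuple(sorted(c))))


def _node_gain(trees, consensus_now: Topology, cand: frozenset) -> int:
    """Resolved nodes gained by pruning ``cand`` from every tree,
    relative to simply dropping it from the current strict consensus."""
    pruned_cons = strict_consensus([t.prune(cand) for t in trees])
    baseline = consensus_now.prune(cand)
    return pruned_cons.n_informative_nodes() - baseline.n_informative_nodes()


def _attachments(trees, cand: frozenset) -> tuple[tuple[str, ...], ...]:
    """Distinct sister groups of the candidate across the MP trees."""
    out = set()
    for tree in trees:
        kept = tree.leaves - cand
        # sister = smallest clade properly containing cand, minus cand
        best = None
        for c in tree.clades(include_root=True):
            if cand < c and (best is None or c < best):
                best = c
        if best is None:
            continue
        out.add(tuple(sorted((best - cand) & kept)))
    return tuple(sorted(out))


def identify_wildcards(mp_trees, min_gain: int = 1,
                       exclusion_threshold: int = 5) -> list[WildcardRecord]:
    """Greedy prune-and-measure rogue detection on one MP-tree set.

    Iteratively prunes the candidate with the largest consensus node gain
    (ties broken lexicographically) while the gain is at least ``min_gain``
    and at least 4 leaves would remain.  Returns the pruning order with the
    gain each prune realized and the alternative attachment positions of
    each pruned candidate.
    """
    trees = list(mp_trees)
    if len(trees) < 2:
        return []
    del exclusion_threshold  # the recommendation is applied downstream
    reports: list[WildcardRecord] = []
    while True:
        consensus_now = strict_consensus(trees)
        best_cand, best_gain = None, None
        for cand in _candidates(trees):
            if len(trees[0].leaves - cand) < 4:
                continue
            gain = _node_gain(trees, consensus_now, cand)
            if gain >= min_gain and (best_gain is None or gain > best_gain):
                best_cand, best_gain = cand, gain
        if best_cand is None:
            break
        reports.append(WildcardRecord(
            best_cand, best_gain, _attachments(trees, best_cand)))
        trees = [t.prune(best_cand) for t in trees]
        if len(trees) > 1 and all(t == trees[0] for t in trees):
            break
    return reports


def aggregate_wildcards(per_cell: dict[str, list[WildcardRecord]],
                        exclusion_threshold: int = 5) -> list[WildcardReport]:
    """Merge per-parameter-set wildcard records into one report per taxon."""
    by_taxa: dict[frozenset, WildcardReport] = {}
    for label in sorted(per_cell):
        for rec in per_cell[label]:
            rep = by_taxa.setdefault(
                rec.taxa, WildcardReport(rec.taxa,
                                         exclusion_threshold=exclusion_threshold))
            rep.flagged_sets.append(label)
            rep.node_gain[label] = rec.node_gain
            rep.alternative_positions = tuple(sorted(
                set(rep.alternative_positions) | set(rec.alternative_positions)))
    return sorted(by_taxa.values(), key=lambda r: tuple(sorted(r.taxa)))
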