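"""Consensus trees, tree comparison and character-fit statistics.

Consensus operations act on rooted topologies with identical leaf sets
(in the supertree pipeline the MP trees are rooted by the all-zero
outgroup).  Three flavours are provided:

* **strict** — clades present in every input;
* **semistrict** (combinable components) — clades present in at least one
  input and contradicted by none;
* **frequency difference** — clades whose frequency exceeds that of every
  incompatible rival clade.

Tree comparison offers Robinson–Foulds counts, SPR distance (exact
breadth-first search through the SPR graph for small trees, a greedy
agreement-set upper bound above that), the "anticonsensus" (clades of one
tree positively incompatible with the other) and the CI/RI character-fit
machinery used to measure how well linguistic classifications sit on a
genetic supertree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TaxonMismatchError, ValidationError
from .matrix import BinaryMatrix, STATE1
from .parsimony import char_step_bounds, fitch_score
from .trees import Topology, compatible, rf_distance


def _oriented_clades(tree: Topology) -> set[frozenset]:
    """Clades in a rooting-independent orientation.

    Rooted trees use their own clades.  Unrooted trees are oriented away
    from the lexicographically smallest leaf, so two storages of the same
    unrooted topology always yield identical sets, and clade compatibility
    on these sets coincides with split compatibility.
    """
    if tree.rooted:
        return tree.clades()
    x = min(tree.leaves)
    out = set()
    for split in tree.splits():
        side = next(s for s in split if x not in s)
        out.add(side)
    return out


def _check_same_leaves(trees) -> tuple:
    trees = tuple(trees)
    if not trees:
        raise ValidationError("no input trees")
    base = trees[0].leaves
    for t in trees[1:]:
        if t.leaves != base:
            raise TaxonMismatchError("input trees differ in leaf sets",
                                     base - t.leaves, t.leaves - base)
    return trees


# ---------------------------------------------------------------------------
# consensus

def strict_consensus(trees) -> Topology:
    """Clades present in every input tree."""
    trees = _check_same_leaves(trees)
    common = set.intersection(*(_oriented_clades(t) for t in trees))
    return Topology.from_clades(trees[0].leaves, common,
                                rooted=trees[0].rooted)


def _clade_counts(trees) -> dict[frozenset, int]:
    counts: dict[frozenset, int] = {}
    for t in trees:
        for c in _oriented_clades(t):
            counts[c] = counts.get(c, 0) + 1
    return counts


def _greedy_compatible(candidates) -> set[frozenset]:
    """Greedy mutually-compatible subset; candidates come pre-sorted."""
    chosen: set[frozenset] = set()
    for c in candidates:
        if all(compatible(c, k) for k in chosen):
            chosen.add(c)
    return chosen


def semistrict_consensus(trees) -> Topology:
    """Combinable components: clades uncontradicted by any input tree."""
    trees = _check_same_leaves(trees)
    counts = _clade_counts(trees)
    ok = [c for c in counts
          if all(all(compatible(c, k) for k in _oriented_clades(t))
                 for t in trees)]
    ok.sort(key=lambda c: (-counts[c], -len(c), tuple(sorted(c))))
    chosen = _greedy_compatible(ok)
    return Topology.from_clades(trees[0].leaves, chosen,
                                rooted=trees[0].rooted)


def frequency_difference_consensus(trees) -> Topology:
    """Clades strictly more frequent than every incompatible rival."""
    trees = _check_same_leaves(trees)
    counts = _clade_counts(trees)
    keep = []
    for c, f in counts.items():
        rivals = [g for g, fg in counts.items() if not compatible(c, g)]
        if all(counts[g] < f for g in rivals):
            keep.append(c)
    keep.sort(key=lambda c: (-counts[c], -len(c), tuple(sorted(c))))
    chosen = _greedy_compatible(keep)
    return Topology.from_clades(trees[0].leaves, chosen,
                                rooted=trees[0].rooted)


# ---------------------------------------------------------------------------
# SPR distance

@dataclass(frozen=True)
class TreeComparisonResult:
    """Distance/similarity summary of two topologies on one leaf set."""

    d_spr: int
    similarity_pct: float
    rf: int
    anticonsensus_clades: tuple[tuple[frozenset, ...], tuple[frozenset, ...]]
    approximate: bool = False


def _resolve_against(tree: Topology, other: Topology) -> Topology:
    """Refine polytomies of ``tree`` using splits of ``other`` where
    compatible, then resolve what remains deterministically (caterpillar)."""
    clades = set(tree.clades())
    for s in sorted(other.splits(),
                    key=lambda s: tuple(sorted(min(s, key=sorted)))):
        for side in sorted(s, key=lambda x: tuple(sorted(x))):
            if all(compatible(side, c) for c in clades) and \
                    2 <= len(side) <= tree.n_leaves - 2:
                clades.add(side)
                break
    t = Topology.from_clades(tree.leaves, clades, rooted=tree.rooted)
    return _resolve_arbitrary(t)


def _resolve_arbitrary(tree: Topology) -> Topology:
    """Deterministic full resolution of remaining polytomies."""

    def walk(node):
        if isinstance(node, str):
            return node
        kids = [walk(c) for c in node]
        while len(kids) > 2:
            b = kids.pop()
            a = kids.pop()
            kids.append((a, b))
        return tuple(kids)

    out = walk(tree.root)
    if not tree.rooted:
        # an unrooted tree keeps one trifurcation at the stored root
        k = tree.root
        kids = [walk(c) for c in k]
        while len(kids) > 3:
            b = kids.pop()
            a = kids.pop()
            kids.append((a, b))
        out = tuple(kids)
    return Topology(out, rooted=tree.rooted)


def _unrooted_binary_neighbors(tree: Topology):
    """All distinct trees one SPR move away (unrooted, binary)."""
    from .parsimony import _spr_neighbors, _topology_to_adj, _adj_to_topology

    taxa = tuple(sorted(tree.leaves))
    adj = _topology_to_adj(tree, taxa)
    seen = set()
    for new in _spr_neighbors(adj, len(taxa)):
        t = _adj_to_topology(new, taxa)
        if t not in seen:
            seen.add(t)
            yield t


def spr_distance_exact(t1: Topology, t2: Topology,
                       max_radius: int = 10) -> int:
    """Exact SPR distance by breadth-first search through the SPR graph."""
    t1, t2 = t1.unroot(), t2.unroot()
    if t1 == t2:
        return 0
    frontier = {t1}
    visited = {t1}
    for d in range(1, max_radius + 1):
        nxt = set()
        for t in frontier:
            for nb in _unrooted_binary_neighbors(t):
                if nb == t2:
                    return d
                if nb not in visited:
                    visited.add(nb)
                    nxt.add(nb)
        frontier = nxt
        if not frontier:
            break
    raise ValidationError("SPR search radius exhausted")


def _greedy_agreement_bound(t1: Topology, t2: Topology) -> int:
    """Upper bound on d_SPR: strip leaves greedily until the restrictions
    agree; each stripped leaf can then be regrafted with one SPR move."""
    t1, t2 = t1.unroot(), t2.unroot()
    kept = sorted(t1.leaves)
    removed = 0
    while len(kept) > 3:
        r1, r2 = t1.restrict(kept), t2.restrict(kept)
        if r1.splits() == r2.splits():
            return removed
        best_leaf, best_rf = None, None
        base = len(r1.splits() ^ r2.splits())
        for leaf in kept:
            sub = [x for x in kept if x != leaf]
            q1, q2 = t1.restrict(sub), t2.restrict(sub)
            rf = len(q1.splits() ^ q2.splits())
            if best_rf is None or rf < best_rf:
                best_leaf, best_rf = leaf, rf
        kept.remove(best_leaf)
        removed += 1
    return removed


def spr_distance(t1: Topology, t2: Topology,
                 exact_limit: int = 8) -> TreeComparisonResult:
    """SPR distance with similarity percentage and anticonsensus report.

    Exact (BFS) for up to ``exact_limit`` leaves and binary inputs; above
    that, or for unresolved inputs, a greedy agreement-set upper bound is
    returned and flagged approximate.  ``similarity_pct`` is
    ``100 * (1 - d / (n - 3))``, the fraction of possible prune-regraft
    disagreement not realized.
    """
    if t1.leaves != t2.leaves:
        raise TaxonMismatchError("leaf sets differ",
                                 t1.leaves - t2.leaves, t2.leaves - t1.leaves)
    n = len(t1.leaves)
    anti = anticonsensus(t1, t2)
    rf = rf_distance(t1.unroot(), t2.unroot())
    approximate = False
    u1, u2 = t1.unroot(), t2.unroot()
    if not (u1.is_binary() and u2.is_binary()):
        u1, u2 = _resolve_against(u1, t2), _resolve_against(u2, t1)
        approximate = True
    if u1 == u2:
        d = 0
    elif n <= exact_limit and not approximate:
        d = spr_distance_exact(u1, u2)
    else:
        d = _greedy_agreement_bound(u1, u2)
        approximate = True
    denom = max(n - 3, 1)
    sim = 100.0 * (1.0 - min(d, denom) / denom)
    return TreeComparisonResult(d, sim, rf, anti, approximate)


def anticonsensus(t1: Topology, t2: Topology):
    """Clades of each tree positively incompatible with the other tree.

    Reported in both directions; clades merely missing (but compatible,
    e.g. against a polytomy) are not counted.
    """
    if t1.leaves != t2.leaves:
        raise TaxonMismatchError("leaf sets differ",
                                 t1.leaves - t2.leaves, t2.leaves - t1.leaves)

    def against(a: Topology, b: Topology):
        bc = _oriented_clades(b)
        out = [c for c in _oriented_clades(a)
               if any(not compatible(c, k) for k in bc)]
        return tuple(sorted(out, key=lambda c: (len(c), tuple(sorted(c)))))

    return against(t1, t2), against(t2, t1)


# ---------------------------------------------------------------------------
# character fit (CI / RI)

@dataclass(frozen=True)
class CharacterFitRecord:
    """Per-character fit of a binary character on a reference tree."""

    char_id: str
    s: int               # observed steps on the tree
    m: int               # minimum possible steps
    g: int               # maximum (star-tree) steps
    ci: float            # m / s
    ri: float            # (g - s) / (g - m); NaN when g == m
    n_scored: int        # taxa scored 1
    ci_min: float        # 1 / N, the floor for a binary character

    @property
    def defined(self) -> bool:
        return self.m > 0 and self.s > 0


def character_fit(tree: Topology, matrix: BinaryMatrix):
    """CI/RI per character plus ensemble indices on a reference tree.

    Characters constant among the scored taxa get an undefined record and
    are excluded from the ensembles.  Ensemble CI = Σm/Σs and ensemble
    RI = (Σg−Σs)/(Σg−Σm) over the defined characters.
    """
    extra = set(matrix.taxa) - tree.leaves
    if extra:
        raise TaxonMismatchError("tree does not cover matrix taxa",
                                 only_right=extra)
    sub = tree.restrict(matrix.taxa) if tree.leaves - set(matrix.taxa) else tree
    unit = matrix.with_weights(np.ones(matrix.n_chars, dtype=np.int64))
    _, steps = fitch_score(sub, unit, per_character=True)
    records = []
    for j in range(matrix.n_chars):
        m, g = char_step_bounds(matrix.states[:, j])
        s = int(steps[j])
        n_scored = int((matrix.states[:, j] == STATE1).sum())
        ci = m / s if (m > 0 and s > 0) else float("nan")
        ri = (g - s) / (g - m) if g > m else float("nan")
        ci_min = 1.0 / n_scored if n_scored else float("nan")
        records.append(CharacterFitRecord(
            char_id=f"{matrix.provenance[j][0]}:{matrix.provenance[j][1]}",
            s=s, m=m, g=g, ci=ci, ri=ri, n_scored=n_scored, ci_min=ci_min))
    defined = [r for r in records if r.defined]
    sm = sum(r.m for r in defined)
    ss = sum(r.s for r in defined)
    sg = sum(r.g for r in defined)
    ensemble_ci = sm / ss if ss else float("nan")
    ensemble_ri = (sg - ss) / (sg - sm) if sg > sm else float("nan")
    return records, ensemble_ci, ensemble_ri


def tanglegram_pairing(t1: Topology, t2: Topology) -> list[tuple[str, str]]:
    """Ordered leaf pairing for an external tanglegram renderer.

    Left order follows ``t1``'s canonical traversal; each leaf pairs with
    itself on the ``t2`` side (shared taxa only).
    """
    shared = t1.leaves & t2.leaves

    def order(tree):
        out = []

        def walk(node):
            if isinstance(node, str):
                if node in shared:
                    out.append(node)
            else:
                for c in node:
                    walk(c)

        walk(tree.root)
        return out

    left = order(t1)
    return [(leaf, leaf) for leaf in left]
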