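"""Weighted Fitch parsimony scoring and maximum-parsimony tree search.

Characters are binary with missing data, so Fitch state sets fit in two
bits: ``1`` = {0}, ``2`` = {1}, ``3`` = {0, 1}.  Scoring is vectorized
across characters with numpy.  Two scorers exist:

* a fast path for fully resolved (binary) trees used inside the search,
  based on the classic Fitch intersection/union pass; and
* a Sankoff-style dynamic program used by the public :func:`fitch_score`,
  which handles hard polytomies exactly (per-state cost vectors).

The search itself is the standard parsimony workhorse: random-addition
stepwise insertion followed by hill-climbing branch swapping (NNI, SPR or
TBR), optionally with a parsimony ratchet, pooling all distinct equally
most-parsimonious trees across replicates.  An exhaustive enumerator over
all ``(2n-5)!!`` unrooted binary topologies serves as the optimality oracle
for small taxon counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SearchError, TaxonMismatchError, ValidationError
from .matrix import BinaryMatrix, STATE0, STATE1
from .trees import Topology

_BIG = np.int64(1 << 30)


@dataclass(frozen=True)
class SearchConfig:
    """Heuristic-search settings (desk-scale defaults)."""

    n_addition_replicates: int = 100
    swap: str = "tbr"
    ratchet_iterations: int = 0
    seed: int = 0
    max_trees_retained: int = 1000
    exhaustive_limit: int = 9

    def __post_init__(self):
        if self.n_addition_replicates < 1:
            raise ValidationError("need at least one addition replicate")
        if self.swap not in ("nni", "spr", "tbr"):
            raise ValidationError(f"unknown swap move {self.swap!r}")
        if self.exhaustive_limit > 10:
            raise ValidationError("exhaustive_limit above 10 is not supported")


@dataclass(frozen=True)
class SearchResult:
    """The set of equally most-parsimonious trees and its score."""

    best_score: int
    mp_trees: tuple[Topology, ...]
    evaluations: int
    exhausted: bool = False
    truncated: bool = False


# ---------------------------------------------------------------------------
# scoring

def _leaf_sets(matrix: BinaryMatrix) -> np.ndarray:
    """Per-leaf Fitch state sets, (n_taxa, n_chars) uint8 in {1, 2, 3}."""
    sets = np.full(matrix.states.shape, 3, dtype=np.uint8)
    sets[matrix.states == STATE0] = 1
    sets[matrix.states == STATE1] = 2
    return sets


def fitch_score(tree: Topology, matrix: BinaryMatrix,
                per_character: bool = False):
    """Weighted parsimony score of a (possibly polytomous) tree.

    ``?`` and ``-`` are both fully missing.  Polytomies are hard: the score
    is the minimum over ancestral assignments of the given multifurcating
    tree, not over its resolutions.  The score is a property of the
    unrooted shape, so rooted and unrooted versions of a tree agree.
    """
    if tree.leaves != frozenset(matrix.taxa):
        raise TaxonMismatchError("tree leaves != matrix taxa",
                                 tree.leaves - set(matrix.taxa),
                                 set(matrix.taxa) - tree.leaves)
    n_chars = matrix.n_chars
    if n_chars == 0:
        return (0, np.zeros(0, dtype=np.int64)) if per_character else 0
    pos = {t: i for i, t in enumerate(matrix.taxa)}
    observed = matrix.states >= 0
    cost = np.zeros((2, n_chars), dtype=np.int64)

    def down(node):
        # returns (cost0, cost1) vectors for the subtree
        if isinstance(node, str):
            i = pos[node]
            c0 = np.where(observed[i] & (matrix.states[i] != STATE0), _BIG, 0)
            c1 = np.where(observed[i] & (matrix.states[i] != STATE1), _BIG, 0)
            return c0.astype(np.int64), c1.astype(np.int64)
        t0 = np.zeros(n_chars, dtype=np.int64)
        t1 = np.zeros(n_chars, dtype=np.int64)
        for child in node:
            c0, c1 = down(child)
            t0 += np.minimum(c0, c1 + 1)
            t1 += np.minimum(c1, c0 + 1)
        return t0, t1

    root = tree.root
    if isinstance(root, str):  # single leaf
        steps = np.zeros(n_chars, dtype=np.int64)
    else:
        c0, c1 = down(root)
        steps = np.minimum(c0, c1)
    total = int(steps @ matrix.weights)
    if per_character:
        return total, steps
    return total


def soft_fitch_binary(tree: Topology, states: dict[str, int],
                      root_state: int | None = None) -> int:
    """Minimum steps of one binary character over all resolutions.

    Polytomies are soft: the program minimizes the step count over every
    binary refinement of each multifurcation.  ``states`` maps leaf to
    0/1/-1 (missing); ``root_state`` optionally forces the root.
    Used by the monophyly/paraphyly status call.
    """
    BIG = 1 << 30

    def down(node):
        if isinstance(node, str):
            s = states.get(node, -1)
            if s == 0:
                return (0, BIG)
            if s == 1:
                return (BIG, 0)
            return (0, 0)
        costs = [down(c) for c in node]
        out = []
        for s in (0, 1):
            direct = sum(min(c[s], BIG) for c in costs)
            mins = sum(min(c) for c in costs)
            compat = [c[s] == min(c) for c in costs]
            if all(compat):
                grouped = mins
            elif any(compat):
                # bundle every opposite-preferring child under one new edge
                grouped = mins + 1
            else:
                grouped = mins + 2
            out.append(min(direct, grouped, BIG))
        return tuple(out)

    if isinstance(tree.root, str):
        return 0
    c0, c1 = down(tree.root)
    if root_state is None:
        return min(c0, c1)
    return (c0, c1)[root_state]


def char_step_bounds(states_column) -> tuple[int, int]:
    """(m, g): minimum and maximum steps of one binary character.

    m = 1 for any character with both observed states, g = the count of the
    rarer observed state (its steps on the star tree); constant characters
    give (0, 0).  Missing entries are excluded throughout.
    """
    col = np.asarray(states_column)
    ones = int((col == STATE1).sum())
    zeros = int((col == STATE0).sum())
    if ones == 0 or zeros == 0:
        return (0, 0)
    return (1, min(ones, zeros))


# ---------------------------------------------------------------------------
# fast scoring machinery for binary search trees

class _Engine:
    """Matrix prepared for repeated scoring of binary trees.

    Only active (weight > 0) parsimony-informative characters enter the hot
    loop; uninformative active characters contribute a constant offset
    (their minimum steps are attained on every topology).
    """

    def __init__(self, matrix: BinaryMatrix):
        self.matrix = matrix
        self.taxa = matrix.taxa
        self.n = len(self.taxa)
        active = matrix.active_mask()
        informative = matrix.informative_mask()
        hot = active & informative
        self.hot = matrix.select_chars(hot)
        offset = 0
        for j in np.flatnonzero(active & ~informative):
            m, _ = char_step_bounds(matrix.states[:, j])
            offset += int(m) * int(matrix.weights[j])
        self.offset = offset
        self.leaf_sets = _leaf_sets(self.hot)
        self.weights = self.hot.weights
        self.n_hot = self.hot.n_chars
        self.evaluations = 0

    def score_adj(self, adj: list[list[int]]) -> int:
        """Score an unrooted binary tree given as an adjacency list.

        Nodes 0..n-1 are leaves in matrix taxon order; internal nodes have
        degree 3.  Scored by rooting at leaf 0.
        """
        self.evaluations += 1
        if self.n_hot == 0:
            return self.offset
        n = self.n
        # iterative postorder rooted at the first attached leaf (partial
        # trees during stepwise addition need not contain leaf 0)
        root = next(i for i in range(n) if adj[i])
        start = adj[root][0]
        order: list[tuple[int, int]] = []  # (node, parent)
        stack = [(start, root)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            if node >= n:
                for nb in adj[node]:
                    if nb != parent:
                        stack.append((nb, node))
        sets: dict[int, np.ndarray] = {}
        steps = 0
        for node, parent in reversed(order):
            if node < n:
                sets[node] = self.leaf_sets[node]
                continue
            kids = [nb for nb in adj[node] if nb != parent]
            a, b = sets[kids[0]], sets[kids[1]]
            inter = a & b
            zero = inter == 0
            if zero.any():
                steps += int(self.weights[zero].sum())
                sets[node] = np.where(zero, a | b, inter)
            else:
                sets[node] = inter
        top = sets[start]
        zero = (top & self.leaf_sets[root]) == 0
        if zero.any():
            steps += int(self.weights[zero].sum())
        return steps + self.offset


# ---------------------------------------------------------------------------
# adjacency-tree helpers

def _initial_adj(n: int, first3) -> tuple[list[list[int]], int]:
    """Unrooted tree on three leaves: one internal hub node."""
    hub = n
    adj: list[list[int]] = [[] for _ in range(2 * n - 2)]
    adj[hub] = list(first3)
    for leaf in first3:
        adj[leaf] = [hub]
    return adj, n + 1


def _edges(adj) -> list[tuple[int, int]]:
    out = []
    for u, nbs in enumerate(adj):
        for v in nbs:
            if u < v:
                out.append((u, v))
    return out


def _attach(adj, next_node, leaf, edge):
    """Insert ``leaf`` on ``edge`` using a fresh internal node (in place)."""
    u, v = edge
    w = next_node
    adj[u][adj[u].index(v)] = w
    adj[v][adj[v].index(u)] = w
    adj[w] = [u, v, leaf]
    adj[leaf] = [w]


def _detach(adj, leaf):
    """Undo `_attach`: remove leaf and splice its hub out (in place)."""
    (w,) = adj[leaf]
    u, v = (x for x in adj[w] if x != leaf)
    adj[u][adj[u].index(w)] = v
    adj[v][adj[v].index(w)] = u
    adj[w] = []
    adj[leaf] = []
    return w


def _copy(adj):
    return [list(x) for x in adj]


def _subtree_nodes(adj, root, avoid) -> set[int]:
    seen = {root}
    stack = [root]
    while stack:
        x = stack.pop()
        for nb in adj[x]:
            if nb != avoid and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return seen


def _splits_key(adj, n) -> frozenset:
    """Canonical identity of an unrooted binary tree over leaves 0..n-1."""
    key = set()
    for u, v in _edges(adj):
        if u < n or v < n:
            continue
        side = frozenset(x for x in _subtree_nodes(adj, v, u) if x < n)
        if 0 in side:
            side = frozenset(range(n)) - side
        key.add(side)
    return frozenset(key)


def _adj_to_topology(adj, taxa) -> Topology:
    n = len(taxa)

    def build(node, parent):
        if node < n:
            return taxa[node]
        return tuple(build(nb, node) for nb in adj[node] if nb != parent)

    hub = adj[0][0]
    kids = [build(nb, hub) for nb in adj[hub] if nb != 0]
    return Topology(tuple(kids) + (taxa[0],), rooted=False)


def _topology_to_adj(tree: Topology, taxa) -> list[list[int]]:
    pos = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    tree = tree.unroot()
    adj: list[list[int]] = [[] for _ in range(2 * n - 2)]
    counter = [n]

    def walk(node):
        if isinstance(node, str):
            return pos[node]
        nid = counter[0]
        counter[0] += 1
        for c in node:
            cid = walk(c)
            adj[nid].append(cid)
            adj[cid].append(nid)
        return nid

    root = tree.root
    if isinstance(root, str) or len(root) < 3:
        raise SearchError("tree must be unrooted binary with >= 4 leaves")
    rid = walk(root)
    # root of an unrooted binary tree has 3 children and no parent: done
    if any(len(adj[i]) not in (0, 1, 3) for i in range(len(adj))):
        raise SearchError("tree is not fully resolved (binary)")
    return adj


# ---------------------------------------------------------------------------
# neighborhoods

def _nni_neighbors(adj, n):
    """Yield adjacency copies one NNI away (internal edges only)."""
    for u, v in _edges(adj):
        if u < n or v < n:
            continue
        u_nbs = [x for x in adj[u] if x != v]
        v_nbs = [x for x in adj[v] if x != u]
        # two of the four swaps are distinct; the others are mirror images
        for a in u_nbs[:1]:
            for b in v_nbs:
                new = _copy(adj)
                new[u][new[u].index(a)] = b
                new[v][new[v].index(b)] = a
                new[a][new[a].index(u)] = v
                new[b][new[b].index(v)] = u
                yield new


def _prune_candidates(adj, n):
    """Directed prune edges (anchor, subroot): the subtree on the subroot
    side is detached, the anchor (always internal) is spliced out."""
    for a, b in _edges(adj):
        for anchor, subroot in ((a, b), (b, a)):
            if anchor < n:
                continue  # anchor must be internal to be spliced
            sub = _subtree_nodes(adj, subroot, anchor)
            if sum(1 for x in sub if x < n) > n - 2:
                continue  # fewer than two leaves would remain
            yield anchor, subroot, sub


def _spr_apply(adj, anchor, subroot, target_edge):
    """Regraft the subtree at ``subroot`` (cut from ``anchor``) onto
    ``target_edge``, reusing the anchor as the new hub."""
    new = _copy(adj)
    a, b = (x for x in new[anchor] if x != subroot)
    new[a][new[a].index(anchor)] = b
    new[b][new[b].index(anchor)] = a
    x, y = target_edge
    new[x][new[x].index(y)] = anchor
    new[y][new[y].index(x)] = anchor
    new[anchor] = [x, y, subroot]
    return new


def _spr_neighbors(adj, n):
    for anchor, subroot, sub in _prune_candidates(adj, n):
        for x, y in _edges(adj):
            if x in sub or y in sub or anchor in (x, y):
                continue
            yield _spr_apply(adj, anchor, subroot, (x, y))


def _tbr_neighbors(adj, n):
    """Tree bisection and reconnection.

    Cut an edge, re-root the detached part at any of its edges, and regraft
    onto every edge of the remainder.  Plain SPR moves (original attachment
    point kept) are the first block yielded for each cut.
    """
    for anchor, subroot, sub in _prune_candidates(adj, n):
        rest_edges = [(x, y) for x, y in _edges(adj)
                      if x not in sub and y not in sub
                      and anchor not in (x, y)]
        for edge in rest_edges:  # handle = subroot itself: pure SPR
            yield _spr_apply(adj, anchor, subroot, edge)
        if subroot < n:
            continue  # a detached leaf has no alternative rootings
        # splice both incident hubs out: 'work' holds the bisected forest
        work = _copy(adj)
        a, b = (t for t in work[anchor] if t != subroot)
        work[a][work[a].index(anchor)] = b
        work[b][work[b].index(anchor)] = a
        work[anchor] = []
        c, d = (t for t in work[subroot] if t != anchor)
        work[c][work[c].index(subroot)] = d
        work[d][work[d].index(subroot)] = c
        work[subroot] = []
        sub2 = sub - {subroot}
        spr_handle = (min(c, d), max(c, d))
        for p, q in _edges(work):
            if p not in sub2 or q not in sub2 or (p, q) == spr_handle:
                continue  # not a detached-part edge, or the SPR case again
            for x, y in rest_edges:
                new = _copy(work)
                new[p][new[p].index(q)] = subroot
                new[q][new[q].index(p)] = subroot
                new[subroot] = [p, q, anchor]
                new[x][new[x].index(y)] = anchor
                new[y][new[y].index(x)] = anchor
                new[anchor] = [x, y, subroot]
                yield new


_MOVES = {"nni": _nni_neighbors, "spr": _spr_neighbors, "tbr": _tbr_neighbors}


# ---------------------------------------------------------------------------
# searches

def exhaustive_search(matrix: BinaryMatrix,
                      exhaustive_limit: int = 9) -> SearchResult:
    """Score every unrooted binary topology; exact MP set for small n."""
    n = matrix.n_taxa
    if n > exhaustive_limit:
        raise SearchError(
            f"{n} taxa exceeds the exhaustive limit of {exhaustive_limit}")
    if n < 3:
        raise SearchError("need at least 3 taxa")
    eng = _Engine(matrix)
    best = None
    best_trees: list = []

    def recurse(adj, next_node, next_leaf):
        nonlocal best, best_trees
        if next_leaf == n:
            s = eng.score_adj(adj)
            if best is None or s < best:
                best = s
                best_trees = [_copy(adj)]
            elif s == best:
                best_trees.append(_copy(adj))
            return
        for edge in _edges(adj):  # snapshot; attach/detach backtracks in place
            _attach(adj, next_node, next_leaf, edge)
            recurse(adj, next_node + 1, next_leaf + 1)
            _detach(adj, next_leaf)

    adj, nxt = _initial_adj(n, (0, 1, 2))
    recurse(adj, nxt, 3)
    trees = tuple(_adj_to_topology(a, matrix.taxa) for a in best_trees)
    # distinct by construction (each enumerated shape appears once)
    return SearchResult(best, trees, eng.evaluations, exhausted=True)


def _stepwise_addition(eng: _Engine, order, rng) -> list[list[int]]:
    n = eng.n
    adj, nxt = _initial_adj(n, tuple(order[:3]))
    # remap: internal nodes are allocated from n upward regardless of order
    next_internal = n + 1
    for leaf in order[3:]:
        best_s = None
        best_edges = []
        for edge in _edges(adj):
            _attach(adj, next_internal, leaf, edge)
            s = eng.score_adj(adj)
            _detach(adj, leaf)
            if best_s is None or s < best_s:
                best_s, best_edges = s, [edge]
            elif s == best_s:
                best_edges.append(edge)
        pick = best_edges[rng.integers(len(best_edges))]
        _attach(adj, next_internal, leaf, pick)
        next_internal += 1
    return adj


def _swap_to_optimum(eng, adj, moves):
    current = eng.score_adj(adj)
    improved = True
    while improved:
        improved = False
        for new in moves(adj, eng.n):
            s = eng.score_adj(new)
            if s < current:
                adj, current = new, s
                improved = True
                break
    return adj, current


def _plateau(eng, adj, score, moves, seen, pool, budget):
    """Collect equal-score neighbors breadth-first (the full MP plateau)."""
    queue = [adj]
    truncated = False
    while queue:
        cur = queue.pop()
        for new in moves(cur, eng.n):
            if len(pool) >= budget:
                return True
            s = eng.score_adj(new)
            if s == score:
                k = _splits_key(new, eng.n)
                if k not in seen:
                    seen.add(k)
                    pool[k] = new
                    queue.append(new)
    return truncated


def heuristic_search(matrix: BinaryMatrix,
                     cfg: SearchConfig = SearchConfig()) -> SearchResult:
    """Random-addition + branch-swapping MP search, deterministic per seed."""
    n = matrix.n_taxa
    if n < 4:
        raise SearchError("heuristic search needs at least 4 taxa")
    eng = _Engine(matrix)
    rng = np.random.default_rng(cfg.seed)
    moves = _MOVES[cfg.swap]

    best_score = None
    pool: dict[frozenset, list] = {}
    truncated = False
    for rep in range(cfg.n_addition_replicates):
        order = list(rng.permutation(n))
        adj = _stepwise_addition(eng, order, rng)
        adj, score = _swap_to_optimum(eng, adj, moves)

        for _ in range(cfg.ratchet_iterations):
            # perturb: upweight a random quarter of the hot characters
            saved = eng.weights
            mask = rng.random(eng.n_hot) < 0.25
            eng.weights = saved + saved * (3 * mask)
            p_adj, _ = _swap_to_optimum(eng, _copy(adj), moves)
            eng.weights = saved
            p_adj, p_score = _swap_to_optimum(eng, p_adj, moves)
            if p_score <= score:
                adj, score = p_adj, p_score

        if best_score is None or score < best_score:
            best_score = score
            pool = {}
        if score == best_score:
            k = _splits_key(adj, n)
            if k not in pool:
                pool[k] = adj
    # explore the equal-score plateau around the found optima
    seen = set(pool)
    for adj in list(pool.values()):
        if len(pool) >= cfg.max_trees_retained:
            truncated = True
            break
        if _plateau(eng, adj, best_score, moves, seen, pool,
                    cfg.max_trees_retained):
            truncated = True
            break
    trees = tuple(sorted((_adj_to_topology(a, matrix.taxa)
                          for a in pool.values()),
                         key=lambda t: t.to_newick()))
    return SearchResult(best_score, trees, eng.evaluations,
                        exhausted=False, truncated=truncated)


def score_topology(tree: Topology, matrix: BinaryMatrix) -> int:
    """Alias of :func:`fitch_score` kept for symmetry with search results."""
    return fitch_score(tree, matrix)
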