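"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, explicit
ancestral-state assignment) so they stay independent of the vectorized
implementations they check.
"""

import itertools

import numpy as np
import pytest

from mrpforge.trees import Topology


def random_binary_tree(labels, rng) -> Topology:
    """Uniform random rooted binary tree by random pair joining."""
    nodes = list(labels)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append((a, b))
    return Topology(tuple(nodes), rooted=True)


def brute_force_steps(tree: Topology, states: dict) -> int:
    """Minimum state changes by enumerating every ancestral assignment.

    ``states`` maps leaf -> 0 / 1 / None (missing, free to take any state).
    Exponential; intended for <= ~8 internal nodes.
    """
    nodes = []       # internal node ids in postorder
    edges = []       # (parent_id, child_id or leaf label)
    counter = itertools.count()

    def walk(node):
        if isinstance(node, str):
            return node
        nid = next(counter)
        for c in node:
            edges.append((nid, walk(c)))
        nodes.append(nid)
        return nid

    root = walk(tree.root)
    if isinstance(root, str):
        return 0
    free_leaves = [l for l, s in states.items() if s is None]
    best = None
    for assign in itertools.product((0, 1), repeat=len(nodes) + len(free_leaves)):
        value = dict(zip(nodes, assign))
        value.update(zip(free_leaves, assign[len(nodes):]))
        for leaf, s in states.items():
            if s is not None:
                value[leaf] = s
        changes = sum(1 for p, c in edges if value[p] != value[c])
        if best is None or changes < best:
            best = changes
    return best


def all_unrooted_topologies(labels) -> list[Topology]:
    """Every distinct unrooted binary topology, by recursive edge addition."""
    labels = list(labels)
    out = []

    def expand(tree, remaining):
        if not remaining:
            out.append(Topology(tree, rooted=False))
            return
        leaf = remaining[0]
        for new in _insert_everywhere(tree, leaf):
            expand(new, remaining[1:])

    base = (labels[0], labels[1], labels[2])
    expand(base, labels[3:])
    return out


def _insert_everywhere(node, leaf, at_root=True):
    """All trees obtained by attaching ``leaf`` onto one edge of ``node``."""
    results = []
    if isinstance(node, tuple):
        kids = list(node)
        for i, k in enumerate(kids):
            # attach on the edge above child i
            results.append(tuple(kids[:i] + [(k, leaf)] + kids[i + 1:]))
            # or deeper inside child i
            for sub in _insert_everywhere(k, leaf, at_root=False):
                results.append(tuple(kids[:i] + [sub] + kids[i + 1:]))
    return results


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
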