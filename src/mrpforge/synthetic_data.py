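"""Ground-truth scenario generation.

The study design this package targets rests on hundreds of published
population trees and admixture plots; a compiled collection of that kind
cannot ship with a software artifact, so every pipeline stage is exercised
on synthetic scenarios with a known true phylogeny instead.  A scenario
consists of

* a Yule (uniform random-split) rooted binary **true tree** over populations
  ``P001``, ``P002``, ...;
* **source trees**: partial taxon subsamples of the truth with a chosen
  number of random NNI perturbations, tagged with a data partition and
  rooted/unrooted status (topological noise, not branch-length noise — the
  method consumes topologies only);
* **admixture plots**: Q-matrices built by cutting the true tree into K
  clades and drawing each population's membership row from a Dirichlet
  centred on its clade indicator (large concentration = crisp plot), with
  optional deliberately admixed populations mixing two clusters 50/50;
* a **linguistic classification** assigning families to clades of the
  truth, with a configurable fraction of taxa reassigned to wrong families
  (gene-language discordance) and optional ``?``-scored language-shift
  taxa;
* optional **planted rogues**: taxa reattached at a random position in
  every source tree that samples them, so their placement carries no
  consistent signal.

Every generator takes a seed and the scenario records a manifest from
which it can be regenerated bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .matrix import BinaryMatrix
from .treeio import QMatrix, SourceRecord, classification_matrix
from .trees import Topology

#: Default partition census for a 40-source scenario, mirroring a dataset
#: dominated by genetic trees with a modest admixture-plot component
#: (~15%) and a minority of language trees.
DEFAULT_PARTITION_CENSUS = {
    "genomic_tree": 6,
    "autosomal_tree": 6,
    "y_tree": 6,
    "mtdna_tree": 6,
    "hla_tree": 5,
    "classical_tree": 2,
    "language_tree": 3,
    "admixture_genomic": 5,
    "admixture_linguistic": 1,
}

#: Partitions whose sources are customarily published rooted (uniparental
#: and genomic trees); others are rooted with probability ~1/2.
_MOSTLY_ROOTED = {"y_tree", "mtdna_tree", "genomic_tree"}


def generate_true_tree(n_taxa: int, seed: int) -> Topology:
    """Yule rooted binary tree with leaves ``P001`` ... ``P<n>``."""
    if n_taxa < 4:
        raise ValidationError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"P{i + 1:03d}" for i in range(n_taxa)]
    rng.shuffle(labels)
    tips: list = [labels[0], labels[1]]
    for label in labels[2:]:
        i = int(rng.integers(len(tips)))
        tips.append((tips[i], label))
        tips[i] = tips[-1]
        tips.pop()
    # tips now holds the two root children
    return Topology(tuple(tips), rooted=True)


def _random_nni(tree: Topology, rng) -> Topology:
    """One random NNI on an internal (unrooted-sense) edge of a rooted tree.

    A rooted tree whose root has two children exposes the edge between them
    as one unrooted-internal edge; an NNI across it swaps a grandchild from
    each side, keeping the root in place.  Every move changes exactly one
    split (unrooted RF distance 2).
    """
    nodes: dict[int, list | str] = {}
    parent: dict[int, int] = {}
    counter = [0]

    def build(node):
        nid = counter[0]
        counter[0] += 1
        if isinstance(node, str):
            nodes[nid] = node
        else:
            kids = [build(c) for c in node]
            nodes[nid] = kids
            for k in kids:
                parent[k] = nid
        return nid

    rid = build(tree.root)
    ops = []
    for v, val in nodes.items():
        if not isinstance(val, list) or v == rid:
            continue
        u = parent[v]
        if u == rid and len(nodes[rid]) == 2:
            w = next(x for x in nodes[rid] if x != v)
            if isinstance(nodes[w], list) and w > v:
                ops.append(("root", v, w))
        else:
            ops.append(("edge", u, v))
    if not ops:
        return tree
    kind, u, v = ops[int(rng.integers(len(ops)))]
    if kind == "root":  # u, v are the two root children, both internal
        a = nodes[u][int(rng.integers(len(nodes[u])))]
        b = nodes[v][int(rng.integers(len(nodes[v])))]
        nodes[u][nodes[u].index(a)] = b
        nodes[v][nodes[v].index(b)] = a
    else:               # swap a sibling of v with a child of v
        sibs = [k for k in nodes[u] if k != v]
        s = sibs[int(rng.integers(len(sibs)))]
        a = nodes[v][int(rng.integers(len(nodes[v])))]
        nodes[u][nodes[u].index(s)] = a
        nodes[v][nodes[v].index(a)] = s

    def render(nid):
        val = nodes[nid]
        if isinstance(val, str):
            return val
        return tuple(render(k) for k in val)

    return Topology(render(rid), rooted=True)


def _leaves_of(node):
    if isinstance(node, str):
        return [node]
    out = []
    for c in node:
        out.extend(_leaves_of(c))
    return out


def sample_source_tree(true_tree: Topology, keep_fraction: float, n_nni: int,
                       partition: str, rooted: bool, seed: int,
                       source_id: str | None = None,
                       has_hominin_outgroup: bool = False,
                       reattach_taxa=()) -> SourceRecord:
    """A partial, perturbed view of the truth as one source record.

    ``reattach_taxa`` (planted rogues) are moved to a random position after
    the NNI perturbations, destroying any consistent signal about them.
    """
    if not 0 < keep_fraction <= 1:
        raise ValidationError("keep_fraction must lie in (0, 1]")
    if n_nni < 0:
        raise ValidationError("n_nni must be non-negative")
    rng = np.random.default_rng(seed)
    leaves = sorted(true_tree.leaves)
    k = max(4, int(round(keep_fraction * len(leaves))))
    if k > len(leaves):
        raise ValidationError("keep_fraction yields more taxa than available")
    subset = sorted(str(x) for x in rng.choice(leaves, size=k, replace=False))
    tree = true_tree.restrict(subset)
    for _ in range(n_nni):
        tree = _random_nni(tree, rng)
    for rogue in sorted(set(reattach_taxa) & tree.leaves):
        if tree.n_leaves < 5:
            break
        tree = _reattach_randomly(tree, rogue, rng)
    if not rooted:
        tree = tree.unroot()
    return SourceRecord(
        source_id=source_id or f"{partition}_{seed}",
        kind="tree", partition=partition, rooted=rooted,
        has_hominin_outgroup=has_hominin_outgroup, tree=tree)


def _reattach_randomly(tree: Topology, taxon: str, rng) -> Topology:
    """Prune one leaf and regraft it onto a random clade (rooted SPR)."""
    rest = tree.prune({taxon})
    targets = sorted(rest.clades(include_root=True),
                     key=lambda c: tuple(sorted(c)))
    target = targets[int(rng.integers(len(targets)))]

    def insert(node):
        if isinstance(node, str):
            if frozenset((node,)) == target:
                return (node, taxon)
            return node
        if frozenset(_leaves_of(node)) == target:
            return (node, taxon)
        return tuple(insert(k) for k in node)

    # also allow attachment to single leaves
    singles = sorted(rest.leaves)
    if int(rng.integers(2)):
        target = frozenset((singles[int(rng.integers(len(singles)))],))
    return Topology(insert(rest.root), rooted=tree.rooted)


def _k_cut(tree: Topology, k: int) -> list[frozenset]:
    """Cut the rooted tree into K leaf-disjoint clades (split largest first)."""
    parts: list[frozenset] = [tree.leaves]
    child_map = {}

    def walk(node):
        if isinstance(node, str):
            return frozenset((node,))
        kids = [walk(c) for c in node]
        here = frozenset().union(*kids)
        child_map[here] = kids
        return here

    walk(tree.root)
    while len(parts) < k:
        big = max((p for p in parts if p in child_map),
                  key=lambda p: (len(p), tuple(sorted(p))), default=None)
        if big is None:
            raise ValidationError(f"cannot cut tree into {k} clades")
        parts.remove(big)
        parts.extend(child_map[big])
    return sorted(parts, key=lambda p: tuple(sorted(p)))


def generate_admixture_plot(true_tree: Topology, k: int, alpha: float,
                            admixed_taxa=(), seed: int = 0,
                            source_id: str | None = None,
                            partition: str = "admixture_genomic",
                            keep_fraction: float = 1.0) -> SourceRecord:
    """A Q-matrix whose clusters mirror a K-clade cut of the true tree.

    Each taxon's row is Dirichlet with concentration ``alpha`` centred on
    its clade indicator (weight 1 - eps on its own cluster); taxa in
    ``admixed_taxa`` are centred on a 50/50 mixture of their own and one
    other cluster.
    """
    if k < 2:
        raise ValidationError("K must be at least 2")
    rng = np.random.default_rng(seed)
    parts = _k_cut(true_tree, k)
    leaves = sorted(true_tree.leaves)
    n_keep = max(4, int(round(keep_fraction * len(leaves))))
    taxa = sorted(str(x) for x in rng.choice(leaves, size=n_keep,
                                             replace=False)) \
        if n_keep < len(leaves) else leaves
    eps = 0.02
    rows = []
    for t in taxa:
        own = next(i for i, p in enumerate(parts) if t in p)
        centre = np.full(k, eps / (k - 1))
        if t in admixed_taxa:
            other = int((own + 1 + rng.integers(k - 1)) % k)
            centre[:] = eps / max(k - 2, 1)
            centre[own] = centre[other] = (1 - eps) / 2
            if k == 2:
                centre = np.array([0.5, 0.5])
        else:
            centre[own] = 1 - eps
        rows.append(rng.dirichlet(alpha * centre))
    q = QMatrix(tuple(taxa), np.array(rows))
    return SourceRecord(
        source_id=source_id or f"{partition}_{seed}", kind="admixture",
        partition=partition, rooted=False, qmatrix=q)


def generate_classification(true_tree: Topology, n_families: int,
                            misfit_rate: float, unknown_taxa=(),
                            seed: int = 0):
    """Family labels as clades of the truth, with planted discordance.

    Returns ``(classification dict, BinaryMatrix)``; a ``misfit_rate``
    fraction of classifiable taxa is reassigned to a wrong family and
    ``unknown_taxa`` are scored ``?`` in every family character.
    """
    if n_families < 2:
        raise ValidationError("need at least 2 families")
    if not 0 <= misfit_rate < 1:
        raise ValidationError("misfit_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    parts = _k_cut(true_tree, n_families)
    names = [f"FAM{i + 1:02d}" for i in range(len(parts))]
    classification = {}
    for name, part in zip(names, parts):
        for t in sorted(part):
            classification[t] = name
    movable = sorted(set(classification) - set(unknown_taxa))
    n_move = int(round(misfit_rate * len(movable)))
    for t in rng.choice(movable, size=n_move, replace=False):
        wrong = [nm for nm in names if nm != classification[t]]
        classification[t] = wrong[int(rng.integers(len(wrong)))]
    for t in unknown_taxa:
        classification[t] = "?"
    matrix = classification_matrix(classification, sorted(true_tree.leaves))
    return classification, matrix


@dataclass
class SyntheticScenario:
    """A full generated study: truth, sources, classification, manifest."""

    true_tree: Topology
    sources: list[SourceRecord]
    classification: dict[str, str]
    classification_matrix: BinaryMatrix
    planted_rogues: frozenset
    planted_admixed: frozenset
    seed: int
    manifest: dict = field(default_factory=dict)


def generate_scenario(n_taxa: int = 30, seed: int = 0,
                      partition_census: dict | None = None,
                      keep_fraction: float = 0.5, n_nni: int = 1,
                      alpha: float = 200.0, admixture_k: int = 4,
                      n_rogues: int = 0, n_admixed: int = 2,
                      n_families: int = 4, misfit_rate: float = 0.0,
                      n_unknown: int = 0,
                      outgroup_fraction: float = 0.3) -> SyntheticScenario:
    """Generate a complete scenario; regenerable from its manifest."""
    census = dict(partition_census or DEFAULT_PARTITION_CENSUS)
    manifest = dict(n_taxa=n_taxa, seed=seed, partition_census=census,
                    keep_fraction=keep_fraction, n_nni=n_nni, alpha=alpha,
                    admixture_k=admixture_k, n_rogues=n_rogues,
                    n_admixed=n_admixed, n_families=n_families,
                    misfit_rate=misfit_rate, n_unknown=n_unknown,
                    outgroup_fraction=outgroup_fraction)
    rng = np.random.default_rng(seed)
    truth = generate_true_tree(n_taxa, seed)
    leaves = sorted(truth.leaves)
    def pick(pool, size):
        if not size:
            return frozenset()
        return frozenset(str(x) for x in rng.choice(pool, size=size,
                                                    replace=False))

    rogues = pick(leaves, n_rogues)
    non_rogue = sorted(set(leaves) - rogues)
    admixed = pick(non_rogue, n_admixed)
    unknown = pick(non_rogue, n_unknown)

    sources: list[SourceRecord] = []
    idx = 0
    for partition in sorted(census):
        for j in range(census[partition]):
            sub_seed = int(rng.integers(2 ** 31 - 1))
            if partition.startswith("admixture"):
                k = int(min(admixture_k, max(2, 2 + j % (admixture_k - 1))))
                sources.append(generate_admixture_plot(
                    truth, k=k, alpha=alpha, admixed_taxa=admixed,
                    seed=sub_seed, source_id=f"S{idx:03d}_{partition}",
                    partition=partition, keep_fraction=max(keep_fraction, 0.5)))
            else:
                if partition in _MOSTLY_ROOTED:
                    rooted = True
                else:
                    rooted = bool(rng.random() < 0.5)
                has_out = rooted and bool(rng.random() < outgroup_fraction)
                sources.append(sample_source_tree(
                    truth, keep_fraction=keep_fraction, n_nni=n_nni,
                    partition=partition, rooted=rooted, seed=sub_seed,
                    source_id=f"S{idx:03d}_{partition}",
                    has_hominin_outgroup=has_out,
                    reattach_taxa=rogues))
            idx += 1

    cls_seed = int(rng.integers(2 ** 31 - 1))
    classification, cmatrix = generate_classification(
        truth, n_families=n_families, misfit_rate=misfit_rate,
        unknown_taxa=unknown, seed=cls_seed)
    return SyntheticScenario(truth, sources, classification, cmatrix,
                             rogues, admixed, seed, manifest)


def regenerate(manifest: dict) -> SyntheticScenario:
    """Rebuild a scenario bit-identically from its manifest."""
    return generate_scenario(**manifest)
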