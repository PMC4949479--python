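"""Topology-only phylogenetic trees.

The whole pipeline is purely topological: source trees contribute clade
membership and nothing else, so branch lengths and support values are parsed
but never stored.  A :class:`Topology` is an immutable nested-tuple tree over
string leaf labels, with a ``rooted`` flag that switches the semantics of
equality and comparison between clade sets (rooted) and bipartition/split
sets (unrooted).

Polytomies are first-class: a node may have any number of children.  All
constructors normalize child order (sorted by smallest contained leaf), so a
given clade structure has exactly one nested-tuple form and topologies are
hashable and directly comparable.
"""

from __future__ import annotations

from collections.abc import Iterable

import dendropy

from .errors import NewickParseError, ValidationError

#: A tree node: either a leaf label or a tuple of child nodes.
Node = "str | tuple"


def _min_leaf(node) -> str:
    while not isinstance(node, str):
        node = node[0]
    return node


def _normalize(node):
    if isinstance(node, str):
        return node
    children = tuple(sorted((_normalize(c) for c in node), key=_min_leaf))
    if len(children) == 1:  # suppress unary nodes
        return children[0]
    return children


def _collect_leaves(node, out: list):
    if isinstance(node, str):
        out.append(node)
    else:
        for c in node:
            _collect_leaves(c, out)


class Topology:
    """An immutable rooted or unrooted tree topology over labelled leaves."""

    __slots__ = ("root", "rooted", "_leaves", "_key", "_hash")

    def __init__(self, root, rooted: bool = True):
        root = _normalize(root)
        if not rooted:
            root = _unroot_root(root)
        self.root = root
        self.rooted = bool(rooted)
        leaves: list[str] = []
        _collect_leaves(root, leaves)
        if len(set(leaves)) != len(leaves):
            dups = sorted({x for x in leaves if leaves.count(x) > 1})
            raise ValidationError(f"duplicate leaf labels: {dups}")
        if not leaves:
            raise ValidationError("empty tree")
        self._leaves = frozenset(leaves)
        self._key = None
        self._hash = None

    # -- basic accessors ---------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        return self._leaves

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def clades(self, include_root: bool = False) -> set[frozenset]:
        """Leaf sets of internal (non-leaf, non-singleton) nodes.

        For a rooted tree these are the clades; for an unrooted tree they are
        one side of each split relative to the arbitrary stored orientation.
        """
        out: set[frozenset] = set()

        def walk(node) -> frozenset:
            if isinstance(node, str):
                return frozenset((node,))
            here = frozenset().union(*(walk(c) for c in node))
            out.add(here)
            return here

        walk(self.root)
        if not include_root:
            out.discard(self._leaves)
        return out

    def splits(self) -> frozenset:
        """Canonical non-trivial bipartitions (each a frozenset of two sides)."""
        n = self.n_leaves
        out = set()
        for c in self.clades(include_root=False):
            if 2 <= len(c) <= n - 2:
                out.add(frozenset((c, self._leaves - c)))
        return frozenset(out)

    def n_informative_nodes(self) -> int:
        """Count of resolved internal nodes, excluding the root.

        This is the resolution measure used for wildcard node-gain: a fully
        unresolved (star) tree scores 0 and a fully resolved rooted binary
        tree on *n* leaves scores *n* − 2.
        """
        return len(self.clades(include_root=False))

    def is_binary(self) -> bool:
        def ok(node, at_root):
            if isinstance(node, str):
                return True
            limit = 3 if (at_root and not self.rooted) else 2
            return len(node) == limit and all(ok(c, False) for c in node)

        if not self.rooted and self.n_leaves <= 3:
            return isinstance(self.root, str) or all(
                isinstance(c, str) for c in self.root
            )
        return ok(self.root, True)

    # -- identity ----------------------------------------------------------

    def key(self):
        if self._key is None:
            if self.rooted:
                self._key = ("R", self._leaves, frozenset(self.clades()))
            else:
                self._key = ("U", self._leaves, self.splits())
        return self._key

    def __eq__(self, other):
        if not isinstance(other, Topology):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self):
        if self._hash is None:
            self._hash = hash(self.key())
        return self._hash

    def __repr__(self):
        kind = "rooted" if self.rooted else "unrooted"
        return f"<Topology {kind} n={self.n_leaves} {self.to_newick()}>"

    # -- transforms --------------------------------------------------------

    def restrict(self, keep: Iterable[str]) -> "Topology":
        """The induced topology on ``keep`` (unary nodes suppressed)."""
        keep = frozenset(keep) & self._leaves
        if not keep:
            raise ValidationError("restriction to an empty leaf set")

        def walk(node):
            if isinstance(node, str):
                return node if node in keep else None
            kids = [w for w in (walk(c) for c in node) if w is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return tuple(kids)

        return Topology(walk(self.root), rooted=self.rooted)

    def prune(self, drop: Iterable[str]) -> "Topology":
        return self.restrict(self._leaves - frozenset(drop))

    def unroot(self) -> "Topology":
        return self if not self.rooted else Topology(self.root, rooted=False)

    def root_at_leaf(self, outgroup: str, remove: bool = True) -> "Topology":
        """Root an unrooted topology using ``outgroup`` and optionally drop it.

        The root of the returned tree is the node adjacent to the outgroup
        leaf; everything else is oriented away from it.
        """
        if outgroup not in self._leaves:
            raise ValidationError(f"outgroup {outgroup!r} not among leaves")
        adj, labels = _to_adjacency(self.root)
        out_id = next(i for i, lab in labels.items() if lab == outgroup)
        (anchor,) = adj[out_id]

        def build(node, parent):
            if node in labels:
                return labels[node]
            kids = [build(v, node) for v in adj[node] if v != parent]
            return tuple(kids) if len(kids) > 1 else kids[0]

        kids = [build(v, anchor) for v in adj[anchor] if v != out_id]
        if not remove:
            kids.append(outgroup)
        root = tuple(kids) if len(kids) > 1 else kids[0]
        return Topology(root, rooted=True)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_clades(cls, leaves: Iterable[str], clades: Iterable[frozenset],
                    rooted: bool = True) -> "Topology":
        """Assemble a topology from a mutually compatible clade set."""
        leaves = frozenset(leaves)
        cset = {frozenset(c) for c in clades}
        cset = {c for c in cset if 1 < len(c) < len(leaves)}
        for a in cset:
            if not a <= leaves:
                raise ValidationError(f"clade {sorted(a)} outside the leaf set")
            for b in cset:
                if not (a <= b or b <= a or not (a & b)):
                    raise ValidationError(
                        f"incompatible clades {sorted(a)} / {sorted(b)}")
        ordered = sorted(cset, key=lambda c: (len(c), min(c)))
        children: dict[frozenset | None, list] = {None: []}
        parent_of: dict = {}
        for item in [frozenset((l,)) for l in sorted(leaves)] + ordered:
            host = None
            for c in ordered:
                if item < c and (host is None or c < host):
                    host = c
            parent_of[item] = host
        for c in ordered + [None]:
            children.setdefault(c, [])
        for item, host in parent_of.items():
            children.setdefault(host, []).append(item)

        def build(c):
            kids = []
            for k in children.get(c, []):
                if len(k) == 1:
                    kids.append(next(iter(k)))
                else:
                    kids.append(build(k))
            return tuple(kids) if len(kids) != 1 else kids[0]

        return cls(build(None), rooted=rooted)

    @classmethod
    def from_newick(cls, text: str, rooted: bool = True) -> "Topology":
        """Parse a Newick string; branch lengths/support are discarded."""
        text = text.strip()
        if not text:
            raise NewickParseError("empty Newick string", 0)
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "Duplicate taxon labels" in str(exc):
                raise ValidationError(f"duplicate leaf labels: {exc}") from None
            offset = getattr(exc, "col_num", None)
            raise NewickParseError(f"Newick parse failure: {exc}", offset) from None

        def conv(nd):
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else None
                if not label:
                    raise NewickParseError("leaf with empty label")
                return label
            return tuple(conv(c) for c in nd.child_nodes())

        return cls(conv(dtree.seed_node), rooted=rooted)

    def to_newick(self) -> str:
        def fmt(node):
            if isinstance(node, str):
                return node
            return "(" + ",".join(fmt(c) for c in node) + ")"

        body = fmt(self.root)
        if isinstance(self.root, str):
            body = f"({body})"
        return body + ";"


def _unroot_root(root):
    """Canonical unrooted orientation: the root is a polytomy of degree >= 3."""
    while (not isinstance(root, str)) and len(root) == 2:
        a, b = root
        if isinstance(a, str) and isinstance(b, str):
            break
        if not isinstance(b, str):
            root = _normalize((a,) + tuple(b))
        else:
            root = _normalize(tuple(a) + (b,))
    return root


def _to_adjacency(root):
    """Nested tuples -> (adjacency dict, leaf-id -> label). Ids are ints."""
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    counter = [0]

    def new_id():
        counter[0] += 1
        return counter[0] - 1

    def walk(node):
        nid = new_id()
        adj[nid] = []
        if isinstance(node, str):
            labels[nid] = node
            return nid
        for c in node:
            cid = walk(c)
            adj[nid].append(cid)
            adj[cid].append(nid)
        return nid

    walk(root)
    return adj, labels


def compatible(a: frozenset, b: frozenset) -> bool:
    """Clade compatibility on a common leaf universe: nested or disjoint."""
    return a <= b or b <= a or not (a & b)


def splits_compatible(s1: frozenset, s2: frozenset) -> bool:
    """Two bipartitions can coexist on one tree iff some sides are disjoint."""
    for a in s1:
        for b in s2:
            if not (a & b):
                return True
    return False


def rf_distance(t1: Topology, t2: Topology) -> int:
    """Robinson–Foulds distance: size of the symmetric split difference."""
    if t1.leaves != t2.leaves:
        from .errors import TaxonMismatchError
        raise TaxonMismatchError("leaf sets differ",
                                 t1.leaves - t2.leaves, t2.leaves - t1.leaves)
    return len(t1.splits() ^ t2.splits())
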