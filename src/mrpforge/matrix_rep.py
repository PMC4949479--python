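"""Matrix representation of source trees and admixture plots.

Additive binary (Baum–Ragan) coding: every internal node of a source tree
becomes one character in which its descendants are scored 1, the other taxa
sampled by that source 0, and taxa absent from the source ``-``
(inapplicable).  An admixture plot contributes one character per ancestry
cluster: a population is scored 1 when at least ``present_threshold`` (10%
by default) of its genotypes are attributed to the cluster, 0 below that,
and optionally ``?`` inside a borderline band around the threshold.

Partial matrices from all sources are merged column-wise over the union of
taxa.  Rooting is expressed by appending a hypothetical all-zero outgroup
(``ALL0``): characters from sources treated as rooted under the chosen
scheme score the outgroup 0, all others score it ``?`` so that they
constrain grouping but not polarity.  Weighting schemes multiply character
weights partition-wise (factor 1,000 by default), or deactivate the
down-weighted class entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .matrix import (BinaryMatrix, INAPPLICABLE, STATE0, STATE1, UNKNOWN)
from .treeio import (ADMIXTURE_PARTITIONS, GENETIC_TREE_PARTITIONS,
                     QMatrix, SourceRecord, TREE_PARTITIONS)
from .trees import Topology

#: Label of the hypothetical all-zero outgroup taxon.
OUTGROUP = "ALL0"

ROOTING_SCHEMES = ("A", "B", "C", "D")
WEIGHTING_SCHEMES = (1, 2, 3, 4)


@dataclass(frozen=True)
class AdmixtureCodingConfig:
    """Thresholds turning ancestry proportions into presence/absence."""

    present_threshold: float = 0.10
    borderline_band: tuple[float, float] | None = None  # [lo, hi)

    def __post_init__(self):
        if not 0 < self.present_threshold < 1:
            raise ValidationError("present_threshold must lie in (0, 1)")
        if self.borderline_band is not None:
            lo, hi = self.borderline_band
            if not (lo <= self.present_threshold < hi):
                raise ValidationError(
                    "borderline band must contain the presence threshold")

    @classmethod
    def with_default_band(cls, present_threshold: float = 0.10,
                          half_width: float = 0.05) -> "AdmixtureCodingConfig":
        return cls(present_threshold,
                   (present_threshold - half_width, present_threshold + half_width))


def code_tree(tree: Topology, universe, source_id: str = "tree",
              partition: str = "genomic_tree") -> BinaryMatrix:
    """Additive binary coding of one source tree over a taxon universe.

    One character per internal node (rooted) or non-trivial split (unrooted,
    arbitrary fixed polarity).  The root node and trivial singletons are
    omitted: they are constant over the sampled taxa and cannot affect the
    parsimony search.
    """
    universe = tuple(universe)
    upos = {t: i for i, t in enumerate(universe)}
    extra = tree.leaves - set(universe)
    if extra:
        raise ValidationError(f"tree leaves outside universe: {sorted(extra)}")
    if tree.n_leaves < 3:
        warnings.warn(f"{source_id}: fewer than 3 leaves, no characters coded")
        groups: list[frozenset] = []
    elif tree.rooted:
        groups = sorted(tree.clades(), key=lambda c: (len(c), min(c)))
    else:
        n = tree.n_leaves
        groups = sorted((c for c in tree.clades() if len(c) <= n - 2),
                        key=lambda c: (len(c), min(c)))
    grid = np.full((len(universe), len(groups)), INAPPLICABLE, dtype=np.int8)
    present = [upos[t] for t in tree.leaves]
    for j, clade in enumerate(groups):
        grid[present, j] = STATE0
        grid[[upos[t] for t in clade], j] = STATE1
    prov = tuple((source_id, "node_" + "|".join(sorted(c))) for c in groups)
    return BinaryMatrix(universe, grid, np.ones(len(groups), dtype=np.int64),
                        prov, (partition,) * len(groups))


def code_admixture(q: QMatrix, cfg: AdmixtureCodingConfig, universe,
                   source_id: str = "admixture",
                   partition: str = "admixture_genomic") -> BinaryMatrix:
    """One character per ancestry cluster, thresholded presence coding."""
    universe = tuple(universe)
    upos = {t: i for i, t in enumerate(universe)}
    extra = set(q.taxa) - set(universe)
    if extra:
        raise ValidationError(f"Q-matrix taxa outside universe: {sorted(extra)}")
    grid = np.full((len(universe), q.k), INAPPLICABLE, dtype=np.int8)
    rows = [upos[t] for t in q.taxa]
    for j in range(q.k):
        col = q.memberships[:, j]
        coded = np.where(col >= cfg.present_threshold, STATE1, STATE0)
        if cfg.borderline_band is not None:
            lo, hi = cfg.borderline_band
            coded = np.where((col >= lo) & (col < hi), UNKNOWN, coded)
        grid[rows, j] = coded.astype(np.int8)
    prov = tuple((source_id, f"cluster_{j + 1}") for j in range(q.k))
    return BinaryMatrix(universe, grid, np.ones(q.k, dtype=np.int64),
                        prov, (partition,) * q.k)


def implied_admixture_tree(q: QMatrix, cfg: AdmixtureCodingConfig):
    """Strict consensus of MP trees of the coded plot (diagnostic view).

    Merging always uses the coded matrix directly; this view only shows the
    clustering a plot implies on its own.  Returns a rooted topology; with
    no informative characters it is an explicit unresolved star.
    """
    from .consensus_compare import strict_consensus
    from .parsimony import SearchConfig, exhaustive_search, heuristic_search

    coded = code_admixture(q, cfg, q.taxa, source_id="implied")
    informative = coded.select_chars(coded.informative_mask())
    if informative.n_chars == 0:
        return Topology(tuple(sorted(q.taxa)), rooted=True)
    rooted = apply_rooting_all(informative)
    if rooted.n_taxa <= 9:
        result = exhaustive_search(rooted)
    else:
        result = heuristic_search(rooted, SearchConfig(n_addition_replicates=10,
                                                       swap="spr", seed=0))
    mp_rooted = [t.root_at_leaf(OUTGROUP) for t in result.mp_trees]
    return strict_consensus(mp_rooted)


def merge(matrices) -> BinaryMatrix:
    """Column-wise concatenation over the union of taxa (order-invariant)."""
    matrices = list(matrices)
    if not matrices:
        raise ValidationError("merge of an empty matrix list")
    universe = tuple(sorted(set().union(*(m.taxa for m in matrices))))
    expanded = [m.expand_taxa(universe) for m in matrices]
    states = np.hstack([m.states for m in expanded])
    weights = np.concatenate([m.weights for m in expanded])
    prov = tuple(p for m in expanded for p in m.provenance)
    parts = tuple(p for m in expanded for p in m.partitions)
    return BinaryMatrix(universe, states, weights, prov, parts).sorted_columns()


def _treated_as_rooted(source: SourceRecord, scheme: str) -> bool:
    if scheme == "A":
        return source.rooted or source.kind == "admixture"
    if scheme == "B":
        return source.kind == "tree" and source.rooted
    if scheme == "C":
        return (source.kind == "tree" and source.rooted
                and source.partition in GENETIC_TREE_PARTITIONS)
    if scheme == "D":
        return source.has_hominin_outgroup
    raise ValidationError(f"unknown rooting scheme {scheme!r}")


def apply_rooting(matrix: BinaryMatrix, sources, scheme: str) -> BinaryMatrix:
    """Append the all-zero outgroup under rooting scheme A, B, C or D.

    Characters whose source is treated as rooted under the scheme score the
    outgroup 0; all other characters score it ``?``.
    """
    if scheme not in ROOTING_SCHEMES:
        raise ValidationError(f"unknown rooting scheme {scheme!r}")
    by_id = {s.source_id: s for s in sources}
    with_out = matrix.add_taxon(OUTGROUP, UNKNOWN)
    row = with_out.taxon_index(OUTGROUP)
    states = with_out.states.copy()
    for j, (source_id, _) in enumerate(matrix.provenance):
        src = by_id.get(source_id)
        if src is None:
            raise ValidationError(
                f"character {j} references unknown source {source_id!r}")
        if _treated_as_rooted(src, scheme):
            states[row, j] = STATE0
    return BinaryMatrix(with_out.taxa, states, with_out.weights,
                        with_out.provenance, with_out.partitions)


def apply_rooting_all(matrix: BinaryMatrix) -> BinaryMatrix:
    """Append an all-zero outgroup scoring 0 for every character."""
    return matrix.add_taxon(OUTGROUP, STATE0)


def apply_weights(matrix: BinaryMatrix, scheme: int, factor: int = 1000,
                  deactivate: bool = False) -> BinaryMatrix:
    """Partition-wise weighting schemes 1-4.

    1. every partition weight 1;
    2. tree characters ``factor``, admixture plots low;
    3. genetic/genomic tree characters ``factor``, language trees and all
       plots low;
    4. genomic tree characters ``factor``, everything else low;

    where "low" is 1, or 0 (deactivated) when ``deactivate`` is set.
    """
    if scheme not in WEIGHTING_SCHEMES:
        raise ValidationError(f"unknown weighting scheme {scheme!r}")
    if factor <= 0:
        raise ValidationError("weight factor must be positive")
    low = 0 if deactivate else 1
    high_parts = {
        1: set(),
        2: set(TREE_PARTITIONS),
        3: set(GENETIC_TREE_PARTITIONS),
        4: {"genomic_tree"},
    }[scheme]
    if scheme == 1:
        weights = np.ones(matrix.n_chars, dtype=np.int64)
    else:
        weights = np.array(
            [factor if p in high_parts else low for p in matrix.partitions],
            dtype=np.int64)
    return matrix.with_weights(weights)


def code_source(source: SourceRecord, universe,
                cfg: AdmixtureCodingConfig | None = None) -> BinaryMatrix:
    """Dispatch a source record to tree or admixture coding."""
    if source.kind == "tree":
        return code_tree(source.tree, universe, source.source_id,
                         source.partition)
    return code_admixture(source.qmatrix, cfg or AdmixtureCodingConfig(),
                          universe, source.source_id, source.partition)


def build_merged_matrix(sources, cfg: AdmixtureCodingConfig | None = None,
                        universe=None) -> BinaryMatrix:
    """Code every source over the shared universe and merge."""
    sources = list(sources)
    if universe is None:
        universe = sorted(set().union(*(s.taxa for s in sources)))
    coded = [code_source(s, universe, cfg) for s in sources]
    coded = [m for m in coded if m.n_chars]
    return merge(coded)
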