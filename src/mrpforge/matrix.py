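"""The additive-binary character matrix shared by coding, I/O and search.

States are stored as a dense ``int8`` array with the encoding

=========  ======  =================================================
symbol     code    meaning
=========  ======  =================================================
``0``      0       absent / not descended from the coded node
``1``      1       present / descended from the coded node
``?``      -1      unknown (ambiguous admixture section, unscored)
``-``      -2      inapplicable (taxon absent from the source)
=========  ======  =================================================

``?`` and ``-`` are distinguished in storage and serialization but are both
treated as fully missing (any state) by parsimony optimization.  Every
character carries an integer weight (0 = deactivated), a provenance pair
``(source_id, node_or_cluster_id)`` and a data-partition label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

STATE0 = 0
STATE1 = 1
UNKNOWN = -1
INAPPLICABLE = -2

_SYM_TO_CODE = {"0": STATE0, "1": STATE1, "?": UNKNOWN, "-": INAPPLICABLE}
_CODE_TO_SYM = {v: k for k, v in _SYM_TO_CODE.items()}


@dataclass(frozen=True)
class BinaryMatrix:
    """Taxa x characters matrix of additive binary characters."""

    taxa: tuple[str, ...]
    states: np.ndarray                  # (n_taxa, n_chars) int8
    weights: np.ndarray                 # (n_chars,) int64
    provenance: tuple[tuple[str, str], ...]
    partitions: tuple[str, ...]

    def __post_init__(self):
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 2 or states.shape[0] != len(self.taxa):
            raise ValidationError("states shape does not match taxa")
        weights = np.asarray(self.weights, dtype=np.int64)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "weights", weights)
        n_chars = states.shape[1]
        if not (len(weights) == len(self.provenance) == len(self.partitions) == n_chars):
            raise ValidationError("per-character metadata lengths disagree")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxa in matrix")
        if np.any(weights < 0):
            raise ValidationError("negative character weight")

    # -- shape -------------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.states.shape[1]

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise ValidationError(f"taxon {taxon!r} not in matrix") from None

    # -- character classification -------------------------------------------

    def informative_mask(self) -> np.ndarray:
        """Parsimony-informative flags: >=2 taxa scored 1 and >=2 scored 0."""
        ones = (self.states == STATE1).sum(axis=0)
        zeros = (self.states == STATE0).sum(axis=0)
        return (ones >= 2) & (zeros >= 2)

    def active_mask(self) -> np.ndarray:
        return self.weights > 0

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_symbols(cls, taxa, rows, weights=None, provenance=None,
                     partitions=None, partition: str = "unknown",
                     source_id: str = "matrix") -> "BinaryMatrix":
        """Build from per-taxon symbol strings such as ``"10?-"``."""
        taxa = tuple(taxa)
        grid = np.array(
            [[_SYM_TO_CODE[s] for s in row] for row in rows], dtype=np.int8
        ).reshape(len(taxa), -1)
        n = grid.shape[1]
        if weights is None:
            weights = np.ones(n, dtype=np.int64)
        if provenance is None:
            provenance = tuple((source_id, f"c{i}") for i in range(n))
        if partitions is None:
            partitions = (partition,) * n
        return cls(taxa, grid, np.asarray(weights), tuple(provenance),
                   tuple(partitions))

    def symbol_rows(self) -> list[str]:
        return ["".join(_CODE_TO_SYM[int(v)] for v in row) for row in self.states]

    # -- manipulation ---------------------------------------------------------

    def reorder_taxa(self, taxa) -> "BinaryMatrix":
        idx = [self.taxon_index(t) for t in taxa]
        return BinaryMatrix(tuple(taxa), self.states[idx], self.weights,
                            self.provenance, self.partitions)

    def expand_taxa(self, universe) -> "BinaryMatrix":
        """Add absent taxa with all-inapplicable rows; keep given order."""
        universe = tuple(universe)
        if set(self.taxa) - set(universe):
            raise ValidationError("universe does not cover matrix taxa")
        grid = np.full((len(universe), self.n_chars), INAPPLICABLE, dtype=np.int8)
        pos = {t: i for i, t in enumerate(universe)}
        for i, t in enumerate(self.taxa):
            grid[pos[t]] = self.states[i]
        return BinaryMatrix(universe, grid, self.weights, self.provenance,
                            self.partitions)

    def add_taxon(self, taxon: str, fill_code: int) -> "BinaryMatrix":
        if taxon in self.taxa:
            raise ValidationError(f"taxon {taxon!r} already present")
        row = np.full((1, self.n_chars), fill_code, dtype=np.int8)
        return BinaryMatrix(self.taxa + (taxon,), np.vstack([self.states, row]),
                            self.weights, self.provenance, self.partitions)

    def select_chars(self, index) -> "BinaryMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return BinaryMatrix(
            self.taxa, self.states[:, index], self.weights[index],
            tuple(self.provenance[i] for i in index),
            tuple(self.partitions[i] for i in index))

    def with_weights(self, weights) -> "BinaryMatrix":
        return BinaryMatrix(self.taxa, self.states, np.asarray(weights),
                            self.provenance, self.partitions)

    def sorted_columns(self) -> "BinaryMatrix":
        """Deterministic provenance-sorted column order."""
        order = sorted(range(self.n_chars),
                       key=lambda i: (self.provenance[i], self.partitions[i],
                                      self.symbol_column(i)))
        return self.select_chars(np.asarray(order, dtype=int)) if self.n_chars \
            else self

    def symbol_column(self, i: int) -> str:
        return "".join(_CODE_TO_SYM[int(v)] for v in self.states[:, i])

    def __eq__(self, other):
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return (self.taxa == other.taxa
                and np.array_equal(self.states, other.states)
                and np.array_equal(self.weights, other.weights)
                and self.provenance == other.provenance
                and self.partitions == other.partitions)
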