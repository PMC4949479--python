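"""Reading and writing trees, Q-matrices, character matrices and name tables.

Population labels in published trees are notoriously inconsistent (spelling,
diacritics, synonyms), so every leaf label passes through a
:class:`TaxonRegistry` that maps display names and aliases onto short
canonical identifiers.  Resolution is case- and diacritic-insensitive.
"""

from __future__ import annotations

import io
import re
import unicodedata
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ResolutionError, ValidationError
from .matrix import (BinaryMatrix, INAPPLICABLE, STATE0, STATE1, UNKNOWN)
from .trees import Topology

#: Data-partition labels recognized throughout the pipeline.
TREE_PARTITIONS = (
    "genomic_tree", "autosomal_tree", "y_tree", "mtdna_tree",
    "hla_tree", "classical_tree", "language_tree",
)
ADMIXTURE_PARTITIONS = ("admixture_genomic", "admixture_linguistic")
GENETIC_TREE_PARTITIONS = tuple(p for p in TREE_PARTITIONS
                                if p != "language_tree")
ALL_PARTITIONS = TREE_PARTITIONS + ADMIXTURE_PARTITIONS

#: Partition label for linguistic-classification characters used as
#: constraints (not a source partition; never upweighted by schemes 2-4).
CLASSIFICATION_PARTITION = "linguistic_classification"


def normalize_label(label: str) -> str:
    """Fold case, strip diacritics and collapse punctuation/whitespace."""
    text = unicodedata.normalize("NFKD", str(label))
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = re.sub(r"[^0-9a-zA-Z]+", " ", text).strip().casefold()
    return text


class TaxonRegistry:
    """Canonical taxon identifiers with alias resolution."""

    def __init__(self):
        self._entries: dict[str, tuple[str, set[str]]] = {}
        self._lookup: dict[str, str] = {}

    def add(self, canonical_id: str, display_name: str | None = None,
            aliases=()) -> None:
        if canonical_id in self._entries:
            raise ValidationError(f"duplicate canonical id {canonical_id!r}")
        display_name = display_name or canonical_id
        names = {canonical_id, display_name, *aliases}
        for name in names:
            key = normalize_label(name)
            if not key:
                raise ValidationError(f"empty alias for {canonical_id!r}")
            owner = self._lookup.get(key)
            if owner is not None and owner != canonical_id:
                raise ValidationError(
                    f"alias {name!r} maps to both {owner!r} and {canonical_id!r}")
            self._lookup[key] = canonical_id
        self._entries[canonical_id] = (display_name, set(aliases))

    def resolve(self, label: str) -> str:
        cid = self._lookup.get(normalize_label(label))
        if cid is None:
            raise ResolutionError(f"unresolvable taxon label {label!r}")
        return cid

    def __contains__(self, label) -> bool:
        return normalize_label(label) in self._lookup

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def canonical_ids(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def display_name(self, canonical_id: str) -> str:
        return self._entries[canonical_id][0]

    @classmethod
    def from_names(cls, names) -> "TaxonRegistry":
        reg = cls()
        for n in names:
            reg.add(n)
        return reg

    @classmethod
    def from_table(cls, text: str) -> "TaxonRegistry":
        """TSV with columns: canonical_id, display_name, aliases (';'-separated)."""
        reg = cls()
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str).fillna("")
        for _, row in df.iterrows():
            aliases = [a for a in str(row.get("aliases", "")).split(";") if a]
            reg.add(row["canonical_id"], row.get("display_name") or None, aliases)
        return reg

    def to_table(self) -> str:
        lines = ["canonical_id\tdisplay_name\taliases"]
        for cid, (disp, aliases) in self._entries.items():
            lines.append(f"{cid}\t{disp}\t{';'.join(sorted(aliases))}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class QMatrix:
    """Population x cluster ancestry proportions from a STRUCTURE-style run."""

    taxa: tuple[str, ...]
    memberships: np.ndarray  # (n_taxa, K) floats in [0, 1]

    ROW_SUM_TOL = 1e-6

    def __post_init__(self):
        mem = np.asarray(self.memberships, dtype=float)
        object.__setattr__(self, "memberships", mem)
        if mem.ndim != 2 or mem.shape[0] != len(self.taxa):
            raise ValidationError("membership shape does not match taxa")
        if mem.shape[1] < 2:
            raise ValidationError("Q-matrix needs K >= 2 clusters")
        if np.any(mem < 0):
            bad = self.taxa[int(np.argwhere(mem < 0)[0][0])]
            raise ValidationError(f"negative proportion for taxon {bad!r}")
        sums = mem.sum(axis=1)
        off = np.abs(sums - 1.0) > self.ROW_SUM_TOL
        if off.any():
            i = int(np.flatnonzero(off)[0])
            raise ValidationError(
                f"row sum {sums[i]:.6g} for taxon {self.taxa[i]!r} (must be 1)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxa in Q-matrix")

    @property
    def k(self) -> int:
        return self.memberships.shape[1]


@dataclass(frozen=True)
class SourceRecord:
    """One source: a published tree or an admixture plot, plus metadata."""

    source_id: str
    kind: str                      # "tree" | "admixture"
    partition: str
    rooted: bool
    has_hominin_outgroup: bool = False
    tree: Topology | None = None
    qmatrix: QMatrix | None = None

    def __post_init__(self):
        if self.kind not in ("tree", "admixture"):
            raise ValidationError(f"unknown source kind {self.kind!r}")
        if self.partition not in ALL_PARTITIONS:
            raise ValidationError(f"unknown partition {self.partition!r}")
        if self.kind == "tree" and self.tree is None:
            raise ValidationError(f"{self.source_id}: tree source without topology")
        if self.kind == "admixture" and self.qmatrix is None:
            raise ValidationError(f"{self.source_id}: admixture source without Q-matrix")

    @property
    def taxa(self) -> frozenset:
        if self.kind == "tree":
            return self.tree.leaves
        return frozenset(self.qmatrix.taxa)


# ---------------------------------------------------------------------------
# trees

def read_newick(text: str, rooted_hint: bool = True,
                registry: TaxonRegistry | None = None) -> Topology:
    """Parse Newick; leaf labels resolved through the registry if given."""
    topo = Topology.from_newick(text, rooted=rooted_hint)
    if registry is not None:
        mapping = {leaf: registry.resolve(leaf) for leaf in topo.leaves}

        def rename(node):
            if isinstance(node, str):
                return mapping[node]
            return tuple(rename(c) for c in node)

        topo = Topology(rename(topo.root), rooted=rooted_hint)
    return topo


def write_newick(topology: Topology) -> str:
    return topology.to_newick()


# ---------------------------------------------------------------------------
# Q-matrices

def read_qmatrix(text: str, registry: TaxonRegistry | None = None) -> QMatrix:
    """Parse a delimited Q-matrix: first column taxa, then K proportions.

    The delimiter is auto-detected between tab and comma; a file containing
    both in its data lines is rejected as ambiguous.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValidationError("no data rows in Q-matrix table")
    has_tab = any("\t" in ln for ln in lines)
    has_comma = any("," in ln for ln in lines)
    if has_tab and has_comma:
        raise ValidationError("ambiguous delimiter: both tab and comma present")
    if not has_tab and not has_comma:
        raise ValidationError("no recognizable delimiter (tab or comma)")
    sep = "\t" if has_tab else ","

    rows = [ln.split(sep) for ln in lines]
    # optional header: second field of the first row non-numeric
    def _numeric(s):
        try:
            float(s)
            return True
        except ValueError:
            return False

    if rows and len(rows[0]) > 1 and not _numeric(rows[0][1]):
        rows = rows[1:]
    if not rows:
        raise ValidationError("no data rows in Q-matrix table")
    taxa, mem = [], []
    for r in rows:
        if len(r) < 3:
            raise ValidationError(f"row for {r[0]!r} has fewer than 2 clusters")
        taxa.append(r[0].strip())
        try:
            mem.append([float(x) for x in r[1:]])
        except ValueError as exc:
            raise ValidationError(f"non-numeric proportion in row {r[0]!r}: {exc}")
    widths = {len(m) for m in mem}
    if len(widths) != 1:
        raise ValidationError("rows have differing cluster counts")
    if registry is not None:
        taxa = [registry.resolve(t) for t in taxa]
    return QMatrix(tuple(taxa), np.array(mem, dtype=float))


def write_qmatrix(q: QMatrix) -> str:
    lines = []
    for t, row in zip(q.taxa, q.memberships):
        # enough digits that read-back rows still sum to 1 within tolerance
        lines.append(t + "\t" + "\t".join(f"{x:.10f}" for x in row))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# character matrices

_NEXUS_BAD = re.compile(r"[\s()\[\]{}/\\,;:=*'\"`+<>~]")


def _check_labels(taxa, dialect):
    for t in taxa:
        if _NEXUS_BAD.search(t):
            raise ValidationError(
                f"taxon label {t!r} is illegal in the {dialect} dialect")


def write_matrix(matrix: BinaryMatrix, dialect: str = "nexus") -> str:
    """Serialize to NEXUS or TNT text, including per-character weights.

    Columns are emitted in deterministic provenance-sorted order so repeated
    runs are byte-identical.
    """
    if matrix.n_chars == 0 or matrix.n_taxa == 0:
        raise ValidationError("refusing to serialize an empty matrix")
    if dialect not in ("nexus", "tnt"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    _check_labels(matrix.taxa, dialect)
    m = matrix.sorted_columns()
    rows = m.symbol_rows()
    width = max(len(t) for t in m.taxa) + 2

    if dialect == "nexus":
        out = ["#NEXUS", "", "BEGIN DATA;",
               f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_chars};",
               "    FORMAT DATATYPE=STANDARD SYMBOLS=\"01\" MISSING=? GAP=-;",
               "    MATRIX"]
        for t, r in zip(m.taxa, rows):
            out.append(f"        {t.ljust(width)}{r}")
        out += ["    ;", "END;", "", "BEGIN ASSUMPTIONS;",
                "    WTSET * forge_weights (VECTOR) = "
                + " ".join(str(int(w)) for w in m.weights) + ";",
                "END;", ""]
        return "\n".join(out)

    # TNT xread + ccode weight statements
    out = ["xread", f"'{m.n_chars} characters, provenance-sorted'",
           f"{m.n_chars} {m.n_taxa}"]
    for t, r in zip(m.taxa, rows):
        out.append(f"{t.ljust(width)}{r}")
    out.append(";")
    by_weight: dict[int, list[int]] = {}
    for i, w in enumerate(m.weights):
        by_weight.setdefault(int(w), []).append(i)
    for w in sorted(by_weight):
        cols = " ".join(str(i) for i in by_weight[w])
        if w == 0:
            out.append(f"ccode -] {cols};")
        else:
            out.append(f"ccode /{w} {cols};")
    out.append("proc /;")
    return "\n".join(out) + "\n"


def read_nexus_matrix(text: str) -> BinaryMatrix:
    """Read back a NEXUS matrix written by :func:`write_matrix`.

    Provenance/partition labels are not carried by NEXUS; they come back as
    generic column identifiers.
    """
    mrows = re.search(r"MATRIX(.*?);", text, re.S | re.I)
    if not mrows:
        raise ValidationError("no MATRIX block found")
    taxa, rows = [], []
    for line in mrows.group(1).strip().splitlines():
        parts = line.split()
        if len(parts) != 2:
            raise ValidationError(f"cannot parse matrix row {line!r}")
        taxa.append(parts[0])
        rows.append(parts[1])
    wt = re.search(r"WTSET[^=]*=\s*([0-9 \t]+);", text, re.I)
    weights = None
    if wt:
        weights = np.array([int(x) for x in wt.group(1).split()], dtype=np.int64)
    return BinaryMatrix.from_symbols(taxa, rows, weights=weights,
                                     source_id="nexus")


# ---------------------------------------------------------------------------
# classification tables

def read_classification(text: str,
                        registry: TaxonRegistry | None = None) -> dict[str, str]:
    """TSV with columns taxon, family; '?' marks language-shift taxa."""
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    if not {"taxon", "family"} <= set(df.columns):
        raise ValidationError("classification table needs 'taxon' and 'family'")
    out = {}
    for _, row in df.iterrows():
        taxon = registry.resolve(row["taxon"]) if registry else row["taxon"]
        out[taxon] = row["family"]
    return out


def classification_matrix(classification: dict[str, str], universe,
                          source_id: str = "classification") -> BinaryMatrix:
    """One binary character per family; '?' taxa unknown in every character."""
    universe = tuple(universe)
    families = sorted({f for f in classification.values() if f != "?"})
    grid = np.full((len(universe), len(families)), INAPPLICABLE, dtype=np.int8)
    for i, taxon in enumerate(universe):
        fam = classification.get(taxon)
        if fam is None:
            continue
        if fam == "?":
            grid[i, :] = UNKNOWN
        else:
            grid[i, :] = STATE0
            grid[i, families.index(fam)] = STATE1
    return BinaryMatrix(
        universe, grid, np.ones(len(families), dtype=np.int64),
        tuple((source_id, fam) for fam in families),
        (CLASSIFICATION_PARTITION,) * len(families))


def write_classification(classification: dict[str, str]) -> str:
    lines = ["taxon\tfamily"]
    for taxon in sorted(classification):
        lines.append(f"{taxon}\t{classification[taxon]}")
    return "\n".join(lines) + "\n"
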