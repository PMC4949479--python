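"""End-to-end orchestration of the supertree analysis.

The full analysis runs the sensitivity grid, identifies wildcard taxa in
every cell's MP set, excludes candidates whose instability collapses the
consensus by at least the exclusion threshold, reruns the grid on the
pruned dataset, and reports consensus trees, pairwise cell comparisons,
wildcard reports and a group-status table.  Everything is reproducible:
given one configuration and seed the emitted report bundle is
byte-identical across runs.

Linguistic classifications enter in two roles: as characters *fitted* onto
a finished supertree (CI/RI per family, compared against the floor
CI_min = 1/N for a family scored in N populations), and as *constraints* —
appended to the rooted matrix upweighted by a large factor (1,000 by
default) so that every fully scored family is forced monophyletic while
``?``-scored language-shift populations remain free to follow the genetic
signal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .consensus_compare import character_fit, spr_distance
from .errors import ValidationError
from .matrix import BinaryMatrix, STATE1
from .matrix_rep import (AdmixtureCodingConfig, OUTGROUP, apply_rooting,
                         build_merged_matrix, merge)
from .parsimony import (SearchConfig, SearchResult, heuristic_search,
                        soft_fitch_binary)
from .stability import (CellResult, aggregate_wildcards, build_parameter_grid,
                        identify_wildcards, run_sensitivity)
from .trees import Topology

log = logging.getLogger("mrpforge")

MONOPHYLETIC = "monophyletic"
PARAPHYLETIC_OR_UNRESOLVED = "paraphyletic_or_unresolved"
POLYPHYLETIC = "polyphyletic"


@dataclass
class AnalysisConfig:
    """Settings of one full analysis run."""

    search: SearchConfig = field(default_factory=SearchConfig)
    admixture: AdmixtureCodingConfig = field(default_factory=AdmixtureCodingConfig)
    exclusion_threshold: int = 5
    wildcard_min_gain: int = 1
    constraint_factor: int = 1000
    weight_factor: int = 1000
    deactivate: bool = False
    groups: dict[str, frozenset] = field(default_factory=dict)
    seed: int = 0


def group_status(tree: Topology, group) -> str:
    """Classify a named group on a (possibly unresolved) topology.

    * ``monophyletic`` — some node's leaf set equals the group;
    * ``paraphyletic_or_unresolved`` — the group's indicator character
      attains at most one step once polytomies are resolved optimally
      (the group is convex: compatible with monophyly or paraphyly);
    * ``polyphyletic`` — at least two independent origins are forced.
    """
    group = frozenset(group)
    if not 2 <= len(group) < len(tree.leaves):
        raise ValidationError("group must be a proper subset of >= 2 leaves")
    if not group <= tree.leaves:
        raise ValidationError("group contains unknown taxa")
    if group in tree.clades(include_root=True):
        return MONOPHYLETIC
    states = {leaf: (1 if leaf in group else 0) for leaf in tree.leaves}
    steps = soft_fitch_binary(tree, states)
    return PARAPHYLETIC_OR_UNRESOLVED if steps <= 1 else POLYPHYLETIC


def fit_classification(tree: Topology, matrix: BinaryMatrix):
    """Per-family CI/RI/CI_min fit of classification characters on a tree.

    Families with fewer than two scored members are excluded (with a note)
    — their CI is 1 trivially and would inflate the ensemble.
    """
    keep, notes = [], []
    for j in range(matrix.n_chars):
        scored = int((matrix.states[:, j] == STATE1).sum())
        if scored < 2:
            notes.append(f"{matrix.provenance[j][1]}: fewer than 2 scored "
                         "members, excluded")
        else:
            keep.append(j)
    sub = matrix.select_chars(np.asarray(keep, dtype=int))
    records, ens_ci, ens_ri = character_fit(tree, sub)
    rows = []
    for rec in records:
        rows.append({
            "family": rec.char_id.split(":", 1)[1],
            "n_scored": rec.n_scored, "s": rec.s, "m": rec.m, "g": rec.g,
            "ci": rec.ci, "ri": rec.ri, "ci_min": rec.ci_min,
            "ci_excess": rec.ci - rec.ci_min,
        })
    rows.sort(key=lambda r: (-(r["ci_excess"] if r["ci_excess"] == r["ci_excess"]
                               else -1e9), r["family"]))
    return {"families": rows, "ensemble_ci": ens_ci, "ensemble_ri": ens_ri,
            "notes": notes}


def _constraint_conflicts(matrix: BinaryMatrix) -> list[tuple[str, str]]:
    """Pairs of classification characters whose 1-sets properly overlap."""
    out = []
    ones = [set(np.flatnonzero(matrix.states[:, j] == STATE1))
            for j in range(matrix.n_chars)]
    for a in range(matrix.n_chars):
        for b in range(a + 1, matrix.n_chars):
            inter = ones[a] & ones[b]
            if inter and not (ones[a] <= ones[b] or ones[b] <= ones[a]):
                out.append((matrix.provenance[a][1], matrix.provenance[b][1]))
    return out


def constrained_supertree(sources, classification_matrix: BinaryMatrix,
                          cfg: AnalysisConfig | None = None) -> SearchResult:
    """Supertree with linguistic classification as soft constraints.

    All partitions are rooted by the all-zero outgroup; language-derived
    characters (language trees and the classification dataset) carry the
    constraint weight factor relative to genetic partitions.  Conflicting
    constraint characters trigger a warning (the heavier-compatible subset
    wins during search).
    """
    import warnings

    cfg = cfg or AnalysisConfig()
    conflicts = _constraint_conflicts(classification_matrix)
    for a, b in conflicts:
        warnings.warn(f"conflicting constraint characters: {a} vs {b}")
    base = build_merged_matrix(sources, cfg.admixture)
    rooted = apply_rooting(base, sources, "A")
    # language sources upweighted together with the classification data
    weights = np.array(
        [cfg.constraint_factor if p == "language_tree" else 1
         for p in rooted.partitions], dtype=np.int64)
    rooted = rooted.with_weights(weights)
    cmat = classification_matrix.expand_taxa(
        tuple(sorted(set(classification_matrix.taxa) | set(base.taxa))))
    cmat = cmat.add_taxon(OUTGROUP, 0).reorder_taxa(rooted.taxa)
    cmat = cmat.with_weights(np.full(cmat.n_chars, cfg.constraint_factor,
                                     dtype=np.int64))
    merged = merge([rooted, cmat])
    return heuristic_search(merged, cfg.search)


# ---------------------------------------------------------------------------
# full analysis

def _tree_report(tree: Topology) -> str:
    return tree.to_newick()


def _json_default(obj):
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"unserializable {type(obj)!r}")


def _matrix_digest(matrix: BinaryMatrix) -> str:
    h = hashlib.sha256()
    h.update("|".join(matrix.taxa).encode())
    h.update(matrix.states.tobytes())
    h.update(matrix.weights.tobytes())
    return h.hexdigest()[:16]


def _grid_phase(sources, cfg: AnalysisConfig, grid):
    cells = run_sensitivity(sources, grid, cfg.search, cfg.admixture,
                            cfg.weight_factor, cfg.deactivate)
    wildcards = {label: identify_wildcards(cell.mp_rooted,
                                           min_gain=cfg.wildcard_min_gain)
                 for label, cell in cells.items()}
    reports = aggregate_wildcards(wildcards, cfg.exclusion_threshold)
    return cells, reports


def _cell_summary(cells: dict[str, CellResult]) -> dict:
    out = {}
    for label, cell in cells.items():
        out[label] = {
            "best_score": cell.search.best_score,
            "n_mp_trees": len(cell.search.mp_trees),
            "truncated": cell.search.truncated,
            "strict": _tree_report(cell.strict),
            "semistrict": _tree_report(cell.semistrict),
            "strict_nodes": cell.strict.n_informative_nodes(),
            "semistrict_nodes": cell.semistrict.n_informative_nodes(),
        }
    return out


def _pairwise_comparisons(cells: dict[str, CellResult]) -> list[dict]:
    labels = sorted(cells)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            r = spr_distance(cells[a].strict, cells[b].strict)
            rows.append({"a": a, "b": b, "d_spr": r.d_spr,
                         "similarity_pct": round(r.similarity_pct, 3),
                         "rf": r.rf, "approximate": r.approximate})
    return rows


def run_full_analysis(sources, cfg: AnalysisConfig,
                      classification_matrix: BinaryMatrix | None = None,
                      out_dir: str | Path | None = None) -> dict:
    """Sensitivity grid -> wildcards -> exclusion -> pruned rerun -> reports.

    Returns the report bundle as a JSON-serializable dict; when ``out_dir``
    is given the bundle and the consensus trees are also written to disk
    (deterministically — rerunning with the same config and seed produces
    byte-identical files).
    """
    sources = list(sources)
    grid = build_parameter_grid()
    log.info("grid phase: %d sources, %d cells", len(sources), len(grid))
    cells, wc_reports = _grid_phase(sources, cfg, grid)

    excluded: set[str] = set()
    for rep in wc_reports:
        if rep.exclude:
            excluded |= set(rep.taxa)
    pruned_cells = None
    if excluded:
        pruned_sources = _prune_sources(sources, excluded)
        log.info("rerunning grid without %s", sorted(excluded))
        pruned_cells, _ = _grid_phase(pruned_sources, cfg, grid)

    final_cells = pruned_cells if pruned_cells else cells
    bundle: dict = {
        "config": {
            "seed": cfg.search.seed,
            "replicates": cfg.search.n_addition_replicates,
            "swap": cfg.search.swap,
            "exclusion_threshold": cfg.exclusion_threshold,
            "weight_factor": cfg.weight_factor,
        },
        "n_sources": len(sources),
        "cells": _cell_summary(cells),
        "comparisons": _pairwise_comparisons(cells),
        "wildcards": [{
            "taxa": sorted(r.taxa),
            "flagged_sets": r.flagged_sets,
            "node_gain": r.node_gain,
            "max_gain": r.max_gain,
            "exclude": r.exclude,
            "alternative_positions": [list(p) for p in r.alternative_positions],
        } for r in wc_reports],
        "excluded_taxa": sorted(excluded),
        "pruned_cells": _cell_summary(pruned_cells) if pruned_cells else None,
    }

    if cfg.groups:
        status: dict[str, dict[str, str]] = {}
        for name, taxa in sorted(cfg.groups.items()):
            status[name] = {}
            for label in sorted(final_cells):
                tree = final_cells[label].semistrict
                present = frozenset(taxa) & tree.leaves
                if len(present) < 2 or len(present) >= len(tree.leaves):
                    status[name][label] = "undefined"
                else:
                    status[name][label] = group_status(tree, present)
        bundle["group_status"] = status

    if classification_matrix is not None:
        ref = final_cells["1.A"].strict
        fit_taxa = [t for t in classification_matrix.taxa if t in ref.leaves]
        fit = fit_classification(
            ref, classification_matrix.reorder_taxa(fit_taxa))
        bundle["classification_fit"] = fit

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(bundle, indent=2, sort_keys=True,
                       default=_json_default) + "\n")
        trees_txt = "".join(
            f"{label}\t{final_cells[label].strict.to_newick()}\n"
            for label in sorted(final_cells))
        (out / "consensus_strict.tsv").write_text(trees_txt)
    return bundle


def _prune_sources(sources, excluded: set[str]):
    out = []
    for s in sources:
        if s.kind == "tree":
            keep = s.tree.leaves - excluded
            if len(keep) < 3:
                continue
            out.append(type(s)(s.source_id, s.kind, s.partition, s.rooted,
                               s.has_hominin_outgroup,
                               tree=s.tree.restrict(keep)))
        else:
            keep = [t for t in s.qmatrix.taxa if t not in excluded]
            if len(keep) < 3:
                continue
            idx = [s.qmatrix.taxa.index(t) for t in keep]
            from .treeio import QMatrix
            mem = s.qmatrix.memberships[idx]  # rows drop, sums unchanged
            out.append(type(s)(s.source_id, s.kind, s.partition, s.rooted,
                               s.has_hominin_outgroup,
                               qmatrix=QMatrix(tuple(keep), mem)))
    return out
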