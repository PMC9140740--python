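"""Ancestral-lineage counting by species-overlap reconciliation.

Given a rooted gene tree whose tips are tagged with species, internal nodes
are labelled duplication or speciation by the species-overlap criterion: a
node is a duplication iff at least two of its children carry intersecting
ingroup species sets.  An *ancestral lineage* is a gene copy present in the
common ancestor of the ingroup: operationally, every duplication node whose
species set maps (by MRCA on the ingroup species tree) to the species-tree
root is removed, and each remaining maximal subtree containing at least one
ingroup tip is one lineage.  With no gene loss this recovers the true
ancestral copy number exactly; losses can merge lineages (the count is a
lower bound, never an overcount).

Outgroup tips are excluded from all species sets: they serve rooting only.
Multifurcations (e.g. after collapsing low-support edges) are treated as
simultaneous divergences, duplications iff any two children overlap.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import dendropy
import pandas as pd

__all__ = [
    "ReconciledTree",
    "AncestralLineageReport",
    "EmptyReconciliationError",
    "collapse_low_support",
    "reconcile",
    "count_ancestral_lineages",
    "detect_expansions",
    "root_split_from_newick",
]


class EmptyReconciliationError(ValueError):
    pass


def _leaf_label(leaf: dendropy.Node) -> str:
    return leaf.taxon.label if leaf.taxon is not None else (leaf.label or "")


def collapse_low_support(tree: dendropy.Tree, min_support: float = 50.0) -> dendropy.Tree:
    """Contract internal edges with support below ``min_support``.

    Returns a new tree; tips are untouched, and nodes whose support is
    missing are kept (treated as at or above threshold).  Contraction turns
    poorly supported resolutions into multifurcations.
    """
    out = copy.deepcopy(tree)
    to_collapse = []
    for node in out.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        sup = getattr(node, "support", None)
        if sup is None and node.label not in (None, ""):
            try:
                sup = float(node.label)
            except ValueError:
                sup = None
        if sup is not None and sup < min_support:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


@dataclass
class ReconciledTree:
    """Gene tree plus per-node ingroup species sets and event labels."""

    tree: dendropy.Tree
    ingroup_species: frozenset[str]
    species_set: dict[int, frozenset[str]]  # keyed by id(node)
    event: dict[int, str]  # duplication | speciation | leaf-parent | leaf

    def species_of(self, node: dendropy.Node) -> frozenset[str]:
        return self.species_set[id(node)]

    def event_of(self, node: dendropy.Node) -> str:
        return self.event[id(node)]


def reconcile(tree: dendropy.Tree, ingroup_species: Iterable[str]) -> ReconciledTree:
    """Species-overlap reconciliation.

    Every leaf must carry a ``species`` attribute (as produced by
    :func:`nbsurvey.io_formats.read_tree`).  Leaves of species outside the
    ingroup contribute empty sets.  Internal nodes with fewer than two
    ingroup-bearing children inherit ``leaf-parent`` status.
    """
    ingroup = frozenset(ingroup_species)
    species_set: dict[int, frozenset[str]] = {}
    event: dict[int, str] = {}
    n_ingroup_tips = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sp = getattr(node, "species", None)
            if sp is None:
                sp = _leaf_label(node).split("_", 1)[0]
            s = frozenset({sp}) & ingroup if sp in ingroup else frozenset()
            if s:
                n_ingroup_tips += 1
            species_set[id(node)] = s
            event[id(node)] = "leaf"
            continue
        children = node.child_nodes()
        sets = [species_set[id(c)] for c in children]
        species_set[id(node)] = frozenset().union(*sets)
        bearing = [s for s in sets if s]
        if len(bearing) < 2:
            event[id(node)] = "leaf-parent"
        else:
            dup = any(
                bearing[i] & bearing[j]
                for i in range(len(bearing))
                for j in range(i + 1, len(bearing))
            )
            event[id(node)] = "duplication" if dup else "speciation"
    if n_ingroup_tips == 0:
        raise EmptyReconciliationError("tree contains no ingroup tips")
    return ReconciledTree(
        tree=tree, ingroup_species=ingroup, species_set=species_set, event=event
    )


def root_split_from_newick(newick: str) -> tuple[frozenset[str], frozenset[str]]:
    """Basal bipartition of an ingroup species tree given as newick,
    e.g. ``"(Ef,(Nc,Nt));"`` -> ({Ef}, {Nc, Nt})."""
    t = dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True
    )
    kids = t.seed_node.child_nodes()
    if len(kids) != 2:
        raise ValueError("ingroup species tree must be rooted and bifurcating at its base")
    sides = []
    for k in kids:
        sides.append(frozenset(_leaf_label(l) for l in k.leaf_iter()))
    return sides[0], sides[1]


@dataclass
class Lineage:
    lineage_id: str
    subclass: str
    species_counts: dict[str, int]
    tip_labels: tuple[str, ...]

    @property
    def size(self) -> int:
        return sum(self.species_counts.values())


@dataclass
class AncestralLineageReport:
    lineages: list[Lineage]
    totals_by_subclass: dict[str, int]
    inherited: dict[str, int]

    @property
    def total(self) -> int:
        return len(self.lineages)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for l in self.lineages:
            row = {"lineage_id": l.lineage_id, "subclass": l.subclass, "n_tips": l.size}
            for sp, n in sorted(l.species_counts.items()):
                row[f"n_{sp}"] = n
            rows.append(row)
        return pd.DataFrame(rows).fillna(0)


def _maps_to_root(
    species: frozenset[str], root_split: tuple[frozenset[str], frozenset[str]]
) -> bool:
    a, b = root_split
    return bool(species & a) and bool(species & b)


def count_ancestral_lineages(
    rec: ReconciledTree,
    species_tree: str = "(Ef,(Nc,Nt));",
    subclass_map: Mapping[str, str] | None = None,
) -> AncestralLineageReport:
    """Cut root-mapping duplications and report the resulting lineages.

    A duplication node maps to the species-tree root when its ingroup
    species set spans both sides of the species tree's basal split.  Those
    nodes are removed; each remaining maximal subtree with at least one
    ingroup tip is an ancestral lineage.  Per-lineage subclass is the
    majority subclass of its tips under ``subclass_map`` (ties are an
    error); ``inherited[X]`` counts lineages containing species X.
    """
    root_split = root_split_from_newick(species_tree)
    tree = rec.tree

    # assign lineage index in preorder; root-mapping duplications get None
    lineage_of: dict[int, int | None] = {}
    lineage_tips: dict[int, list[dendropy.Node]] = {}
    next_id = 0
    for node in tree.preorder_node_iter():
        is_cut = (
            rec.event_of(node) == "duplication"
            and _maps_to_root(rec.species_of(node), root_split)
        )
        if is_cut:
            lineage_of[id(node)] = None
            continue
        parent = node.parent_node
        parent_lin = lineage_of[id(parent)] if parent is not None else None
        if parent_lin is None:
            lin = next_id
            next_id += 1
            lineage_tips[lin] = []
        else:
            lin = parent_lin
        lineage_of[id(node)] = lin
        if node.is_leaf() and rec.species_of(node):
            lineage_tips[lin].append(node)

    lineages: list[Lineage] = []
    width = 3
    count = 0
    for lin in sorted(lineage_tips):
        tips = lineage_tips[lin]
        if not tips:
            continue
        count += 1
        counts: dict[str, int] = {}
        labels: list[str] = []
        for t in tips:
            sp = next(iter(rec.species_of(t)))
            counts[sp] = counts.get(sp, 0) + 1
            labels.append(_leaf_label(t))
        subclass = "NA"
        if subclass_map is not None:
            votes: dict[str, int] = {}
            for lab in labels:
                sc = subclass_map.get(lab)
                if sc is not None:
                    votes[sc] = votes.get(sc, 0) + 1
            if votes:
                ranked = sorted(votes.items(), key=lambda kv: -kv[1])
                if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
                    raise ValueError(
                        f"lineage {count}: subclass tie {ranked[0][0]}/{ranked[1][0]}; "
                        "subclasses are expected to be monophyletic"
                    )
                subclass = ranked[0][0]
        lineages.append(
            Lineage(
                lineage_id=f"C{count:0{width}d}",
                subclass=subclass,
                species_counts=counts,
                tip_labels=tuple(labels),
            )
        )

    totals: dict[str, int] = {}
    inherited: dict[str, int] = {sp: 0 for sp in sorted(rec.ingroup_species)}
    for l in lineages:
        totals[l.subclass] = totals.get(l.subclass, 0) + 1
        for sp in l.species_counts:
            inherited[sp] = inherited.get(sp, 0) + 1
    return AncestralLineageReport(
        lineages=lineages, totals_by_subclass=totals, inherited=inherited
    )


def detect_expansions(
    report: AncestralLineageReport, min_size: int = 10
) -> pd.DataFrame:
    """Per-(lineage, species) gene counts at or above ``min_size``, largest first."""
    rows = [
        {"lineage_id": l.lineage_id, "species": sp, "count": n}
        for l in report.lineages
        for sp, n in sorted(l.species_counts.items())
        if n >= min_size
    ]
    df = pd.DataFrame(rows, columns=["lineage_id", "species", "count"])
    return df.sort_values(
        ["count", "lineage_id", "species"], ascending=[False, True, True]
    ).reset_index(drop=True)
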