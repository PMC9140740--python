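"""Chromosomal anchoring: 250-kb cluster calling and distribution summaries.

Two family members belong to the same cluster when the window extending
``window`` bases up- and downstream of one gene's full interval overlaps the
other gene's interval, i.e. when the inter-gene gap is at most ``window``.
Loci are the connected components of this relation (single-linkage
transitive closure), computed with a sorted sweep per chromosome; a locus
with one member is a singleton, with two or more a cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .io_formats import GeneModel, ValidationError, chrom_sort_key

__all__ = [
    "Locus",
    "LocusAssignment",
    "InsufficientDataError",
    "call_clusters",
    "distribution_summary",
    "length_correlation",
    "CorrelationResult",
]


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class Locus:
    locus_id: str
    chrom: str
    members: tuple[str, ...]
    span_start: int
    span_end: int

    @property
    def kind(self) -> str:
        return "cluster" if len(self.members) >= 2 else "singleton"

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class LocusAssignment:
    loci: list[Locus]

    @property
    def singletons(self) -> list[Locus]:
        return [l for l in self.loci if l.kind == "singleton"]

    @property
    def clusters(self) -> list[Locus]:
        return [l for l in self.loci if l.kind == "cluster"]

    def locus_of(self) -> dict[str, str]:
        return {g: l.locus_id for l in self.loci for g in l.members}


def call_clusters(
    genes: Iterable[GeneModel],
    window: int = 250_000,
    anchor: str = "interval",
    known_chromosomes: set[str] | None = None,
) -> LocusAssignment:
    """Group positioned family members into singleton/cluster loci.

    ``anchor="interval"`` measures the linkage gap between gene intervals
    (window anchored on the whole gene); ``anchor="start"`` measures it
    between start points.  Because loci live on a line, a sweep that links a
    gene to the open locus whenever its gap to the furthest right edge seen
    so far is within the window is exactly single-linkage closure.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if anchor not in ("interval", "start"):
        raise ValueError(f"unknown anchor mode {anchor!r}")
    gene_list = list(genes)
    if known_chromosomes is not None:
        for g in gene_list:
            if g.chrom not in known_chromosomes:
                raise ValidationError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.chrom, []).append(g)

    loci: list[Locus] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        members = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        groups: list[list[GeneModel]] = []
        reach = -math.inf  # furthest right edge of the open locus
        for g in members:
            edge = g.start if anchor == "start" else g.start
            prev_edge = reach
            linked = groups and (edge - prev_edge) <= window
            if linked:
                groups[-1].append(g)
            else:
                groups.append([g])
            right = g.start if anchor == "start" else g.end
            reach = max(reach, right) if linked else right
        for grp in groups:
            loci.append(
                Locus(
                    locus_id="",
                    chrom=chrom,
                    members=tuple(x.gene_id for x in grp),
                    span_start=min(x.start for x in grp),
                    span_end=max(x.end for x in grp),
                )
            )
    # deterministic ids by chromosome order then span start
    loci.sort(key=lambda l: (chrom_sort_key(l.chrom), l.span_start, l.span_end))
    width = max(3, len(str(len(loci))))
    loci = [
        Locus(f"L{idx + 1:0{width}d}", l.chrom, l.members, l.span_start, l.span_end)
        for idx, l in enumerate(loci)
    ]
    return LocusAssignment(loci=loci)


def distribution_summary(
    assignment: LocusAssignment,
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict:
    """Per-chromosome counts plus the headline totals.

    Chromosomes listed in ``chrom_lengths`` but devoid of family members are
    reported with count 0.  Totals satisfy genes = clustered + singletons and
    loci = clusters + singletons.
    """
    loci = assignment.loci
    chroms = sorted(
        set(l.chrom for l in loci) | set(chrom_lengths or {}), key=chrom_sort_key
    )
    rows = []
    for c in chroms:
        here = [l for l in loci if l.chrom == c]
        rows.append(
            {
                "chrom": c,
                "n_genes": sum(l.size for l in here),
                "n_loci": len(here),
                "n_clusters": sum(1 for l in here if l.kind == "cluster"),
                "length": (chrom_lengths or {}).get(c, pd.NA),
            }
        )
    per_chrom = pd.DataFrame(rows)
    clusters = assignment.clusters
    singles = assignment.singletons
    n_clustered = sum(l.size for l in clusters)
    totals = {
        "genes": n_clustered + len(singles),
        "loci": len(loci),
        "singletons": len(singles),
        "clusters": len(clusters),
        "clustered_genes": n_clustered,
        "mean_cluster_size": (n_clustered / len(clusters)) if clusters else float("nan"),
        "max_cluster_size": max((l.size for l in clusters), default=0),
        "percent_clustered": (
            100.0 * n_clustered / (n_clustered + len(singles))
            if loci
            else float("nan")
        ),
    }
    return {"per_chromosome": per_chrom, "totals": totals}


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    pvalue: float
    degenerate: bool = False


def length_correlation(
    per_chrom_counts: Mapping[str, int], chrom_lengths: Mapping[str, int]
) -> CorrelationResult:
    """Spearman rank correlation of family-member count vs chromosome length.

    Ties get midranks (scipy default).  Zero variance on either axis makes
    rho undefined; it is reported as 0 with the ``degenerate`` flag set.
    Requires at least 3 chromosomes present in both mappings.
    """
    chroms = sorted(set(per_chrom_counts) & set(chrom_lengths), key=chrom_sort_key)
    if len(chroms) < 3:
        raise InsufficientDataError(
            f"need >= 3 chromosomes for a rank correlation, got {len(chroms)}"
        )
    counts = [per_chrom_counts[c] for c in chroms]
    lengths = [chrom_lengths[c] for c in chroms]
    if len(set(counts)) == 1 or len(set(lengths)) == 1:
        return CorrelationResult(rho=0.0, pvalue=float("nan"), degenerate=True)
    rho, p = stats.spearmanr(counts, lengths)
    return CorrelationResult(rho=float(rho), pvalue=float(p), degenerate=False)
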