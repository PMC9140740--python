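"""Duplication-type classification over an all-vs-all similarity table.

Follows the widely used duplicate-gene-classifier convention: paralog pairs
are the top-5 non-self BLAST hits per query at E <= 1e-10; collinear
(syntenic) blocks are chains of at least 5 anchor pairs with rank gaps of at
most 25 genes on both axes; and each family member is labelled by
precedence WGD/segmental > tandem > proximal > dispersed > singleton.
Rank (gene-order) distance, not base-pair distance, defines tandem
(adjacent, distance 1) and proximal (distance <= 20 by default).

The block detector is an in-house dynamic programme: within each chromosome
pair, anchors are chained maximizing anchor count under the gap constraint,
with both collinearity orientations tried; best chains are peeled off
iteratively, so a region can yield several blocks and a gene may appear in
more than one block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GeneModel, HomologyHit, ValidationError, chrom_sort_key

__all__ = [
    "ParalogPair",
    "CollinearBlock",
    "DuplicationLabel",
    "find_paralog_pairs",
    "detect_collinear_blocks",
    "classify_duplications",
    "LABEL_ORDER",
]

LABEL_ORDER = ("wgd_segmental", "tandem", "proximal", "dispersed", "singleton")


@dataclass(frozen=True)
class ParalogPair:
    """Unordered paralogous gene pair (stored with gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"self-pair {self.gene_a}")
        if self.gene_a > self.gene_b:
            object.__setattr__(self, "gene_a", self.gene_b)
            object.__setattr__(self, "gene_b", self.gene_a)

    @property
    def genes(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    # anchors as ((gene_on_a, rank_a), (gene_on_b, rank_b)) in chain order
    anchors: tuple[tuple[tuple[str, int], tuple[str, int]], ...]
    score: float

    @property
    def genes(self) -> set[str]:
        return {a[0][0] for a in self.anchors} | {a[1][0] for a in self.anchors}


@dataclass(frozen=True)
class DuplicationLabel:
    gene_id: str
    label: str


def find_paralog_pairs(
    similarity: Iterable[HomologyHit],
    evalue_max: float = 1e-10,
    top_n_hits: int = 5,
) -> set[ParalogPair]:
    """Paralog pairs from an all-vs-all protein similarity table.

    Self-hits are dropped; per query only the ``top_n_hits`` best non-self
    subjects by bitscore survive; pairs are de-duplicated as unordered,
    keeping the best E-value/bitscore seen in either direction.
    """
    per_query: dict[str, dict[str, tuple[float, float]]] = {}
    for h in similarity:
        if h.query_id == h.target or h.evalue > evalue_max:
            continue
        best = per_query.setdefault(h.query_id, {})
        cur = best.get(h.target)
        if cur is None or (h.score, -h.evalue) > (cur[1], -cur[0]):
            best[h.target] = (h.evalue, h.score)
    pairs: dict[tuple[str, str], tuple[float, float]] = {}
    for query in sorted(per_query):
        ranked = sorted(
            per_query[query].items(), key=lambda kv: (-kv[1][1], kv[1][0], kv[0])
        )[:top_n_hits]
        for subject, (ev, bs) in ranked:
            key = (query, subject) if query < subject else (subject, query)
            cur = pairs.get(key)
            if cur is None or (bs, -ev) > (cur[1], -cur[0]):
                pairs[key] = (ev, bs)
    return {
        ParalogPair(gene_a=a, gene_b=b, evalue=ev, bitscore=bs)
        for (a, b), (ev, bs) in pairs.items()
    }


def _best_chain(
    anchors: Sequence[tuple[int, int]], max_gap: int
) -> list[int]:
    """Longest chain (as indices) with strictly increasing first ranks,
    strictly monotone second ranks of a single sign, and consecutive rank
    gaps <= max_gap on both axes.  O(n^2) DP per orientation; ties broken
    toward the lexicographically earliest index sequence."""
    n = len(anchors)
    if n == 0:
        return []
    best_overall: list[int] = []
    order = sorted(range(n), key=lambda i: (anchors[i][0], anchors[i][1], i))
    for sign in (+1, -1):
        dp = [1] * n
        parent = [-1] * n
        for oi in range(n):
            i = order[oi]
            ra, rb = anchors[i]
            for oj in range(oi):
                j = order[oj]
                qa, qb = anchors[j]
                if qa >= ra or ra - qa > max_gap:
                    continue
                if sign * (rb - qb) <= 0 or abs(rb - qb) > max_gap:
                    continue
                if dp[j] + 1 > dp[i]:
                    dp[i] = dp[j] + 1
                    parent[i] = j
        end = max(order, key=lambda i: (dp[i], -order.index(i)))
        chain: list[int] = []
        k = end
        while k != -1:
            chain.append(k)
            k = parent[k]
        chain.reverse()
        if len(chain) > len(best_overall):
            best_overall = chain
    return best_overall


def detect_collinear_blocks(
    pairs: Iterable[ParalogPair],
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    min_block_size: int = 5,
    max_gap: int = 25,
) -> list[CollinearBlock]:
    """Chain anchor pairs into collinear blocks per chromosome pair.

    Each paralog pair whose two genes are positioned becomes an anchor at
    (rank_a, rank_b).  Within a chromosome pair the best chain is extracted
    repeatedly (dynamic programme above) until it falls below
    ``min_block_size``; every extracted chain is one block.
    """
    if min_block_size <= 0 or max_gap <= 0:
        raise ValueError("min_block_size and max_gap must be positive")
    if not isinstance(genes, Mapping):
        genes = {g.gene_id: g for g in genes}

    grouped: dict[tuple[str, str], list[tuple[tuple[str, int], tuple[str, int]]]] = {}
    for p in sorted(pairs, key=lambda p: (p.gene_a, p.gene_b)):
        for gid in p.genes:
            if gid not in genes:
                raise ValidationError(f"paralog pair references unpositioned gene {gid!r}")
        ga, gb = genes[p.gene_a], genes[p.gene_b]
        # orient: lower chromosome (natural order) on the a-axis; same
        # chromosome -> lower rank on the a-axis
        if (chrom_sort_key(ga.chrom), ga.rank) > (chrom_sort_key(gb.chrom), gb.rank):
            ga, gb = gb, ga
        grouped.setdefault((ga.chrom, gb.chrom), []).append(
            ((ga.gene_id, ga.rank), (gb.gene_id, gb.rank))
        )

    blocks: list[CollinearBlock] = []
    for (ca, cb) in sorted(grouped, key=lambda k: (chrom_sort_key(k[0]), chrom_sort_key(k[1]))):
        remaining = grouped[(ca, cb)]
        while True:
            coords = [(a[1], b[1]) for a, b in remaining]
            chain = _best_chain(coords, max_gap=max_gap)
            if len(chain) < min_block_size:
                break
            picked = [remaining[i] for i in chain]
            blocks.append(
                CollinearBlock(chrom_a=ca, chrom_b=cb, anchors=tuple(picked), score=float(len(picked)))
            )
            chosen = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in chosen]
    return blocks


def classify_duplications(
    nbs_genes: Iterable[GeneModel],
    pairs: Iterable[ParalogPair],
    blocks: Iterable[CollinearBlock],
    proximal_max_rank_gap: int = 20,
) -> list[DuplicationLabel]:
    """Label every family member with exactly one duplication type.

    Precedence: wgd_segmental (anchor in any collinear block) > tandem
    (family paralog at rank distance 1 on the same chromosome) > proximal
    (family paralog at rank distance <= ``proximal_max_rank_gap`` on the same
    chromosome) > dispersed (any family paralog) > singleton.  Paralog
    partners must themselves be family members: the all-gene background
    contributes only gene ranks.
    """
    nbs_list = sorted(nbs_genes, key=lambda g: (chrom_sort_key(g.chrom), g.rank))
    nbs_ids = {g.gene_id for g in nbs_list}
    pos = {g.gene_id: g for g in nbs_list}

    block_members: set[str] = set()
    for b in blocks:
        for (ga, _), (gb, _) in b.anchors:
            block_members.add(ga)
            block_members.add(gb)

    partners: dict[str, set[str]] = {g: set() for g in nbs_ids}
    for p in pairs:
        if p.gene_a in nbs_ids and p.gene_b in nbs_ids:
            partners[p.gene_a].add(p.gene_b)
            partners[p.gene_b].add(p.gene_a)

    labels: list[DuplicationLabel] = []
    for g in nbs_list:
        if g.gene_id in block_members:
            label = "wgd_segmental"
        else:
            dists = [
                abs(pos[q].rank - g.rank)
                for q in partners[g.gene_id]
                if pos[q].chrom == g.chrom
            ]
            if any(d == 1 for d in dists):
                label = "tandem"
            elif any(d <= proximal_max_rank_gap for d in dists):
                label = "proximal"
            elif partners[g.gene_id]:
                label = "dispersed"
            else:
                label = "singleton"
        labels.append(DuplicationLabel(gene_id=g.gene_id, label=label))
    return labels
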