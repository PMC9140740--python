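"""Independent brute-force oracles used to cross-check the fast paths."""

from __future__ import annotations

from itertools import combinations


class DisjointSet:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_partition_bruteforce(genes, window):
    """O(n^2) pairwise window-linkage + union-find; returns the partition of
    gene ids as a set of frozensets (per chromosome, transitive closure)."""
    dsu = DisjointSet([g.gene_id for g in genes])
    for a, b in combinations(genes, 2):
        if a.chrom != b.chrom:
            continue
        # [start-w, end+w] of one overlaps the other's interval
        if a.start - window <= b.end and b.start - window <= a.end:
            dsu.union(a.gene_id, b.gene_id)
    groups: dict[str, set[str]] = {}
    for g in genes:
        groups.setdefault(dsu.find(g.gene_id), set()).add(g.gene_id)
    return {frozenset(v) for v in groups.values()}


def _chain_valid(anchors, idxs, max_gap, sign):
    for prev, cur in zip(idxs, idxs[1:]):
        pa, pb = anchors[prev]
        ca, cb = anchors[cur]
        if ca <= pa or ca - pa > max_gap:
            return False
        if sign * (cb - pb) <= 0 or abs(cb - pb) > max_gap:
            return False
    return True


def best_chain_bruteforce(anchors, max_gap):
    """Exhaustive maximum-anchor chain length over both orientations.

    Depth-first extension over anchors sorted by first rank; exponential but
    fine for <= 15 anchors.
    """
    n = len(anchors)
    order = sorted(range(n), key=lambda i: anchors[i])
    best = 0

    def extend(last_idx, length, sign, start_pos):
        nonlocal best
        best = max(best, length)
        for pos in range(start_pos, n):
            i = order[pos]
            if _chain_valid(anchors, [last_idx, i], max_gap, sign):
                extend(i, length + 1, sign, pos + 1)

    for sign in (+1, -1):
        for pos in range(n):
            extend(order[pos], 1, sign, pos + 1)
    return best
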