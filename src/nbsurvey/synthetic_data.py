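"""Synthetic genomes and gene trees with planted ground truth.

The generator emulates the statistical structure the survey assumes: a
multi-chromosome annotation carrying a configurable number of NBS-LRR genes
with planted domain architectures, planted singleton/cluster loci (internal
gaps under the 250-kb rule, inter-locus gaps above it), planted duplication
histories (adjacent tandem pairs, proximal copies at small gene-order
distance, segmental copies embedded in collinear anchor runs, dispersed
copies with remote partners), decoy candidates that fail the strict NBS
re-scan, and a birth-death gene tree over a 3-ingroup + 1-outgroup species
tree with a known ancestral copy number.

Every planted count in :class:`SimulationConfig` is recorded in the emitted
ground truth, so each pipeline stage can be checked for exact recovery.
Output is deterministic per (config, seed): identical inputs give
byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .io_formats import GeneModel, rank_genes, write_gff

__all__ = [
    "ConfigError",
    "TreePlan",
    "SimulationConfig",
    "GroundTruth",
    "TreeTruth",
    "simulate_genome",
    "simulate_gene_tree",
    "default_architecture_catalog",
]


class ConfigError(ValueError):
    pass


_LETTER = {"TIR": "T", "CC": "C", "RPW8": "R", "NBS": "N", "LRR": "L"}
_NTERM = {"CNL": "CC", "TNL": "TIR", "RNL": "RPW8"}
_DOMAIN_LEN = {"TIR": 170, "CC": 60, "RPW8": 130, "NBS": 280, "LRR": 230}
_ID_LEN = 100


def default_architecture_catalog() -> dict[str, list[tuple[tuple[str, ...], int]]]:
    """24 domain combinations: 7 CNL + 13 TNL + 4 RNL groups.

    The RNL groups (6 intact, 7 lacking LRR, 4 NBS-only, 1 RNRN) and the
    integrated-domain constraints (4 distinct IDs carried by 9 TNL genes,
    7 C-terminal and 2 N-terminal fusions) are fixed; the remaining group
    multiplicities are a fabricated but internally consistent catalog.
    """
    return {
        "CNL": [
            (("CC", "NBS", "LRR"), 18),
            (("CC", "NBS"), 8),
            (("NBS", "LRR"), 5),
            (("NBS",), 4),
            (("CC", "NBS", "LRR", "LRR"), 2),
            (("CC", "CC", "NBS", "LRR"), 2),
            (("CC", "NBS", "NBS"), 1),
        ],
        "TNL": [
            (("TIR", "NBS", "LRR"), 32),
            (("TIR", "NBS"), 12),
            (("NBS", "LRR"), 6),
            (("NBS",), 5),
            (("TIR", "NBS", "LRR", "LRR"), 4),
            (("TIR", "TIR", "NBS", "LRR"), 3),
            (("TIR", "NBS", "NBS"), 2),
            (("TIR", "NBS", "LRR", "MARCH1"), 2),
            (("TIR", "NBS", "MARCH1"), 2),
            (("TIR", "NBS", "LRR", "WRKY"), 2),
            (("TIR", "NBS", "LRR", "BED"), 1),
            (("BED", "TIR", "NBS", "LRR"), 1),
            (("PKinase", "TIR", "NBS", "LRR"), 1),
        ],
        "RNL": [
            (("RPW8", "NBS", "LRR"), 6),
            (("RPW8", "NBS"), 7),
            (("NBS",), 4),
            (("RPW8", "NBS", "RPW8", "NBS"), 1),
        ],
    }


def arch_string_of(tokens: Sequence[str]) -> str:
    """Canonical letters glue into runs; integrated-domain names hyphenate."""
    chunks: list[str] = []
    run = False
    for tok in tokens:
        if tok in _LETTER:
            if run:
                chunks[-1] += _LETTER[tok]
            else:
                chunks.append(_LETTER[tok])
            run = True
        else:
            chunks.append(tok)
            run = False
    return "-".join(chunks)


def _subclass_of_tokens(tokens: Sequence[str], planted: str) -> tuple[bool, list]:
    """intact flag + integrated domains for a planted (subclass, tokens)."""
    nterm = _NTERM[planted]
    intact = nterm in tokens and "LRR" in tokens
    first_nbs = tokens.index("NBS")
    ids = [
        [tok, "N" if i < first_nbs else "C"]
        for i, tok in enumerate(tokens)
        if tok not in _LETTER
    ]
    return intact, ids


@dataclass
class TreePlan:
    """Birth-death gene-tree plan over ((Ef,(Nc,Nt)), outgroup).

    ``k_per_subclass`` plants that many independent gene copies at the
    ingroup root per subclass; ``ef_present`` caps how many of them carry
    the Ef lineage (None: all do), planting the inheritance pattern
    deterministically.  ``expansion`` = (subclass, species, n_tips) grows a
    species-specific burst clade inside the first lineage of that subclass.
    """

    species_tree: str = "(Ef,(Nc,Nt));"
    outgroup: str = "Og"
    k_per_subclass: dict[str, int] = field(
        default_factory=lambda: {"CNL": 44, "TNL": 66, "RNL": 12}
    )
    birth: float = 0.25
    loss: float = 0.0
    ef_present: dict[str, int] | None = field(
        default_factory=lambda: {"CNL": 25, "TNL": 38, "RNL": 7}
    )
    expansion: tuple[str, str, int] | None = ("CNL", "Nc", 102)
    support_range: tuple[int, int] = (75, 100)
    max_retries: int = 20


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults mirror the surveyed genome's headline structure: 131 NBS-LRR
    genes (40 CNL / 73 TNL / 18 RNL) on 29 chromosomes of an annotation of
    21,837 genes (0.6%), 18 clusters covering 87 genes plus 44 singletons,
    duplication plan 28 tandem / 18 dispersed / 15 proximal / 70
    WGD-segmental, clusters concentrated on chromosomes 11/15/18 and no
    family member on chromosome 22.
    """

    n_chromosomes: int = 29
    genes_per_chromosome: int = 753
    n_nbs: int = 131
    subclass_mix: dict[str, int] = field(
        default_factory=lambda: {"CNL": 40, "TNL": 73, "RNL": 18}
    )
    architecture_catalog: dict[str, list[tuple[tuple[str, ...], int]]] = field(
        default_factory=default_architecture_catalog
    )
    cluster_sizes: tuple[int, ...] = (10, 9, 8, 7, 6, 6, 5, 5, 4, 4, 4, 4, 3, 3, 3, 2, 2, 2)
    duplication_plan: dict[str, int] = field(
        default_factory=lambda: {"tandem": 28, "dispersed": 18, "proximal": 15, "wgd_segmental": 70}
    )
    cluster_chromosomes: tuple[int, ...] = (11, 15, 18)
    empty_chromosomes: tuple[int, ...] = (22,)
    decoy_count: int = 25
    decoy_evalue_range: tuple[float, float] = (1e-3, 0.9)
    gap_range: tuple[int, int] = (5_000, 40_000)
    gene_length_range: tuple[int, int] = (1_000, 5_000)
    min_site_rank_gap: int = 60
    hit_table_inclusion: float = 0.85
    fraction_low: float = 0.7
    low_tpm_range: tuple[float, float] = (0.01, 0.5)
    expressed_tpm_range: tuple[float, float] = (2.0, 100.0)
    n_expression_samples: int = 3
    n_background_expression: int = 200
    adversarial: bool = False
    tree: TreePlan = field(default_factory=TreePlan)

    @classmethod
    def small(cls) -> "SimulationConfig":
        """A light plan for unit tests: 26 NBS genes on 5 chromosomes."""
        return cls(
            n_chromosomes=5,
            genes_per_chromosome=400,
            n_nbs=26,
            subclass_mix={"CNL": 10, "TNL": 10, "RNL": 6},
            architecture_catalog={
                "CNL": [(("CC", "NBS", "LRR"), 6), (("CC", "NBS"), 4)],
                "TNL": [
                    (("TIR", "NBS", "LRR"), 5),
                    (("TIR", "NBS"), 3),
                    (("TIR", "NBS", "LRR", "MARCH1"), 2),
                ],
                "RNL": [(("RPW8", "NBS", "LRR"), 3), (("RPW8", "NBS"), 2), (("NBS",), 1)],
            },
            cluster_sizes=(5, 4, 3),
            duplication_plan={"tandem": 4, "dispersed": 6, "proximal": 2, "wgd_segmental": 14},
            cluster_chromosomes=(2,),
            empty_chromosomes=(5,),
            decoy_count=6,
            n_background_expression=50,
            tree=TreePlan(
                k_per_subclass={"CNL": 8, "TNL": 8, "RNL": 4},
                ef_present={"CNL": 6, "TNL": 6, "RNL": 3},
                expansion=("CNL", "Nc", 12),
            ),
        )


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact-recovery checks."""

    nbs_ids: list[str]
    decoy_ids: list[str]
    subclass: dict[str, str]
    arch_string: dict[str, str]
    intact: dict[str, bool]
    integrated: dict[str, list]
    loci: list[dict]
    duplication: dict[str, str]
    blocks: list[list]
    expression_regime: dict[str, str]
    counts: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# plan validation and allocation
# ---------------------------------------------------------------------------

def _validate(cfg: SimulationConfig) -> dict:
    mix_total = sum(cfg.subclass_mix.values())
    if mix_total != cfg.n_nbs:
        raise ConfigError(f"subclass mix sums to {mix_total}, expected n_nbs={cfg.n_nbs}")
    for sub, groups in cfg.architecture_catalog.items():
        got = sum(n for _t, n in groups)
        want = cfg.subclass_mix.get(sub, 0)
        if got != want:
            raise ConfigError(f"architecture catalog for {sub} sums to {got}, expected {want}")
        for tokens, _n in groups:
            if "NBS" not in tokens:
                raise ConfigError(f"catalog entry {tokens} lacks an NBS domain")
    n_clustered = sum(cfg.cluster_sizes)
    if n_clustered > cfg.n_nbs:
        raise ConfigError("cluster plan covers more genes than n_nbs")
    if any(s < 2 for s in cfg.cluster_sizes):
        raise ConfigError("clusters need >= 2 members")
    dup_total = sum(cfg.duplication_plan.values())
    if dup_total != cfg.n_nbs:
        raise ConfigError(f"duplication plan sums to {dup_total}, expected {cfg.n_nbs}")
    n_tandem = cfg.duplication_plan.get("tandem", 0)
    n_prox = cfg.duplication_plan.get("proximal", 0)
    n_disp = cfg.duplication_plan.get("dispersed", 0)
    n_wgd = cfg.duplication_plan.get("wgd_segmental", 0)
    if n_tandem % 2:
        raise ConfigError("tandem count must be even (planted as adjacent pairs)")
    if n_wgd % 2:
        raise ConfigError("wgd_segmental count must be even (planted as anchor pairs)")
    if n_disp % 2:
        raise ConfigError("dispersed count must be even (planted as remote pairs)")
    if n_prox not in (0,) and n_prox < 2:
        raise ConfigError("proximal count must be 0 or >= 2")
    n_single = cfg.n_nbs - n_clustered
    wgd_single = n_single - n_disp
    if wgd_single < 0 or wgd_single > n_wgd:
        raise ConfigError(
            "singleton loci must be exactly the dispersed genes plus singleton "
            f"wgd copies; got {n_single} singles, {n_disp} dispersed, {n_wgd} wgd"
        )
    bad = set(cfg.cluster_chromosomes) & set(cfg.empty_chromosomes)
    if bad:
        raise ConfigError(f"chromosomes {bad} both cluster-bearing and empty")
    if max(cfg.cluster_chromosomes, default=0) > cfg.n_chromosomes or (
        cfg.empty_chromosomes and max(cfg.empty_chromosomes) > cfg.n_chromosomes
    ):
        raise ConfigError("chromosome index out of range")
    return {
        "n_tandem_pairs": n_tandem // 2,
        "n_prox": n_prox,
        "n_disp": n_disp,
        "n_wgd": n_wgd,
        "n_single": n_single,
        "wgd_single": wgd_single,
        "wgd_clustered": n_wgd - wgd_single,
    }


def _prox_units(n: int) -> list[int]:
    if n == 0:
        return []
    units = []
    if n % 2:
        units.append(3)
        n -= 3
    units.extend([2] * (n // 2))
    return sorted(units, reverse=True)


def _allocate_roles(cfg: SimulationConfig, plan: dict) -> list[dict]:
    """Fill each cluster with tandem pairs, proximal units and wgd copies."""
    sizes = sorted(cfg.cluster_sizes, reverse=True)
    remaining = list(sizes)
    alloc = [{"size": s, "tandem_pairs": 0, "prox_units": [], "wgd": 0} for s in sizes]

    def take(amount: int) -> int:
        best, best_i = -1, -1
        for i, r in enumerate(remaining):
            if r >= amount and r > best:
                best, best_i = r, i
        if best_i < 0:
            raise ConfigError("cluster plan cannot accommodate the duplication plan")
        remaining[best_i] -= amount
        return best_i

    for u in _prox_units(plan["n_prox"]):
        alloc[take(u)]["prox_units"].append(u)
    for _ in range(plan["n_tandem_pairs"]):
        alloc[take(2)]["tandem_pairs"] += 1
    if sum(remaining) != plan["wgd_clustered"]:
        raise ConfigError(
            f"cluster slots leave {sum(remaining)} wgd positions, plan needs "
            f"{plan['wgd_clustered']}"
        )
    for i, r in enumerate(remaining):
        alloc[i]["wgd"] = r
    return alloc


def _cluster_layout(entry: dict) -> list[tuple[int, str, int]]:
    """Member (offset, role, unit_id) list for one cluster.

    Tandem pairs are rank-adjacent; proximal-unit members sit 2 ranks apart
    (one background gene between); units are separated by 2 background
    genes, keeping every internal family gap <= 3 ranks (< 250 kb) while
    avoiding unintended adjacency.
    """
    members: list[tuple[int, str, int]] = []
    cur = 0
    unit = 0
    for _ in range(entry["tandem_pairs"]):
        members += [(cur, "tandem", unit), (cur + 1, "tandem", unit)]
        cur += 1 + 3
        unit += 1
    for u in entry["prox_units"]:
        for k in range(u):
            members.append((cur + 2 * k, "proximal", unit))
        cur += 2 * (u - 1) + 3
        unit += 1
    for _ in range(entry["wgd"]):
        members.append((cur, "wgd_segmental", unit))
        cur += 3
        unit += 1
    return members


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _f(x: float) -> str:
    return f"{x:.3g}"


def simulate_genome(
    cfg: SimulationConfig, seed: int, outdir: str | Path
) -> GroundTruth:
    """Emit genome.gff3, hit tables, all-vs-all table, expression matrix and
    truth.json under ``outdir``; return the :class:`GroundTruth`."""
    plan = _validate(cfg)
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chroms = [f"chr{i}" for i in range(1, cfg.n_chromosomes + 1)]
    cluster_chroms = [f"chr{i}" for i in cfg.cluster_chromosomes]
    empty = {f"chr{i}" for i in cfg.empty_chromosomes}
    single_chroms = [c for c in chroms if c not in empty and c not in set(cluster_chroms)]
    if not single_chroms and plan["n_single"]:
        raise ConfigError("no chromosomes left for singleton loci")

    alloc = _allocate_roles(cfg, plan)

    # sites: (chrom, span, member layout); singletons are 1-member sites
    sites_by_chrom: dict[str, list[dict]] = {c: [] for c in chroms}
    for i, entry in enumerate(alloc):
        layout = _cluster_layout(entry)
        chrom = cluster_chroms[i % len(cluster_chroms)]
        sites_by_chrom[chrom].append(
            {"kind": "cluster", "layout": layout, "span": max(o for o, _r, _u in layout) + 1}
        )
    single_roles = ["dispersed"] * plan["n_disp"] + ["wgd_segmental"] * plan["wgd_single"]
    for i, role in enumerate(single_roles):
        chrom = single_chroms[i % len(single_chroms)]
        sites_by_chrom[chrom].append(
            {"kind": "single", "layout": [(0, role, 0)], "span": 1}
        )

    # rank placement with guaranteed separation between sites
    sep = cfg.min_site_rank_gap
    nbs_slots: list[tuple[str, int, str, dict, int]] = []  # chrom, rank, role, site, unit
    site_records: list[dict] = []
    for chrom in chroms:
        sites = sites_by_chrom[chrom]
        if not sites:
            continue
        need = sum(s["span"] for s in sites) + (len(sites) + 1) * sep
        if need > cfg.genes_per_chromosome:
            raise ConfigError(
                f"{chrom}: sites need {need} gene ranks, chromosome has "
                f"{cfg.genes_per_chromosome}"
            )
        slack = cfg.genes_per_chromosome - need
        extra = rng.multinomial(slack, [1.0 / (len(sites) + 1)] * (len(sites) + 1))
        pos = 0
        for k, site in enumerate(sites):
            pos += sep + int(extra[k])
            members = []
            for off, role, unit in site["layout"]:
                nbs_slots.append((chrom, pos + off, role, site, unit))
                members.append(pos + off)
            site_records.append({"chrom": chrom, "kind": site["kind"], "ranks": members})
            pos += site["span"]

    # gene coordinates
    genes: list[GeneModel] = []
    nbs_rank_set = {(c, r) for c, r, _ro, _s, _u in nbs_slots}
    gid = 0
    id_by_slot: dict[tuple[str, int], str] = {}
    chrom_lengths: dict[str, int] = {}
    for chrom in chroms:
        pos = 0
        for rank in range(cfg.genes_per_chromosome):
            gap = int(rng.integers(cfg.gap_range[0], cfg.gap_range[1] + 1))
            length = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
            start = pos + gap
            end = start + length - 1
            pos = end
            gid += 1
            gene_id = f"g{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(chrom=chrom, start=start, end=end, gene_id=gene_id, strand=strand))
            id_by_slot[(chrom, rank)] = gene_id
        chrom_lengths[chrom] = pos + int(rng.integers(*cfg.gap_range))
    genes = rank_genes(genes)
    gene_by_id = {g.gene_id: g for g in genes}

    nbs_ids_ordered = [id_by_slot[(c, r)] for c, r, _ro, _s, _u in nbs_slots]
    role_of = {id_by_slot[(c, r)]: ro for c, r, ro, _s, _u in nbs_slots}

    # architecture assignment: dispersed slots get one subclass's catalog when
    # the counts line up (mirrors the surveyed RNLs being the non-syntenic,
    # scattered subclass); otherwise a global shuffle
    arch_pool: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
    for sub in sorted(cfg.architecture_catalog):
        pool = []
        for tokens, n in cfg.architecture_catalog[sub]:
            pool.extend([(sub, tokens)] * n)
        arch_pool[sub] = pool
    dispersed_ids = [g for g in nbs_ids_ordered if role_of[g] == "dispersed"]
    other_ids = [g for g in nbs_ids_ordered if role_of[g] != "dispersed"]
    match_sub = next(
        (s for s in ("RNL", "CNL", "TNL") if len(arch_pool.get(s, [])) == len(dispersed_ids)),
        None,
    )
    assignment: dict[str, tuple[str, tuple[str, ...]]] = {}
    if match_sub is not None and dispersed_ids:
        pool_d = arch_pool[match_sub][:]
        rng.shuffle(pool_d)
        for g, a in zip(dispersed_ids, pool_d):
            assignment[g] = a
        pool_o = [a for s in sorted(arch_pool) if s != match_sub for a in arch_pool[s]]
    else:
        pool_o = [a for s in sorted(arch_pool) for a in arch_pool[s]]
        other_ids = nbs_ids_ordered
    rng.shuffle(pool_o)
    for g, a in zip(other_ids, pool_o):
        assignment[g] = a

    subclass = {g: assignment[g][0] for g in nbs_ids_ordered}
    tokens_of = {g: assignment[g][1] for g in nbs_ids_ordered}

    # paralog pair plan
    pair_rows: list[tuple[str, str]] = []
    # tandem + proximal: pairs within units
    unit_members: dict[tuple[int, int], list[str]] = {}
    for idx, (c, r, ro, site, unit) in enumerate(nbs_slots):
        if ro in ("tandem", "proximal"):
            unit_members.setdefault((id(site), unit), []).append(id_by_slot[(c, r)])
    for key in sorted(unit_members, key=lambda k: unit_members[k][0]):
        mem = unit_members[key]
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                pair_rows.append((mem[i], mem[j]))
    # dispersed: consecutive remote pairs
    for i in range(0, len(dispersed_ids), 2):
        pair_rows.append((dispersed_ids[i], dispersed_ids[i + 1]))
    # wgd: first half paired with second half in genome order
    wgd_ids = [g for g in nbs_ids_ordered if role_of[g] == "wgd_segmental"]
    wgd_ids.sort(key=lambda g: (gene_by_id[g].chrom, gene_by_id[g].rank))
    half = len(wgd_ids) // 2
    wgd_pairs = list(zip(wgd_ids[:half], wgd_ids[half:]))
    for a, b in wgd_pairs:
        if gene_by_id[a].chrom == gene_by_id[b].chrom:
            raise ConfigError(
                "wgd pairing placed both copies on one chromosome; spread the "
                "plan over more chromosomes"
            )
        pair_rows.append((a, b))

    # collinear blocks: one 5-anchor run per wgd pair (2 background anchors
    # flanking the family anchor on each side)
    genes_sorted_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_sorted_by_chrom.setdefault(g.chrom, []).append(g)
    for c in genes_sorted_by_chrom:
        genes_sorted_by_chrom[c].sort(key=lambda g: g.rank)
    nbs_id_set = set(nbs_ids_ordered)

    def flanking_background(gene: GeneModel, n_each: int = 2) -> tuple[list[str], list[str]]:
        row = genes_sorted_by_chrom[gene.chrom]
        below, above = [], []
        r = gene.rank - 1
        while r >= 0 and len(below) < n_each:
            if row[r].gene_id not in nbs_id_set:
                below.append(row[r].gene_id)
            r -= 1
        r = gene.rank + 1
        while r < len(row) and len(above) < n_each:
            if row[r].gene_id not in nbs_id_set:
                above.append(row[r].gene_id)
            r += 1
        if len(below) < n_each or len(above) < n_each:
            raise ConfigError(f"not enough background genes around {gene.gene_id}")
        return below[::-1], above

    blocks_truth: list[list] = []
    background_pairs: list[tuple[str, str]] = []
    for a, b in wgd_pairs:
        ga, gb = gene_by_id[a], gene_by_id[b]
        a_below, a_above = flanking_background(ga)
        b_below, b_above = flanking_background(gb)
        anchors = list(zip(a_below, b_below)) + [(a, b)] + list(zip(a_above, b_above))
        for x, y in anchors:
            if x not in nbs_id_set:
                background_pairs.append((x, y))
        blocks_truth.append([list(p) for p in anchors])

    duplication = {g: role_of[g] for g in nbs_ids_ordered}

    # adversarial mode: wire the first tandem pair into a block through the
    # first proximal pair, so precedence must promote all four to wgd
    if cfg.adversarial:
        units_sorted = [unit_members[k] for k in sorted(unit_members, key=lambda k: unit_members[k][0])]
        t_units = [u for u in units_sorted if duplication[u[0]] == "tandem"]
        p_units = [u[:2] for u in units_sorted if duplication[u[0]] == "proximal"]
        t_pair = p_pair = None
        for tu in t_units:
            for pu in p_units:
                if gene_by_id[tu[0]].chrom != gene_by_id[pu[0]].chrom:
                    t_pair, p_pair = tu, pu
                    break
            if t_pair:
                break
        if t_pair is None:
            raise ConfigError(
                "adversarial mode needs a tandem pair and a proximal pair on "
                "different chromosomes; spread clusters over more chromosomes"
            )
        if True:
            t1, t2 = sorted(t_pair, key=lambda g: gene_by_id[g].rank)
            p1, p2 = sorted(p_pair, key=lambda g: gene_by_id[g].rank)
            a_below, _ = flanking_background(gene_by_id[t1])
            _, a_above = flanking_background(gene_by_id[t2])
            b_below, _ = flanking_background(gene_by_id[p1])
            _, b_above = flanking_background(gene_by_id[p2])
            anchors = list(zip(a_below, b_below)) + [(t1, p1), (t2, p2)] + list(
                zip(a_above, b_above)
            )
            for x, y in anchors:
                if x not in nbs_id_set:
                    background_pairs.append((x, y))
                else:
                    pair_rows.append((x, y))
            blocks_truth.append([list(p) for p in anchors])
            for g in (t1, t2, p1, p2):
                duplication[g] = "wgd_segmental"

    # ------------------------------------------------------------------
    # emit files
    # ------------------------------------------------------------------
    write_gff(genes, outdir / "genome.gff3")
    with open(outdir / "chrom_lengths.tsv", "w") as fh:
        fh.write("chrom\tlength\n")
        for c in chroms:
            fh.write(f"{c}\t{chrom_lengths[c]}\n")

    decoy_pool = [g.gene_id for g in genes if g.gene_id not in nbs_id_set]
    decoy_ids = sorted(
        rng.choice(decoy_pool, size=cfg.decoy_count, replace=False).tolist()
    ) if cfg.decoy_count else []

    def hmm_row(gene: str, profile: str, ev: float, score: float, qs: int, qe: int) -> str:
        return (
            f"{gene} - 900 {profile} - 300 {_f(ev)} {_f(score)} 0.1 1 1 "
            f"{_f(ev)} {_f(ev)} {_f(score)} 0.1 1 300 {qs} {qe} {qs} {qe} 0.95 -\n"
        )

    def blast_row(q: str, s: str, ev: float, score: float, qs: int, qe: int) -> str:
        return (
            f"{q}\t{s}\t88.5\t{qe - qs + 1}\t10\t1\t{qs}\t{qe}\t{qs}\t{qe}\t"
            f"{_f(ev)}\t{_f(score)}\n"
        )

    candidates = nbs_ids_ordered + decoy_ids
    with open(outdir / "hmm_hits.tsv", "w") as hmm_fh, open(
        outdir / "blast_hits.tsv", "w"
    ) as blast_fh:
        hmm_fh.write("# permissive NB-ARC search (E <= 1.0)\n")
        for g in candidates:
            ev = 10 ** rng.uniform(-40, -0.1)
            score = float(rng.uniform(30, 400))
            in_hmm = rng.random() < cfg.hit_table_inclusion
            in_blast = rng.random() < cfg.hit_table_inclusion
            if not in_hmm and not in_blast:
                in_hmm = True
            if in_hmm:
                hmm_fh.write(hmm_row(g, "NB-ARC", ev, score, 150, 420))
            if in_blast:
                blast_fh.write(blast_row(g, "NB-ARC", ev, score, 150, 420))

    with open(outdir / "rescan_hits.tsv", "w") as fh:
        fh.write("# strict NB-ARC re-scan (E <= 1e-4 confirms)\n")
        for g in nbs_ids_ordered:
            ev = 10 ** rng.uniform(-50, -6)
            fh.write(hmm_row(g, f"NB-ARC_{subclass[g]}", ev, float(rng.uniform(80, 500)), 150, 420))
        lo, hi = cfg.decoy_evalue_range
        for g in decoy_ids:
            ev = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            fh.write(hmm_row(g, "NB-ARC", ev, float(rng.uniform(5, 25)), 150, 420))

    with open(outdir / "cdd_domains.tsv", "w") as fh:
        for g in nbs_ids_ordered:
            pos = 1
            for tok in tokens_of[g]:
                length = _DOMAIN_LEN.get(tok, _ID_LEN)
                pos += int(rng.integers(10, 31))
                qs, qe = pos, pos + length - 1
                pos = qe + 1
                fh.write(blast_row(g, tok, 10 ** rng.uniform(-30, -10), float(rng.uniform(50, 300)), qs, qe))
        for g in decoy_ids:
            fh.write(blast_row(g, "PKinase", 10 ** rng.uniform(-20, -8), 120.0, 40, 300))

    with open(outdir / "allvall.tsv", "w") as fh:
        for g in nbs_ids_ordered:
            fh.write(blast_row(g, g, 0.0, 1500.0, 1, 900))
        for a, b in pair_rows + background_pairs:
            ev = 10 ** rng.uniform(-80, -30)
            score = float(rng.uniform(300, 900))
            fh.write(blast_row(a, b, ev, score, 1, 850))
            fh.write(blast_row(b, a, ev * 1.5, score - 5, 1, 850))
        # weak similarity noise above the paralog E-value cutoff
        n_noise = max(10, cfg.decoy_count)
        noise = rng.choice(decoy_pool, size=(n_noise, 2), replace=True)
        for a, b in noise:
            if a == b:
                continue
            fh.write(blast_row(str(a), str(b), 10 ** rng.uniform(-8, -3), float(rng.uniform(40, 60)), 1, 200))

    # expression
    samples = [f"S{i + 1}" for i in range(cfg.n_expression_samples)]
    regime = {
        g: ("low" if rng.random() < cfg.fraction_low else "expressed")
        for g in nbs_ids_ordered
    }
    with open(outdir / "expr.tsv", "w") as fh:
        fh.write("gene_id\t" + "\t".join(samples) + "\n")
        for g in nbs_ids_ordered:
            lo, hi = cfg.low_tpm_range if regime[g] == "low" else cfg.expressed_tpm_range
            vals = rng.uniform(lo, hi, size=len(samples))
            fh.write(g + "\t" + "\t".join(f"{v:.4f}" for v in vals) + "\n")
        for g in decoy_pool[: cfg.n_background_expression]:
            vals = rng.uniform(0.0, 50.0, size=len(samples))
            fh.write(g + "\t" + "\t".join(f"{v:.4f}" for v in vals) + "\n")

    # truth
    loci_truth = []
    for rec in site_records:
        members = sorted(
            (id_by_slot[(rec["chrom"], r)] for r in rec["ranks"]),
            key=lambda g: gene_by_id[g].rank,
        )
        loci_truth.append(
            {
                "chrom": rec["chrom"],
                "members": members,
                "kind": "cluster" if len(members) > 1 else "singleton",
            }
        )
    arch_string = {g: arch_string_of(tokens_of[g]) for g in nbs_ids_ordered}
    intact, integrated = {}, {}
    for g in nbs_ids_ordered:
        i_flag, ids = _subclass_of_tokens(tokens_of[g], subclass[g])
        intact[g] = i_flag
        integrated[g] = ids
    dup_counts: dict[str, int] = {}
    for g, lab in duplication.items():
        dup_counts[lab] = dup_counts.get(lab, 0) + 1
    counts = {
        "n_genes_total": len(genes),
        "n_nbs": len(nbs_ids_ordered),
        "subclass": {s: sum(1 for g in nbs_ids_ordered if subclass[g] == s)
                     for s in sorted(set(subclass.values()))},
        "loci": {
            "singletons": sum(1 for l in loci_truth if l["kind"] == "singleton"),
            "clusters": sum(1 for l in loci_truth if l["kind"] == "cluster"),
            "clustered_genes": sum(len(l["members"]) for l in loci_truth if l["kind"] == "cluster"),
            "cluster_sizes": sorted(
                (len(l["members"]) for l in loci_truth if l["kind"] == "cluster"), reverse=True
            ),
        },
        "duplication": dict(sorted(dup_counts.items())),
        "expression": {
            "low": sum(1 for v in regime.values() if v == "low"),
            "expressed": sum(1 for v in regime.values() if v == "expressed"),
        },
    }
    truth = GroundTruth(
        nbs_ids=sorted(nbs_ids_ordered),
        decoy_ids=decoy_ids,
        subclass=subclass,
        arch_string=arch_string,
        intact=intact,
        integrated=integrated,
        loci=loci_truth,
        duplication=duplication,
        blocks=blocks_truth,
        expression_regime=regime,
        counts=counts,
    )
    truth.to_json(outdir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# gene-tree simulation
# ---------------------------------------------------------------------------

@dataclass
class TreeTruth:
    k_total: int
    k_per_subclass: dict[str, int]
    n_surviving: int
    subclass_of_tip: dict[str, str]
    copies: list[dict]  # per ancestral copy: subclass, species tip counts
    inherited: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


class _N:
    __slots__ = ("children", "label")

    def __init__(self, children=None, label=None):
        self.children = children or []
        self.label = label


def _parse_species_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True
    )


def simulate_gene_tree(
    cfg: SimulationConfig, seed: int, outdir: str | Path
) -> TreeTruth:
    """Emit tree.nwk, tree_subclasses.tsv and tree_truth.json under ``outdir``.

    Each of the K planted ancestral copies evolves independently down the
    ingroup species tree under a birth-death process (rates per unit branch
    length); copies join above the ingroup root through duplication nodes,
    subclass by subclass, so subclasses stay monophyletic; a single outgroup
    tip roots the whole tree.
    """
    plan = cfg.tree
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sp_tree = _parse_species_tree(plan.species_tree)
    lam, mu = plan.birth, plan.loss
    tip_counter: dict[str, int] = {}
    subclass_of_tip: dict[str, str] = {}

    def new_tip(species: str, subclass: str) -> _N:
        tip_counter[subclass] = tip_counter.get(subclass, 0) + 1
        label = f"{species}_{subclass}{tip_counter[subclass]:04d}"
        subclass_of_tip[label] = subclass
        return _N(label=label)

    def branch_len(edge) -> float:
        return edge.length if edge.length is not None else 1.0

    def evolve(sp_node, t_remaining: float, subclass: str, burst: tuple[str, int] | None) -> _N | None:
        rate = lam + mu
        while True:
            w = rng.exponential(1.0 / rate) if rate > 0 else float("inf")
            if w < t_remaining:
                t_remaining -= w
                if rng.random() < (lam / rate if rate > 0 else 0):
                    left = evolve(sp_node, t_remaining, subclass, burst)
                    right = evolve(sp_node, t_remaining, subclass, None)
                    if left is not None and right is not None:
                        return _N(children=[left, right])
                    return left if left is not None else right
                return None  # loss
            break
        if sp_node.is_leaf():
            species = sp_node.taxon.label
            if burst is not None and burst[0] == species:
                tips = [new_tip(species, subclass) for _ in range(burst[1])]
                node = tips[0]
                for t in tips[1:]:
                    node = _N(children=[node, t])
                return node
            return new_tip(species, subclass)
        kids = []
        for child in sp_node.child_nodes():
            kids.append(evolve(child, branch_len(child.edge), subclass, burst))
        alive = [k for k in kids if k is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        node = alive[0]
        for k in alive[1:]:
            node = _N(children=[node, k])
        return node

    def make_copy(subclass: str, with_ef: bool, burst: tuple[str, int] | None) -> _N | None:
        root_children = sp_tree.seed_node.child_nodes()
        kids = []
        for child in root_children:
            species_below = {l.taxon.label for l in child.leaf_iter()}
            if not with_ef and species_below == {"Ef"}:
                continue
            kids.append(evolve(child, branch_len(child.edge), subclass, burst))
        alive = [k for k in kids if k is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        node = alive[0]
        for k in alive[1:]:
            node = _N(children=[node, k])
        return node

    def copy_species(node: _N, acc: set[str]) -> None:
        if not node.children:
            acc.add(node.label.split("_", 1)[0])
            return
        for c in node.children:
            copy_species(c, acc)

    for attempt in range(plan.max_retries):
        tip_counter.clear()
        subclass_of_tip.clear()
        copies_meta: list[dict] = []
        subclass_clades: list[_N] = []
        ok = True
        for subclass in sorted(plan.k_per_subclass):
            k = plan.k_per_subclass[subclass]
            if k < 1:
                continue
            n_ef = k if plan.ef_present is None else plan.ef_present.get(subclass, k)
            if n_ef > k or n_ef < 0:
                raise ConfigError(f"ef_present[{subclass}]={n_ef} outside 0..{k}")
            copies: list[_N] = []
            for i in range(k):
                burst = None
                if (
                    plan.expansion is not None
                    and plan.expansion[0] == subclass
                    and i == 0
                ):
                    burst = (plan.expansion[1], plan.expansion[2])
                node = make_copy(subclass, with_ef=i < n_ef, burst=burst)
                if node is not None:
                    copies.append(node)
                    sp: set[str] = set()
                    copy_species(node, sp)
                    tips: dict[str, int] = {}

                    def count_tips(n: _N) -> None:
                        if not n.children:
                            s = n.label.split("_", 1)[0]
                            tips[s] = tips.get(s, 0) + 1
                        else:
                            for c in n.children:
                                count_tips(c)

                    count_tips(node)
                    copies_meta.append({"subclass": subclass, "tips": tips})
            if not copies:
                ok = False
                break
            clade = copies[0]
            for c in copies[1:]:
                clade = _N(children=[clade, c])
            subclass_clades.append(clade)
        if ok and subclass_clades:
            break
        warnings.warn(f"all gene copies lost (attempt {attempt + 1}); regenerating")
    else:
        raise ConfigError("birth-death simulation lost every copy in every retry")

    ingroup_root = subclass_clades[0]
    for clade in subclass_clades[1:]:
        ingroup_root = _N(children=[ingroup_root, clade])
    out_tip = _N(label=f"{plan.outgroup}_out0001")
    root = _N(children=[ingroup_root, out_tip])

    # convert to dendropy with supports and branch lengths
    tree = dendropy.Tree()
    tns = tree.taxon_namespace

    def convert(n: _N) -> dendropy.Node:
        node = dendropy.Node()
        if not n.children:
            node.taxon = tns.new_taxon(label=n.label)
        else:
            node.support = float(rng.integers(plan.support_range[0], plan.support_range[1] + 1))
            for c in n.children:
                child = convert(c)
                node.add_child(child)
        node.edge.length = round(float(rng.uniform(0.01, 0.3)), 4)
        return node

    tree.seed_node = convert(root)
    tree.is_rooted = True
    from .io_formats import write_tree

    write_tree(tree, outdir / "tree.nwk")
    with open(outdir / "tree_subclasses.tsv", "w") as fh:
        fh.write("tip\tsubclass\n")
        for tip in sorted(subclass_of_tip):
            fh.write(f"{tip}\t{subclass_of_tip[tip]}\n")

    inherited: dict[str, int] = {}
    for meta in copies_meta:
        for sp in meta["tips"]:
            inherited[sp] = inherited.get(sp, 0) + 1
    truth = TreeTruth(
        k_total=sum(plan.k_per_subclass.values()),
        k_per_subclass=dict(sorted(plan.k_per_subclass.items())),
        n_surviving=len(copies_meta),
        subclass_of_tip=subclass_of_tip,
        copies=copies_meta,
        inherited=dict(sorted(inherited.items())),
    )
    truth.to_json(outdir / "tree_truth.json")
    return truth
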