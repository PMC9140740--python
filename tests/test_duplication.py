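import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbsurvey.duplication import (
    CollinearBlock,
    ParalogPair,
    _best_chain,
    classify_duplications,
    detect_collinear_blocks,
    find_paralog_pairs,
)
from nbsurvey.io_formats import GeneModel, HomologyHit, rank_genes

from oracles import best_chain_bruteforce


def hit(q, s, ev=1e-50, score=500.0):
    return HomologyHit(
        query_id=q, target=s, evalue=ev, score=score, q_start=1, q_end=100, source="blast"
    )


def pair(a, b):
    return ParalogPair(gene_a=a, gene_b=b, evalue=1e-50, bitscore=500.0)


# ---------------------------------------------------------------------------
# paralog pairs
# ---------------------------------------------------------------------------

def test_self_hits_excluded_and_pairs_deduplicated():
    pairs = find_paralog_pairs([hit("a", "a"), hit("a", "b", 1e-50), hit("b", "a", 1e-48)])
    assert len(pairs) == 1
    (p,) = pairs
    assert p.genes == ("a", "b")


def test_top_n_best_subjects_kept():
    hits = [hit("q", f"s{i}", score=100.0 + i) for i in range(8)]
    pairs = find_paralog_pairs(hits, top_n_hits=5)
    partners = {p.gene_b if p.gene_a == "q" else p.gene_a for p in pairs}
    assert partners == {"s7", "s6", "s5", "s4", "s3"}


def test_planted_pairs_recovered_against_decoys():
    """30 true pairs below the E cutoff, 10 decoys above it."""
    rng = np.random.default_rng(4)
    hits = []
    truth = set()
    for i in range(30):
        a, b = f"t{2 * i}", f"t{2 * i + 1}"
        truth.add((a, b))
        hits.append(hit(a, b, ev=10 ** rng.uniform(-80, -20)))
    for i in range(10):
        hits.append(hit(f"d{2 * i}", f"d{2 * i + 1}", ev=10 ** rng.uniform(-9, -3)))
    pairs = find_paralog_pairs(hits, evalue_max=1e-10)
    assert {p.genes for p in pairs} == truth


# ---------------------------------------------------------------------------
# collinearity chaining
# ---------------------------------------------------------------------------

def _genes_for(anchors):
    """Two chromosomes whose ranks cover the anchor coordinates."""
    n = max(max(a, b) for a, b in anchors) + 1
    gs = []
    for chrom in ("chrA", "chrB"):
        for r in range(n):
            gs.append(GeneModel(chrom=chrom, start=1 + 10_000 * r, end=10_000 * r + 2_000,
                                gene_id=f"{chrom}.{r}"))
    return {g.gene_id: g for g in rank_genes(gs)}


def _pairs_for(anchors):
    return {pair(f"chrA.{a}", f"chrB.{b}") for a, b in anchors}


def test_clean_diagonal_one_block():
    anchors = [(0, 0), (2, 1), (3, 3), (5, 4), (6, 6), (8, 8)]
    blocks = detect_collinear_blocks(_pairs_for(anchors), _genes_for(anchors))
    assert len(blocks) == 1 and len(blocks[0].anchors) == 6


def test_below_min_block_size_reports_nothing():
    anchors = [(0, 0), (1, 1), (2, 2), (3, 3)]
    assert detect_collinear_blocks(_pairs_for(anchors), _genes_for(anchors)) == []


def test_antidiagonal_orientation_detected():
    anchors = [(0, 10), (1, 8), (2, 6), (3, 4), (4, 2), (5, 0)]
    blocks = detect_collinear_blocks(_pairs_for(anchors), _genes_for(anchors))
    assert len(blocks) == 1 and len(blocks[0].anchors) == 6


def test_interleaved_diagonals_split_into_two_blocks():
    d1 = [(i, i) for i in range(6)]
    d2 = [(i, 60 + i) for i in range(6)]
    anchors = [v for z in zip(d1, d2) for v in z]
    blocks = detect_collinear_blocks(_pairs_for(anchors), _genes_for(anchors))
    assert len(blocks) == 2
    assert sorted(len(b.anchors) for b in blocks) == [6, 6]
    got = {frozenset((a[0][1], a[1][1]) for a in b.anchors) for b in blocks}
    assert got == {frozenset(d1), frozenset(d2)}
    # matches the exhaustive best-chain oracle for the first extraction
    assert len(blocks[0].anchors) == best_chain_bruteforce(anchors, 25)


def test_unpositioned_gene_rejected():
    from nbsurvey.io_formats import ValidationError

    with pytest.raises(ValidationError, match="unpositioned"):
        detect_collinear_blocks({pair("x", "y")}, {})


@given(
    anchors=st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30)), min_size=1, max_size=12,
        unique=True,
    ),
    max_gap=st.integers(1, 30),
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_dp_chain_equals_exhaustive_enumeration(anchors, max_gap):
    # distinct a-ranks come from distinct genes; duplicates on one axis are fine
    chain = _best_chain(anchors, max_gap=max_gap)
    assert len(chain) == best_chain_bruteforce(anchors, max_gap)
    # returned chain is itself valid
    for i, j in zip(chain, chain[1:]):
        (pa, pb), (ca, cb) = anchors[i], anchors[j]
        assert 0 < ca - pa <= max_gap
        assert 0 < abs(cb - pb) <= max_gap


# ---------------------------------------------------------------------------
# duplication typing
# ---------------------------------------------------------------------------

def _nbs(chrom, rank):
    return GeneModel(
        chrom=chrom, start=1 + 10_000 * rank, end=10_000 * rank + 2_000,
        gene_id=f"{chrom}.n{rank}", rank=rank,
    )


def labels_of(genes, pairs, blocks, **kw):
    return {
        l.gene_id: l.label for l in classify_duplications(genes, pairs, blocks, **kw)
    }


def test_adjacent_paralogs_are_tandem():
    a, b = _nbs("chr1", 7), _nbs("chr1", 8)
    out = labels_of([a, b], {pair(a.gene_id, b.gene_id)}, [])
    assert out == {a.gene_id: "tandem", b.gene_id: "tandem"}


def test_rank_gap_classifies_proximal_vs_dispersed():
    a, b, c = _nbs("chr1", 0), _nbs("chr1", 15), _nbs("chr1", 90)
    out = labels_of([a, b, c], {pair(a.gene_id, b.gene_id), pair(a.gene_id, c.gene_id)}, [])
    assert out[b.gene_id] == "proximal"
    assert out[c.gene_id] == "dispersed"
    assert out[a.gene_id] == "proximal"  # nearest qualifying partner wins


def test_block_membership_beats_tandem():
    a, b = _nbs("chr1", 7), _nbs("chr1", 8)
    other = _nbs("chr2", 7)
    block = CollinearBlock(
        chrom_a="chr1", chrom_b="chr2",
        anchors=(((a.gene_id, 7), (other.gene_id, 7)),), score=1.0,
    )
    out = labels_of([a, b, other], {pair(a.gene_id, b.gene_id)}, [block])
    assert out[a.gene_id] == "wgd_segmental"
    assert out[b.gene_id] == "tandem"


def test_no_paralog_is_singleton():
    a = _nbs("chr1", 3)
    assert labels_of([a], set(), []) == {a.gene_id: "singleton"}


def test_labels_partition_fixture_and_match_truth(small_fixture):
    d, cfg, truth, _tt = small_fixture
    from nbsurvey.io_formats import read_gff, read_hit_table

    genes = read_gff(d / "genome.gff3")
    by_id = {g.gene_id: g for g in genes}
    pairs = find_paralog_pairs(read_hit_table(d / "allvall.tsv", "blast_tab12"))
    blocks = detect_collinear_blocks(pairs, by_id)
    nbs = [by_id[g] for g in truth.nbs_ids]
    out = labels_of(nbs, pairs, blocks)
    assert out == truth.duplication
    counts: dict[str, int] = {}
    for v in out.values():
        counts[v] = counts.get(v, 0) + 1
    assert sum(counts.values()) == cfg.n_nbs
    assert counts == cfg.duplication_plan

    # precedence monotonicity: dropping all blocks only demotes wgd genes
    without = labels_of(nbs, pairs, [])
    for g, lab in out.items():
        if lab == "wgd_segmental":
            assert without[g] != "wgd_segmental"
        else:
            assert without[g] == lab


def test_adversarial_precedence_conflicts_resolved(tmp_path):
    """Tandem/proximal pairs wired into a collinear block must come out
    wgd_segmental by precedence."""
    from collections import Counter

    from nbsurvey.pipeline_report import inputs_from_dir, run_pipeline
    from nbsurvey.synthetic_data import SimulationConfig, simulate_genome

    cfg = SimulationConfig.small()
    cfg.cluster_chromosomes = (2, 3)
    cfg.genes_per_chromosome = 600
    cfg.adversarial = True
    truth = simulate_genome(cfg, 3, tmp_path)
    counts = Counter(truth.duplication.values())
    assert counts["wgd_segmental"] == cfg.duplication_plan["wgd_segmental"] + 4
    rep = run_pipeline(inputs_from_dir(tmp_path))
    assert rep.duplication["labels"] == truth.duplication
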