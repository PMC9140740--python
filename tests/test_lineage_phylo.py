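from itertools import combinations_with_replacement

import dendropy
import pytest

from nbsurvey.io_formats import read_tree
from nbsurvey.lineage_phylo import (
    EmptyReconciliationError,
    collapse_low_support,
    count_ancestral_lineages,
    detect_expansions,
    reconcile,
)
from nbsurvey.synthetic_data import SimulationConfig, TreePlan, simulate_gene_tree

INGROUP = ("Ef", "Nc", "Nt")


def tree_from(newick, tmp_path, name="t.nwk"):
    p = tmp_path / name
    p.write_text(newick + "\n")
    return read_tree(p)


def n_children_of_root(tree):
    return len(tree.seed_node.child_nodes())


# ---------------------------------------------------------------------------
# support collapsing
# ---------------------------------------------------------------------------

def test_collapse_noop_when_all_supported(tmp_path):
    t = tree_from("((Ef_a:1,Nc_b:1)100:1,(Ef_c:1,Nt_d:1)100:1);", tmp_path)
    c = collapse_low_support(t, 50)
    assert sum(1 for _ in c.preorder_internal_node_iter()) == sum(
        1 for _ in t.preorder_internal_node_iter()
    )


def test_collapse_single_weak_edge(tmp_path):
    t = tree_from("((Ef_a:1,Nc_b:1)30:1,(Ef_c:1,Nt_d:1)90:1);", tmp_path)
    c = collapse_low_support(t, 50)
    assert n_children_of_root(c) == 3  # cherry dissolved into the root
    assert sum(1 for _ in c.leaf_node_iter()) == 4


def test_collapse_everything_gives_star(tmp_path):
    newick = "(((Ef_a:1,Ef_b:1)60:1,(Nc_c:1,Nc_d:1)70:1)80:1,(Nt_e:1,Nt_f:1)90:1);"
    t = tree_from(newick, tmp_path)
    c = collapse_low_support(t, 101)
    assert n_children_of_root(c) == 6
    assert sum(1 for _ in c.preorder_internal_node_iter()) == 1


# ---------------------------------------------------------------------------
# species-overlap reconciliation
# ---------------------------------------------------------------------------

def test_cherry_events(tmp_path):
    t = tree_from("((Ef_1:1,Nc_1:1):1,Og_x:1);", tmp_path)
    rec = reconcile(t, INGROUP)
    cherry = t.seed_node.child_nodes()[0]
    assert rec.event_of(cherry) == "speciation"
    t2 = tree_from("((Ef_1:1,Ef_2:1):1,Og_x:1);", tmp_path, "t2.nwk")
    rec2 = reconcile(t2, INGROUP)
    cherry2 = t2.seed_node.child_nodes()[0]
    assert rec2.event_of(cherry2) == "duplication"


def test_overlap_rule_over_all_species_set_pairs(tmp_path):
    """Exhaustive check: a join of clades with species sets A and B is a
    duplication iff A and B intersect, for every pair of non-empty subsets
    of the three ingroup species."""
    subsets = [("Ef",), ("Nc",), ("Nt",), ("Ef", "Nc"), ("Ef", "Nt"), ("Nc", "Nt"),
               ("Ef", "Nc", "Nt")]
    for A, B in combinations_with_replacement(subsets, 2):
        def clade(species, tag):
            tips = [f"{s}_{tag}{i}" for i, s in enumerate(species)]
            return tips[0] if len(tips) == 1 else "(" + ",".join(tips) + ")"
        newick = f"(({clade(A, 'a')},{clade(B, 'b')}),Og_x);"
        t = tree_from(newick, tmp_path, "pair.nwk")
        rec = reconcile(t, INGROUP)
        join = t.seed_node.child_nodes()[0]
        expected = "duplication" if set(A) & set(B) else "speciation"
        assert rec.event_of(join) == expected, (A, B)


def test_outgroup_excluded_and_empty_ingroup_rejected(tmp_path):
    t = tree_from("((Ef_1:1,Og_y:1):1,Og_x:1);", tmp_path)
    rec = reconcile(t, INGROUP)
    assert rec.species_of(t.seed_node) == frozenset({"Ef"})
    t2 = tree_from("(Og_a:1,Og_b:1);", tmp_path, "og.nwk")
    with pytest.raises(EmptyReconciliationError):
        reconcile(t2, INGROUP)


# ---------------------------------------------------------------------------
# lineage counting
# ---------------------------------------------------------------------------

def count(newick, tmp_path, **kw):
    t = tree_from(newick, tmp_path, "c.nwk")
    rec = reconcile(t, INGROUP)
    return count_ancestral_lineages(rec, **kw)


def test_two_lineage_hand_example(tmp_path):
    """Root duplication spanning the 3-species ancestor cuts into 2 lineages."""
    rep = count("((Ef_1:1,Nc_1:1):1,(Ef_2:1,Nt_1:1):1);", tmp_path)
    assert rep.total == 2
    assert rep.inherited == {"Ef": 2, "Nc": 1, "Nt": 1}


def test_single_copy_species_topology_is_one_lineage(tmp_path):
    rep = count("(Ef_1:1,(Nc_1:1,Nt_1:1):1);", tmp_path)
    assert rep.total == 1
    assert rep.inherited == {"Ef": 1, "Nc": 1, "Nt": 1}


def test_within_species_duplications_do_not_split_lineages(tmp_path):
    rep = count("(((Ef_1:1,Ef_2:1):1,Nc_1:1):1,Og_x:1);", tmp_path)
    assert rep.total == 1
    assert rep.lineages[0].species_counts == {"Ef": 2, "Nc": 1}


def test_lineage_count_invariant_to_rotation_and_relabeling(tmp_path):
    a = count("((Ef_1:1,Nc_1:1):1,(Ef_2:1,Nt_1:1):1);", tmp_path)
    b = count("((Nt_9:1,Ef_7:1):1,(Nc_5:1,Ef_8:1):1);", tmp_path)
    assert a.total == b.total
    assert a.inherited == b.inherited


def test_subclass_totals_and_tie_error(tmp_path):
    newick = "((Ef_1:1,Nc_1:1):1,(Ef_2:1,Nt_1:1):1);"
    t = tree_from(newick, tmp_path, "s.nwk")
    rec = reconcile(t, INGROUP)
    rep = count_ancestral_lineages(
        rec, subclass_map={"Ef_1": "CNL", "Nc_1": "CNL", "Ef_2": "TNL", "Nt_1": "TNL"}
    )
    assert rep.totals_by_subclass == {"CNL": 1, "TNL": 1}
    with pytest.raises(ValueError, match="tie"):
        count_ancestral_lineages(
            rec, subclass_map={"Ef_1": "CNL", "Nc_1": "TNL", "Ef_2": "CNL", "Nt_1": "TNL"}
        )


# ---------------------------------------------------------------------------
# against the birth-death simulator
# ---------------------------------------------------------------------------

def _run_tree(tmp_path, plan, seed):
    cfg = SimulationConfig.small()
    cfg.tree = plan
    truth = simulate_gene_tree(cfg, seed, tmp_path)
    tree = read_tree(tmp_path / "tree.nwk")
    rec = reconcile(tree, INGROUP)
    rep = count_ancestral_lineages(rec, subclass_map=truth.subclass_of_tip)
    return truth, rep


def test_no_loss_recovers_planted_copy_number(tmp_path):
    for seed in range(103, 113):
        plan = TreePlan(k_per_subclass={"CNL": 7}, loss=0.0, birth=0.4,
                        ef_present=None, expansion=None)
        truth, rep = _run_tree(tmp_path, plan, seed)
        assert rep.total == truth.k_total == 7


def test_loss_never_inflates_the_count(tmp_path):
    for seed in range(200, 215):
        plan = TreePlan(k_per_subclass={"CNL": 10}, loss=0.25, birth=0.3,
                        ef_present=None, expansion=None)
        truth, rep = _run_tree(tmp_path, plan, seed)
        assert 1 <= rep.total <= truth.k_total


def test_planted_inheritance_pattern_recovered(tmp_path):
    plan = TreePlan(k_per_subclass={"CNL": 10, "TNL": 6}, loss=0.0, birth=0.2,
                    ef_present={"CNL": 4, "TNL": 5}, expansion=None)
    truth, rep = _run_tree(tmp_path, plan, 42)
    assert rep.total == 16
    assert rep.inherited["Ef"] == 9
    assert rep.inherited["Nc"] == rep.inherited["Nt"] == 16
    assert rep.totals_by_subclass == {"CNL": 10, "TNL": 6}


def test_collapse_moves_lineage_count_toward_tip_count(tmp_path):
    """Contracting edges dissolves resolved nodes into root-mapping
    multifurcations, so the count stays within [1, n ingroup tips] and the
    fully collapsed star attains the tip-count maximum; a tree whose
    supports all clear the threshold is untouched."""
    for seed in (7, 8, 9):
        cfg = SimulationConfig.small()
        cfg.tree = TreePlan(k_per_subclass={"CNL": 12}, loss=0.1, birth=0.5,
                            ef_present=None, expansion=None, support_range=(20, 100))
        simulate_gene_tree(cfg, seed, tmp_path)
        tree = read_tree(tmp_path / "tree.nwk")
        n_tips = sum(
            1 for l in tree.leaf_node_iter() if l.species in INGROUP
        )
        base = count_ancestral_lineages(reconcile(tree, INGROUP)).total
        collapsed = count_ancestral_lineages(
            reconcile(collapse_low_support(tree, 80), INGROUP)
        ).total
        assert 1 <= base <= n_tips
        assert 1 <= collapsed <= n_tips
        star = count_ancestral_lineages(
            reconcile(collapse_low_support(tree, 101), INGROUP)
        ).total
        assert star == n_tips
        untouched = count_ancestral_lineages(
            reconcile(collapse_low_support(tree, 0), INGROUP)
        ).total
        assert untouched == base


def test_expansion_burst_tops_the_table(tmp_path):
    plan = TreePlan(k_per_subclass={"CNL": 6, "TNL": 4}, loss=0.0, birth=0.1,
                    ef_present=None, expansion=("CNL", "Nc", 30))
    truth, rep = _run_tree(tmp_path, plan, 5)
    table = detect_expansions(rep, min_size=10)
    assert len(table) >= 1
    top = table.iloc[0]
    assert top["species"] == "Nc" and top["count"] >= 30
    burst_lineage = next(l for l in rep.lineages if l.lineage_id == top["lineage_id"])
    assert burst_lineage.subclass == "CNL"
    assert detect_expansions(rep, min_size=10**6).empty
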