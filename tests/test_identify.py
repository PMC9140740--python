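import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nbsurvey.identify import (
    build_domain_annotations,
    classify_architecture,
    merge_candidates,
    profile_hints_from_rescan,
    strict_rescan_filter,
    summarize_architecture_groups,
    DomainAnnotation,
    DomainSegment,
)
from nbsurvey.io_formats import HomologyHit, read_hit_table
from nbsurvey.synthetic_data import GroundTruth


def hit(q, target="NB-ARC", ev=1e-20, qs=1, qe=100, source="hmm", score=100.0):
    return HomologyHit(
        query_id=q, target=target, evalue=ev, score=score, q_start=qs, q_end=qe,
        source=source,
    )


# ---------------------------------------------------------------------------
# candidate merge + strict re-scan
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "hmm,blast,expected",
    [
        (["a", "b", "c"], ["b", "c", "d"], {"a", "b", "c", "d"}),
        ([], ["x"], {"x"}),
        ([], [], set()),
    ],
)
def test_merge_candidates_is_union(hmm, blast, expected):
    assert merge_candidates([hit(q) for q in hmm], [hit(q) for q in blast]) == expected


def test_merge_distinct_count_matches_independent_tally():
    rng = np.random.default_rng(3)
    ids = [f"g{i}" for i in range(137)]
    hmm = [hit(ids[rng.integers(len(ids))]) for _ in range(120)]
    blast = [hit(x) for x in ids] + [hit(ids[rng.integers(len(ids))]) for _ in range(80)]
    independent = len(set(h.query_id for h in hmm) | set(h.query_id for h in blast))
    assert independent == 137
    assert len(merge_candidates(hmm, blast)) == 137


def test_strict_rescan_threshold_boundary():
    cands = {"keep", "drop"}
    hits = [hit("keep", ev=5e-5), hit("drop", ev=2e-3)]
    assert strict_rescan_filter(cands, hits) == {"keep"}


def test_strict_rescan_ignores_strays_with_warning():
    with pytest.warns(UserWarning, match="not in the candidate set"):
        out = strict_rescan_filter({"a"}, [hit("a", ev=1e-9), hit("zz", ev=1e-9)])
    assert out == {"a"}


@given(
    evalues=st.lists(st.floats(min_value=1e-30, max_value=1.0), min_size=1, max_size=30),
    t_pair=st.tuples(
        st.floats(min_value=1e-8, max_value=1e-2), st.floats(min_value=1e-8, max_value=1e-2)
    ),
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_strict_rescan_is_monotone_in_threshold(evalues, t_pair):
    """Lowering the threshold never adds genes."""
    cands = {f"g{i}" for i in range(len(evalues))}
    hits = [hit(f"g{i}", ev=e) for i, e in enumerate(evalues)]
    lo, hi = min(t_pair), max(t_pair)
    assert strict_rescan_filter(cands, hits, lo) <= strict_rescan_filter(cands, hits, hi)


def test_planted_decoys_rejected_exactly(small_fixture):
    d, _cfg, truth, _tt = small_fixture
    hmm = read_hit_table(d / "hmm_hits.tsv", "hmm_tab")
    blast = read_hit_table(d / "blast_hits.tsv", "blast_tab12")
    rescan = read_hit_table(d / "rescan_hits.tsv", "hmm_tab")
    candidates = merge_candidates(hmm, blast)
    assert candidates == set(truth.nbs_ids) | set(truth.decoy_ids)
    assert strict_rescan_filter(candidates, rescan) == set(truth.nbs_ids)


# ---------------------------------------------------------------------------
# architecture classification
# ---------------------------------------------------------------------------

def annot(gene, *names, start=1, step=100):
    segs = []
    pos = start
    for n in names:
        segs.append(DomainSegment(n, pos, pos + step - 21, 1e-12, "cdd"))
        pos += step
    return DomainAnnotation(gene_id=gene, segments=segs)


@pytest.mark.parametrize(
    "names,arch,subclass,intact,ids",
    [
        (("RPW8", "NBS", "RPW8", "NBS"), "RNRN", "RNL", False, ()),
        (("TIR", "NBS", "LRR"), "TNL", "TNL", True, ()),
        (("TIR", "NBS", "LRR", "MARCH1"), "TNL-MARCH1", "TNL", True, (("MARCH1", "C"),)),
        (("BED", "TIR", "NBS", "LRR"), "BED-TNL", "TNL", True, (("BED", "N"),)),
        (("CC", "NBS"), "CN", "CNL", False, ()),
        (("CC", "TIR", "NBS", "LRR"), "CTNL", "TNL", True, ()),  # TIR beats CC
        (("RPW8", "TIR", "NBS"), "RTN", "RNL", False, ()),  # RPW8 beats TIR
    ],
)
def test_architecture_calls(names, arch, subclass, intact, ids):
    call = classify_architecture(annot("g", *names))
    assert call.arch_string == arch
    assert call.subclass == subclass
    assert call.intact is intact
    assert call.integrated_domains == ids


def test_nbs_only_falls_back_to_profile_hint():
    call = classify_architecture(annot("g", "NBS"))
    assert call.subclass == "NL-ambiguous"
    call = classify_architecture(annot("g", "NBS"), profile_hint="RNL")
    assert call.subclass == "RNL" and call.intact is False


def test_no_nbs_segment_is_an_error():
    with pytest.raises(ValueError, match="no NBS"):
        classify_architecture(annot("g", "TIR", "LRR"))


def test_classification_invariant_to_coordinate_scaling():
    a = annot("g", "TIR", "NBS", "LRR", "WRKY")
    scaled = DomainAnnotation(
        gene_id="g",
        segments=[
            DomainSegment(s.name, s.q_start * 7, s.q_end * 7, s.evalue, s.source)
            for s in a.segments
        ],
    )
    assert classify_architecture(a) == classify_architecture(scaled)


def test_domain_merging_rules():
    # same-name overlapping hits merge; different-name overlap keeps lower E
    hits = [
        hit("g", "NBS", ev=1e-20, qs=100, qe=200, source="cdd"),
        hit("g", "NBS", ev=1e-15, qs=180, qe=300, source="hmm"),
        hit("g", "LRR", ev=1e-5, qs=250, qe=400, source="cdd"),  # overlaps merged NBS
        hit("g", "TIR", ev=1e-9, qs=1, qe=80, source="cdd"),
    ]
    ann = build_domain_annotations(hits)["g"]
    assert [(s.name, s.q_start, s.q_end) for s in ann.segments] == [
        ("TIR", 1, 80),
        ("NBS", 100, 300),
    ]


def test_profile_hints_take_best_evalue():
    hits = [
        hit("g", "NB-ARC_CNL", ev=1e-6),
        hit("g", "NB-ARC_TNL", ev=1e-12),
        hit("h", "NB-ARC", ev=1e-12),  # no subclass suffix -> no hint
    ]
    assert profile_hints_from_rescan(hits) == {"g": "TNL"}


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

def test_rnl_group_table_mirrors_four_group_split():
    """18 RNLs split 6 intact / 7 no-LRR / 4 NBS-only / 1 RNRN."""
    calls = (
        [classify_architecture(annot(f"a{i}", "RPW8", "NBS", "LRR")) for i in range(6)]
        + [classify_architecture(annot(f"b{i}", "RPW8", "NBS")) for i in range(7)]
        + [classify_architecture(annot(f"c{i}", "NBS"), "RNL") for i in range(4)]
        + [classify_architecture(annot("d0", "RPW8", "NBS", "RPW8", "NBS"))]
    )
    table = summarize_architecture_groups(calls)
    assert len(table) == 4
    assert int(table["count"].sum()) == 18
    intact_row = table[table["arch_string"] == "RNL"].iloc[0]
    assert intact_row["count"] == 6
    assert intact_row["percent"] == pytest.approx(100 * 6 / 18)  # prints as 33.3%
    assert table.groupby("subclass")["percent"].sum().round(6).eq(100.0).all()


def test_group_table_single_call():
    table = summarize_architecture_groups([classify_architecture(annot("g", "TIR", "NBS"))])
    assert len(table) == 1 and table.iloc[0]["percent"] == 100.0


def test_fixture_group_table_matches_planted_catalog(small_fixture):
    d, cfg, truth, _tt = small_fixture
    rescan = read_hit_table(d / "rescan_hits.tsv", "hmm_tab")
    hints = profile_hints_from_rescan(rescan)
    domains = read_hit_table(d / "cdd_domains.tsv", "blast_tab12", source="cdd")
    annots = build_domain_annotations(
        h for h in domains if h.query_id in set(truth.nbs_ids)
    )
    calls = [
        classify_architecture(a, profile_hint=hints.get(g)) for g, a in annots.items()
    ]
    table = summarize_architecture_groups(calls)
    # every planted (subclass, multiplicity) recovered exactly
    from nbsurvey.synthetic_data import arch_string_of

    want = {
        (sub, arch_string_of(tokens)): n
        for sub, groups in cfg.architecture_catalog.items()
        for tokens, n in groups
    }
    got = {
        (r["subclass"], r["arch_string"]): int(r["count"]) for _, r in table.iterrows()
    }
    assert got == want
    # subclass totals sum to the confirmed total
    assert int(table["count"].sum()) == cfg.n_nbs
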