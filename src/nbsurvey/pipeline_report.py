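"""End-to-end survey orchestration and paper-style report assembly.

``run_pipeline`` executes identify -> cluster -> duplication -> lineage ->
expression over a set of input files, cross-checks the internal count
identities (subclass counts sum to the confirmed total, duplication labels
partition the gene set, loci = singletons + clusters), and assembles a
:class:`SurveyReport` that can be serialized to JSON (full precision) and
Markdown (display rounding).  Percentages follow the printed convention:
whole percents for duplication shares, one decimal for within-subclass
group shares.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .io_formats import (
    read_expression,
    read_gff,
    read_hit_table,
    read_tree,
)
from .identify import (
    build_domain_annotations,
    classify_architecture,
    merge_candidates,
    profile_hints_from_rescan,
    strict_rescan_filter,
    summarize_architecture_groups,
)
from .cluster_map import call_clusters, distribution_summary, length_correlation
from .duplication import classify_duplications, detect_collinear_blocks, find_paralog_pairs
from .expression_summary import classify_expression
from .lineage_phylo import (
    collapse_low_support,
    count_ancestral_lineages,
    detect_expansions,
    reconcile,
)

__all__ = [
    "SurveyReport",
    "ReportInconsistencyError",
    "DEFAULT_PARAMS",
    "run_pipeline",
    "format_percent",
    "summarize_percentages",
    "report_to_json",
    "report_to_markdown",
]


class ReportInconsistencyError(RuntimeError):
    pass


DEFAULT_PARAMS: dict[str, Any] = {
    "strict_evalue": 1e-4,
    "window": 250_000,
    "anchor": "interval",
    "paralog_evalue": 1e-10,
    "top_n_hits": 5,
    "min_block_size": 5,
    "max_gap": 25,
    "proximal_max_rank_gap": 20,
    "min_support": 50.0,
    "ingroup": ("Ef", "Nc", "Nt"),
    "species_tree": "(Ef,(Nc,Nt));",
    "expansion_min": 10,
    "low_threshold": 1.0,
}

#: default file names inside a fixture/input directory
DEFAULT_FILES = {
    "gff": "genome.gff3",
    "hmm_hits": "hmm_hits.tsv",
    "blast_hits": "blast_hits.tsv",
    "rescan_hits": "rescan_hits.tsv",
    "cdd_domains": "cdd_domains.tsv",
    "allvall": "allvall.tsv",
    "chrom_lengths": "chrom_lengths.tsv",
    "tree": "tree.nwk",
    "tree_subclasses": "tree_subclasses.tsv",
    "expr": "expr.tsv",
}


@dataclass
class SurveyReport:
    totals: dict
    architecture_groups: pd.DataFrame
    architecture_calls: dict
    locus: dict
    duplication: dict
    lineage: dict
    expression: dict
    provenance: dict
    complete: bool = True
    errors: list = field(default_factory=list)


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ReportInconsistencyError(message)


def run_pipeline(
    inputs: Mapping[str, str | Path],
    params: Mapping[str, Any] | None = None,
) -> SurveyReport:
    """Run every stage over the named input files.

    ``inputs`` maps the keys of :data:`DEFAULT_FILES` to paths; ``tree``,
    ``tree_subclasses``, ``chrom_lengths`` and ``expr`` are optional (their
    report sections are marked skipped when absent).
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    errors: list[str] = []

    # --- identify ----------------------------------------------------
    genes = read_gff(inputs["gff"])
    gene_by_id = {g.gene_id: g for g in genes}
    hmm_hits = read_hit_table(inputs["hmm_hits"], "hmm_tab")
    blast_hits = read_hit_table(inputs["blast_hits"], "blast_tab12")
    rescan_hits = read_hit_table(inputs["rescan_hits"], "hmm_tab")
    candidates = merge_candidates(hmm_hits, blast_hits)
    confirmed = strict_rescan_filter(candidates, rescan_hits, threshold=p["strict_evalue"])
    hints = profile_hints_from_rescan(rescan_hits)

    domain_hits = read_hit_table(inputs["cdd_domains"], "blast_tab12", source="cdd")
    annotations = build_domain_annotations(h for h in domain_hits if h.query_id in confirmed)
    calls = {
        g: classify_architecture(annotations[g], profile_hint=hints.get(g))
        for g in sorted(confirmed)
        if g in annotations
    }
    groups = summarize_architecture_groups(calls.values())
    subclass_counts: dict[str, int] = {}
    for c in calls.values():
        subclass_counts[c.subclass] = subclass_counts.get(c.subclass, 0) + 1
    _check(sum(subclass_counts.values()) == len(calls), "subclass counts do not sum to total")
    _check(int(groups["count"].sum()) == len(calls) if len(calls) else True,
           "architecture group counts do not sum to total")

    totals = {
        "n_genes_annotated": len(genes),
        "n_candidates": len(candidates),
        "n_confirmed": len(calls),
        "subclass": dict(sorted(subclass_counts.items())),
        "nbs_fraction_pct": 100.0 * len(calls) / len(genes) if genes else float("nan"),
    }

    # --- cluster -----------------------------------------------------
    nbs_genes = [gene_by_id[g] for g in sorted(calls) if g in gene_by_id]
    assignment = call_clusters(nbs_genes, window=p["window"], anchor=p["anchor"])
    chrom_lengths = None
    if inputs.get("chrom_lengths") and Path(inputs["chrom_lengths"]).exists():
        cl = pd.read_csv(inputs["chrom_lengths"], sep="\t")
        chrom_lengths = dict(zip(cl["chrom"], cl["length"]))
    summary = distribution_summary(assignment, chrom_lengths)
    t = summary["totals"]
    _check(t["genes"] == t["clustered_genes"] + t["singletons"],
           "locus totals: genes != clustered + singletons")
    _check(t["loci"] == t["clusters"] + t["singletons"],
           "locus totals: loci != clusters + singletons")
    _check(t["genes"] == len(nbs_genes), "locus totals: not all confirmed genes assigned")
    locus_section = {
        "totals": t,
        "per_chromosome": summary["per_chromosome"],
        "assignment": assignment,
    }
    if chrom_lengths is not None and len(summary["per_chromosome"]) >= 3:
        counts = dict(
            zip(summary["per_chromosome"]["chrom"], summary["per_chromosome"]["n_genes"])
        )
        corr = length_correlation(counts, chrom_lengths)
        locus_section["length_correlation"] = {
            "rho": corr.rho, "pvalue": corr.pvalue, "degenerate": corr.degenerate,
        }

    # --- duplication -------------------------------------------------
    similarity = read_hit_table(inputs["allvall"], "blast_tab12")
    pairs = find_paralog_pairs(
        similarity, evalue_max=p["paralog_evalue"], top_n_hits=p["top_n_hits"]
    )
    blocks = detect_collinear_blocks(
        pairs, gene_by_id, min_block_size=p["min_block_size"], max_gap=p["max_gap"]
    )
    labels = classify_duplications(
        nbs_genes, pairs, blocks, proximal_max_rank_gap=p["proximal_max_rank_gap"]
    )
    dup_counts: dict[str, int] = {}
    for l in labels:
        dup_counts[l.label] = dup_counts.get(l.label, 0) + 1
    _check(sum(dup_counts.values()) == len(nbs_genes),
           "duplication labels do not partition the gene set")
    nbs_set = set(calls)
    nbs_syntenic_pairs = sorted(
        {
            (a[0][0], a[1][0])
            for b in blocks
            for a in b.anchors
            if a[0][0] in nbs_set and a[1][0] in nbs_set
        }
    )
    duplication_section = {
        "counts": dict(sorted(dup_counts.items())),
        "labels": {l.gene_id: l.label for l in labels},
        "n_blocks": len(blocks),
        "blocks": blocks,
        "nbs_syntenic_pairs": nbs_syntenic_pairs,
    }

    # --- lineage (optional) ------------------------------------------
    lineage_section: dict = {"skipped": True}
    tree_path = inputs.get("tree")
    if tree_path and Path(tree_path).exists():
        try:
            tree = read_tree(tree_path)
            tree = collapse_low_support(tree, min_support=p["min_support"])
            rec = reconcile(tree, p["ingroup"])
            subclass_map = None
            sc_path = inputs.get("tree_subclasses")
            if sc_path and Path(sc_path).exists():
                sc = pd.read_csv(sc_path, sep="\t")
                subclass_map = dict(zip(sc["tip"], sc["subclass"]))
            rep = count_ancestral_lineages(
                rec, species_tree=p["species_tree"], subclass_map=subclass_map
            )
            expansions = detect_expansions(rep, min_size=p["expansion_min"])
            lineage_section = {
                "skipped": False,
                "total": rep.total,
                "by_subclass": dict(sorted(rep.totals_by_subclass.items())),
                "inherited": rep.inherited,
                "expansions": expansions,
                "report": rep,
            }
        except Exception as exc:  # stage failure: keep earlier results
            errors.append(f"lineage stage failed: {exc}")
            lineage_section = {"skipped": True, "error": str(exc)}

    # --- expression (optional) ---------------------------------------
    expression_section: dict = {"skipped": True}
    expr_path = inputs.get("expr")
    if expr_path and Path(expr_path).exists():
        try:
            matrix = read_expression(expr_path)
            es = classify_expression(matrix, set(calls), low_threshold=p["low_threshold"])
            expression_section = {
                "skipped": False,
                "n_low": sum(1 for c in es.calls if c.level == "low"),
                "n_expressed": sum(1 for c in es.calls if c.level == "expressed"),
                "fraction_low": es.fraction_low,
                "missing": es.missing,
                "calls": es.calls,
            }
        except Exception as exc:
            errors.append(f"expression stage failed: {exc}")
            expression_section = {"skipped": True, "error": str(exc)}

    provenance = {
        "tool": "nbsurvey",
        "version": __version__,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in p.items()},
    }
    return SurveyReport(
        totals=totals,
        architecture_groups=groups,
        architecture_calls={
            g: {
                "subclass": c.subclass,
                "arch_string": c.arch_string,
                "intact": c.intact,
                "integrated_domains": [list(x) for x in c.integrated_domains],
            }
            for g, c in calls.items()
        },
        locus=locus_section,
        duplication=duplication_section,
        lineage=lineage_section,
        expression=expression_section,
        provenance=provenance,
        complete=not errors,
        errors=errors,
    )


def inputs_from_dir(fixture_dir: str | Path) -> dict[str, Path]:
    d = Path(fixture_dir)
    return {key: d / name for key, name in DEFAULT_FILES.items()}


# ---------------------------------------------------------------------------
# percentage formatting and serialization
# ---------------------------------------------------------------------------

def format_percent(numerator: float, denominator: float, decimals: int = 0) -> str:
    """Printed-convention percentage; ``N/A`` on a zero denominator."""
    if denominator == 0:
        return "N/A"
    pct = 100.0 * numerator / denominator
    if decimals == 0:
        return f"{pct:.0f}%"
    return f"{pct:.{decimals}f}%"


def summarize_percentages(report: SurveyReport) -> dict[str, str]:
    """Display-rounded percentage fields: whole percents for duplication
    shares, one decimal for within-subclass architecture-group shares."""
    out: dict[str, str] = {}
    n = report.totals["n_confirmed"]
    for label, count in report.duplication["counts"].items():
        out[f"duplication_{label}"] = format_percent(count, n, 0)
    g = report.architecture_groups
    for _, row in g.iterrows():
        key = f"group_{row['subclass']}_{row['arch_string']}"
        sub_total = int(g.loc[g["subclass"] == row["subclass"], "count"].sum())
        out[key] = format_percent(row["count"], sub_total, 1)
    out["nbs_fraction"] = format_percent(
        report.totals["n_confirmed"], report.totals["n_genes_annotated"], 1
    )
    return out


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if True] if isinstance(obj, set) else [
            _jsonable(v) for v in obj
        ]
    if hasattr(obj, "__dataclass_fields__"):
        return {
            f: _jsonable(getattr(obj, f))
            for f in obj.__dataclass_fields__
            if f not in ("tree",)
        }
    if isinstance(obj, (pd.Timestamp,)):
        return str(obj)
    try:
        json.dumps(obj)
        return obj
    except TypeError:
        return str(obj)


def report_to_json(report: SurveyReport, path: str | Path) -> None:
    """Full-precision machine-readable report (stable ordering)."""
    payload = {
        "totals": _jsonable(report.totals),
        "architecture_groups": _jsonable(report.architecture_groups),
        "architecture_calls": _jsonable(report.architecture_calls),
        "locus": {
            k: _jsonable(v) for k, v in report.locus.items() if k != "assignment"
        },
        "loci": [
            {
                "locus_id": l.locus_id,
                "chrom": l.chrom,
                "kind": l.kind,
                "n_genes": l.size,
                "span_start": l.span_start,
                "span_end": l.span_end,
                "members": list(l.members),
            }
            for l in report.locus["assignment"].loci
        ],
        "duplication": {
            "counts": report.duplication["counts"],
            "labels": report.duplication["labels"],
            "n_blocks": report.duplication["n_blocks"],
            "nbs_syntenic_pairs": [list(p) for p in report.duplication["nbs_syntenic_pairs"]],
        },
        "lineage": {
            k: _jsonable(v) for k, v in report.lineage.items() if k != "report"
        },
        "expression": {
            k: _jsonable(v) for k, v in report.expression.items() if k != "calls"
        },
        "percent_display": summarize_percentages(report),
        "provenance": _jsonable(report.provenance),
        "complete": report.complete,
        "errors": report.errors,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def report_to_markdown(report: SurveyReport, path: str | Path) -> None:
    """Human-readable summary mirroring every number in the JSON."""
    lines: list[str] = ["# NBS-LRR survey report", ""]
    t = report.totals
    lines.append(
        f"Confirmed NBS-LRR genes: **{t['n_confirmed']}** of {t['n_genes_annotated']} "
        f"annotated genes ({format_percent(t['n_confirmed'], t['n_genes_annotated'], 1)})."
    )
    lines.append(
        "Subclasses: "
        + ", ".join(f"{k} {v}" for k, v in t["subclass"].items())
    )
    lines.append("")
    lines.append("## Architecture groups")
    lines.append(report.architecture_groups.to_string(index=False))
    lines.append("")
    lt = report.locus["totals"]
    lines.append("## Chromosomal distribution")
    lines.append(
        f"{lt['genes']} genes in {lt['loci']} loci: {lt['singletons']} singletons and "
        f"{lt['clusters']} clusters covering {lt['clustered_genes']} genes "
        f"(mean cluster size {lt['mean_cluster_size']:.2f}, max {lt['max_cluster_size']})."
    )
    if "length_correlation" in report.locus:
        c = report.locus["length_correlation"]
        lines.append(
            f"Spearman count-vs-length: rho={c['rho']:.3f}, p={c['pvalue']:.3g}"
            + (" (degenerate)" if c["degenerate"] else "")
        )
    lines.append("")
    lines.append("## Duplication types")
    n = t["n_confirmed"]
    for label, count in report.duplication["counts"].items():
        lines.append(f"- {label}: {count} ({format_percent(count, n, 0)})")
    lines.append(f"- collinear blocks: {report.duplication['n_blocks']}")
    lines.append("")
    lines.append("## Ancestral lineages")
    if report.lineage.get("skipped"):
        lines.append("skipped (no tree provided)")
    else:
        lines.append(
            f"{report.lineage['total']} ancestral lineages ("
            + ", ".join(f"{k} {v}" for k, v in report.lineage["by_subclass"].items())
            + "); inherited: "
            + ", ".join(f"{k} {v}" for k, v in report.lineage["inherited"].items())
        )
    lines.append("")
    lines.append("## Expression")
    if report.expression.get("skipped"):
        lines.append("skipped (no matrix provided)")
    else:
        e = report.expression
        lines.append(
            f"{e['n_low']} low / {e['n_expressed']} expressed "
            f"(fraction low {e['fraction_low']:.3f})"
        )
    if not report.complete:
        lines.append("")
        lines.append("## INCOMPLETE: " + "; ".join(report.errors))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
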