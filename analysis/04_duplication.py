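#!/usr/bin/env python
"""Classify each NBS-LRR gene's duplication type.

Builds paralog pairs from the all-vs-all similarity table, chains collinear
blocks, applies the precedence classifier, and writes
results/duplication_labels.tsv and results/collinear_blocks.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from nbsurvey.duplication import (
    classify_duplications,
    detect_collinear_blocks,
    find_paralog_pairs,
)
from nbsurvey.io_formats import read_gff, read_hit_table
from nbsurvey.pipeline_report import format_percent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    genes = read_gff(args.fixtures / "genome.gff3")
    by_id = {g.gene_id: g for g in genes}
    nbs_ids = set(
        pd.read_csv(args.outdir / "architecture_calls.tsv", sep="\t")["gene_id"]
    )
    pairs = find_paralog_pairs(read_hit_table(args.fixtures / "allvall.tsv", "blast_tab12"))
    blocks = detect_collinear_blocks(pairs, by_id)
    labels = classify_duplications([by_id[g] for g in sorted(nbs_ids)], pairs, blocks)

    pd.DataFrame([{"gene_id": l.gene_id, "label": l.label} for l in labels]).to_csv(
        args.outdir / "duplication_labels.tsv", sep="\t", index=False
    )
    with open(args.outdir / "collinear_blocks.tsv", "w") as fh:
        fh.write("block_id\tchrom_a\tchrom_b\tgene_a\trank_a\tgene_b\trank_b\n")
        for i, b in enumerate(blocks, 1):
            for (ga, ra), (gb, rb) in b.anchors:
                fh.write(f"B{i:03d}\t{b.chrom_a}\t{b.chrom_b}\t{ga}\t{ra}\t{gb}\t{rb}\n")

    counts = pd.Series([l.label for l in labels]).value_counts().to_dict()
    n = len(labels)
    print(f"{len(pairs)} paralog pairs, {len(blocks)} collinear blocks")
    for label in ("tandem", "dispersed", "proximal", "wgd_segmental", "singleton"):
        if label in counts:
            print(f"  {label}: {counts[label]} ({format_percent(counts[label], n)})")
    assert sum(counts.values()) == n, "labels must partition the gene set"


if __name__ == "__main__":
    main()
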