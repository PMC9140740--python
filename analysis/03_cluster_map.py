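#!/usr/bin/env python
"""Anchor confirmed NBS-LRR genes to chromosomes and call 250-kb clusters.

Writes results/loci.tsv (one row per locus) and prints the locus totals,
the per-chromosome distribution, and the count-vs-length rank correlation.
"""

import argparse
from pathlib import Path

import pandas as pd

from nbsurvey.cluster_map import call_clusters, distribution_summary, length_correlation
from nbsurvey.io_formats import read_gff


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixtures", type=Path, default=Path("results/fixtures"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--window", type=int, default=250_000)
    args = ap.parse_args()

    calls = pd.read_csv(args.outdir / "architecture_calls.tsv", sep="\t")
    nbs_ids = set(calls["gene_id"])
    genes = [g for g in read_gff(args.fixtures / "genome.gff3") if g.gene_id in nbs_ids]
    assignment = call_clusters(genes, window=args.window)

    pd.DataFrame(
        [
            {
                "locus_id": l.locus_id, "chrom": l.chrom, "kind": l.kind,
                "n_genes": l.size, "span_start": l.span_start,
                "span_end": l.span_end, "members": ",".join(l.members),
            }
            for l in assignment.loci
        ]
    ).to_csv(args.outdir / "loci.tsv", sep="\t", index=False)

    lengths = pd.read_csv(args.fixtures / "chrom_lengths.tsv", sep="\t")
    lengths_map = dict(zip(lengths["chrom"], lengths["length"]))
    summary = distribution_summary(assignment, lengths_map)
    t = summary["totals"]
    print(
        f"{t['genes']} genes in {t['loci']} loci: {t['singletons']} singletons + "
        f"{t['clusters']} clusters ({t['clustered_genes']} genes, "
        f"mean {t['mean_cluster_size']:.2f} ~ {round(t['mean_cluster_size'])} per cluster, "
        f"max {t['max_cluster_size']})"
    )
    per = summary["per_chromosome"]
    occupied = per[per["n_genes"] > 0]
    print(
        f"family members on {len(occupied)}/{len(per)} chromosomes; "
        f"empty: {', '.join(per.loc[per['n_genes'] == 0, 'chrom'])}"
    )
    counts = dict(zip(per["chrom"], per["n_genes"]))
    corr = length_correlation(counts, lengths_map)
    verdict = "not correlated" if corr.degenerate or corr.pvalue > 0.05 else "correlated"
    print(
        f"count vs chromosome length: Spearman rho={corr.rho:.3f}, "
        f"p={corr.pvalue:.3g} -> {verdict}"
    )


if __name__ == "__main__":
    main()
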