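# nbsurvey

A genome-wide survey toolkit for the NBS-LRR (NLR) disease resistance gene
family — the largest class of plant resistance genes, defined by a
nucleotide-binding site (NBS/NB-ARC) and leucine-rich repeats (LRR), and
divided into TNL, CNL and RNL subclasses by the N-terminal domain (TIR,
coiled-coil, or RPW8). The package is aimed at comparative genomicists
characterizing the family in a newly assembled plant genome: it takes the
standard upstream artifacts (GFF3 annotation, HMMER/BLAST hit tables, an
all-vs-all protein similarity table, a rooted gene tree, an expression
matrix) and produces the family profile end to end.

The five analysis stages, each exposed as a library module, a CLI
subcommand, and a numbered driver under `analysis/`:

1. **Identification** — merge a permissive NB-ARC profile-HMM scan with a
   permissive BLASTp search, confirm candidates by a strict re-scan
   (E ≤ 10⁻⁴), and classify domain architectures into subclasses and
   combination groups (including integrated domains fused at either
   terminus).
2. **Cluster calling** — two family members share a locus when the
   window w = 250 kb around one gene overlaps the other; loci are the
   transitive closure of this relation, computed by an exact sweep.
3. **Duplication typing** — paralog pairs (top-5 hits, E ≤ 10⁻¹⁰) are
   chained into collinear blocks by dynamic programming (≥ 5 anchors,
   rank gap ≤ 25), and every gene is labelled by precedence
   `wgd_segmental > tandem > proximal > dispersed > singleton`.
4. **Ancestral lineages** — species-overlap reconciliation of a rooted
   gene tree: a node is a duplication iff two children share ingroup
   species; duplications mapping to the ingroup root are cut, and the
   surviving subtrees are the gene copies present in the common
   ancestor (a lower bound under gene loss).
5. **Expression profile** — family members are called low vs expressed by
   mean TPM against a 1.0 threshold.

A first-class synthetic-data module (`nbsurvey.synthetic_data`) generates
multi-chromosome genomes and birth–death gene trees with planted ground
truth for every stage, so the whole pipeline is validated by exact
recovery of what was planted.

## Worked example

Running the numbered drivers on the default synthetic study conditions:

```
python analysis/01_simulate.py        # writes results/fixtures/
python analysis/02_identify.py
python analysis/03_cluster_map.py
python analysis/04_duplication.py
python analysis/05_lineages.py
python analysis/06_report.py          # consolidated report.json / report.md
```

prints, in order:

```
156 merged candidates -> 131 confirmed after strict re-scan
subclasses: {'TNL': 73, 'CNL': 40, 'RNL': 18}; 24 distinct domain combinations
9 genes carry integrated (non-canonical) domains

131 genes in 62 loci: 44 singletons + 18 clusters (87 genes, mean 4.83 ~ 5 per cluster, max 10)
family members on 28/29 chromosomes; empty: chr22
count vs chromosome length: Spearman rho=-0.289, p=0.128 -> not correlated

197 paralog pairs, 30 collinear blocks
  tandem: 28 (21%)
  dispersed: 18 (14%)
  proximal: 15 (11%)
  wgd_segmental: 70 (53%)

122 ancestral lineages at the 3-species common ancestor (CNL 44, RNL 12, TNL 66)
inherited per species: Ef 70, Nc 122, Nt 122
largest species-specific expansion: lineage C001 with 103 Nc genes

fraction of family at low expression: 0.702
```

Reading the numbers: of 21,837 annotated genes, 131 (0.6%) are confirmed
family members, split 40 CNL / 73 TNL / 18 RNL across 24 domain
combinations. They occupy 62 loci — 44 singletons plus 18 multigene
clusters holding 87 genes (about five per cluster) — with one chromosome
empty. Segmental/WGD duplication dominates the family's expansion (70
genes, 53%), while tandem duplication accounts for only 21%. On the gene
tree, cutting root-mapping duplications recovers 122 ancestral lineages,
of which the focal species inherited 70, and one lineage shows a drastic
single-species expansion. Most family members sit below 1 TPM without
pathogen stimulation.

The same stages run on real inputs through the CLI, e.g.:

```
nbsurvey identify --gff genome.gff3 --hmm-hits hmm.tsv --blast-hits blast.tsv \
    --rescan-hits rescan.tsv --cdd-domains cdd.tsv -o calls.tsv
nbsurvey cluster --gff genome.gff3 --nbs-ids calls.tsv --window 250000 -o loci.tsv
nbsurvey dup --gff genome.gff3 --blast-allvall allvall.tsv --nbs-ids calls.tsv -o dup.tsv
nbsurvey lineage --tree tree.nwk --ingroup Ef,Nc,Nt --min-support 50 -o lineages.tsv
nbsurvey run --config survey.yaml
```

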