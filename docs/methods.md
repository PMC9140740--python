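# Methods

`nbsurvey` implements a genome-wide survey of the NBS-LRR (NLR) disease
resistance gene family: identification from homology hit tables, domain
architecture subclassing, chromosomal cluster calling, duplication-type
classification over collinearity blocks, and ancestral-lineage counting by
gene-tree/species-tree reconciliation. Each stage is validated against a
synthetic-genome generator that plants a fully known ground truth. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Identification

Candidates come from the union of two permissive searches against the
NB-ARC (NBS) domain — a profile-HMM scan and a BLASTp search, both run
elsewhere and consumed as tables (HMMER per-domain tabular and 12-column
BLAST tabular). Redundant hits collapse to one candidate per gene. A
strict re-scan then keeps a candidate only if it has at least one NBS hit
with E ≤ 1e-4 (configurable); the filter is monotone, so tightening the
threshold can only shrink the confirmed set.

Domain architecture is called from CDD-style domain hit tables on protein
residue coordinates. Same-name overlapping hits are merged by interval
union (best E-value retained); when differently named hits overlap, the
lower-E segment wins. The subclass is set by the canonical domain
preceding the first NBS segment — RPW8 → RNL, TIR → TNL, CC → CNL — with
precedence RPW8 > TIR > CC when several are present (the RNL and TNL calls
override coiled-coil co-occurrence; the source data never disambiguates
this, so a fixed precedence provides determinism). Genes whose
architecture retains no N-terminal canonical domain (e.g. bare NBS
fragments) are assigned the subclass of their best-scoring NBS profile
when the strict re-scan used subclass-specific profiles (targets named
like `NB-ARC_TNL`); otherwise they are reported as `NL-ambiguous`. A gene
is *intact* when it carries its subclass's N-terminal domain, an NBS, and
an LRR. Any non-canonical domain is an integrated domain (ID), recorded
with an N or C terminus relative to the first NBS; the ID vocabulary is
open-ended. Only segment order matters to the call, never coordinates or
scale.

## Cluster calling

Two family members share a locus when the window extending 250 kb up- and
downstream of one gene's full interval touches the other gene's interval —
equivalently, when the inter-gene gap is ≤ 250 kb. Loci are the connected
components of this relation (single-linkage transitive closure). Because
loci live on a line, a sorted sweep that tracks the furthest right edge of
the open locus is exact; a brute-force O(n²) pairwise-linkage + union-find
oracle confirms equivalence on randomized instances (up to 200 genes, 200
instances) in the test suite. The window anchors on the whole gene
interval rather than the start point (a literal reading of "upstream and
downstream" of a gene); `anchor="start"` switches to start-point distance.
Locus identifiers are assigned by chromosome order then span start, ties
in gene order broken by (start, end, gene_id), so output is reproducible.

The distribution summary reports per-chromosome counts (chromosomes with
no family member are listed with count 0), locus totals, and a Spearman
rank correlation of family count against chromosome length (midranks for
ties; with zero variance on either axis the coefficient is undefined and
is reported as 0 with a degenerate flag; fewer than 3 chromosomes is an
error).

## Duplication typing

Paralog pairs are the top-5 non-self all-vs-all BLAST hits per query at
E ≤ 1e-10, deduplicated as unordered pairs. Collinear (syntenic) blocks
are chains of anchors (paralog pairs plotted at gene-rank coordinates)
detected by an in-house dynamic programme: within each chromosome pair,
the maximum-anchor chain with strictly monotone ranks (either orientation
on the second axis) and rank gaps ≤ 25 on both axes is peeled off
repeatedly; chains of ≥ 5 anchors are blocks. The DP equals exhaustive
best-chain enumeration on all random instances up to 15 anchors (200
instances in the tests). Ties between equal-length chains break toward
the forward orientation and the earliest sorted anchor indices.

Each family member receives exactly one label by precedence

    wgd_segmental > tandem > proximal > dispersed > singleton

— block anchor membership first; then a family paralog at gene-rank
distance 1 on the same chromosome (tandem); then rank distance ≤ 20
(proximal); then any family paralog (dispersed); else singleton. Distances
are gene-order ranks over the *whole* annotation, not base pairs, so the
gene background contributes spacing even though paralog partners must
themselves be family members (the survey classifies family expansion, not
background duplication). Block size (5), gap (25), proximal distance (20),
top-N (5) and the E cutoff follow the widely used duplicate-gene-classifier
convention and are all configurable. Both genes of a block anchor get
`wgd_segmental`, including intra-chromosomal blocks; WGD and segmental
events are deliberately pooled.

## Ancestral lineages

Input is a rooted gene tree whose tips encode species as the prefix before
the first underscore (configurable rule), with outgroup tips used only for
rooting. Internal edges with support below 50 (default; ultrafast
bootstrap scale) are contracted into multifurcations first. Species-
overlap reconciliation labels a node a duplication iff at least two of its
children carry intersecting ingroup species sets; multifurcations are
treated as simultaneous divergences under the same rule.

An *ancestral lineage* is a gene copy present in the ingroup's common
ancestor. Operationally, every duplication node whose ingroup species set
spans both sides of the ingroup species tree's basal split (i.e. maps to
the species-tree root under LCA mapping) is removed; each remaining
maximal subtree with ≥ 1 ingroup tip is one lineage. With no gene loss
this recovers the true ancestral copy number exactly; losses can merge
lineages but never split them, so the count is a lower bound — the
"at least K" reading. Per-lineage subclass is the majority subclass of
its tips (ties are an error, as subclasses are expected to be
monophyletic); `inherited(X)` counts lineages containing ≥ 1 tip of
species X; expansions are (lineage, species) cells with ≥ `min_size` tips.

One behaviour worth stating plainly: contracting poorly supported edges
does **not** monotonically reduce the lineage count. Dissolving a resolved
speciation into a root-mapping multifurcating duplication splits that
speciation's children into separate lineages, and the fully collapsed star
tree attains the maximum of one lineage per ingroup tip. Lineage counts
should therefore be read on a conservatively resolved tree: the support
threshold trades resolution against inflation, and the default of 50 keeps
well-supported structure intact. The property tests assert the true bounds
(count within [1, tip count]; star tree at the maximum; no-op when every
support clears the threshold) rather than a monotonicity that does not
hold.

## Expression profile

Abundances (TPM) arrive precomputed as a gene × sample TSV. A family
member is *low* when its arithmetic mean across samples falls below 1.0
TPM (configurable; the threshold is a reporting convention, not a fitted
quantity). Ids absent from the matrix are listed and excluded from the
low fraction's denominator. A log2(x+1) matrix is returned for plotting.
Multi-sample handling is deliberately simple (plain means) because the
motivating use case is a single accession.

## Synthetic data: what it emulates, and what it does not

`SimulationConfig` defaults *are* the study conditions of the surveyed
genome: 131 family members (40 CNL / 73 TNL / 18 RNL) among 21,837
annotated genes (0.6%) on 29 chromosomes; 24 architecture groups
(the four RNL groups 6/7/4/1 and the integrated-domain constraints — four
distinct IDs in nine TNLs, seven C-terminal and two N-terminal fusions —
are fixed; the remaining multiplicities are a consistent but fabricated
catalog, since no complete enumeration is available); 18 clusters of
sizes 10…2 covering 87 genes plus 44 singletons, clusters concentrated on
chromosomes 11/15/18 and chromosome 22 empty; duplication plan 28 tandem /
15 proximal / 18 dispersed / 70 WGD-segmental, with the 18 dispersed genes
being the 18 RNLs (reproducing the observation that RNLs are scattered
without synteny); 25 decoy candidates whose strict re-scan E-values exceed
1e-4; and 70% of family members in the low-expression regime.

Geometry guarantees make the planted loci unambiguous: intergenic gaps are
U(5, 40) kb and gene lengths U(1, 5) kb, so sites ≥ 60 gene ranks apart
are always > 250 kb apart, while cluster members ≤ 4 ranks apart are
always < 250 kb apart. Tandem pairs are rank-adjacent; proximal copies sit
2 ranks apart; each WGD pair is embedded in a 5-anchor collinear run (two
background anchors flanking the family anchor on each side). An
adversarial mode wires a tandem pair and a proximal pair into a shared
block to exercise label precedence. Everything is deterministic per
(config, seed) down to the byte.

The gene-tree generator plants K independent copies at the ingroup root of
((Ef,(Nc,Nt)), outgroup) — default 44 CNL + 66 TNL + 12 RNL = 122 — and
evolves each down the species tree under a birth–death process (default
birth 0.25, loss 0 per unit branch length). The inheritance pattern is
planted at the copy level: 70 of the 122 copies carry the Ef lineage
(25/38/7 per subclass), all carry both water-lily lineages, which makes
"inherited(Ef) = 70" a deterministic study condition rather than a lucky
stochastic draw. One designated CNL lineage receives a 102-tip burst in
Nc, emulating a drastic species-specific expansion. Subclass clades join
above the ingroup root through duplication nodes, so subclasses are
monophyletic by construction.

What the generator does **not** emulate — hence what passing tests do not
show about real data: no sequence evolution (domain hits are placed, not
scored, so real HMM/BLAST error modes such as borderline E-values,
split/partial hits, or chimeric models are absent); gene density is
uniform rather than clustered around pericentromeric repeats; collinear
blocks are short idealized runs, not Mb-scale blocks with inversions and
nested losses; the gene tree has no incomplete lineage sorting, no
horizontal transfer, and no topological error beyond what support
collapsing simulates. Exact planted-truth recovery therefore certifies the
*logic* of each stage, not robustness to noisy upstream annotation.

## Numerical and scale choices

All coordinates are 1-based inclusive (GFF3 convention); ranks are 0-based
per chromosome in start order with (end, gene_id) tie-breaks. Strand is
recorded but ignored by clustering and duplication logic. Reports carry
full-precision values in JSON plus display-rounded percentages (whole
percents for duplication shares, one decimal for within-subclass group
shares; zero denominators render as N/A), and regenerate byte-identically
from the same inputs.

Test problem sizes: the cluster oracle runs 200 random instances of up to
200 genes; the chaining oracle 200 instances of up to 15 anchors; the
end-to-end recovery check runs the full default-scale genome for 10 seeds;
lineage recovery runs 100 replicates for each K in {1, 5, 20, 122} without
loss and 100 lossy replicates. These sizes make the whole suite run in
well under a minute while covering every planted configuration class.

## Known limitations

- WGD vs segmental duplication is not disambiguated (no Ka/Ks dating).
- The ancestral-lineage count is a reconciliation lower bound; consecutive
  root copies surviving in disjoint species subsets are indistinguishable
  from a single later duplication and merge.
- CC (coiled-coil) presence must arrive via hit tables; no coiled-coil
  prediction from sequence is performed.
- Expression classification is a thresholded mean, not a statistical call;
  induction contrasts are out of scope.
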