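"""Readers and writers for the external formats the survey consumes.

Everything downstream operates on the validated in-memory structures built
here: :class:`GeneModel` (positioned genes with per-chromosome rank),
:class:`HomologyHit` (rows of HMMER/BLAST/CDD-style hit tables), expression
matrices (plain pandas DataFrames), and rooted dendropy trees with
species-tagged tips.

Coordinates are 1-based and inclusive throughout, following the GFF3
convention; any half-open arithmetic stays inside individual functions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import dendropy
import pandas as pd

__all__ = [
    "GeneModel",
    "HomologyHit",
    "ParseError",
    "DialectError",
    "ValidationError",
    "LabelingError",
    "RootingError",
    "read_gff",
    "write_gff",
    "read_hit_table",
    "write_hit_table",
    "read_tree",
    "write_tree",
    "read_expression",
    "write_expression",
    "chrom_sort_key",
    "species_from_prefix",
]


class ParseError(ValueError):
    """A file does not conform to its declared format."""


class DialectError(ParseError):
    """A table row does not match the declared dialect (e.g. column count)."""


class ValidationError(ValueError):
    """Parsed content violates a semantic invariant (duplicate IDs, negative E-values...)."""


class LabelingError(ValueError):
    """Tree tips that cannot be assigned a species under the tagging rule."""


class RootingError(ValueError):
    """Tree is not usably rooted (basal trifurcation without an outgroup)."""


@dataclass(frozen=True, order=True)
class GeneModel:
    """A positioned gene.

    ``rank`` is the 0-based ordinal of the gene among all genes on its
    chromosome sorted by start (ties broken by end, then gene_id).
    """

    chrom: str
    start: int
    end: int
    gene_id: str
    strand: str = "+"
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class HomologyHit:
    """One row of a homology-search hit table.

    ``query_id`` is always the annotated gene/protein; ``target`` is the
    domain, profile, or subject it hit.  ``q_start``/``q_end`` are 1-based
    inclusive residue coordinates on the query protein.
    """

    query_id: str
    target: str
    evalue: float
    score: float
    q_start: int
    q_end: int
    source: str  # {hmm, blast, cdd}

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.target}: negative E-value {self.evalue}"
            )
        if self.q_start > self.q_end:
            raise ValidationError(
                f"hit {self.query_id}->{self.target}: q_start {self.q_start} > q_end {self.q_end}"
            )


_CHROM_NUM = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural sort key so chr2 sorts before chr10."""
    parts = _CHROM_NUM.split(chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_ATTR_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def read_gff(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene features from a GFF3 file into ranked :class:`GeneModel`\\ s.

    Only rows whose type column equals ``feature_type`` are consumed; every
    such row must carry an ``ID`` attribute.  Ranks are assigned per
    chromosome by ascending start (ties: end, then gene_id).

    Raises :class:`ParseError` naming the offending line for malformed rows
    and :class:`ValidationError` for duplicate gene IDs.
    """
    raw: list[tuple[str, int, int, str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            m = _GFF_ATTR_ID.search(attrs)
            if m is None:
                raise ParseError(f"{path}: line {lineno}: {feature_type} feature lacks ID attribute")
            gene_id = m.group(1).strip()
            if gene_id in seen:
                raise ValidationError(f"{path}: line {lineno}: duplicate gene ID {gene_id!r}")
            seen.add(gene_id)
            if strand not in ("+", "-"):
                strand = "+"
            raw.append((chrom, start, end, gene_id, strand))
    return rank_genes(
        GeneModel(chrom=c, start=s, end=e, gene_id=g, strand=st) for c, s, e, g, st in raw
    )


def rank_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Return genes re-ranked per chromosome by (start, end, gene_id)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneModel] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        members = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(members):
            out.append(
                GeneModel(
                    chrom=g.chrom, start=g.start, end=g.end,
                    gene_id=g.gene_id, strand=g.strand, rank=rank,
                )
            )
    return out


def write_gff(genes: Sequence[GeneModel], path: str | Path, source: str = "nbsurvey") -> None:
    """Write genes as GFF3 ``gene`` features (sorted by chromosome then start)."""
    ordered = sorted(genes, key=lambda g: (chrom_sort_key(g.chrom), g.start, g.end, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ordered:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

_BLAST12_NCOL = 12
_DOMTBL_NCOL = 22  # fixed columns before the free-text description

_DIALECT_SOURCE = {"blast_tab12": "blast", "hmm_tab": "hmm"}


def read_hit_table(
    path: str | Path,
    dialect: str,
    source: str | None = None,
) -> list[HomologyHit]:
    """Read a homology hit table.

    dialect ``blast_tab12``
        12-column BLAST tabular (outfmt 6): qseqid sseqid pident length
        mismatch gapopen qstart qend sstart send evalue bitscore.
    dialect ``hmm_tab``
        HMMER per-domain table (domtblout): the annotated protein is the
        target sequence; we map it to ``query_id`` and the profile name to
        ``target``, with alignment coordinates as q_start/q_end and the
        independent per-domain E-value as ``evalue``.

    ``source`` overrides the HomologyHit.source tag (use ``"cdd"`` for
    domain-confirmation tables exported in BLAST tabular layout).
    """
    if dialect not in _DIALECT_SOURCE:
        raise ValueError(f"unknown dialect {dialect!r}")
    src = source if source is not None else _DIALECT_SOURCE[dialect]
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                if dialect == "blast_tab12":
                    f = line.split("\t")
                    if len(f) != _BLAST12_NCOL:
                        raise DialectError(
                            f"{path}: line {lineno}: blast_tab12 expects {_BLAST12_NCOL} "
                            f"columns, got {len(f)}"
                        )
                    hits.append(
                        HomologyHit(
                            query_id=f[0], target=f[1],
                            evalue=float(f[10]), score=float(f[11]),
                            q_start=int(f[6]), q_end=int(f[7]),
                            source=src,
                        )
                    )
                else:  # hmm_tab / domtblout
                    f = line.split(None, _DOMTBL_NCOL)
                    if len(f) < _DOMTBL_NCOL:
                        raise DialectError(
                            f"{path}: line {lineno}: hmm_tab expects >= {_DOMTBL_NCOL} "
                            f"whitespace-separated columns, got {len(f)}"
                        )
                    hits.append(
                        HomologyHit(
                            query_id=f[0], target=f[3],
                            evalue=float(f[12]), score=float(f[13]),
                            q_start=int(f[17]), q_end=int(f[18]),
                            source=src,
                        )
                    )
            except DialectError:
                raise
            except ValidationError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Sequence[HomologyHit], path: str | Path, dialect: str) -> None:
    """Write hits back out in the named dialect (inverse of :func:`read_hit_table`)."""
    with open(path, "w") as fh:
        if dialect == "blast_tab12":
            for h in hits:
                fh.write(
                    f"{h.query_id}\t{h.target}\t90.0\t{h.q_end - h.q_start + 1}\t0\t0\t"
                    f"{h.q_start}\t{h.q_end}\t{h.q_start}\t{h.q_end}\t{h.evalue:g}\t{h.score:g}\n"
                )
        elif dialect == "hmm_tab":
            fh.write("# target name        accession   tlen query name           accession   "
                     "qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  "
                     "from    to  from    to  from    to  acc description of target\n")
            for h in hits:
                fh.write(
                    f"{h.query_id} - 500 {h.target} - 300 {h.evalue:g} {h.score:g} 0.1 1 1 "
                    f"{h.evalue:g} {h.evalue:g} {h.score:g} 0.1 1 300 {h.q_start} {h.q_end} "
                    f"{h.q_start} {h.q_end} 0.95 -\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def species_from_prefix(label: str, delimiter: str = "_") -> str:
    """Default species-tagging rule: the prefix before the first delimiter."""
    if delimiter not in label:
        raise LabelingError(f"tip label {label!r} has no {delimiter!r} species delimiter")
    return label.split(delimiter, 1)[0]


def read_tree(
    path: str | Path,
    species_tag_rule: Callable[[str], str] | None = None,
    require_rooted: bool = True,
) -> dendropy.Tree:
    """Read a rooted newick tree with species-tagged tips.

    Each leaf gets a ``species`` attribute derived from its label by
    ``species_tag_rule`` (default: prefix before the first underscore); each
    internal node gets a ``support`` attribute parsed from its newick label
    where present (``None`` otherwise).

    Raises :class:`LabelingError` listing every tip that fails the rule, and
    :class:`RootingError` when the root is a basal trifurcation (the usual
    signature of an unrooted tree) and ``require_rooted`` is set.
    """
    rule = species_tag_rule or species_from_prefix
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    root_children = tree.seed_node.child_nodes()
    if require_rooted and len(root_children) > 2:
        raise RootingError(
            f"{path}: root has {len(root_children)} children; the tree looks unrooted - "
            "root it on an outgroup before lineage analysis"
        )
    offenders: list[str] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else (leaf.label or "")
        try:
            leaf.species = rule(label)
        except LabelingError:
            offenders.append(label)
    if offenders:
        raise LabelingError(
            f"{path}: {len(offenders)} tip label(s) do not match the species rule: "
            + ", ".join(sorted(offenders)[:10])
        )
    for node in tree.preorder_internal_node_iter():
        support = None
        if node.label not in (None, ""):
            try:
                support = float(node.label)
            except ValueError:
                support = None
        node.support = support
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    """Write a tree as rooted newick, emitting ``support`` attrs as internal labels."""
    for node in tree.preorder_internal_node_iter():
        sup = getattr(node, "support", None)
        if sup is not None:
            node.label = f"{sup:g}"
    tree.write(
        path=str(path), schema="newick",
        suppress_rooting=False, unquoted_underscores=True,
    )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample abundance TSV (header row = sample names).

    Returns a DataFrame indexed by gene id.  Values must be non-negative and
    gene ids unique.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dupes[:5]}")
    if (df.values < 0).any():
        raise ValidationError(f"{path}: negative abundance values present")
    return df


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")
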