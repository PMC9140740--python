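"""Candidate NBS-LRR identification and domain-architecture classification.

The identification protocol mirrors the standard two-pronged survey: a
permissive profile-HMM search and a permissive BLASTp search are merged into
a non-redundant candidate set, which is then re-scanned against the NBS
(NB-ARC) profile at a strict E-value cutoff (1e-4).  Confirmed genes are
classified into the TNL / CNL / RNL subclasses by the canonical domain that
precedes the first NBS domain (TIR, coiled-coil, or RPW8 respectively), and
into architecture groups by their ordered domain-letter string ("TNL",
"RN", "RNRN", ...).  Non-canonical domains fused into the protein are
recorded as integrated domains (IDs) with an N- or C-terminal position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import HomologyHit

__all__ = [
    "CANONICAL_DOMAINS",
    "DomainSegment",
    "DomainAnnotation",
    "ArchitectureCall",
    "merge_candidates",
    "strict_rescan_filter",
    "profile_hints_from_rescan",
    "build_domain_annotations",
    "classify_architecture",
    "summarize_architecture_groups",
]

#: canonical domain name -> architecture letter
CANONICAL_DOMAINS = {"TIR": "T", "CC": "C", "RPW8": "R", "NBS": "N", "LRR": "L"}

#: aliases normalised onto the canonical vocabulary
_DOMAIN_ALIASES = {"NB-ARC": "NBS", "NB_ARC": "NBS", "NACHT": "NBS"}

#: N-terminal domain that defines each subclass, in precedence order
_SUBCLASS_BY_NTERM = (("RPW8", "RNL"), ("TIR", "TNL"), ("CC", "CNL"))
_NTERM_OF_SUBCLASS = {"RNL": "RPW8", "TNL": "TIR", "CNL": "CC"}


def _canon(name: str) -> str:
    return _DOMAIN_ALIASES.get(name, name)


@dataclass(frozen=True)
class DomainSegment:
    name: str
    q_start: int
    q_end: int
    evalue: float
    source: str


@dataclass
class DomainAnnotation:
    """Ordered, non-redundant domain segments for one gene."""

    gene_id: str
    segments: list[DomainSegment] = field(default_factory=list)


@dataclass(frozen=True)
class ArchitectureCall:
    gene_id: str
    arch_string: str
    subclass: str  # TNL | CNL | RNL | NL-ambiguous
    intact: bool
    integrated_domains: tuple[tuple[str, str], ...]  # (name, terminus N|C)


# ---------------------------------------------------------------------------
# candidate search
# ---------------------------------------------------------------------------

def merge_candidates(
    hmm_hits: Iterable[HomologyHit], blast_hits: Iterable[HomologyHit]
) -> set[str]:
    """Union of query gene ids from the two permissive searches, de-duplicated."""
    return {h.query_id for h in hmm_hits} | {h.query_id for h in blast_hits}


def _is_nbs_profile(target: str) -> bool:
    base = _canon(target.split("_", 1)[0])
    return base == "NBS" or _canon(target) == "NBS"


def strict_rescan_filter(
    candidates: set[str],
    rescan_hits: Iterable[HomologyHit],
    threshold: float = 1e-4,
) -> set[str]:
    """Keep candidates with at least one NBS-profile hit at E <= threshold.

    Rescan hits for non-candidate ids are ignored with a warning.  The result
    is always a subset of ``candidates``; lowering the threshold can only
    shrink it (monotonicity).
    """
    confirmed: set[str] = set()
    strays: set[str] = set()
    for h in rescan_hits:
        if h.query_id not in candidates:
            strays.add(h.query_id)
            continue
        if _is_nbs_profile(h.target) and h.evalue <= threshold:
            confirmed.add(h.query_id)
    if strays:
        warnings.warn(
            f"{len(strays)} rescan hit id(s) were not in the candidate set and were ignored",
            stacklevel=2,
        )
    return confirmed


def profile_hints_from_rescan(
    rescan_hits: Iterable[HomologyHit],
) -> dict[str, str]:
    """Best-scoring subclass profile per gene, from suffixed NBS profile names.

    A rescan target named like ``NB-ARC_TNL`` carries the subclass of the
    best-matching NBS profile; the lowest-E hit wins.  Genes whose hits carry
    no subclass suffix get no hint.
    """
    best: dict[str, tuple[float, str]] = {}
    for h in rescan_hits:
        if "_" not in h.target:
            continue
        base, suffix = h.target.rsplit("_", 1)
        if not _is_nbs_profile(base) or suffix not in _NTERM_OF_SUBCLASS:
            continue
        cur = best.get(h.query_id)
        if cur is None or (h.evalue, suffix) < cur:
            best[h.query_id] = (h.evalue, suffix)
    return {g: subclass for g, (_e, subclass) in best.items()}


# ---------------------------------------------------------------------------
# domain annotation
# ---------------------------------------------------------------------------

def build_domain_annotations(hits: Iterable[HomologyHit]) -> dict[str, DomainAnnotation]:
    """Collapse raw domain hits into per-gene ordered segment lists.

    Same-name overlapping hits (from any source) are merged by interval
    union, keeping the best E-value.  When segments of *different* names
    overlap, the lower-E segment wins and the other is dropped.
    """
    per_gene: dict[str, list[HomologyHit]] = {}
    for h in hits:
        per_gene.setdefault(h.query_id, []).append(h)

    out: dict[str, DomainAnnotation] = {}
    for gene_id in sorted(per_gene):
        # union same-name intervals
        by_name: dict[str, list[list]] = {}
        for h in sorted(per_gene[gene_id], key=lambda h: (h.q_start, h.q_end)):
            name = _canon(h.target)
            merged = by_name.setdefault(name, [])
            if merged and h.q_start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], h.q_end)
                merged[-1][2] = min(merged[-1][2], h.evalue)
            else:
                merged.append([h.q_start, h.q_end, h.evalue, h.source])
        pool = [
            DomainSegment(name, s, e, ev, src)
            for name, ivs in by_name.items()
            for s, e, ev, src in ivs
        ]
        # conflicting-name overlaps: greedy accept by ascending E-value
        accepted: list[DomainSegment] = []
        for seg in sorted(pool, key=lambda s: (s.evalue, s.q_start, s.name)):
            if any(
                a.name != seg.name and not (seg.q_end < a.q_start or seg.q_start > a.q_end)
                for a in accepted
            ):
                continue
            accepted.append(seg)
        accepted.sort(key=lambda s: (s.q_start, s.q_end, s.name))
        out[gene_id] = DomainAnnotation(gene_id=gene_id, segments=accepted)
    return out


# ---------------------------------------------------------------------------
# architecture classification
# ---------------------------------------------------------------------------

def classify_architecture(
    annot: DomainAnnotation, profile_hint: str | None = None
) -> ArchitectureCall:
    """Classify one gene's domain architecture.

    Subclass is decided by the canonical N-terminal domain that precedes the
    first NBS segment, with precedence RPW8 > TIR > CC when several are
    present.  Genes with no such domain fall back to ``profile_hint`` (the
    subclass of their best-scoring NBS profile) or to ``NL-ambiguous``.

    The architecture string concatenates canonical letters in positional
    order with repeats preserved; integrated (non-canonical) domains are
    appended/prepended by name with a hyphen, and recorded with an N or C
    terminus relative to the first NBS segment.  ``intact`` requires the
    subclass's N-terminal domain, an NBS and an LRR.  Only order matters:
    the call is invariant to any monotone rescaling of coordinates.
    """
    segs = annot.segments
    names = [_canon(s.name) for s in segs]
    if "NBS" not in names:
        raise ValueError(f"gene {annot.gene_id}: no NBS segment; not a classifiable candidate")
    first_nbs = names.index("NBS")

    preceding = set(names[:first_nbs])
    subclass = None
    for dom, sub in _SUBCLASS_BY_NTERM:
        if dom in preceding:
            subclass = sub
            break
    if subclass is None:
        subclass = profile_hint if profile_hint in _NTERM_OF_SUBCLASS else "NL-ambiguous"

    tokens: list[str] = []
    ids: list[tuple[str, str]] = []
    for i, name in enumerate(names):
        if name in CANONICAL_DOMAINS:
            tokens.append(CANONICAL_DOMAINS[name])
        else:
            terminus = "N" if i < first_nbs else "C"
            ids.append((name, terminus))
            tokens.append(name)
    # runs of canonical letters concatenate ("TNL"); ID names hyphenate ("TNL-MARCH1")
    chunks: list[str] = []
    letter_run = False
    for tok in tokens:
        is_letter = len(tok) == 1
        if is_letter and letter_run:
            chunks[-1] += tok
        else:
            chunks.append(tok)
        letter_run = is_letter
    arch = "-".join(chunks)
    nterm = _NTERM_OF_SUBCLASS.get(subclass)
    has = set(names)
    intact = nterm is not None and nterm in has and "LRR" in has
    return ArchitectureCall(
        gene_id=annot.gene_id,
        arch_string=arch,
        subclass=subclass,
        intact=intact,
        integrated_domains=tuple(ids),
    )


def summarize_architecture_groups(calls: Iterable[ArchitectureCall]) -> pd.DataFrame:
    """Group table: one row per (subclass, arch_string) with count and
    percent within subclass.  Counts sum to the number of calls; percents
    sum to 100 per subclass up to rounding."""
    rows = [(c.subclass, c.arch_string, c.intact) for c in calls]
    if not rows:
        return pd.DataFrame(columns=["subclass", "arch_string", "count", "percent", "intact"])
    df = pd.DataFrame(rows, columns=["subclass", "arch_string", "intact"])
    grouped = (
        df.groupby(["subclass", "arch_string"], as_index=False)
        .agg(count=("arch_string", "size"), intact=("intact", "first"))
    )
    totals = grouped.groupby("subclass")["count"].transform("sum")
    grouped["percent"] = 100.0 * grouped["count"] / totals
    grouped = grouped.sort_values(
        ["subclass", "count", "arch_string"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return grouped[["subclass", "arch_string", "count", "percent", "intact"]]
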