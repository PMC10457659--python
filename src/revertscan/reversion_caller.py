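"""Per-read reversion assessment and aggregation into distinct alleles."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .alignment_core import ObservedVariant
from .genome_model import (
    ProteinOutcome,
    ReferenceContext,
    TranscriptModel,
    translate_with_variants,
)

log = logging.getLogger(__name__)

CATEGORIES = (
    "not_reverted",
    "reference_read",
    "reversion_secondary_indel",
    "reversion_spanning_deletion",
    "reversion_snv",
)

_REVERSION_CATEGORIES = frozenset(
    ("reversion_secondary_indel", "reversion_spanning_deletion", "reversion_snv")
)


@dataclass(frozen=True)
class _GenomicEdit:
    """Anchor-free edit lifted to genomic coordinates for translation."""

    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class ReversionAssessment:
    read_id: str
    observed: Tuple[ObservedVariant, ...]
    carries_pathogenic: bool
    outcome: ProteinOutcome
    category: str
    is_candidate_reversion: bool


def _spans_pathogenic(v: ObservedVariant, ctx: ReferenceContext) -> bool:
    """True for a non-pathogenic deletion whose span covers the pathogenic edit."""
    if v.kind != "DEL" or v.is_pathogenic_match:
        return False
    lo, hi = ctx.var_start, max(ctx.var_end, ctx.var_start + 1)
    return v.pos <= lo and v.pos + len(v.ref) >= hi


def assess_read(
    read_id: str,
    variants: Sequence[ObservedVariant],
    ctx: ReferenceContext,
    tx: TranscriptModel,
    genome,
) -> ReversionAssessment:
    """Classify one read's (post-normalization) variants.

    The read's full variant set — including the pathogenic allele when
    present — is written into the transcript and translated; a read is a
    candidate reversion only when the resulting protein keeps the canonical
    stop codon.  Reads observing neither the pathogenic allele nor a deletion
    spanning it can never be candidates: a read indistinguishable from
    reference carries no evidence of reversion.  The downstream-stop rule is
    implicit: any premature stop forfeits the canonical stop.
    """
    variants = tuple(sorted(variants, key=lambda v: (v.pos, v.ref, v.alt)))
    carries = any(v.is_pathogenic_match for v in variants)
    spanning = any(_spans_pathogenic(v, ctx) for v in variants)
    edits = [
        _GenomicEdit(v.pos + ctx.window.start, v.ref, v.alt) for v in variants
    ]
    outcome = translate_with_variants(tx, genome, edits)

    if not carries and not spanning:
        category = "reference_read" if outcome.same_stop_as_canonical else "not_reverted"
    elif not outcome.same_stop_as_canonical:
        category = "not_reverted"
    elif spanning:
        category = "reversion_spanning_deletion"
    else:
        secondary_indels = [
            v for v in variants if v.kind in ("DEL", "INS") and not v.is_pathogenic_match
        ]
        snvs = [v for v in variants if v.kind == "SNV"]
        if secondary_indels:
            category = "reversion_secondary_indel"
        elif snvs:
            category = "reversion_snv"
        else:
            category = "not_reverted"  # pathogenic allele alone, in-frame
    is_candidate = outcome.same_stop_as_canonical and category in _REVERSION_CATEGORIES
    return ReversionAssessment(
        read_id=read_id,
        observed=variants,
        carries_pathogenic=carries,
        outcome=outcome,
        category=category,
        is_candidate_reversion=is_candidate,
    )


@dataclass(frozen=True)
class ReversionAllele:
    """A distinct set of non-pathogenic variants with its supporting reads."""

    key: str
    variants: Tuple[ObservedVariant, ...]
    supporting_reads: Tuple[str, ...]
    n_support: int
    vaf: float
    homopolymer_flag: bool
    category: str
    net_indel: int
    frame_restored: bool
    same_stop: bool


def allele_key(variants: Sequence[ObservedVariant], ctx: ReferenceContext) -> str:
    """Canonical allele identifier: sorted ``chrom:pos1:ref>alt`` of the
    non-pathogenic variants (1-based genomic positions, '-' for empty allele)."""
    parts = []
    for v in sorted(variants, key=lambda v: (v.pos, v.ref, v.alt)):
        if v.is_pathogenic_match:
            continue
        parts.append(
            f"{ctx.window.chrom}:{ctx.window.start + v.pos + 1}:"
            f"{v.ref or '-'}>{v.alt or '-'}"
        )
    return ";".join(parts)


def aggregate_alleles(
    assessments: Sequence[ReversionAssessment],
    depth_at_variant: int,
    ctx: ReferenceContext,
    min_support: int = 1,
) -> List[ReversionAllele]:
    """Group candidate reads into distinct reversion alleles.

    VAF is ``n_support / depth_at_variant``; an allele is flagged when any of
    its variants intersects a homopolymer run of the window.  Output is sorted
    by descending support, then key.
    """
    if depth_at_variant < 1:
        raise ValueError("depth_at_variant must be >= 1")
    groups: dict = {}
    for a in assessments:
        if not a.is_candidate_reversion:
            continue
        key = allele_key(a.observed, ctx)
        groups.setdefault(key, []).append(a)
    alleles: List[ReversionAllele] = []
    for key, members in groups.items():
        rep = members[0]
        non_path = tuple(v for v in rep.observed if not v.is_pathogenic_match)
        flag = any(
            v.span[0] < he and hs < v.span[1]
            for v in non_path
            for hs, he in ctx.homopolymers
        )
        reads = tuple(sorted(m.read_id for m in members))
        if len(reads) < min_support:
            continue
        alleles.append(
            ReversionAllele(
                key=key,
                variants=non_path,
                supporting_reads=reads,
                n_support=len(reads),
                vaf=len(reads) / depth_at_variant,
                homopolymer_flag=flag,
                category=rep.category,
                net_indel=sum(v.net for v in rep.observed),
                frame_restored=rep.outcome.frame_intact,
                same_stop=rep.outcome.same_stop_as_canonical,
            )
        )
    alleles.sort(key=lambda a: (-a.n_support, a.key))
    return alleles
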