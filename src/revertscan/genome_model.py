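"""Reference-window modelling around a known pathogenic variant.

This module builds the data the realignment engine works against: a windowed
slice of the reference genome, the "personalized" copy of that window with the
patient's pathogenic allele written into it, a bidirectional coordinate map
between the two, homopolymer-run annotation, and transcript translation
machinery used to decide whether a read's variants restore the reading frame.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open.  VCF positions (1-based) are
converted at construction time.  Positions inside a :class:`ReferenceContext`
are *window offsets* unless explicitly documented as genomic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple, Union

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Standard genetic code, bases in TCAG order.
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_BASES = "TCAG"
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_bases(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")
    return seq


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch ``[start, end)`` of ``chrom`` from any common genome container.

    Accepts a plain mapping of contig name to sequence string, a
    ``pyfaidx.Fasta``, or a ``pysam.FastaFile``.
    """
    if isinstance(genome, Mapping):
        return str(genome[chrom][start:end]).upper()
    if hasattr(genome, "fetch"):  # pysam.FastaFile
        return genome.fetch(chrom, start, end).upper()
    # pyfaidx.Fasta
    return str(genome[chrom][start:end]).upper()


# ---------------------------------------------------------------------------
# Intervals and variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named contig."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start <= self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PathogenicVariant:
    """A known inactivating allele in VCF-style representation.

    ``pos`` is the 1-based VCF position of the first base of ``ref``.
    Anchored indels (e.g. ref ``AGA`` / alt ``A``) are normalized internally
    to an anchor-free edit span via :meth:`core_edit`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", _check_bases(self.ref, "ref allele"))
        object.__setattr__(self, "alt", _check_bases(self.alt, "alt allele"))
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be nonempty (use anchored VCF style)")
        if self.ref == self.alt:
            raise ValueError("ref and alt are identical")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def vclass(self) -> str:
        core_ref, core_alt = self.core_edit()[1:]
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        if core_ref and not core_alt:
            return "DEL"
        if core_alt and not core_ref:
            return "INS"
        return "DELINS"

    def core_edit(self) -> Tuple[int, str, str]:
        """Anchor-free edit: ``(genomic start0, deleted bases, inserted bases)``.

        Shared prefix then shared suffix bases are stripped; the returned
        start is the 0-based genomic position of the first edited base (for a
        pure insertion, the position *before which* bases are inserted).
        """
        ref, alt = self.ref, self.alt
        p = 0
        while p < min(len(ref), len(alt)) and ref[p] == alt[p]:
            p += 1
        r, a = ref[p:], alt[p:]
        s = 0
        while s < min(len(r), len(a)) and r[len(r) - 1 - s] == a[len(a) - 1 - s]:
            s += 1
        return self.pos - 1 + p, r[: len(r) - s], a[: len(a) - s]


def left_align_edit(seq: str, start: int, ref_core: str, alt_core: str) -> Tuple[int, str, str]:
    """Left-shift a pure insertion or deletion to its smallest equivalent start.

    ``seq`` is the haplotype the edit applies to (the sequence containing
    ``ref_core`` at ``start`` for a deletion; the insertion target otherwise).
    Complex substitutions are returned unchanged.
    """
    if ref_core and alt_core:
        return start, ref_core, alt_core
    if ref_core:
        n = len(ref_core)
        while start > 0 and seq[start - 1] == seq[start + n - 1]:
            start -= 1
        return start, seq[start : start + n], ""
    ins = alt_core
    while start > 0 and ins and seq[start - 1] == ins[-1]:
        ins = seq[start - 1] + ins[:-1]
        start -= 1
    return start, "", ins


# ---------------------------------------------------------------------------
# Reference context
# ---------------------------------------------------------------------------


@dataclass
class ReferenceContext:
    """Windowed reference around a pathogenic variant plus its personalized copy.

    Attributes
    ----------
    window:
        Genomic interval covered by ``ref_seq``.
    ref_seq / pers_seq:
        Window sequence before / after writing in the pathogenic allele.
    var_start, var_ref, var_alt:
        Anchor-free pathogenic edit in *window* coordinates.  ``var_ref`` is
        the deleted reference bases ("" for a pure insertion), ``var_alt`` the
        inserted bases ("" for a pure deletion).
    ref2pers / pers2ref:
        Per-position coordinate maps (window offset -> window offset in the
        other sequence, or ``None`` for positions with no image).
    homopolymers:
        Maximal homopolymer runs of ``ref_seq`` (window-offset intervals).
    """

    window: GenomicInterval
    ref_seq: str
    pers_seq: str
    variant: PathogenicVariant
    var_start: int
    var_ref: str
    var_alt: str
    ref2pers: List[Optional[int]]
    pers2ref: List[Optional[int]]
    homopolymers: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def var_end(self) -> int:
        """Window offset one past the pathogenic edit span (== var_start for INS)."""
        return self.var_start + len(self.var_ref)

    @classmethod
    def build(
        cls,
        variant: PathogenicVariant,
        window: GenomicInterval,
        ref_seq: str,
        min_homopolymer: int = 5,
    ) -> "ReferenceContext":
        ref_seq = _check_bases(ref_seq, "window sequence")
        if len(ref_seq) != len(window):
            raise ValueError("ref_seq length does not match window")
        g0, core_ref, core_alt = variant.core_edit()
        var_start = g0 - window.start
        if not (0 <= var_start and var_start + len(core_ref) <= len(ref_seq)):
            raise ValueError("pathogenic variant does not lie inside the window")
        anchored_off = variant.pos - 1 - window.start
        observed = ref_seq[anchored_off : anchored_off + len(variant.ref)]
        if observed != variant.ref:
            raise ValueError(
                f"reference mismatch at {variant.chrom}:{variant.pos}: "
                f"FASTA has {observed!r}, variant.ref is {variant.ref!r} "
                "(genome build mismatch?)"
            )
        er, ea = len(core_ref), len(core_alt)
        pers_seq = ref_seq[:var_start] + core_alt + ref_seq[var_start + er :]
        shift = ea - er
        ref2pers: List[Optional[int]] = []
        for i in range(len(ref_seq)):
            if i < var_start:
                ref2pers.append(i)
            elif i < var_start + er:
                k = i - var_start
                ref2pers.append(i if k < min(er, ea) else None)
            else:
                ref2pers.append(i + shift)
        pers2ref: List[Optional[int]] = []
        for i in range(len(pers_seq)):
            if i < var_start:
                pers2ref.append(i)
            elif i < var_start + ea:
                k = i - var_start
                pers2ref.append(i if k < min(er, ea) else None)
            else:
                pers2ref.append(i - shift)
        return cls(
            window=window,
            ref_seq=ref_seq,
            pers_seq=pers_seq,
            variant=variant,
            var_start=var_start,
            var_ref=core_ref,
            var_alt=core_alt,
            ref2pers=ref2pers,
            pers2ref=pers2ref,
            homopolymers=find_homopolymer_runs(ref_seq, min_homopolymer),
        )


def build_reference_context(
    fasta_path: str,
    variant: PathogenicVariant,
    window_radius: int = 500,
    min_homopolymer: int = 5,
) -> ReferenceContext:
    """Load the reference window around ``variant`` and personalize it.

    The window spans ``window_radius`` bases on each side of the anchored
    variant span, truncated (with a warning) at contig bounds.  Raises if the
    contig is missing or the FASTA base(s) at the variant position do not
    equal ``variant.ref``.
    """
    import pyfaidx

    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    fa = pyfaidx.Fasta(fasta_path)
    if variant.chrom not in fa:
        raise KeyError(f"contig {variant.chrom!r} not found in {fasta_path}")
    contig_len = len(fa[variant.chrom])
    v0 = variant.pos - 1
    start = v0 - window_radius
    end = v0 + len(variant.ref) + window_radius
    if start < 0 or end > contig_len:
        log.warning(
            "window [%d, %d) truncated to contig %s bounds [0, %d)",
            start, end, variant.chrom, contig_len,
        )
        start, end = max(0, start), min(contig_len, end)
    seq = str(fa[variant.chrom][start:end])
    window = GenomicInterval(variant.chrom, start, end)
    return ReferenceContext.build(variant, window, seq, min_homopolymer)


def map_position(ctx: ReferenceContext, pos: int, direction: str = "ref2pers") -> Optional[int]:
    """Map a window offset between reference and personalized coordinates.

    ``direction`` is ``"ref2pers"`` or ``"pers2ref"``.  Positions inside a
    deleted (resp. inserted) span have no image and map to ``None``.
    """
    if direction == "ref2pers":
        table = ctx.ref2pers
    elif direction == "pers2ref":
        table = ctx.pers2ref
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if not (0 <= pos < len(table)):
        raise IndexError(f"position {pos} outside window of length {len(table)}")
    return table[pos]


def find_homopolymer_runs(seq: str, min_run: int = 5) -> List[Tuple[int, int]]:
    """Maximal runs of a single repeated base with length >= ``min_run``.

    Returns half-open ``(start, end)`` offsets into ``seq``.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    runs: List[Tuple[int, int]] = []
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


# ---------------------------------------------------------------------------
# Transcripts and translation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinOutcome:
    """Verdict of translating a (possibly variant-modified) coding sequence."""

    protein: str
    premature_stop: bool
    stop_pos: Optional[int]
    frame_intact: bool
    same_stop_as_canonical: bool


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's exon/CDS structure in genomic coordinates.

    Exons are sorted, non-overlapping 0-based half-open intervals; the CDS is
    the genomic span ``[cds_start, cds_end)`` intersected with the exons.
    ``canonical_stop_pos`` (genomic position of the first base, in transcript
    orientation, of the canonical stop codon) is computed on demand if None.
    """

    gene: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_start: int
    cds_end: int
    canonical_stop_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = -1
        for s, e in exons:
            if s >= e or s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if not (exons[0][0] <= self.cds_start < self.cds_end <= exons[-1][1]):
            raise ValueError("CDS bounds outside exon span")

    def exonic_span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0][0], self.exons[-1][1])


def translate_cds(cds: str) -> ProteinOutcome:
    """Translate a coding sequence with the standard genetic code.

    Translation stops at the first stop codon.  ``premature_stop`` is true iff
    a stop occurs before the final complete codon; ``stop_pos`` is the string
    offset of the stop codon's first base (None if no stop is reached).
    """
    cds = _check_bases(cds, "cds")
    if len(cds) < 3:
        raise ValueError("cds shorter than one codon")
    n_codons = len(cds) // 3
    protein = []
    stop_idx: Optional[int] = None
    for k in range(n_codons):
        codon = cds[3 * k : 3 * k + 3]
        aa = CODON_TABLE.get(codon, "X")
        if aa == "*":
            stop_idx = 3 * k
            break
        protein.append(aa)
    frame_intact = len(cds) % 3 == 0
    premature = stop_idx is not None and stop_idx < 3 * (n_codons - 1)
    same_stop = frame_intact and stop_idx == len(cds) - 3
    return ProteinOutcome(
        protein="".join(protein),
        premature_stop=premature,
        stop_pos=stop_idx,
        frame_intact=frame_intact,
        same_stop_as_canonical=same_stop,
    )


def _spliced_track(tx: TranscriptModel, genome) -> List[Tuple[Optional[int], str]]:
    """Per-base ``(genomic position, base)`` track over the exon union, genomic order."""
    track: List[Tuple[Optional[int], str]] = []
    for s, e in tx.exons:
        seq = fetch_sequence(genome, tx.chrom, s, e)
        track.extend((s + i, b) for i, b in enumerate(seq))
    return track


def _apply_variants_to_track(
    track: List[Tuple[Optional[int], str]],
    variants: Sequence,
) -> List[Tuple[Optional[int], str]]:
    """Apply anchor-free edits (objects with genomic .pos/.ref/.alt) to a track."""
    vs = sorted(variants, key=lambda v: (v.pos, len(v.ref)))
    for a, b in zip(vs, vs[1:]):
        if a.pos + len(a.ref) > b.pos:
            raise ValueError(f"overlapping variants at {a.pos} and {b.pos}")
    gpos_index = {g: i for i, (g, _) in enumerate(track) if g is not None}
    exon_positions = set(gpos_index)
    out = list(track)
    # apply right-to-left so earlier indices stay valid
    for v in reversed(vs):
        span = set(range(v.pos, v.pos + len(v.ref))) if v.ref else {v.pos}
        if not (span & exon_positions) and v.pos not in exon_positions:
            log.warning("variant at %d lies outside exons; ignored for translation", v.pos)
            continue
        if v.ref and v.alt and len(v.ref) == len(v.alt):  # substitution
            for k, base in enumerate(v.alt):
                idx = gpos_index.get(v.pos + k)
                if idx is not None:
                    out[idx] = (out[idx][0], base)
            continue
        if v.ref:  # deletion (or delins ref part)
            del_idx = sorted(gpos_index[g] for g in span if g in gpos_index)
            for idx in reversed(del_idx):
                out.pop(idx)
            if v.alt:
                at = del_idx[0] if del_idx else None
                if at is not None:
                    out[at:at] = [(None, b) for b in v.alt]
            # rebuild index after structural change
            gpos_index = {g: i for i, (g, _) in enumerate(out) if g is not None}
            continue
        # pure insertion before genomic position v.pos
        idx = gpos_index.get(v.pos)
        if idx is None:
            log.warning("insertion point %d outside exons; ignored", v.pos)
            continue
        out[idx:idx] = [(None, b) for b in v.alt]
        gpos_index = {g: i for i, (g, _) in enumerate(out) if g is not None}
    return out


def _translate_track(
    tx: TranscriptModel, track: List[Tuple[Optional[int], str]]
) -> Tuple[str, Optional[int], bool]:
    """Translate a (possibly modified) track from the CDS start.

    Returns ``(protein, stop_first_base_gpos_or_None, stop_found)``.  The
    track is oriented and complemented here for minus-strand transcripts.
    """
    if tx.strand == "-":
        oriented = [(g, b.translate(_COMPLEMENT)) for g, b in reversed(track)]
        entering = lambda g: g is not None and g <= tx.cds_end - 1
    else:
        oriented = track
        entering = lambda g: g is not None and g >= tx.cds_start
    start_idx = next((i for i, (g, _) in enumerate(oriented) if entering(g)), None)
    if start_idx is None:
        raise ValueError("CDS start not found in transcript track")
    protein = []
    i = start_idx
    while i + 3 <= len(oriented):
        codon = "".join(b for _, b in oriented[i : i + 3])
        aa = CODON_TABLE.get(codon, "X")
        if aa == "*":
            return "".join(protein), oriented[i][0], True
        protein.append(aa)
        i += 3
    return "".join(protein), None, False


def translate_with_variants(
    tx: TranscriptModel, genome, variants: Sequence
) -> ProteinOutcome:
    """Translate ``tx`` after writing anchor-free ``variants`` into its exons.

    ``variants`` are objects with genomic 0-based ``pos`` and anchor-free
    ``ref``/``alt`` strings (either possibly empty, not both).  Exons are
    spliced (reverse-complemented for minus-strand transcripts), variants are
    applied in genomic order, and translation proceeds from the canonical CDS
    start through the end of the transcript, so frameshifts may terminate in
    the 3' UTR.  ``same_stop_as_canonical`` compares the genomic position of
    the realized stop codon's first base against the canonical one.
    """
    base_track = _spliced_track(tx, genome)
    canon_protein, canon_stop, canon_found = _translate_track(tx, base_track)
    if not canon_found:
        raise ValueError(f"canonical transcript {tx.gene} has no stop codon")
    if tx.canonical_stop_pos is not None and tx.canonical_stop_pos != canon_stop:
        raise ValueError(
            f"declared canonical_stop_pos {tx.canonical_stop_pos} != computed {canon_stop}"
        )
    if not variants:
        return ProteinOutcome(
            protein=canon_protein,
            premature_stop=False,
            stop_pos=canon_stop,
            frame_intact=True,
            same_stop_as_canonical=True,
        )
    track = _apply_variants_to_track(base_track, variants)
    protein, stop_gpos, stop_found = _translate_track(tx, track)

    net = 0
    for v in variants:
        if v.ref:
            lo = max(v.pos, tx.cds_start)
            hi = min(v.pos + len(v.ref), tx.cds_end)
            net -= max(0, hi - lo)
            if v.alt and tx.cds_start <= v.pos < tx.cds_end:
                net += len(v.alt)
        elif v.alt and tx.cds_start <= v.pos <= tx.cds_end:
            net += len(v.alt)
    frame_intact = net % 3 == 0
    same_stop = (
        frame_intact
        and stop_found
        and stop_gpos is not None
        and stop_gpos == canon_stop
    )
    premature = stop_found and len(protein) < len(canon_protein)
    return ProteinOutcome(
        protein=protein,
        premature_stop=premature,
        stop_pos=stop_gpos if stop_found else None,
        frame_intact=frame_intact,
        same_stop_as_canonical=same_stop,
    )
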