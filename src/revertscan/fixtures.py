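"""Deterministic synthetic fixtures: reference, transcript, VCF, SAM and truth.

Everything is generated from a seed, as plain text (FASTA, SAM, VCF, TSV,
JSON), with deliberately naive read alignments so the realignment stages have
real work to do: reads carrying the pathogenic (and secondary) indels are
written as full-length M with mismatched tails, and reads over large spanning
deletions are written soft-clipped at the junction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genome_model import (
    PathogenicVariant,
    TranscriptModel,
    left_align_edit,
    translate_with_variants,
)

_STOPS = ("TAA", "TAG", "TGA")
_QUAL = "I"


@dataclass(frozen=True)
class PlantedVariantSpec:
    """Shape of one secondary variant; position drawn at generation time
    unless ``pos`` (genomic, anchor-free) is given."""

    kind: str  # DEL | INS
    length: int
    pos: Optional[int] = None
    alt: Optional[str] = None  # inserted bases for INS (drawn if None)


@dataclass(frozen=True)
class PlantedAllele:
    n_reads: int
    category: str  # reversion_secondary_indel | reversion_spanning_deletion
    variants: Tuple[PlantedVariantSpec, ...]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic data set (all coordinates genomic, 0-based)."""

    seed: int
    planted_alleles: List[PlantedAllele] = field(default_factory=list)
    n_reference_reads: int = 30
    n_pathogenic_only_reads: int = 30
    read_len: int = 150
    dup_fraction: float = 0.0
    error_rate: float = 0.0
    contig: str = "chrT"
    contig_len: int = 1600
    exon: Tuple[int, int] = (100, 1500)
    cds_start: int = 150
    n_codons: int = 360  # incl. start and stop codons
    pathogenic_pos: int = 650  # genomic start of the deleted dinucleotide
    pathogenic_del_len: int = 2
    max_secondary_offset: int = 90
    min_secondary_offset: int = 12

    @property
    def cds_end(self) -> int:
        return self.cds_start + 3 * self.n_codons


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = [c for c in _all_codons() if c not in _STOPS and c != "ATG"]
    body = "".join(codons[i] for i in rng.integers(0, len(codons), n_codons - 2))
    return "ATG" + body + "TAA"


def _all_codons() -> List[str]:
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _build_contig(spec: FixtureSpec, rng: np.random.Generator) -> str:
    seq = list(_random_seq(rng, spec.contig_len))
    seq[spec.cds_start : spec.cds_end] = _random_cds(rng, spec.n_codons)
    return "".join(seq)


def _apply_edits(seq: str, edits: Sequence[Tuple[int, str, str]]):
    """Apply non-overlapping anchor-free edits; returns (haplotype, hap->ref map)."""
    parts: List[str] = []
    maps: List[Optional[int]] = []
    cur = 0
    for pos, ref, alt in sorted(edits):
        if pos < cur:
            raise ValueError("overlapping edits")
        parts.append(seq[cur:pos])
        maps.extend(range(cur, pos))
        if alt:
            parts.append(alt)
            maps.extend([None] * len(alt))
        cur = pos + len(ref)
    parts.append(seq[cur:])
    maps.extend(range(cur, len(seq)))
    return "".join(parts), maps


def _key(contig: str, edits: Sequence[Tuple[int, str, str]]) -> str:
    parts = [
        f"{contig}:{pos + 1}:{ref or '-'}>{alt or '-'}"
        for pos, ref, alt in sorted(edits)
    ]
    return ";".join(parts)


def _transcript(spec: FixtureSpec) -> TranscriptModel:
    return TranscriptModel(
        gene="TOY1",
        chrom=spec.contig,
        strand="+",
        exons=((spec.exon[0], spec.exon[1]),),
        cds_start=spec.cds_start,
        cds_end=spec.cds_end,
    )


class _Edit(tuple):
    """(pos, ref, alt) with attribute access for translate_with_variants."""

    @property
    def pos(self):
        return self[0]

    @property
    def ref(self):
        return self[1]

    @property
    def alt(self):
        return self[2]


def _translation_ok(spec: FixtureSpec, seq: str, edits, want_same_stop: bool) -> bool:
    tx = _transcript(spec)
    try:
        out = translate_with_variants(tx, {spec.contig: seq}, [_Edit(e) for e in edits])
    except ValueError:
        return False
    return out.same_stop_as_canonical == want_same_stop


def _unambiguous(hap: str, pos: int, ref: str, alt: str) -> bool:
    """Planted placement must already be the leftmost equivalent one."""
    return left_align_edit(hap, pos, ref, alt)[0] == pos


@dataclass
class _Read:
    name: str
    flag: int
    pos: int  # 0-based
    cigar: str
    seq: str


def _sample_reads(
    spec: FixtureSpec,
    rng: np.random.Generator,
    seq: str,
    edits: Sequence[Tuple[int, str, str]],
    n_reads: int,
    name_prefix: str,
    soft_clip_junction: Optional[Tuple[int, int]] = None,
) -> List[_Read]:
    """Reads over the haplotype implied by ``edits``, with naive CIGARs.

    ``soft_clip_junction`` = (del_start, del_end) requests breakpoint-style
    soft-clipped records instead of plain full-length M.
    """
    hap, maps = _apply_edits(seq, edits)
    ref2hap = {r: h for h, r in enumerate(maps) if r is not None}
    rl, margin = spec.read_len, 10

    spans: List[Tuple[int, int]] = []
    for pos, ref, alt in edits:
        if ref:
            h = ref2hap[pos + len(ref)]
            spans.append((h - 1, h + 1))
        else:
            h = ref2hap[pos]
            spans.append((h - len(alt) - 1, h + 1))
    # always cover the pathogenic locus
    p_after = spec.pathogenic_pos + spec.pathogenic_del_len
    ph = ref2hap.get(p_after)
    if ph is None:
        ph = ref2hap.get(spec.pathogenic_pos)
    if ph is not None:  # locus may sit inside a spanning deletion
        spans.append((ph - 1, ph + 1))
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    s_min, s_max = hi + margin - rl, lo - margin
    if soft_clip_junction is not None:
        jh = ref2hap[soft_clip_junction[1]]
        s_min = max(s_min, jh - (rl - 25))
        s_max = min(s_max, jh - 25)
    if s_max < s_min:
        raise ValueError("read length too short to span the planted allele")

    reads: List[_Read] = []
    for k in range(n_reads):
        s = int(rng.integers(s_min, s_max + 1))
        while maps[s] is None:
            s += 1
        bases = list(hap[s : s + rl])
        if spec.error_rate > 0:
            errs = np.nonzero(rng.random(rl) < spec.error_rate)[0]
            for e in errs:
                cur = bases[e]
                bases[e] = "ACGT"[(("ACGT".index(cur)) + int(rng.integers(1, 4))) % 4]
        read_seq = "".join(bases)
        if soft_clip_junction is not None:
            d0, d1 = soft_clip_junction
            a = ref2hap[d1] - s  # bases left of the junction
            if int(rng.integers(0, 2)) == 0:
                cigar, pos0 = f"{a}M{rl - a}S", maps[s]
            else:
                cigar, pos0 = f"{a}S{rl - a}M", d1
        else:
            cigar, pos0 = f"{rl}M", maps[s]
        reads.append(_Read(f"{name_prefix}_{k:04d}", 0, pos0, cigar, read_seq))
    return reads


def _place_allele(
    spec: FixtureSpec,
    rng: np.random.Generator,
    seq: str,
    allele: PlantedAllele,
    pathogenic_edit: Tuple[int, str, str],
    used_keys: set,
) -> List[Tuple[int, str, str]]:
    """Draw concrete (pos, ref, alt) edits for an allele spec, validated for
    placement unambiguity, frame restoration and key uniqueness."""
    p0, pref, _ = pathogenic_edit
    p1 = p0 + len(pref)
    pers, _ = _apply_edits(seq, [pathogenic_edit])

    def to_pers(pos: int) -> int:
        return pos if pos < p0 else pos - len(pref)

    for _attempt in range(500):
        edits: List[Tuple[int, str, str]] = []
        ok = True
        for vs in allele.variants:
            if allele.category == "reversion_spanning_deletion":
                if vs.pos is None:
                    left = int(rng.integers(5, max(6, vs.length - len(pref) - 5)))
                    pos = p0 - left
                else:
                    pos = vs.pos
                ref = seq[pos : pos + vs.length]
                if not (pos <= p0 and pos + vs.length >= p1):
                    ok = False
                    break
                pers_ref = seq[pos:p0] + seq[p1 : pos + vs.length]
                if not _unambiguous(pers, to_pers(pos), pers_ref, ""):
                    ok = False
                    break
                edits.append((pos, ref, ""))
                continue
            pos = vs.pos
            if pos is None:
                off = int(
                    rng.integers(spec.min_secondary_offset, spec.max_secondary_offset)
                )
                pos = p1 + off if rng.integers(0, 2) else p0 - off - vs.length
            if vs.kind == "DEL":
                ref, alt = seq[pos : pos + vs.length], ""
                if pos < p1 and pos + vs.length > p0:
                    ok = False
                    break
            else:
                ref = ""
                alt = vs.alt or _random_seq(rng, vs.length)
                # insertions must be unshiftable in either direction
                if alt[0] == pers[to_pers(pos)]:
                    ok = False
                    break
            if not _unambiguous(pers, to_pers(pos), ref, alt):
                ok = False
                break
            edits.append((pos, ref, alt))
        if not ok:
            continue
        key = _key(spec.contig, edits)
        if key in used_keys:
            continue
        if allele.category == "reversion_spanning_deletion":
            full = edits
        else:
            full = sorted(edits + [pathogenic_edit])
        if not _translation_ok(spec, seq, full, want_same_stop=True):
            continue
        used_keys.add(key)
        return edits
    raise RuntimeError("could not place allele after 500 attempts")


def _write_fasta(path: Path, contig: str, seq: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(path))  # writes the .fai sidecar


def _write_vcf(path: Path, spec: FixtureSpec, pv: PathogenicVariant) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={spec.contig},length={spec.contig_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        fh.write(
            f"{pv.chrom}\t{pv.pos}\t{pv.id}\t{pv.ref}\t{pv.alt}\t.\tPASS\t.\n"
        )


def _write_transcript_tsv(path: Path, spec: FixtureSpec) -> None:
    with open(path, "w") as fh:
        fh.write("#gene\tchrom\tstrand\texons\tcds_start\tcds_end\n")
        fh.write(
            f"TOY1\t{spec.contig}\t+\t{spec.exon[0]}-{spec.exon[1]}\t"
            f"{spec.cds_start}\t{spec.cds_end}\n"
        )


def _write_sam(path: Path, spec: FixtureSpec, reads: List[_Read]) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{spec.contig}\tLN:{spec.contig_len}\n")
        for r in sorted(reads, key=lambda r: (r.pos, r.name)):
            fh.write(
                f"{r.name}\t{r.flag}\t{spec.contig}\t{r.pos + 1}\t60\t{r.cigar}"
                f"\t*\t0\t0\t{r.seq}\t{_QUAL * len(r.seq)}\n"
            )


def generate_fixture(spec: FixtureSpec, out_dir) -> Dict:
    """Write a complete synthetic data set into ``out_dir``; returns the truth dict.

    Files: ``ref.fa`` (+ ``.fai``), ``reads.sam``, ``pathogenic.vcf``,
    ``transcript.tsv``, ``truth.json``.  Fully reproducible from ``spec.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    p0, plen = spec.pathogenic_pos, spec.pathogenic_del_len
    if not (spec.cds_start + 3 < p0 and p0 + plen < spec.cds_end - 3):
        raise ValueError("pathogenic variant must sit inside the CDS")

    # sequence such that the pathogenic frameshift truncates the protein
    for _ in range(100):
        seq = _build_contig(spec, rng)
        pathogenic_edit = (p0, seq[p0 : p0 + plen], "")
        if _translation_ok(spec, seq, [pathogenic_edit], want_same_stop=False):
            break
    else:  # pragma: no cover
        raise RuntimeError("could not construct a truncating pathogenic variant")

    pv = PathogenicVariant(
        chrom=spec.contig,
        pos=p0,  # 1-based position of the anchor base at 0-based p0-1
        ref=seq[p0 - 1 : p0 + plen],
        alt=seq[p0 - 1],
        id="PV1",
    )

    used_keys: set = set()
    reads: List[_Read] = []
    truth_alleles = []
    for i, allele in enumerate(spec.planted_alleles):
        edits = _place_allele(spec, rng, seq, allele, pathogenic_edit, used_keys)
        if allele.category == "reversion_spanning_deletion":
            full = edits
            junction = (edits[0][0], edits[0][0] + len(edits[0][1]))
        else:
            full = sorted(edits + [pathogenic_edit])
            junction = None
        reads.extend(
            _sample_reads(
                spec, rng, seq, full, allele.n_reads, f"al{i:02d}",
                soft_clip_junction=junction,
            )
        )
        truth_alleles.append(
            {
                "key": _key(spec.contig, edits),
                "n_reads": allele.n_reads,
                "category": allele.category,
            }
        )

    reads.extend(
        _sample_reads(spec, rng, seq, [pathogenic_edit],
                      spec.n_pathogenic_only_reads, "path")
    )
    reads.extend(
        _sample_reads(spec, rng, seq, [], spec.n_reference_reads, "ref")
    )

    n_primary = len(reads)
    n_dup = int(round(spec.dup_fraction * n_primary))
    if n_dup:
        picks = rng.choice(n_primary, size=n_dup, replace=False)
        for j, p in enumerate(sorted(int(x) for x in picks)):
            src = reads[p]
            reads.append(_Read(f"{src.name}_dup{j}", 0x400, src.pos, src.cigar, src.seq))

    _write_fasta(out / "ref.fa", spec.contig, seq)
    _write_vcf(out / "pathogenic.vcf", spec, pv)
    _write_transcript_tsv(out / "transcript.tsv", spec)
    _write_sam(out / "reads.sam", spec, reads)

    truth = {
        "contig": spec.contig,
        "pathogenic": {"pos": pv.pos, "ref": pv.ref, "alt": pv.alt, "id": pv.id},
        "depth": n_primary,
        "n_reads_total": len(reads),
        "n_duplicates": n_dup,
        "alleles": sorted(truth_alleles, key=lambda a: a["key"]),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


def default_spec(
    seed: int,
    n_alleles: int = 10,
    depth: int = 1000,
    vaf_range: Tuple[float, float] = (0.01, 0.05),
    error_rate: float = 0.0,
    dup_fraction: float = 0.0,
    n_spanning: int = 2,
) -> FixtureSpec:
    """A mixed fixture: ``n_alleles`` distinct reversion alleles at low VAF
    plus reference and pathogenic-only reads filling up to ``depth``."""
    rng = np.random.default_rng(seed ^ 0x5EED)
    alleles: List[PlantedAllele] = []
    n_planted = 0
    for i in range(n_alleles):
        vaf = rng.uniform(*vaf_range)
        n_reads = max(2, int(round(vaf * depth)))
        n_planted += n_reads
        if i < n_spanning:
            length = int(rng.choice([48, 51]))
            alleles.append(
                PlantedAllele(
                    n_reads=n_reads,
                    category="reversion_spanning_deletion",
                    variants=(PlantedVariantSpec("DEL", length),),
                )
            )
        else:
            if rng.random() < 0.6:
                vs = PlantedVariantSpec("DEL", int(rng.choice([1, 4, 7])))
            else:
                vs = PlantedVariantSpec("INS", int(rng.choice([2, 5])))
            alleles.append(
                PlantedAllele(
                    n_reads=n_reads,
                    category="reversion_secondary_indel",
                    variants=(vs,),
                )
            )
    rest = max(0, depth - n_planted)
    n_path = rest // 2
    return FixtureSpec(
        seed=seed,
        planted_alleles=alleles,
        n_reference_reads=rest - n_path,
        n_pathogenic_only_reads=n_path,
        error_rate=error_rate,
        dup_fraction=dup_fraction,
    )


def make_fig1b_case(out_dir) -> Dict:
    """Single-read worked example: a germline 2-nt deletion plus a secondary
    1-nt deletion, written with the suboptimal CIGAR ``10M1D140M`` and one
    mismatched base in the leading 10M.  The corrected alignment is
    ``4M2D6M1D140M`` (three bases deleted in total, frame restored)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for attempt in range(200):
        spec = FixtureSpec(seed=900 + attempt)
        rng = np.random.default_rng(spec.seed)
        seq_l = list(_build_contig(spec, rng))
        p0 = spec.pathogenic_pos
        w = p0 - 4
        seq_l[w : w + 6] = "AAGAGA"
        seq = "".join(seq_l)
        pathogenic_edit = (p0, "GA", "")
        secondary = (w + 12, seq[w + 12], "")
        # the secondary 1-nt deletion must be placement-unambiguous
        if seq[w + 11] == seq[w + 12] or seq[w + 12] == seq[w + 13]:
            continue
        if not _translation_ok(spec, seq, [pathogenic_edit], want_same_stop=False):
            continue
        if not _translation_ok(
            spec, seq, [pathogenic_edit, secondary], want_same_stop=True
        ):
            continue
        break
    else:  # pragma: no cover
        raise RuntimeError("could not construct the worked example")

    hap, _ = _apply_edits(seq, [pathogenic_edit, secondary])
    read_seq = hap[w : w + 150]
    assert read_seq[:10] == seq[w : w + 4] + seq[w + 6 : w + 12]
    pv = PathogenicVariant(
        chrom=spec.contig, pos=p0, ref=seq[p0 - 1 : p0 + 2], alt=seq[p0 - 1], id="PV1"
    )
    read = _Read("fig1b_read", 0, w + 2, "10M1D140M", read_seq)

    _write_fasta(out / "ref.fa", spec.contig, seq)
    _write_vcf(out / "pathogenic.vcf", spec, pv)
    _write_transcript_tsv(out / "transcript.tsv", spec)
    _write_sam(out / "reads.sam", spec, [read])
    truth = {
        "contig": spec.contig,
        "pathogenic": {"pos": pv.pos, "ref": pv.ref, "alt": pv.alt, "id": pv.id},
        "depth": 1,
        "n_reads_total": 1,
        "n_duplicates": 0,
        "initial_cigar": "10M1D140M",
        "corrected_cigar": "4M2D6M1D140M",
        "alleles": [
            {
                "key": _key(spec.contig, [secondary]),
                "n_reads": 1,
                "category": "reversion_secondary_indel",
            }
        ],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
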