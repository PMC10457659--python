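"""Realignment engine: CIGAR algebra, Smith-Waterman, soft-clip rescue,
personalized-reference realignment and indel-placement normalization.

The engine is deliberately deterministic: Smith-Waterman ties are broken by
(smallest target offset, then fewest gap openings) and traceback prefers
diagonal continuation, which places gaps leftmost among equal-score paths.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from .genome_model import ReferenceContext

try:  # numba accelerates the DP fill; plain python fallback keeps tests portable
    from numba import njit as _njit

    def _jit(fn):
        return _njit(cache=True)(fn)

except Exception:  # pragma: no cover - numba is present in the target env

    def _jit(fn):
        return fn


# ---------------------------------------------------------------------------
# CIGAR
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")


@dataclass(frozen=True)
class Cigar:
    """Run-length encoded alignment structure (SAM semantics)."""

    ops: Tuple[Tuple[int, str], ...]

    def __post_init__(self) -> None:
        merged: List[Tuple[int, str]] = []
        for n, op in self.ops:
            if n < 1:
                raise ValueError(f"zero/negative length op {n}{op}")
            if op not in "MIDNSHP=X":
                raise ValueError(f"illegal CIGAR op {op!r}")
            if merged and merged[-1][1] == op:
                merged[-1] = (merged[-1][0] + n, op)
            else:
                merged.append((n, op))
        object.__setattr__(self, "ops", tuple(merged))

    @classmethod
    def parse(cls, text: str) -> "Cigar":
        if not text or text == "*":
            raise ValueError("empty CIGAR")
        pos = 0
        ops: List[Tuple[int, str]] = []
        for m in _CIGAR_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"malformed CIGAR {text!r}")
            ops.append((int(m.group(1)), m.group(2)))
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"malformed CIGAR {text!r}")
        return cls(tuple(ops))

    def render(self) -> str:
        return "".join(f"{n}{op}" for n, op in self.ops)

    def __str__(self) -> str:
        return self.render()

    @property
    def query_len(self) -> int:
        return sum(n for n, op in self.ops if op in QUERY_OPS)

    @property
    def ref_span(self) -> int:
        return sum(n for n, op in self.ops if op in REF_OPS)


def parse_cigar(text: str) -> Cigar:
    return Cigar.parse(text)


def cigar_summary(c: Cigar) -> dict:
    """Aggregate op-length totals of a CIGAR."""
    return {
        "query_len": c.query_len,
        "ref_span": c.ref_span,
        "n_deleted": sum(n for n, op in c.ops if op == "D"),
        "n_inserted": sum(n for n, op in c.ops if op == "I"),
        "n_clipped": sum(n for n, op in c.ops if op in "SH"),
    }


# ---------------------------------------------------------------------------
# Alignment records and scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRecord:
    """A read's placement inside the reference window.

    ``ref_start`` is a 0-based *window* offset; ``query`` includes
    soft-clipped bases (SAM convention).
    """

    read_id: str
    query: str
    ref_start: int
    cigar: Cigar
    quals: Optional[Tuple[int, ...]] = None
    is_duplicate: bool = False
    is_reverse: bool = False
    mapq: int = 60
    provenance: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.cigar.query_len != len(self.query):
            raise ValueError(
                f"{self.read_id}: CIGAR query length {self.cigar.query_len} "
                f"!= read length {len(self.query)}"
            )
        if self.ref_start < 0:
            raise ValueError(f"{self.read_id}: negative ref_start")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.cigar.ref_span

    def with_provenance(self, tag: str) -> "AlignmentRecord":
        return replace(self, provenance=self.provenance | {tag})


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; a length-k gap costs ``gap_open + k * gap_extend``."""

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -2.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


#: Indel-lenient defaults: one small gap is preferred over two mismatches.
DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class ObservedVariant:
    """An anchor-free edit observed on one read, in window coordinates.

    ``ref`` is empty for insertions, ``alt`` empty for deletions; for an
    insertion ``pos`` is the window offset before which bases are inserted.
    """

    pos: int
    ref: str
    alt: str
    is_pathogenic_match: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt identical")

    @property
    def kind(self) -> str:
        if self.ref and self.alt:
            return "SNV" if len(self.ref) == len(self.alt) == 1 else "DELINS"
        return "DEL" if self.ref else "INS"

    @property
    def span(self) -> Tuple[int, int]:
        """Window-offset interval touched by the variant (>= 1 base wide)."""
        if self.ref:
            return (self.pos, self.pos + len(self.ref))
        return (max(0, self.pos - 1), self.pos + 1)

    @property
    def net(self) -> int:
        return len(self.alt) - len(self.ref)


# ---------------------------------------------------------------------------
# Smith-Waterman
# ---------------------------------------------------------------------------


def _fill_matrices(q, t, match, mismatch, gap_open, gap_extend):
    """Affine-gap local alignment DP over (score, target start, gap count).

    State H ends in a diagonal column, E in a target-consuming gap (deletion),
    F in a query-consuming gap (insertion).  Each cell stores the
    lexicographically best (score desc, target start asc, gap openings asc)
    triple achievable for alignments ending at that cell in that state;
    alignments start only with a diagonal column.
    """
    m, n = len(q), len(t)
    NEG = -1e18
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    Ht = np.zeros((m + 1, n + 1), dtype=np.int64)
    Et = np.zeros((m + 1, n + 1), dtype=np.int64)
    Ft = np.zeros((m + 1, n + 1), dtype=np.int64)
    Hg = np.zeros((m + 1, n + 1), dtype=np.int64)
    Eg = np.zeros((m + 1, n + 1), dtype=np.int64)
    Fg = np.zeros((m + 1, n + 1), dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # E: gap consuming target
            bs, bt, bg = NEG, 0, 0
            s = H[i][j - 1] + gap_open + gap_extend
            if s > bs or (s == bs and (Ht[i][j - 1] < bt or (Ht[i][j - 1] == bt and Hg[i][j - 1] + 1 < bg))):
                bs, bt, bg = s, Ht[i][j - 1], Hg[i][j - 1] + 1
            s = E[i][j - 1] + gap_extend
            if s > bs or (s == bs and (Et[i][j - 1] < bt or (Et[i][j - 1] == bt and Eg[i][j - 1] < bg))):
                bs, bt, bg = s, Et[i][j - 1], Eg[i][j - 1]
            s = F[i][j - 1] + gap_open + gap_extend
            if s > bs or (s == bs and (Ft[i][j - 1] < bt or (Ft[i][j - 1] == bt and Fg[i][j - 1] + 1 < bg))):
                bs, bt, bg = s, Ft[i][j - 1], Fg[i][j - 1] + 1
            E[i][j], Et[i][j], Eg[i][j] = bs, bt, bg
            # F: gap consuming query
            bs, bt, bg = NEG, 0, 0
            s = H[i - 1][j] + gap_open + gap_extend
            if s > bs or (s == bs and (Ht[i - 1][j] < bt or (Ht[i - 1][j] == bt and Hg[i - 1][j] + 1 < bg))):
                bs, bt, bg = s, Ht[i - 1][j], Hg[i - 1][j] + 1
            s = F[i - 1][j] + gap_extend
            if s > bs or (s == bs and (Ft[i - 1][j] < bt or (Ft[i - 1][j] == bt and Fg[i - 1][j] < bg))):
                bs, bt, bg = s, Ft[i - 1][j], Fg[i - 1][j]
            s = E[i - 1][j] + gap_open + gap_extend
            if s > bs or (s == bs and (Et[i - 1][j] < bt or (Et[i - 1][j] == bt and Eg[i - 1][j] + 1 < bg))):
                bs, bt, bg = s, Et[i - 1][j], Eg[i - 1][j] + 1
            F[i][j], Ft[i][j], Fg[i][j] = bs, bt, bg
            # H: diagonal
            sub = match if q[i - 1] == t[j - 1] else mismatch
            bs, bt, bg = 0.0, j - 1, 0  # fresh local start
            if H[i - 1][j - 1] > bs or (H[i - 1][j - 1] == bs and (Ht[i - 1][j - 1] < bt or (Ht[i - 1][j - 1] == bt and Hg[i - 1][j - 1] < bg))):
                bs, bt, bg = H[i - 1][j - 1], Ht[i - 1][j - 1], Hg[i - 1][j - 1]
            if E[i - 1][j - 1] > bs or (E[i - 1][j - 1] == bs and (Et[i - 1][j - 1] < bt or (Et[i - 1][j - 1] == bt and Eg[i - 1][j - 1] < bg))):
                bs, bt, bg = E[i - 1][j - 1], Et[i - 1][j - 1], Eg[i - 1][j - 1]
            if F[i - 1][j - 1] > bs or (F[i - 1][j - 1] == bs and (Ft[i - 1][j - 1] < bt or (Ft[i - 1][j - 1] == bt and Fg[i - 1][j - 1] < bg))):
                bs, bt, bg = F[i - 1][j - 1], Ft[i - 1][j - 1], Fg[i - 1][j - 1]
            H[i][j], Ht[i][j], Hg[i][j] = bs + sub, bt, bg
    return H, E, F, Ht, Et, Ft, Hg, Eg, Fg


_fill_matrices_jit = _jit(_fill_matrices)


@dataclass(frozen=True)
class SWResult:
    """Best local alignment under the scheme, with deterministic tie-breaking."""

    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    cigar: Optional[Cigar]
    n_gaps: int

    @property
    def aligned(self) -> bool:
        return self.cigar is not None

    def columns(self, q_offset: int = 0, t_offset: int = 0) -> Iterator[Tuple[str, Optional[int], Optional[int]]]:
        """Yield ``(op, query index, target index)`` per alignment column."""
        qi, tj = self.q_start + q_offset, self.t_start + t_offset
        if self.cigar is None:
            return
        for n, op in self.cigar.ops:
            for _ in range(n):
                if op == "M":
                    yield ("M", qi, tj)
                    qi += 1
                    tj += 1
                elif op == "I":
                    yield ("I", qi, None)
                    qi += 1
                elif op == "D":
                    yield ("D", None, tj)
                    tj += 1
        return


_EMPTY = SWResult(0.0, 0, 0, 0, 0, None, 0)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)


def smith_waterman(query: str, target: str, scheme: ScoringScheme = DEFAULT_SCHEME) -> SWResult:
    """Best-scoring local alignment of ``query`` against ``target``.

    Affine-gap scoring per ``scheme``.  Ties are broken by smallest target
    offset, then fewest gap openings; traceback prefers diagonal moves, which
    left-aligns gaps among equivalent placements.  If no alignment scores
    above zero, an empty result is returned.
    """
    if not query or not target:
        raise ValueError("query and target must be nonempty")
    q, t = _encode(query), _encode(target)
    H, E, F, Ht, Et, Ft, Hg, Eg, Fg = _fill_matrices_jit(
        q, t, float(scheme.match), float(scheme.mismatch),
        float(scheme.gap_open), float(scheme.gap_extend),
    )
    m, n = len(query), len(target)
    best = (0.0, 0, 0)
    bi = bj = -1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cand = (H[i][j], int(Ht[i][j]), int(Hg[i][j]))
            if (
                cand[0] > best[0]
                or (cand[0] == best[0] and bi >= 0 and (cand[1], cand[2], j, i) < (best[1], best[2], bj, bi))
                or (cand[0] > 0 and bi < 0)
            ):
                best, bi, bj = cand, i, j
    if bi < 0 or best[0] <= 0:
        return _EMPTY

    go, ge = scheme.gap_open, scheme.gap_extend
    ops: List[str] = []
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            sub = scheme.match if query[i - 1] == target[j - 1] else scheme.mismatch
            tr = (H[i][j] - sub, Ht[i][j], Hg[i][j])
            ops.append("M")
            i, j = i - 1, j - 1
            if tr[0] == 0.0 and tr[1] == j and tr[2] == 0:
                break  # fresh local start
            # Diagonal-first preference places gaps leftmost among equal-score
            # placements.
            if H[i][j] == tr[0] and Ht[i][j] == tr[1] and Hg[i][j] == tr[2]:
                state = "H"
            elif E[i][j] == tr[0] and Et[i][j] == tr[1] and Eg[i][j] == tr[2]:
                state = "E"
            elif F[i][j] == tr[0] and Ft[i][j] == tr[1] and Fg[i][j] == tr[2]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed in H state")
        elif state == "E":
            tr_ext = (E[i][j] - ge, Et[i][j], Eg[i][j])
            tr_open = (E[i][j] - go - ge, Et[i][j], Eg[i][j] - 1)
            ops.append("D")
            j -= 1
            if E[i][j] == tr_ext[0] and Et[i][j] == tr_ext[1] and Eg[i][j] == tr_ext[2]:
                state = "E"
            elif H[i][j] == tr_open[0] and Ht[i][j] == tr_open[1] and Hg[i][j] == tr_open[2]:
                state = "H"
            elif F[i][j] == tr_open[0] and Ft[i][j] == tr_open[1] and Fg[i][j] == tr_open[2]:
                state = "F"
            else:  # pragma: no cover
                raise AssertionError("traceback failed in E state")
        else:  # F
            tr_ext = (F[i][j] - ge, Ft[i][j], Fg[i][j])
            tr_open = (F[i][j] - go - ge, Ft[i][j], Fg[i][j] - 1)
            ops.append("I")
            i -= 1
            if F[i][j] == tr_ext[0] and Ft[i][j] == tr_ext[1] and Fg[i][j] == tr_ext[2]:
                state = "F"
            elif H[i][j] == tr_open[0] and Ht[i][j] == tr_open[1] and Hg[i][j] == tr_open[2]:
                state = "H"
            elif E[i][j] == tr_open[0] and Et[i][j] == tr_open[1] and Eg[i][j] == tr_open[2]:
                state = "E"
            else:  # pragma: no cover
                raise AssertionError("traceback failed in F state")
    ops.reverse()
    cigar = Cigar(tuple((1, op) for op in ops))
    return SWResult(
        score=float(best[0]),
        q_start=i,
        q_end=bi,
        t_start=j,
        t_end=bj,
        cigar=cigar,
        n_gaps=int(best[2]),
    )


# ---------------------------------------------------------------------------
# Record inspection helpers
# ---------------------------------------------------------------------------


def extract_observed_variants(rec: AlignmentRecord, ctx: ReferenceContext) -> List[ObservedVariant]:
    """Decompose a finalized record into anchor-free variants vs the window.

    Emits SNVs at mismatching M columns, DELs for D ops and INSs for I ops;
    an emitted variant equal to the pathogenic core edit is flagged
    ``is_pathogenic_match``.
    """
    out: List[ObservedVariant] = []
    r, q = rec.ref_start, 0
    ref = ctx.ref_seq
    for n, op in rec.cigar.ops:
        if op in ("S",):
            q += n
        elif op == "H" or op == "P":
            continue
        elif op == "N":
            r += n
        elif op in ("M", "=", "X"):
            if r + n > len(ref):
                raise ValueError(f"{rec.read_id}: alignment extends past window")
            for k in range(n):
                rb, qb = ref[r + k], rec.query[q + k]
                if rb != qb:
                    out.append(ObservedVariant(r + k, rb, qb))
            r += n
            q += n
        elif op == "D":
            if r + n > len(ref):
                raise ValueError(f"{rec.read_id}: deletion extends past window")
            out.append(ObservedVariant(r, ref[r : r + n], ""))
            r += n
        elif op == "I":
            out.append(ObservedVariant(r, "", rec.query[q : q + n]))
            q += n
        else:  # pragma: no cover
            raise ValueError(f"unsupported CIGAR op {op}")
    flagged = []
    for v in out:
        match = v.pos == ctx.var_start and v.ref == ctx.var_ref and v.alt == ctx.var_alt
        flagged.append(replace(v, is_pathogenic_match=match) if match else v)
    return flagged


def compose_alignment(
    ref_seq: str, start: int, end: int, variants: Sequence[ObservedVariant]
) -> Tuple[str, Cigar]:
    """Rebuild the query and CIGAR implied by ``variants`` over ``[start, end)``.

    Inverse of :func:`extract_observed_variants` for records without clips.
    """
    vs = sorted(variants, key=lambda v: (v.pos, -len(v.ref)))
    dels = {}
    snvs = {}
    inss = {}
    for v in vs:
        if v.kind == "DEL":
            dels[v.pos] = len(v.ref)
        elif v.kind == "INS":
            inss.setdefault(v.pos, "")
            inss[v.pos] += v.alt
        elif v.kind == "SNV":
            snvs[v.pos] = v.alt
        else:
            raise ValueError("DELINS not supported in composition")
    query: List[str] = []
    ops: List[Tuple[int, str]] = []
    r = start
    while r < end:
        if r in inss:
            query.append(inss[r])
            ops.append((len(inss[r]), "I"))
        if r in dels:
            n = dels[r]
            ops.append((n, "D"))
            r += n
            continue
        query.append(snvs.get(r, ref_seq[r]))
        ops.append((1, "M"))
        r += 1
    if end in inss:
        query.append(inss[end])
        ops.append((len(inss[end]), "I"))
    return "".join(query), Cigar(tuple(ops))


def count_mismatches(rec: AlignmentRecord, ctx: ReferenceContext) -> int:
    return sum(1 for v in extract_observed_variants(rec, ctx) if v.kind == "SNV")


def _longest_perfect_run(res: SWResult, query: str, target: str) -> int:
    best = run = 0
    for op, qi, tj in res.columns():
        if op == "M" and query[qi] == target[tj]:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


# ---------------------------------------------------------------------------
# Soft-clip rescue
# ---------------------------------------------------------------------------


def rescue_soft_clips(
    rec: AlignmentRecord,
    ctx: ReferenceContext,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    min_perfect: int = 20,
) -> AlignmentRecord:
    """Try to convert terminal soft clips into matched structure.

    Each S segment is Smith-Waterman aligned against the reference window; if
    the best placement contains a contiguous run of at least ``min_perfect``
    perfectly matched bases, sits on the correct side of the anchored portion
    and reaches the clip boundary, the S op is replaced by the aligned
    structure plus a joining D for any skipped reference bases.  Unconvertible
    clips are left untouched.
    """
    ops = list(rec.cigar.ops)
    if not any(op == "S" for _, op in ops):
        return rec
    changed = False
    query, ref = rec.query, ctx.ref_seq

    # leading clip
    if ops[0][1] == "S":
        clip_len = ops[0][0]
        res = smith_waterman(query[:clip_len], ref, scheme)
        if (
            res.aligned
            and res.q_end == clip_len
            and res.t_end <= rec.ref_start
            and _longest_perfect_run(res, query[:clip_len], ref) >= min_perfect
        ):
            new_ops: List[Tuple[int, str]] = []
            if res.q_start > 0:
                new_ops.append((res.q_start, "S"))
            new_ops.extend(res.cigar.ops)
            if rec.ref_start - res.t_end > 0:
                new_ops.append((rec.ref_start - res.t_end, "D"))
            new_ops.extend(ops[1:])
            rec = replace(rec, ref_start=res.t_start, cigar=Cigar(tuple(new_ops)))
            ops = list(rec.cigar.ops)
            changed = True

    # trailing clip
    if ops[-1][1] == "S":
        clip_len = ops[-1][0]
        anchor_end = rec.ref_start + Cigar(tuple(ops[:-1])).ref_span
        res = smith_waterman(query[len(query) - clip_len :], ref, scheme)
        if (
            res.aligned
            and res.q_start == 0
            and res.t_start >= anchor_end
            and _longest_perfect_run(res, query[len(query) - clip_len :], ref) >= min_perfect
        ):
            new_ops = list(ops[:-1])
            if res.t_start - anchor_end > 0:
                new_ops.append((res.t_start - anchor_end, "D"))
            new_ops.extend(res.cigar.ops)
            if clip_len - res.q_end > 0:
                new_ops.append((clip_len - res.q_end, "S"))
            rec = replace(rec, cigar=Cigar(tuple(new_ops)))
            changed = True

    return rec.with_provenance("softclip_rescued") if changed else rec


# ---------------------------------------------------------------------------
# Personalized realignment
# ---------------------------------------------------------------------------


def _collapse_indel_pairs(
    cols: List[Tuple[str, Optional[int], Optional[int]]],
    query: str,
    ref: str,
    max_sep: int = 20,
) -> List[Tuple[str, Optional[int], Optional[int]]]:
    """Collapse gap-placement artifacts in a per-column alignment.

    An equal-length I run and D run, adjacent or separated by a short M run,
    whose combined segment reads identically in query and reference, is an
    artifact of where the aligner placed the gaps (it arises when the
    pathogenic edit borders repeated sequence); the segment is rewritten as
    matches.  Columns are ``(op, ref_pos, query_pos)``.
    """
    changed = True
    while changed:
        changed = False
        groups: List[Tuple[str, int, int]] = []  # (op, start, end) over cols
        for k, col in enumerate(cols):
            if groups and groups[-1][0] == col[0]:
                groups[-1] = (col[0], groups[-1][1], k + 1)
            else:
                groups.append((col[0], k, k + 1))
        for a in range(len(groups)):
            op_a, sa, ea = groups[a]
            if op_a not in "ID":
                continue
            for b in (a + 1, a + 2):
                if b >= len(groups):
                    break
                op_b, sb, eb = groups[b]
                if b == a + 1 and op_b == "M":
                    if eb - sb > max_sep:
                        break
                    continue
                if {op_a, op_b} != {"I", "D"} or (ea - sa) != (eb - sb):
                    break
                seg = cols[sa:eb]
                q_idx = [q for _, _, q in seg if q is not None]
                r_idx = [r for _, r, _ in seg if r is not None]
                if len(q_idx) == len(r_idx) and all(
                    query[q] == ref[r] for q, r in zip(q_idx, r_idx)
                ):
                    cols[sa:eb] = [("M", r, q) for q, r in zip(q_idx, r_idx)]
                    changed = True
                break
            if changed:
                break
    return cols


def _lift_to_reference(
    res: SWResult, query: str, ctx: ReferenceContext
) -> Tuple[int, Cigar]:
    """Re-express a personalized-space alignment in reference window coordinates.

    The pathogenic edit re-appears as D/I structure implied by the coordinate
    map; paired indel artifacts around the junction are collapsed back to
    matches when the read actually follows the reference there.
    """
    cols: List[Tuple[str, Optional[int], Optional[int]]] = []
    prev_r: Optional[int] = None
    for op, qi, tj in res.columns():
        if op == "I":
            cols.append(("I", None, qi))
            continue
        r = ctx.pers2ref[tj]
        if r is None:  # personalized-only base (pathogenic insertion)
            if op == "M":
                cols.append(("I", None, qi))
            continue
        if prev_r is not None and r > prev_r + 1:
            # reference bases absent from the personalized sequence
            cols.extend(("D", g, None) for g in range(prev_r + 1, r))
        cols.append((op, r, qi))
        prev_r = r
    cols = _collapse_indel_pairs(cols, query, ctx.ref_seq)

    ops: List[Tuple[int, str]] = []
    if res.q_start > 0:
        ops.append((res.q_start, "S"))
    ops.extend((1, op) for op, _, _ in cols)
    if len(query) - res.q_end > 0:
        ops.append((len(query) - res.q_end, "S"))
    ref_positions = [r for _, r, _ in cols if r is not None]
    if not ref_positions:
        raise ValueError("lifted alignment has no reference footprint")
    return ref_positions[0], Cigar(tuple(ops))


def realign_over_pathogenic(
    rec: AlignmentRecord,
    ctx: ReferenceContext,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> AlignmentRecord:
    """Realign a read against the personalized window; accept only perfect matches.

    Triggered when the record's span overlaps the pathogenic edit and the
    record either contains a mismatch or does not already encode the
    pathogenic allele.  The read is Smith-Waterman aligned to the personalized
    sequence; the new alignment is accepted iff every aligned base matches
    exactly (additional indels — the candidate reversions — are permitted) and
    the previously aligned portion of the read is fully covered.  Accepted
    alignments are lifted back to reference coordinates via the coordinate
    map; anything else leaves the record untouched.
    """
    p_lo, p_hi = ctx.var_start, max(ctx.var_end, ctx.var_start + 1)
    if rec.ref_end <= p_lo or rec.ref_start >= p_hi:
        return rec
    observed = extract_observed_variants(rec, ctx)
    has_mismatch = any(v.kind == "SNV" for v in observed)
    encodes_pathogenic = any(v.is_pathogenic_match for v in observed)
    if not has_mismatch and encodes_pathogenic:
        return rec

    res = smith_waterman(rec.query, ctx.pers_seq, scheme)
    if not res.aligned:
        return rec
    for op, qi, tj in res.columns():
        if op == "M" and rec.query[qi] != ctx.pers_seq[tj]:
            return rec  # mismatch against the personalized genome: reject
    lead_s = rec.cigar.ops[0][0] if rec.cigar.ops[0][1] == "S" else 0
    trail_s = rec.cigar.ops[-1][0] if rec.cigar.ops[-1][1] == "S" else 0
    if res.q_start > lead_s or res.q_end < len(rec.query) - trail_s:
        return rec  # previously anchored bases left unaligned: reject

    new_start, new_cigar = _lift_to_reference(res, rec.query, ctx)
    if new_start == rec.ref_start and new_cigar.ops == rec.cigar.ops:
        return rec
    return replace(rec, ref_start=new_start, cigar=new_cigar).with_provenance(
        "realigned_personalized"
    )


# ---------------------------------------------------------------------------
# Indel placement normalization
# ---------------------------------------------------------------------------


def normalize_indel_placement(rec: AlignmentRecord, ctx: ReferenceContext) -> AlignmentRecord:
    """Move a sequence-equivalent indel onto the pathogenic span.

    If the record carries an indel of the same shape as the pathogenic edit at
    a different position, and rewriting it to sit on the pathogenic span
    reconstructs the identical read sequence, the CIGAR is rewritten to the
    genetically plausible placement.  Idempotent; the read's bases are never
    altered.
    """
    variants = extract_observed_variants(rec, ctx)
    if any(v.is_pathogenic_match for v in variants):
        return rec
    lead_s = rec.cigar.ops[0][0] if rec.cigar.ops[0][1] == "S" else 0
    trail_s = rec.cigar.ops[-1][0] if rec.cigar.ops[-1][1] == "S" else 0
    aligned_query = rec.query[lead_s : len(rec.query) - trail_s or None]
    span_lo, span_hi = rec.ref_start, rec.ref_end
    if not (span_lo <= ctx.var_start and ctx.var_start + len(ctx.var_ref) <= span_hi):
        return rec
    for v in variants:
        if v.kind not in ("DEL", "INS"):
            continue
        if len(v.ref) != len(ctx.var_ref) or len(v.alt) != len(ctx.var_alt):
            continue
        trial = [w for w in variants if w is not v]
        trial.append(ObservedVariant(ctx.var_start, ctx.var_ref, ctx.var_alt, True))
        positions = sorted((w.pos, len(w.ref)) for w in trial)
        if any(a[0] + a[1] > b[0] for a, b in zip(positions, positions[1:])):
            continue
        try:
            q2, cig2 = compose_alignment(ctx.ref_seq, span_lo, span_hi, trial)
        except ValueError:
            continue
        if q2 != aligned_query:
            continue
        new_ops: List[Tuple[int, str]] = []
        if lead_s:
            new_ops.append((lead_s, "S"))
        new_ops.extend(cig2.ops)
        if trail_s:
            new_ops.append((trail_s, "S"))
        return replace(rec, cigar=Cigar(tuple(new_ops))).with_provenance("normalized")
    return rec
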