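import random
from dataclasses import replace

import pytest
from hypothesis import given, settings, strategies as st

from revertscan.alignment_core import (
    AlignmentRecord,
    Cigar,
    DEFAULT_SCHEME,
    ObservedVariant,
    ScoringScheme,
    cigar_summary,
    compose_alignment,
    extract_observed_variants,
    normalize_indel_placement,
    parse_cigar,
    realign_over_pathogenic,
    rescue_soft_clips,
    smith_waterman,
)
from revertscan.genome_model import GenomicInterval, PathogenicVariant, ReferenceContext

from conftest import random_dna, sw_oracle, sw_result_triple

LENIENT = ScoringScheme(2, -3, -0.5, -0.5)


# ---------------------------------------------------------------------------
# CIGAR
# ---------------------------------------------------------------------------


class TestCigar:
    def test_parse_example(self):
        assert parse_cigar("10M1D140M").ops == ((10, "M"), (1, "D"), (140, "M"))

    def test_single_op(self):
        assert parse_cigar("150M").ops == ((150, "M"),)

    @pytest.mark.parametrize("bad", ["", "*", "10", "M", "10M5", "3Q", "0M", "-1M"])
    def test_malformed(self, bad):
        with pytest.raises(ValueError):
            parse_cigar(bad)

    def test_adjacent_ops_merged(self):
        assert Cigar(((5, "M"), (3, "M"), (1, "D"))).render() == "8M1D"

    def test_round_trip_random(self):
        rng = random.Random(99)
        ops_pool = "MIDNSX="
        for _ in range(1000):
            ops = []
            prev = None
            for _k in range(rng.randint(1, 8)):
                op = rng.choice([o for o in ops_pool if o != prev])
                ops.append(f"{rng.randint(1, 300)}{op}")
                prev = op
            text = "".join(ops)
            assert parse_cigar(text).render() == text

    def test_summary_worked_example(self):
        s = cigar_summary(parse_cigar("4M2D6M1D140M"))
        assert s["n_deleted"] == 3
        assert s["query_len"] == 150
        assert s["ref_span"] == 153

    def test_summary_trivial(self):
        assert cigar_summary(parse_cigar("150M"))["n_deleted"] == 0

    def test_summary_matches_per_op_accumulation(self):
        rng = random.Random(4)
        for _ in range(200):
            ops = []
            prev = None
            for _k in range(rng.randint(1, 10)):
                op = rng.choice([o for o in "MIDNS" if o != prev])
                ops.append((rng.randint(1, 50), op))
                prev = op
            c = Cigar(tuple(ops))
            q = r = d = i_ = cl = 0
            for n, op in ops:
                if op in "MIS":
                    q += n
                if op in "MDN":
                    r += n
                if op == "D":
                    d += n
                if op == "I":
                    i_ += n
                if op == "S":
                    cl += n
            s = cigar_summary(c)
            assert (s["query_len"], s["ref_span"], s["n_deleted"], s["n_inserted"], s["n_clipped"]) == (q, r, d, i_, cl)


# ---------------------------------------------------------------------------
# Smith-Waterman
# ---------------------------------------------------------------------------


class TestSmithWaterman:
    def test_perfect_substring(self):
        res = smith_waterman("ACGT", "TTACGTTT", DEFAULT_SCHEME)
        assert res.score == 4 * DEFAULT_SCHEME.match
        assert (res.t_start, res.t_end) == (2, 6)
        assert str(res.cigar) == "4M"

    def test_dinucleotide_tie_break_leftmost(self):
        # two equal-score 2-nt deletion placements; the leftmost must win
        res = smith_waterman("ACGAT", "ACGAGAT", LENIENT)
        assert res.t_start == 0
        assert str(res.cigar) == "2M2D3M"
        assert res.n_gaps == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")

    def test_no_positive_alignment(self):
        res = smith_waterman("AAAA", "CCCC", DEFAULT_SCHEME)
        assert not res.aligned
        assert res.score == 0.0

    def test_query_coverage_consistency(self):
        rng = random.Random(21)
        for _ in range(50):
            t = random_dna(rng, 60)
            q = t[20:40]
            res = smith_waterman(q, t, DEFAULT_SCHEME)
            assert res.cigar.query_len == res.q_end - res.q_start
            assert res.cigar.ref_span == res.t_end - res.t_start

    @pytest.mark.parametrize("scheme", [DEFAULT_SCHEME, LENIENT, ScoringScheme(3, -2, -1, -1)])
    def test_matches_enumeration_oracle(self, scheme):
        rng = random.Random(hash((scheme.match, scheme.gap_open)) & 0xFFFF)
        for _ in range(400):
            q = random_dna(rng, rng.randint(1, 8)).replace("T", "G")
            t = random_dna(rng, rng.randint(1, 8)).replace("T", "G")
            assert sw_result_triple(q, t, scheme) == sw_oracle(q, t, scheme)


# ---------------------------------------------------------------------------
# Shared context builders
# ---------------------------------------------------------------------------


def _make_ctx(seed=17, n=600, var_pos=300, del_len=2):
    rng = random.Random(seed)
    seq = random_dna(rng, n)
    pv = PathogenicVariant("w", var_pos, seq[var_pos - 1 : var_pos + del_len], seq[var_pos - 1])
    return ReferenceContext.build(pv, GenomicInterval("w", 0, n), seq)


# ---------------------------------------------------------------------------
# Soft-clip rescue
# ---------------------------------------------------------------------------


class TestRescueSoftClips:
    def test_no_clip_is_noop(self, dinuc_ctx):
        rec = AlignmentRecord("r", "ACGAGAT", 0, parse_cigar("7M"))
        assert rescue_soft_clips(rec, dinuc_ctx) is rec

    def test_leading_clip_converted_to_m_d_m(self):
        ctx = _make_ctx(seed=31, n=400, var_pos=380)
        ref = ctx.ref_seq
        read = ref[120:150] + ref[200:320]  # clipped part matches 50 nt upstream
        rec = AlignmentRecord("r", read, 200, parse_cigar("30S120M"))
        out = rescue_soft_clips(rec, ctx, min_perfect=20)
        assert out.ref_start == 120
        assert str(out.cigar) == "30M50D120M"
        assert "softclip_rescued" in out.provenance
        assert out.query == rec.query

    def test_trailing_clip_converted(self):
        ctx = _make_ctx(seed=32, n=400, var_pos=20)
        ref = ctx.ref_seq
        read = ref[100:220] + ref[260:290]
        rec = AlignmentRecord("r", read, 100, parse_cigar("120M30S"))
        out = rescue_soft_clips(rec, ctx, min_perfect=20)
        assert str(out.cigar) == "120M40D30M"
        assert out.ref_start == 100
        assert "softclip_rescued" in out.provenance

    def test_short_perfect_run_left_unchanged(self):
        ctx = _make_ctx(seed=33, n=400, var_pos=380)
        ref = ctx.ref_seq
        read = ref[130:140] + ref[200:340]
        rec = AlignmentRecord("r", read, 200, Cigar(((10, "S"), (140, "M"))))
        out = rescue_soft_clips(rec, ctx, min_perfect=20)
        assert out is rec  # 10-nt run is shorter than min_perfect


# ---------------------------------------------------------------------------
# Personalized realignment
# ---------------------------------------------------------------------------


class TestRealignOverPathogenic:
    def test_perfect_reference_read_unchanged(self):
        ctx = _make_ctx(seed=41)
        read = ctx.ref_seq[250:400]  # spans the pathogenic locus, matches reference
        rec = AlignmentRecord("r", read, 250, parse_cigar("150M"))
        out = realign_over_pathogenic(rec, ctx)
        assert out == rec

    def test_non_overlapping_read_untouched(self):
        ctx = _make_ctx(seed=42)
        read = ctx.ref_seq[10:160]
        rec = AlignmentRecord("r", read, 10, parse_cigar("150M"))
        assert realign_over_pathogenic(rec, ctx) is rec

    def test_pathogenic_read_recovers_deletion(self):
        ctx = _make_ctx(seed=43)
        read = ctx.pers_seq[250:400]  # carries the 2-nt pathogenic deletion
        rec = AlignmentRecord("r", read, 250, parse_cigar("150M"))
        out = realign_over_pathogenic(rec, ctx)
        assert "realigned_personalized" in out.provenance
        assert cigar_summary(out.cigar)["n_deleted"] == len(ctx.var_ref)
        variants = extract_observed_variants(out, ctx)
        assert [v.is_pathogenic_match for v in variants] == [True]
        assert out.query == rec.query

    def test_secondary_deletion_read_accepted_with_total_deletions(self):
        ctx = _make_ctx(seed=44)
        hap = ctx.pers_seq[:330] + ctx.pers_seq[334:]  # extra 4-nt deletion
        read = hap[250:400]
        rec = AlignmentRecord("r", read, 250, parse_cigar("150M"))
        out = realign_over_pathogenic(rec, ctx)
        assert "realigned_personalized" in out.provenance
        assert cigar_summary(out.cigar)["n_deleted"] == len(ctx.var_ref) + 4
        assert out.query == rec.query
        assert cigar_summary(out.cigar)["query_len"] == 150

    def test_mismatching_read_rejected_bit_identical(self):
        ctx = _make_ctx(seed=45)
        read = list(ctx.pers_seq[250:400])
        read[75] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[75]]
        rec = AlignmentRecord("r", "".join(read), 250, parse_cigar("150M"))
        out = realign_over_pathogenic(rec, ctx)
        assert out is rec

    def test_pathogenic_insertion_lifted(self):
        rng = random.Random(46)
        seq = random_dna(rng, 400)
        pv = PathogenicVariant("w", 200, seq[199], seq[199] + "TTCG")
        ctx = ReferenceContext.build(pv, GenomicInterval("w", 0, 400), seq)
        read = ctx.pers_seq[150:300]
        rec = AlignmentRecord("r", read, 150, parse_cigar("150M"))
        out = realign_over_pathogenic(rec, ctx)
        assert "realigned_personalized" in out.provenance
        variants = extract_observed_variants(out, ctx)
        assert any(v.is_pathogenic_match and v.kind == "INS" for v in variants)


# ---------------------------------------------------------------------------
# Indel placement normalization
# ---------------------------------------------------------------------------


class TestNormalizeIndelPlacement:
    def test_dinucleotide_example(self, dinuc_ctx):
        rec = AlignmentRecord("r", "ACGAT", 0, parse_cigar("4M2D1M"))
        out = normalize_indel_placement(rec, dinuc_ctx)
        assert str(out.cigar) == "2M2D3M"
        assert "normalized" in out.provenance

    def test_idempotent(self, dinuc_ctx):
        rec = AlignmentRecord("r", "ACGAT", 0, parse_cigar("2M2D3M"))
        out = normalize_indel_placement(rec, dinuc_ctx)
        assert out is rec

    def test_reconstruction_preserved_on_random_tandem_contexts(self):
        rng = random.Random(55)
        done = 0
        while done < 40:
            seq = list(random_dna(rng, 200))
            L = rng.randint(2, 4)
            p = rng.randint(60, 120)
            seq[p + L : p + 2 * L] = seq[p : p + L]  # tandem repeat
            seq = "".join(seq)
            # pathogenic deletion of the first repeat copy [p, p+L)
            pv = PathogenicVariant("w", p, seq[p - 1 : p + L], seq[p - 1])
            try:
                ctx = ReferenceContext.build(pv, GenomicInterval("w", 0, 200), seq)
            except ValueError:
                continue
            assert (ctx.var_start, ctx.var_ref) == (p, seq[p : p + L])
            # a record placing the deletion over the second repeat copy
            second = ctx.var_start + L
            dele = ObservedVariant(second, seq[second : second + L], "")
            start, end = p - 30, p + 2 * L + 30
            query, cigar = compose_alignment(seq, start, end, [dele])
            rec = AlignmentRecord("r", query, start, cigar)
            out = normalize_indel_placement(rec, ctx)
            assert out.query == rec.query
            vs = extract_observed_variants(out, ctx)
            q2, _ = compose_alignment(seq, start, end, vs)
            assert q2 == query  # reconstruction is byte-identical
            assert any(v.is_pathogenic_match for v in vs)
            assert normalize_indel_placement(out, ctx) is out
            done += 1


# ---------------------------------------------------------------------------
# Variant extraction
# ---------------------------------------------------------------------------


class TestExtractObservedVariants:
    def test_perfect_match_is_empty(self, dinuc_ctx):
        rec = AlignmentRecord("r", "ACGAGAT", 0, parse_cigar("7M"))
        assert extract_observed_variants(rec, dinuc_ctx) == []

    def test_two_deletions_worked_example(self, fig1b_dir):
        from conftest import run_config_for
        from revertscan.genome_model import build_reference_context
        from revertscan.io_cli import fetch_reads, load_pathogenic_variants, process_read, load_transcript
        import pyfaidx

        d, truth = fig1b_dir
        cfg = run_config_for(d)
        pv = load_pathogenic_variants(cfg.vcf_path)[0]
        ctx = build_reference_context(cfg.fasta_path, pv)
        rec = fetch_reads(cfg.bam_path, ctx.window, cfg)[0]
        assert str(rec.cigar) == "10M1D140M"
        final, _ = process_read(
            rec, ctx, load_transcript(cfg.transcript_path), pyfaidx.Fasta(cfg.fasta_path), cfg
        )
        assert str(final.cigar) == "4M2D6M1D140M"
        vs = extract_observed_variants(final, ctx)
        assert [v.kind for v in vs] == ["DEL", "DEL"]
        assert sum(len(v.ref) for v in vs) == 3
        assert [v.is_pathogenic_match for v in vs] == [True, False]

    def test_round_trip_with_planted_variants(self):
        ctx = _make_ctx(seed=61)
        rng = random.Random(61)
        for _ in range(30):
            planted = []
            pos = 150
            while pos < 420:
                kind = rng.choice(["SNV", "DEL", "INS", None])
                if kind == "SNV":
                    alt = rng.choice([b for b in "ACGT" if b != ctx.ref_seq[pos]])
                    planted.append(ObservedVariant(pos, ctx.ref_seq[pos], alt))
                elif kind == "DEL":
                    n = rng.randint(1, 5)
                    planted.append(ObservedVariant(pos, ctx.ref_seq[pos : pos + n], ""))
                    pos += n
                elif kind == "INS":
                    planted.append(ObservedVariant(pos, "", random_dna(rng, rng.randint(1, 4))))
                pos += rng.randint(10, 40)
            query, cigar = compose_alignment(ctx.ref_seq, 140, 440, planted)
            rec = AlignmentRecord("r", query, 140, cigar)
            got = extract_observed_variants(rec, ctx)
            key = lambda v: (v.pos, v.ref, v.alt)
            assert sorted(map(key, got)) == sorted(map(key, planted))

    def test_query_length_conserved_through_stages(self):
        ctx = _make_ctx(seed=62)
        hap = ctx.pers_seq[:320] + ctx.pers_seq[321:]
        read = hap[250:400]
        rec = AlignmentRecord("r", read, 250, parse_cigar("150M"))
        out = normalize_indel_placement(
            realign_over_pathogenic(rescue_soft_clips(rec, ctx), ctx), ctx
        )
        assert cigar_summary(out.cigar)["query_len"] == 150
        assert out.query == read
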