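"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random
from functools import lru_cache
from typing import Optional, Tuple

import pytest

from revertscan.alignment_core import ScoringScheme, smith_waterman
from revertscan.fixtures import FixtureSpec, default_spec, generate_fixture, make_fig1b_case
from revertscan.genome_model import (
    GenomicInterval,
    PathogenicVariant,
    ReferenceContext,
    TranscriptModel,
)
from revertscan.io_cli import RunConfig


# ---------------------------------------------------------------------------
# Smith-Waterman enumeration oracle (independent of the DP implementation)
# ---------------------------------------------------------------------------


def sw_oracle(query: str, target: str, scheme: ScoringScheme) -> Tuple[float, Optional[int], Optional[int]]:
    """Best local alignment by recursive enumeration over all gapped paths.

    Returns ``(score, target_start, n_gap_openings)`` under the same objective
    as the implementation: maximize score, then smallest target start, then
    fewest gap openings.  ``(0.0, None, None)`` if nothing scores above zero.
    Alignments begin and may end anywhere, but start with an aligned column.
    """
    m, n = len(query), len(target)
    mt, mm = scheme.match, scheme.mismatch
    go, ge = scheme.gap_open, scheme.gap_extend

    @lru_cache(maxsize=None)
    def suffix_best(i: int, j: int, state: int) -> Tuple[float, int]:
        """Best (score, -n_gaps) continuation from (i, j); may stop immediately.
        state: 0 after an aligned column, 1 inside a target gap, 2 query gap."""
        best = (0.0, 0)
        if i < m and j < n:
            s = mt if query[i] == target[j] else mm
            sc, ng = suffix_best(i + 1, j + 1, 0)
            best = max(best, (s + sc, ng), key=lambda x: (x[0], x[1]))
        if j < n:
            cost, dg = (ge, 0) if state == 1 else (go + ge, -1)
            sc, ng = suffix_best(i, j + 1, 1)
            best = max(best, (cost + sc, ng + dg), key=lambda x: (x[0], x[1]))
        if i < m:
            cost, dg = (ge, 0) if state == 2 else (go + ge, -1)
            sc, ng = suffix_best(i + 1, j, 2)
            best = max(best, (cost + sc, ng + dg), key=lambda x: (x[0], x[1]))
        return best

    best_score, best_t, best_g = 0.0, None, None
    for j0 in range(n):
        for i0 in range(m):
            s0 = mt if query[i0] == target[j0] else mm
            sc, neg_g = suffix_best(i0 + 1, j0 + 1, 0)
            tot, g = s0 + sc, -neg_g
            if tot > best_score or (
                tot == best_score
                and best_t is not None
                and (j0, g) < (best_t, best_g)
            ):
                best_score, best_t, best_g = tot, j0, g
    suffix_best.cache_clear()
    if best_score <= 0:
        return 0.0, None, None
    return best_score, best_t, best_g


def sw_result_triple(query: str, target: str, scheme: ScoringScheme):
    res = smith_waterman(query, target, scheme)
    if not res.aligned:
        return 0.0, None, None
    return res.score, res.t_start, res.n_gaps


# ---------------------------------------------------------------------------
# Toy reference context: window ACGAGAT with the pathogenic GA deletion
# ---------------------------------------------------------------------------


@pytest.fixture
def dinuc_ctx() -> ReferenceContext:
    pv = PathogenicVariant("w", 2, "CGA", "C")  # deletes the first GA
    return ReferenceContext.build(pv, GenomicInterval("w", 0, 7), "ACGAGAT")


# ---------------------------------------------------------------------------
# Generated data sets (session-scoped; regeneration is deterministic)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def fig1b_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fig1b")
    truth = make_fig1b_case(d)
    return d, truth


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """3 planted alleles, depth ~120, no errors or duplicates: exact recovery."""
    d = tmp_path_factory.mktemp("small_fixture")
    spec = default_spec(11, n_alleles=3, depth=120, error_rate=0.0, n_spanning=1)
    truth = generate_fixture(spec, d)
    return d, truth


@pytest.fixture(scope="session")
def dup_fixture(tmp_path_factory):
    """~100 primary reads plus 10% duplicate-flagged copies."""
    d = tmp_path_factory.mktemp("dup_fixture")
    spec = default_spec(23, n_alleles=2, depth=100, dup_fraction=0.1)
    truth = generate_fixture(spec, d)
    return d, truth


def run_config_for(d) -> RunConfig:
    return RunConfig(
        bam_path=str(d / "reads.sam"),
        vcf_path=str(d / "pathogenic.vcf"),
        fasta_path=str(d / "ref.fa"),
        transcript_path=str(d / "transcript.tsv"),
        out_dir=str(d),
    )


@pytest.fixture(scope="session")
def sw_warm():
    """Trigger numba compilation once so timed tests measure the algorithm."""
    smith_waterman("ACGT", "TTACGTT")
    return True


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))
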