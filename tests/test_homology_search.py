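"""Alignment, E-value and RBH tests, including the independent DP oracle."""

import math
import random

import numpy as np
import pytest

from lspscan.homology_search import (
    AlignmentError,
    HitTable,
    Hit,
    align_pair,
    all_vs_all,
    bitscore,
    estimate_evalue,
    hit_table_from_rows,
    hit_table_to_rows,
    load_substitution_matrix,
    reciprocal_best_hits,
)
from lspscan.io_formats import Gene

MAT = load_substitution_matrix()
AAS = "ACDEFGHIKLMNPQRSTVWY"

NEG = -(10 ** 9)


def oracle_sw(a: str, b: str, go: int = 11, ge: int = 1) -> int:
    """Independent three-state affine Smith-Waterman, written from the recurrences."""
    n, m = len(a), len(b)
    best = 0
    M = [[0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - go - ge, X[i - 1][j] - ge)
            Y[i][j] = max(M[i][j - 1] - go - ge, Y[i][j - 1] - ge)
            M[i][j] = max(
                0, MAT[(a[i - 1], b[j - 1])] + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            )
            best = max(best, M[i][j])
    return best


def oracle_enumerate(a: str, b: str, go: int = 11, ge: int = 1) -> int:
    """Brute-force enumeration of every local alignment (tiny inputs only).

    Walks all monotone alignment paths between all substring pairs, scoring
    affine gaps; validates the DP oracle itself.
    """
    best = 0

    def extend(i, j, score, state):
        nonlocal best
        best = max(best, score)
        if i < len(a) and j < len(b):
            extend(i + 1, j + 1, score + MAT[(a[i], b[j])], "m")
        if i < len(a):
            cost = ge if state == "x" else go + ge
            extend(i + 1, j, score - cost, "x")
        if j < len(b):
            cost = ge if state == "y" else go + ge
            extend(i, j + 1, score - cost, "y")

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            extend(i0, j0, 0, "m")
    return best


def rand_seq(rng: random.Random, lo: int, hi: int) -> str:
    return "".join(rng.choices(AAS, k=rng.randint(lo, hi)))


class TestAlignPair:
    def test_identical_short_sequence_scores_diagonal_sum(self):
        aln = align_pair("ACDE", "ACDE")
        assert aln.raw_score == sum(MAT[(c, c)] for c in "ACDE")

    def test_self_alignment_full_identity_and_coverage(self):
        seq = "MKVLWAALLVTFLAGCQA"
        aln = align_pair(seq, seq)
        assert aln.identity == 1.0
        assert aln.query_coverage == 1.0
        assert aln.subject_coverage == 1.0

    def test_empty_sequence_errors(self):
        with pytest.raises(AlignmentError):
            align_pair("", "ACD")

    def test_bad_residue_errors(self):
        with pytest.raises(AlignmentError):
            align_pair("AC1", "ACD")

    def test_x_scores_zero(self):
        # an all-X query can never score above zero against anything
        aln = align_pair("AXA", "AYA")
        assert aln.raw_score == 2 * MAT[("A", "A")]

    def test_enumeration_validates_dp_oracle(self):
        rng = random.Random(17)
        for _ in range(12):
            a = rand_seq(rng, 2, 5)
            b = rand_seq(rng, 2, 5)
            assert oracle_enumerate(a, b) == oracle_sw(a, b)

    def test_matches_dp_oracle_on_short_sequences(self):
        rng = random.Random(42)
        seqs = [rand_seq(rng, 3, 8) for _ in range(50)]
        for i in range(len(seqs)):
            for j in range(i, len(seqs)):
                assert align_pair(seqs[i], seqs[j]).raw_score == oracle_sw(seqs[i], seqs[j])

    def test_score_symmetry(self):
        rng = random.Random(9)
        for _ in range(100):
            a = rand_seq(rng, 3, 12)
            b = rand_seq(rng, 3, 12)
            assert align_pair(a, b).raw_score == align_pair(b, a).raw_score


class TestEvalue:
    def test_doubling_m_doubles_e(self):
        e1 = estimate_evalue(100.0, 1000, 1000)
        e2 = estimate_evalue(100.0, 2000, 1000)
        assert e2 == pytest.approx(2 * e1)

    def test_monotone_decreasing_to_zero(self):
        values = [estimate_evalue(b, 10**6, 10**6) for b in (50, 100, 500, 1000, 2000)]
        assert all(x > y for x, y in zip(values, values[1:]))
        assert values[-1] == 0.0

    def test_one_bit_halves_e(self):
        e1 = estimate_evalue(100.0, 10**4, 10**4)
        e2 = estimate_evalue(101.0, 10**4, 10**4)
        assert e2 / e1 == pytest.approx(0.5)

    def test_bad_search_space(self):
        with pytest.raises(ValueError):
            estimate_evalue(100.0, 0, 10)

    def test_bitscore_conversion(self):
        assert bitscore(0) == pytest.approx(-math.log(0.041) / math.log(2))


def _gene(gid, species, chrom, seq, start=1):
    return Gene(gid, species, chrom, start, start + 3 * len(seq) - 1, "+", seq)


def _random_proteome(rng, species, n, length=60):
    return [
        _gene(f"{species}_g{i}", species, "chr1", "".join(rng.choices(AAS, k=length)), 1 + 1000 * i)
        for i in range(n)
    ]


class TestAllVsAll:
    def test_self_search_best_hit_is_self(self):
        rng = random.Random(2)
        genes = _random_proteome(rng, "sp", 8)
        table = all_vs_all(genes, genes, report_evalue=10.0, min_kmer_hits=None)
        for g in genes:
            best = table.best_hit(g.gene_id)
            assert best is not None and best.subject_id == g.gene_id

    def test_disjoint_proteomes_empty_at_stringent_threshold(self):
        rng = random.Random(3)
        a = _random_proteome(rng, "spa", 6)
        b = _random_proteome(rng, "spb", 6)
        table = all_vs_all(a, b, report_evalue=1e-20, min_kmer_hits=None)
        assert table.hits == []

    def test_empty_proteome_errors(self):
        rng = random.Random(4)
        genes = _random_proteome(rng, "sp", 3)
        with pytest.raises(ValueError):
            all_vs_all([], genes)

    def test_family_copies_hit_each_other(self):
        rng = random.Random(5)
        base = "".join(rng.choices(AAS, k=120))
        a1 = _gene("a1", "spa", "chr1", base)
        a2 = _gene("a2", "spa", "chr2", base[:119] + "W", 50_000)
        b1 = _gene("b1", "spb", "chr1", base[:118] + "YY")
        filler = _random_proteome(rng, "spa", 3, length=120)
        table = all_vs_all([a1, a2] + filler, [b1], report_evalue=1e-10)
        assert {h.query_id for h in table.hits if h.subject_id == "b1"} >= {"a1", "a2"}

    def test_prefilter_matches_full_search_on_reported_pairs(self):
        rng = random.Random(6)
        base = "".join(rng.choices(AAS, k=80))
        genes_a = [_gene("x1", "spa", "chr1", base), _gene("x2", "spa", "chr2", base[:79] + "A", 9000)]
        genes_b = [_gene("y1", "spb", "chr1", base[:78] + "CC")]
        full = all_vs_all(genes_a, genes_b, report_evalue=1e-5, min_kmer_hits=None)
        pre = all_vs_all(genes_a, genes_b, report_evalue=1e-5, min_kmer_hits=3)
        as_dict = lambda t: {(h.query_id, h.subject_id): h.raw_score for h in t.hits}
        assert as_dict(full) == as_dict(pre)


def _hit(q, s, bits):
    return Hit(
        query_id=q, subject_id=s, raw_score=int(bits), bitscore=float(bits),
        evalue=estimate_evalue(float(bits), 10**4, 10**4), identity=0.9,
        aln_length=100, mismatches=10, gap_opens=0,
        qstart=1, qend=100, sstart=1, send=100,
    )


class TestRBH:
    def test_two_by_two_enumeration(self):
        # a1<->b1 mutual best; a2's best is b2 but b2's best is a3: only (a1,b1)
        ab = HitTable(("A", "B"), [_hit("a1", "b1", 500), _hit("a2", "b2", 400)])
        ba = HitTable(("B", "A"), [_hit("b1", "a1", 500), _hit("b2", "a3", 450), _hit("b2", "a2", 400)])
        assert reciprocal_best_hits(ab, ba) == [("a1", "b1")]

    def test_empty_tables(self):
        assert reciprocal_best_hits(HitTable(("A", "B")), HitTable(("B", "A"))) == []

    def test_transpose_symmetry_and_matching(self):
        rng = random.Random(12)
        a_ids = [f"a{i}" for i in range(10)]
        b_ids = [f"b{i}" for i in range(10)]
        hits_ab, hits_ba = [], []
        for a in a_ids:
            for b in rng.sample(b_ids, 4):
                hits_ab.append(_hit(a, b, rng.randint(50, 500)))
        for b in b_ids:
            for a in rng.sample(a_ids, 4):
                hits_ba.append(_hit(b, a, rng.randint(50, 500)))
        ab = HitTable(("A", "B"), hits_ab)
        ba = HitTable(("B", "A"), hits_ba)
        fwd = reciprocal_best_hits(ab, ba)
        rev = reciprocal_best_hits(ba, ab)
        assert sorted(fwd) == sorted((a, b) for b, a in rev)
        # partial matching: no gene in two pairs
        lefts = [a for a, _ in fwd]
        rights = [b for _, b in fwd]
        assert len(lefts) == len(set(lefts)) and len(rights) == len(set(rights))

    def test_tie_yields_no_pair(self):
        ab = HitTable(("A", "B"), [_hit("a1", "b1", 500), _hit("a1", "b2", 500)])
        ba = HitTable(("B", "A"), [_hit("b1", "a1", 500)])
        assert reciprocal_best_hits(ab, ba) == []

    def test_direction_mismatch_errors(self):
        ab = HitTable(("A", "B"))
        ac = HitTable(("A", "C"))
        with pytest.raises(ValueError):
            reciprocal_best_hits(ab, ac)


class TestHitTable:
    def test_best_row_kept_per_pair(self):
        table = HitTable(("A", "B"), [_hit("a1", "b1", 100), _hit("a1", "b1", 300)])
        assert len(table.hits) == 1
        assert table.hits[0].bitscore == 300

    def test_rows_round_trip(self):
        table = HitTable(("A", "B"), [_hit("a1", "b1", 100), _hit("a2", "b2", 220)])
        rows = hit_table_to_rows(table)
        back = hit_table_from_rows(rows, direction=("A", "B"))
        assert [(h.query_id, h.subject_id, h.bitscore) for h in back.hits] == [
            (h.query_id, h.subject_id, h.bitscore) for h in table.hits
        ]

    def test_invariant_coverage_identity_ranges(self):
        rng = random.Random(31)
        a = _random_proteome(rng, "spa", 5)
        table = all_vs_all(a, a, report_evalue=10.0, min_kmer_hits=None)
        for h in table.hits:
            assert 0 < h.identity <= 1
            assert 0 < h.query_coverage <= 1
            assert 0 < h.subject_coverage <= 1
            assert h.evalue >= 0
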