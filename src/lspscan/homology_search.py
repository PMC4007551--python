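"""Pairwise protein similarity: local alignment, E-values, hit tables, RBH.

The aligner is Smith-Waterman with affine gaps (open 11, extend 1) over a
BLOSUM62 matrix shipped as a data file; `X` scores 0 against everything.
E-values use the bitscore form E = m*n*2**(-bitscore) with the standard
gapped-BLOSUM62 constants lambda=0.267, K=0.041 converting raw scores to
bits. Edge corrections and composition statistics are not modelled;
externally computed tabular hit files can be imported instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import biotite.sequence as _bseq
import biotite.sequence.align as _balign
import numpy as np

from .io_formats import Gene, VALID_RESIDUES

# Gapped BLOSUM62 Karlin-Altschul constants (BLASTp defaults, open 11 extend 1)
LAMBDA = 0.267
K = 0.041

GAP_OPEN = 11
GAP_EXTEND = 1

DEFAULT_REPORT_EVALUE = 1e-3


class AlignmentError(ValueError):
    pass


def load_substitution_matrix(x_score: int = 0) -> dict[tuple[str, str], int]:
    """Load the packaged BLOSUM62 file as a pair->score dict.

    Rows/columns involving ``X`` are overridden to ``x_score`` (default 0:
    unknown residues are neutral, never rewarded or punished).
    """
    text = resources.files("lspscan.data").joinpath("blosum62.mat").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    alphabet = lines[0].split()
    matrix: dict[tuple[str, str], int] = {}
    for line in lines[1:]:
        parts = line.split()
        row = parts[0]
        for col, score in zip(alphabet, parts[1:]):
            matrix[(row, col)] = int(score)
    for a in alphabet:
        matrix[("X", a)] = x_score
        matrix[(a, "X")] = x_score
    return matrix


def _biotite_matrix(matrix: dict[tuple[str, str], int]) -> _balign.SubstitutionMatrix:
    alph = _bseq.ProteinSequence.alphabet
    letters = alph.get_symbols()
    arr = np.zeros((len(letters), len(letters)), dtype=np.int32)
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            arr[i, j] = matrix.get((a, b), 0)
    return _balign.SubstitutionMatrix(alph, alph, arr)


_DEFAULT_MATRIX = load_substitution_matrix()
_DEFAULT_BMATRIX = _biotite_matrix(_DEFAULT_MATRIX)


@dataclass(frozen=True)
class Alignment:
    """Result of a local pairwise alignment."""

    raw_score: int
    query_span: tuple[int, int]  # 1-based inclusive over the query
    subject_span: tuple[int, int]
    aligned_length: int
    matches: int
    mismatches: int
    gap_opens: int
    identity: float
    query_coverage: float
    subject_coverage: float


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise AlignmentError(f"{name} sequence is empty")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise AlignmentError(f"{name} sequence has residues outside the alphabet: {sorted(bad)}")


def align_pair(
    seq_a: str,
    seq_b: str,
    matrix: dict[tuple[str, str], int] | None = None,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> Alignment:
    """Optimal Smith-Waterman local alignment with affine gap penalties.

    A gap of length L costs gap_open + L*gap_extend.
    """
    _check_sequence(seq_a, "query")
    _check_sequence(seq_b, "subject")
    if matrix is None:
        bmat = _DEFAULT_BMATRIX
    else:
        bmat = _biotite_matrix(matrix)
    # identical sequences: the optimal local alignment is the full diagonal
    mat = matrix if matrix is not None else _DEFAULT_MATRIX
    if seq_a == seq_b and all(mat[(c, c)] > 0 for c in set(seq_a)):
        score = sum(mat[(c, c)] for c in seq_a)
        n = len(seq_a)
        return Alignment(score, (1, n), (1, n), n, n, 0, 0, 1.0, 1.0, 1.0)
    # biotite's affine penalty charges (open+extend) for the first gap residue
    aln = _balign.align_optimal(
        _bseq.ProteinSequence(seq_a),
        _bseq.ProteinSequence(seq_b),
        bmat,
        gap_penalty=(-(gap_open + gap_extend), -gap_extend),
        local=True,
        max_number=1,
    )[0]
    trace = aln.trace
    matches = mismatches = gap_opens = 0
    prev_gap_q = prev_gap_s = False
    for qi, si in trace:
        if qi == -1 or si == -1:
            if qi == -1:
                if not prev_gap_q:
                    gap_opens += 1
                prev_gap_q, prev_gap_s = True, False
            else:
                if not prev_gap_s:
                    gap_opens += 1
                prev_gap_q, prev_gap_s = False, True
            continue
        prev_gap_q = prev_gap_s = False
        if seq_a[qi] == seq_b[si]:
            matches += 1
        else:
            mismatches += 1
    q_idx = trace[:, 0][trace[:, 0] >= 0]
    s_idx = trace[:, 1][trace[:, 1] >= 0]
    if aln.score <= 0 or len(q_idx) == 0 or len(s_idx) == 0:
        # nothing aligns with a positive score: empty local alignment
        return Alignment(0, (0, 0), (0, 0), 0, 0, 0, 0, 0.0, 0.0, 0.0)
    q_span = (int(q_idx.min()) + 1, int(q_idx.max()) + 1)
    s_span = (int(s_idx.min()) + 1, int(s_idx.max()) + 1)
    aligned_length = len(trace)
    return Alignment(
        raw_score=int(aln.score),
        query_span=q_span,
        subject_span=s_span,
        aligned_length=aligned_length,
        matches=matches,
        mismatches=mismatches,
        gap_opens=gap_opens,
        identity=matches / aligned_length,
        query_coverage=(q_span[1] - q_span[0] + 1) / len(seq_a),
        subject_coverage=(s_span[1] - s_span[0] + 1) / len(seq_b),
    )


def bitscore(raw_score: float) -> float:
    """Convert a raw alignment score to bits: (lambda*S - ln K) / ln 2."""
    return (LAMBDA * raw_score - math.log(K)) / math.log(2)


def estimate_evalue(bits: float, m: int, n: int) -> float:
    """Karlin-Altschul E-value E = m*n*2**(-bitscore)."""
    if m < 1 or n < 1:
        raise ValueError("search space dimensions must be >= 1")
    # 2**(-bits) underflows for bits > ~1074; work in logs
    log10_e = math.log10(m) + math.log10(n) - bits * math.log10(2)
    if log10_e < -320:
        return 0.0
    return 10.0 ** log10_e


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    raw_score: int
    bitscore: float
    evalue: float
    identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    query_coverage: float | None = None
    subject_coverage: float | None = None


@dataclass
class HitTable:
    """Directed hit set between two proteomes; one (best) row per pair."""

    direction: tuple[str, str]
    hits: list[Hit] = field(default_factory=list)
    search_space: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        best: dict[tuple[str, str], Hit] = {}
        for h in self.hits:
            key = (h.query_id, h.subject_id)
            if key not in best or h.bitscore > best[key].bitscore:
                best[key] = h
        self.hits = sorted(
            best.values(), key=lambda h: (h.query_id, -h.bitscore, h.subject_id)
        )
        self._by_query: dict[str, list[Hit]] = {}
        for h in self.hits:
            self._by_query.setdefault(h.query_id, []).append(h)

    def hits_from(self, query_id: str) -> list[Hit]:
        return self._by_query.get(query_id, [])

    def best_hit(self, query_id: str) -> Hit | None:
        """Unique best subject by bitscore; ties yield None (no best hit)."""
        hits = self._by_query.get(query_id)
        if not hits:
            return None
        if len(hits) > 1 and hits[1].bitscore == hits[0].bitscore:
            return None
        return hits[0]

    def best_subjects(self, query_id: str) -> list[Hit]:
        """All hits tied at the query's maximum bitscore."""
        hits = self._by_query.get(query_id)
        if not hits:
            return []
        top = hits[0].bitscore
        return [h for h in hits if h.bitscore == top]

    def queries_with_hit(self, evalue_max: float) -> set[str]:
        """Queries with >= 1 subject at E <= evalue_max ("positive hits")."""
        return {h.query_id for h in self.hits if h.evalue <= evalue_max}

    def filtered(self, evalue_max: float) -> "HitTable":
        return HitTable(
            direction=self.direction,
            hits=[h for h in self.hits if h.evalue <= evalue_max],
            search_space=self.search_space,
        )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def hit_from_alignment(query: Gene, subject: Gene, aln: Alignment, m: int, n: int) -> Hit:
    bits = bitscore(aln.raw_score)
    return Hit(
        query_id=query.gene_id,
        subject_id=subject.gene_id,
        raw_score=aln.raw_score,
        bitscore=bits,
        evalue=estimate_evalue(bits, m, n),
        identity=aln.identity,
        aln_length=aln.aligned_length,
        mismatches=aln.mismatches,
        gap_opens=aln.gap_opens,
        qstart=aln.query_span[0],
        qend=aln.query_span[1],
        sstart=aln.subject_span[0],
        send=aln.subject_span[1],
        query_coverage=aln.query_coverage,
        subject_coverage=aln.subject_coverage,
    )


def all_vs_all(
    genes_from: Sequence[Gene],
    genes_to: Sequence[Gene],
    report_evalue: float = DEFAULT_REPORT_EVALUE,
    kmer_size: int = 4,
    min_kmer_hits: int | None = 3,
    matrix: dict[tuple[str, str], int] | None = None,
    _pair_cache: dict[tuple[str, str], Alignment] | None = None,
) -> HitTable:
    """All-vs-all local-alignment search from one proteome into another.

    A shared-k-mer prefilter (``min_kmer_hits`` k-mers of length ``kmer_size``
    in common) selects candidate pairs; full Smith-Waterman is then run, so
    reported scores are exact. Set ``min_kmer_hits=None`` to disable the
    prefilter and align every pair. ``_pair_cache`` may be shared across
    calls to reuse the (symmetric) alignment of an unordered sequence pair.
    """
    if not genes_from or not genes_to:
        raise ValueError("both proteomes must be non-empty")
    m = sum(len(g.peptide) for g in genes_from)
    n = sum(len(g.peptide) for g in genes_to)
    if min_kmer_hits is not None:
        kmer_index: dict[str, list[int]] = {}
        for j, g in enumerate(genes_to):
            for kmer in _kmer_set(g.peptide, kmer_size):
                kmer_index.setdefault(kmer, []).append(j)
    hits: list[Hit] = []
    cache = _pair_cache if _pair_cache is not None else {}
    for gq in genes_from:
        if min_kmer_hits is None:
            candidates: Iterable[Gene] = genes_to
        else:
            counts: dict[int, int] = {}
            for kmer in _kmer_set(gq.peptide, kmer_size):
                for j in kmer_index.get(kmer, ()):
                    counts[j] = counts.get(j, 0) + 1
            candidates = [
                genes_to[j] for j, c in sorted(counts.items()) if c >= min_kmer_hits
            ]
        for gs in candidates:
            # cache on the lexicographically ordered sequence pair; SW scores
            # are symmetric and spans just swap roles
            flipped = gq.peptide > gs.peptide
            key = (gs.peptide, gq.peptide) if flipped else (gq.peptide, gs.peptide)
            aln = cache.get(key)
            if aln is None:
                aln = align_pair(key[0], key[1], matrix=matrix)
                cache[key] = aln
            if flipped:
                aln = Alignment(
                    aln.raw_score,
                    aln.subject_span,
                    aln.query_span,
                    aln.aligned_length,
                    aln.matches,
                    aln.mismatches,
                    aln.gap_opens,
                    aln.identity,
                    aln.subject_coverage,
                    aln.query_coverage,
                )
            hit = hit_from_alignment(gq, gs, aln, m, n)
            if hit.evalue <= report_evalue:
                hits.append(hit)
    return HitTable(
        direction=(genes_from[0].species, genes_to[0].species),
        hits=hits,
        search_space=(m, n),
    )


def reciprocal_best_hits(table_ab: HitTable, table_ba: HitTable) -> list[tuple[str, str]]:
    """Pairs (a, b) where each is the other's unique best hit by bitscore."""
    if table_ab.direction != tuple(reversed(table_ba.direction)):
        raise ValueError(
            f"tables are not reciprocal: {table_ab.direction} vs {table_ba.direction}"
        )
    best_ba = {}
    for q in {h.query_id for h in table_ba.hits}:
        best = table_ba.best_hit(q)
        if best is not None:
            best_ba[q] = best.subject_id
    pairs = []
    for q in sorted({h.query_id for h in table_ab.hits}):
        best = table_ab.best_hit(q)
        if best is not None and best_ba.get(best.subject_id) == q:
            pairs.append((q, best.subject_id))
    return pairs


def hit_table_to_rows(table: HitTable) -> list[dict]:
    return [
        {
            "query_id": h.query_id,
            "subject_id": h.subject_id,
            "identity_pct": 100.0 * h.identity,
            "aln_length": h.aln_length,
            "mismatches": h.mismatches,
            "gap_opens": h.gap_opens,
            "qstart": h.qstart,
            "qend": h.qend,
            "sstart": h.sstart,
            "send": h.send,
            "evalue": h.evalue,
            "bitscore": h.bitscore,
        }
        for h in table.hits
    ]


def hit_table_from_rows(
    rows: Iterable[dict],
    direction: tuple[str, str] = ("?", "?"),
    search_space: tuple[int, int] = (1, 1),
) -> HitTable:
    hits = [
        Hit(
            query_id=r["query_id"],
            subject_id=r["subject_id"],
            raw_score=0,
            bitscore=r["bitscore"],
            evalue=r["evalue"],
            identity=r["identity_pct"] / 100.0,
            aln_length=r["aln_length"],
            mismatches=r["mismatches"],
            gap_opens=r["gap_opens"],
            qstart=r["qstart"],
            qend=r["qend"],
            sstart=r["sstart"],
            send=r["send"],
        )
        for r in rows
    ]
    return HitTable(direction=direction, hits=hits, search_space=search_space)
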