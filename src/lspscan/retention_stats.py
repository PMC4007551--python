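"""Chromosome-distribution statistics and GO-slim hypergeometric enrichment.

The per-chromosome LSP/duplicate-gene ratio is treated as a pseudoreplicate
for the panel mean and standard error; association between per-chromosome
duplicate and LSP counts is measured by Spearman rank correlation with a
permutation p-value (never reported as exactly zero). Term enrichment is an
upper-tail hypergeometric test with Benjamini-Hochberg control, computed
against a user-supplied annotation and fine-term-to-slim mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _sps


@dataclass
class ChromosomeStats:
    per_chromosome: dict[str, tuple[int, int]]  # chrom -> (tsgd_count, lsp_count)
    ratios: dict[str, float]
    mean_ratio: float
    se_ratio: float
    excluded_chromosomes: list[str] = field(default_factory=list)
    rho: float | None = None
    p_perm: float | None = None


def chromosome_table(
    tsgd_gene_chromosomes: Iterable[str],
    lsp_gene_chromosomes: Iterable[str],
) -> ChromosomeStats:
    """Per-chromosome duplicate/LSP gene counts and pseudoreplicate ratios.

    Each input is one chromosome label per gene (genes of a family count on
    their own chromosomes). Chromosomes with zero duplicate genes are
    excluded from the ratio mean and listed in ``excluded_chromosomes``.
    SE = sd / sqrt(n_chromosomes) with the sample (n-1) standard deviation.
    """
    tsgd_counts: dict[str, int] = {}
    for c in tsgd_gene_chromosomes:
        tsgd_counts[c] = tsgd_counts.get(c, 0) + 1
    lsp_counts: dict[str, int] = {}
    for c in lsp_gene_chromosomes:
        lsp_counts[c] = lsp_counts.get(c, 0) + 1
    bad = set(lsp_counts) - set(tsgd_counts)
    if bad:
        raise ValueError(f"LSP genes on chromosomes with no duplicate genes: {sorted(bad)}")
    per_chrom = {
        c: (tsgd_counts.get(c, 0), lsp_counts.get(c, 0))
        for c in sorted(set(tsgd_counts) | set(lsp_counts))
    }
    for c, (t, l) in per_chrom.items():
        if l > t:
            raise ValueError(f"chromosome {c}: lsp_count {l} exceeds tsgd_count {t}")
    ratios = {c: l / t for c, (t, l) in per_chrom.items() if t > 0}
    excluded = [c for c, (t, _) in per_chrom.items() if t == 0]
    if ratios:
        vals = np.array(list(ratios.values()))
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    else:
        mean = se = 0.0
    return ChromosomeStats(
        per_chromosome=per_chrom,
        ratios=ratios,
        mean_ratio=mean,
        se_ratio=se,
        excluded_chromosomes=excluded,
    )


def _midranks(x: Sequence[float]) -> np.ndarray:
    return _sps.rankdata(x, method="average")


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho (Pearson correlation of mid-ranks) with permutation p.

    p = (1 + #{permutations with |rho*| >= |rho|}) / (1 + n_permutations),
    so the p-value is never exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)

    def _pearson(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = _pearson(rx, ry)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ry)
        if abs(_pearson(rx, perm)) >= abs(rho) - 1e-12:
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_permutations)
    return rho, p_perm


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    study_count: int
    background_count: int
    p_value: float
    q_value: float
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.study_count > self.background_count:
            raise ValueError(
                f"{self.term_id}: study_count exceeds background_count"
            )


def hypergeometric_p(study_count: int, study_size: int, term_total: int, universe: int) -> float:
    """Upper-tail P(X >= study_count) for X ~ Hypergeom(universe, term_total, study_size)."""
    if study_count == 0:
        return 1.0
    return float(_sps.hypergeom.sf(study_count - 1, universe, term_total, study_size))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def hypergeometric_enrichment(
    study_genes: Iterable[str],
    background_annotation: Mapping[str, set[str]],
    min_genes: int = 10,
    term_names: Mapping[str, str] | None = None,
) -> tuple[list[EnrichmentRow], list[EnrichmentRow]]:
    """Per-term upper-tail hypergeometric enrichment of a study set.

    ``background_annotation`` maps every universe gene to its term set.
    Returns (reported, all_rows): rows with study_count <= ``min_genes`` are
    filtered from the report but kept in the full output, mirroring a
    more-than-N-genes reporting rule. Rows are sorted by (p, term).
    """
    study = sorted(set(study_genes))
    universe = set(background_annotation)
    missing = [g for g in study if g not in universe]
    if missing:
        raise ValueError(f"study gene(s) absent from the universe: {missing[:5]}")
    term_background: dict[str, set[str]] = {}
    for gene, terms in background_annotation.items():
        for t in terms:
            term_background.setdefault(t, set()).add(gene)
    study_set = set(study)
    rows = []
    terms = sorted(term_background)
    p_values = []
    for t in terms:
        bg = term_background[t]
        hit_genes = sorted(bg & study_set)
        p = hypergeometric_p(len(hit_genes), len(study), len(bg), len(universe))
        p_values.append(min(max(p, np.finfo(float).tiny), 1.0))
        rows.append((t, hit_genes, bg))
    q_values = bh_adjust(p_values) if p_values else []
    all_rows = [
        EnrichmentRow(
            term_id=t,
            term_name=(term_names or {}).get(t, t),
            study_count=len(hit_genes),
            background_count=len(bg),
            p_value=p,
            q_value=max(q, p),
            gene_ids=hit_genes,
        )
        for (t, hit_genes, bg), p, q in zip(rows, p_values, q_values)
    ]
    all_rows.sort(key=lambda r: (r.p_value, r.term_id))
    reported = [r for r in all_rows if r.study_count > min_genes]
    return reported, all_rows


def map_to_slim(
    term_assignments: Mapping[str, set[str]],
    slim_table: Mapping[str, set[str]],
) -> dict[str, set[str]]:
    """Replace each gene's fine terms with their slim ancestors.

    ``slim_table`` maps fine terms to parent terms (possibly chained over
    several levels); slim terms are the sinks of the mapping. Genes none of
    whose terms reach a slim term are bucketed under ``"unmapped"``.
    Cycles in the mapping are an error.
    """
    closure: dict[str, set[str]] = {}

    def ancestors(term: str, trail: tuple[str, ...]) -> set[str]:
        if term in trail:
            raise ValueError(f"cyclic slim mapping at term {term!r}")
        if term in closure:
            return closure[term]
        parents = slim_table.get(term)
        if not parents:
            result = {term} if term in _slim_sinks else set()
        else:
            result = set()
            for p in parents:
                result |= ancestors(p, trail + (term,))
        closure[term] = result
        return result

    _slim_sinks = {p for ps in slim_table.values() for p in ps if p not in slim_table}
    out: dict[str, set[str]] = {}
    for gene, terms in term_assignments.items():
        slims: set[str] = set()
        for t in terms:
            slims |= ancestors(t, ())
        out[gene] = slims if slims else {"unmapped"}
    return out
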