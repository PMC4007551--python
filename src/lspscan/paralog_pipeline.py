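"""The calling cascade: seed-genome duplicate pairs, artifact exclusion,
outgroup singleton tests, per-species copy numbers and two-lineage
lineage-specific-paralog (LSP) classification.

Candidate duplicate pairs are derived annotation-free from within-genome
similarity: genes joined by mutual above-cutoff hits form families, and only
size-2 families become candidate pairs (larger families are flagged and set
aside — pair identity inside bigger families is ambiguous). A family is
called lineage-A-specific when every lineage-A species carries two copies on
different chromosomes and every lineage-B species carries exactly one, with
the symmetric rule for lineage B.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .homology_search import Alignment, HitTable
from .io_formats import Gene, PanelConfig

CALLS = ("A_LSP", "B_LSP", "shared_duplicate", "unresolved")


@dataclass
class ParalogFamily:
    """A candidate WGD-duplicate unit anchored on a seed-genome gene pair."""

    family_id: str
    seed_species: str
    seed_pair: tuple[str, str]
    seed_chromosomes: tuple[str, str]
    outgroup_orthologs: dict[str, str] = field(default_factory=dict)
    copy_number: dict[str, int] = field(default_factory=dict)
    supporting_genes: dict[str, list[str]] = field(default_factory=dict)
    ambiguous_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed_chromosomes[0] == self.seed_chromosomes[1]:
            raise ValueError(
                f"{self.family_id}: seed pair must lie on different chromosomes"
            )


@dataclass
class LSPCall:
    family_id: str
    call: str
    per_species_evidence: dict[str, tuple[int, float | None]] = field(default_factory=dict)
    verification_status: str = "untested"

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")


@dataclass
class DropRecord:
    stage: str
    item: str
    reason: str


def find_duplicate_pairs(
    seed_species: str,
    self_hits: HitTable,
    cutoff: float,
) -> tuple[list[tuple[str, str]], list[frozenset]]:
    """Candidate duplicate pairs from a seed proteome's self-search.

    Genes connected by mutual hits at E <= cutoff are grouped; connected
    components of exactly two genes yield one candidate pair (ids ordered
    lexicographically), larger components are returned as flagged families.
    """
    above = {}
    for h in self_hits.hits:
        if h.query_id != h.subject_id and h.evalue <= cutoff:
            above.setdefault(h.query_id, set()).add(h.subject_id)
    adj: dict[str, set[str]] = {}
    for q, subjects in above.items():
        for s in subjects:
            if q in above.get(s, ()):  # mutual
                adj.setdefault(q, set()).add(s)
                adj.setdefault(s, set()).add(q)
    seen: set[str] = set()
    pairs: list[tuple[str, str]] = []
    flagged: list[frozenset] = []
    for g in sorted(adj):
        if g in seen:
            continue
        comp = {g}
        stack = [g]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        if len(comp) == 2:
            pairs.append(tuple(sorted(comp)))
        else:
            flagged.append(frozenset(comp))
    return pairs, flagged


def exclude_artifacts(
    alignment: Alignment,
    len_a: int,
    len_b: int,
    coverage_min: float,
    length_ratio_max: float,
) -> tuple[bool, str | None]:
    """Keep a candidate pair only if it does not look like a chimera/isoform.

    Requires both coverages >= coverage_min and peptide length ratio
    <= length_ratio_max; returns (keep, drop_reason).
    """
    if alignment.query_coverage < coverage_min or alignment.subject_coverage < coverage_min:
        return False, "coverage"
    ratio = max(len_a, len_b) / min(len_a, len_b)
    if ratio > length_ratio_max:
        return False, "length_ratio"
    return True, None


def outgroup_singleton_test(
    pair: tuple[str, str],
    seed_to_out: HitTable,
    out_to_seed: HitTable,
    cutoff: float,
) -> tuple[bool, str | None]:
    """Both pair members must share a unique best outgroup ortholog.

    Passes iff both members' best hit in the outgroup is the same gene and
    that gene has no above-cutoff hit back into the seed genome outside the
    pair. Returns (pass, outgroup_gene_id).
    """
    g1, g2 = pair
    b1 = seed_to_out.best_hit(g1)
    b2 = seed_to_out.best_hit(g2)
    if b1 is None or b2 is None:
        return False, None
    if b1.subject_id != b2.subject_id:
        return False, None
    og = b1.subject_id
    for h in out_to_seed.hits_from(og):
        if h.evalue <= cutoff and h.subject_id not in pair:
            return False, None
    return True, og


def copy_number(
    pair: tuple[str, str],
    seed_to_target: HitTable,
    target_to_seed: HitTable,
    target_genes: dict[str, Gene],
    cutoff: float,
) -> tuple[int, list[str], bool]:
    """Count the target species' reciprocally supported co-orthologs of a pair.

    A target gene matches the family when its best hit in the seed genome is
    one of the pair members and a pair member hits it at E <= cutoff. Two or
    more matching genes on different chromosomes score 2; matching genes
    confined to one chromosome (tandem-like) score 1. Target genes hitting
    the pair above cutoff whose best seed hit lies elsewhere mark the species
    ambiguous. Returns (count capped at 2, supporting gene ids, ambiguous).
    """
    hit_by_pair: set[str] = set()
    for g in pair:
        for h in seed_to_target.hits_from(g):
            if h.evalue <= cutoff:
                hit_by_pair.add(h.subject_id)
    matching: list[str] = []
    ambiguous = False
    for t in sorted(hit_by_pair):
        best = target_to_seed.best_subjects(t)
        best = [h for h in best if h.evalue <= cutoff]
        if not best:
            continue
        # a bitscore tie between the two pair members is still unambiguous
        # support for the family; a tied-best hit outside the pair is not
        if all(h.subject_id in pair for h in best):
            matching.append(t)
        else:
            ambiguous = True
    if not matching:
        return 0, [], ambiguous
    chroms = {target_genes[t].chromosome for t in matching if t in target_genes}
    if len(matching) >= 2 and len(chroms) >= 2:
        return 2, matching, ambiguous
    return 1, matching, ambiguous


def classify_lsp(family: ParalogFamily, panel: PanelConfig) -> LSPCall:
    """Apply the two-lineage retention rule to a family's copy-number map."""
    missing = [
        s
        for s in panel.ingroup_species
        if s not in family.copy_number and s not in panel.allow_missing_species
    ]
    if missing:
        raise ValueError(
            f"{family.family_id}: copy_number missing for species {missing}"
        )
    a = [family.copy_number[s] for s in panel.lineage_a if s in family.copy_number]
    b = [family.copy_number[s] for s in panel.lineage_b if s in family.copy_number]
    evidence = {s: (c, None) for s, c in family.copy_number.items()}
    if family.ambiguous_species:
        call = "unresolved"
    elif all(c >= 2 for c in a) and all(c == 1 for c in b):
        call = "A_LSP"
    elif all(c == 1 for c in a) and all(c >= 2 for c in b):
        call = "B_LSP"
    elif all(c >= 2 for c in a + b):
        call = "shared_duplicate"
    else:
        call = "unresolved"
    return LSPCall(family_id=family.family_id, call=call, per_species_evidence=evidence)


def round_half_up(value: float, ndigits: int) -> float:
    exp = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(exp, rounding=ROUND_HALF_UP))


@dataclass
class PanelSummary:
    totals: dict[str, int]
    tsgd_gene_counts: dict[str, int]
    lsp_family_counts: dict[str, int]
    lsp_gene_counts: dict[str, int]
    tsgd_gene_pct: dict[str, float]
    lsp_gene_pct: dict[str, float]


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """100*count/total, rounded half-up to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(100.0 * count / total, ndigits)


def summarize_panel(
    tsgd_gene_counts: dict[str, int],
    lsp_family_counts: dict[str, int],
    lsp_gene_counts: dict[str, int],
    totals: dict[str, int],
) -> PanelSummary:
    """Headline counts and percentages per direction (keys 'a' and 'b')."""
    for direction, total in totals.items():
        if total <= 0:
            raise ValueError(f"total for direction {direction!r} must be positive")
    return PanelSummary(
        totals=dict(totals),
        tsgd_gene_counts=dict(tsgd_gene_counts),
        lsp_family_counts=dict(lsp_family_counts),
        lsp_gene_counts=dict(lsp_gene_counts),
        tsgd_gene_pct={
            d: percentage(tsgd_gene_counts.get(d, 0), t) for d, t in totals.items()
        },
        lsp_gene_pct={
            d: percentage(lsp_gene_counts.get(d, 0), t) for d, t in totals.items()
        },
    )
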