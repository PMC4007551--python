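"""End-to-end orchestration of the two-direction LSP cascade.

Direction "a" seeds on ``seed_a``: duplicate pairs are called in the seed
genome, screened against isoform/chimera artifacts and the
different-chromosome rule, required to have a unique singleton ortholog in
every outgroup, scored for copy number in every other panel species, and
classified. Direction "b" mirrors this from ``seed_b``; shared-duplicate
families rediscovered from the second seed are dropped as duplicates of
their direction-a counterpart. Stage survivor counts are logged and
non-increasing within a direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import homology_search as hs
from . import paralog_pipeline as pp
from . import retention_stats as rs
from . import verification as vf
from .io_formats import (
    Gene,
    PanelConfig,
    is_unplaced,
    write_json,
    write_tsv,
)

logger = logging.getLogger("lspscan")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ResultBundle:
    tsgd_families: list[pp.ParalogFamily]
    lsp_calls: list[pp.LSPCall]
    chromosome_stats: rs.ChromosomeStats
    enrichment: list[rs.EnrichmentRow]
    summary: pp.PanelSummary
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    drops: list[pp.DropRecord] = field(default_factory=list)
    synteny: list[vf.SyntenyScore] = field(default_factory=list)
    newicks: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fam_ids = {f.family_id for f in self.tsgd_families}
        for call in self.lsp_calls:
            if call.family_id not in fam_ids:
                raise ValueError(f"call references unknown family {call.family_id}")

    def calls_by_family(self) -> dict[str, pp.LSPCall]:
        return {c.family_id: c for c in self.lsp_calls}


class _TableStore:
    """Lazily computed, cached directed hit tables with a shared alignment cache."""

    def __init__(self, proteomes: Mapping[str, list[Gene]], report_evalue: float):
        self.proteomes = proteomes
        self.report_evalue = report_evalue
        self._tables: dict[tuple[str, str], hs.HitTable] = {}
        self._aln_cache: dict[tuple[str, str], hs.Alignment] = {}

    def get(self, sp_from: str, sp_to: str) -> hs.HitTable:
        key = (sp_from, sp_to)
        if key not in self._tables:
            genes_from = self.proteomes.get(sp_from)
            genes_to = self.proteomes.get(sp_to)
            if not genes_from:
                raise ValueError(f"species {sp_from!r} has an empty proteome")
            if not genes_to:
                raise ValueError(f"species {sp_to!r} has an empty proteome")
            logger.info("searching %s -> %s (%d x %d genes)", sp_from, sp_to, len(genes_from), len(genes_to))
            self._tables[key] = hs.all_vs_all(
                genes_from,
                genes_to,
                report_evalue=self.report_evalue,
                _pair_cache=self._aln_cache,
            )
        return self._tables[key]

    def align(self, seq_a: str, seq_b: str) -> hs.Alignment:
        flipped = seq_a > seq_b
        key = (seq_b, seq_a) if flipped else (seq_a, seq_b)
        aln = self._aln_cache.get(key)
        if aln is None:
            aln = hs.align_pair(key[0], key[1])
            self._aln_cache[key] = aln
        if flipped:
            aln = hs.Alignment(
                aln.raw_score, aln.subject_span, aln.query_span, aln.aligned_length,
                aln.matches, aln.mismatches, aln.gap_opens, aln.identity,
                aln.subject_coverage, aln.query_coverage,
            )
        return aln


def _apply_unplaced_filter(
    proteomes: Mapping[str, list[Gene]], config: PanelConfig
) -> tuple[dict[str, list[Gene]], list[pp.DropRecord]]:
    if not config.exclude_unplaced:
        return {s: list(g) for s, g in proteomes.items()}, []
    drops = []
    kept: dict[str, list[Gene]] = {}
    for species, genes in proteomes.items():
        kept[species] = []
        for g in genes:
            if is_unplaced(g.chromosome, config.scaffold_pattern):
                drops.append(pp.DropRecord("unplaced", g.gene_id, f"chromosome {g.chromosome}"))
            else:
                kept[species].append(g)
    return kept, drops


def _direction_pass(
    direction: str,
    seed_species: str,
    other_seed: str,
    config: PanelConfig,
    store: _TableStore,
    gene_index: Mapping[str, dict[str, Gene]],
    drops: list[pp.DropRecord],
) -> tuple[list[pp.ParalogFamily], list[pp.LSPCall], dict[str, int], int]:
    cutoff = config.evalue_cutoff
    counts: dict[str, int] = {}

    def stage(name: str):
        return f"{direction}:{name}"

    try:
        cross = store.get(seed_species, other_seed)
    except ValueError as exc:
        raise StageError(stage("cross_search"), str(exc)) from exc
    total_analyzed = len(cross.queries_with_hit(cutoff))

    try:
        self_table = store.get(seed_species, seed_species)
    except ValueError as exc:
        raise StageError(stage("self_search"), str(exc)) from exc
    pairs, flagged = pp.find_duplicate_pairs(seed_species, self_table, cutoff)
    counts["candidate_pairs"] = len(pairs)
    for fam in flagged:
        drops.append(
            pp.DropRecord(stage("pair_calling"), "|".join(sorted(fam)), "family_size>2")
        )

    seed_genes = gene_index[seed_species]
    kept_pairs = []
    for g1, g2 in pairs:
        aln = store.align(seed_genes[g1].peptide, seed_genes[g2].peptide)
        keep, reason = pp.exclude_artifacts(
            aln,
            len(seed_genes[g1].peptide),
            len(seed_genes[g2].peptide),
            config.coverage_min,
            config.length_ratio_max,
        )
        if keep:
            kept_pairs.append((g1, g2))
        else:
            drops.append(pp.DropRecord(stage("artifact_exclusion"), f"{g1}|{g2}", reason))
    counts["after_artifact_exclusion"] = len(kept_pairs)

    chrom_pairs = []
    for g1, g2 in kept_pairs:
        if seed_genes[g1].chromosome == seed_genes[g2].chromosome:
            drops.append(
                pp.DropRecord(stage("chromosome_filter"), f"{g1}|{g2}", "same_chromosome")
            )
        else:
            chrom_pairs.append((g1, g2))
    counts["after_chromosome_filter"] = len(chrom_pairs)

    surviving = []
    for g1, g2 in chrom_pairs:
        orthologs: dict[str, str] = {}
        ok = True
        for og in config.outgroups:
            try:
                fwd = store.get(seed_species, og)
                rev = store.get(og, seed_species)
            except ValueError as exc:
                raise StageError(stage("outgroup_test"), str(exc)) from exc
            passed, og_gene = pp.outgroup_singleton_test((g1, g2), fwd, rev, cutoff)
            if not passed:
                ok = False
                drops.append(
                    pp.DropRecord(stage("outgroup_test"), f"{g1}|{g2}", f"outgroup:{og}")
                )
                break
            orthologs[og] = og_gene
        if ok:
            surviving.append(((g1, g2), orthologs))
    counts["after_outgroup_test"] = len(surviving)

    families: list[pp.ParalogFamily] = []
    calls: list[pp.LSPCall] = []
    for idx, ((g1, g2), orthologs) in enumerate(surviving):
        fid = f"{direction}{idx:04d}"
        family = pp.ParalogFamily(
            family_id=fid,
            seed_species=seed_species,
            seed_pair=(g1, g2),
            seed_chromosomes=(seed_genes[g1].chromosome, seed_genes[g2].chromosome),
            outgroup_orthologs=orthologs,
        )
        family.copy_number[seed_species] = 2
        family.supporting_genes[seed_species] = [g1, g2]
        for species in config.ingroup_species:
            if species == seed_species:
                continue
            try:
                fwd = store.get(seed_species, species)
                rev = store.get(species, seed_species)
            except ValueError as exc:
                if species in config.allow_missing_species:
                    continue
                raise StageError(stage("copy_number"), str(exc)) from exc
            count, support, ambiguous = pp.copy_number(
                (g1, g2), fwd, rev, gene_index[species], cutoff
            )
            family.copy_number[species] = count
            family.supporting_genes[species] = support
            if ambiguous:
                family.ambiguous_species.append(species)
        families.append(family)
        calls.append(pp.classify_lsp(family, config))
    counts["families"] = len(families)
    return families, calls, counts, total_analyzed


def _assign_copies(
    family: pp.ParalogFamily,
    store: _TableStore,
    config: PanelConfig,
) -> tuple[set[str], set[str]]:
    """Split duplicate-species genes into the two seed-copy groups by best hit."""
    g1, g2 = family.seed_pair
    copy1, copy2 = {g1}, {g2}
    for species, support in family.supporting_genes.items():
        if species == family.seed_species or len(support) < 2:
            continue
        fwd = store.get(family.seed_species, species)
        for t in support:
            s1 = next((h.bitscore for h in fwd.hits_from(g1) if h.subject_id == t), None)
            s2 = next((h.bitscore for h in fwd.hits_from(g2) if h.subject_id == t), None)
            if s1 is None and s2 is None:
                continue
            if s2 is None or (s1 is not None and s1 >= s2):
                copy1.add(t)
            else:
                copy2.add(t)
    return copy1, copy2


def _verify_family(
    family: pp.ParalogFamily,
    call: pp.LSPCall,
    config: PanelConfig,
    store: _TableStore,
    gene_index: Mapping[str, dict[str, Gene]],
    proteomes: Mapping[str, list[Gene]],
    rbh_map: dict[str, str],
    other_seed: str,
) -> tuple[str | None, list[vf.SyntenyScore], str | None]:
    all_genes: list[Gene] = []
    for species, support in family.supporting_genes.items():
        for gid in support:
            all_genes.append(gene_index[species][gid])
    og_species = config.outgroups[0]
    og_gene_id = family.outgroup_orthologs.get(og_species)
    if og_gene_id is None:
        return None, [], None
    all_genes.append(gene_index[og_species][og_gene_id])
    copy1, copy2 = _assign_copies(family, store, config)
    if len(all_genes) < 4:
        return None, [], None
    tree = vf.tree_from_genes(all_genes)
    passed = vf.duplication_topology_test(tree, copy1, copy2, og_gene_id)
    status = "topology_pass" if passed else "topology_fail"
    scores: list[vf.SyntenyScore] = []
    singleton = family.supporting_genes.get(other_seed, [])
    if len(singleton) == 1:
        scores = vf.synteny_score(
            family.family_id,
            list(family.seed_pair),
            singleton[0],
            proteomes[family.seed_species],
            proteomes[other_seed],
            (family.seed_species, other_seed),
            rbh_map,
            config.synteny_window,
        )
    return status, scores, tree.to_newick(og_gene_id)


def run_pipeline(
    config: PanelConfig,
    proteomes: Mapping[str, list[Gene]],
    annotation: Mapping[str, set[str]] | None = None,
    slim_table: Mapping[str, set[str]] | None = None,
    verify: bool = True,
    report_evalue: float | None = None,
    n_permutations: int = 9999,
) -> ResultBundle:
    """Run the full cascade over in-memory proteomes.

    Deterministic given ``config.seed``; every stage logs its survivor count
    and per-item drop reasons are recorded.
    """
    missing = [
        s
        for s in config.all_species
        if s not in proteomes and s not in config.allow_missing_species
    ]
    if missing:
        raise StageError("input", f"species missing from input: {missing}")
    proteomes, drops = _apply_unplaced_filter(proteomes, config)
    gene_index = {
        s: {g.gene_id: g for g in genes} for s, genes in proteomes.items()
    }
    store = _TableStore(
        proteomes, report_evalue if report_evalue is not None else hs.DEFAULT_REPORT_EVALUE
    )

    stage_counts: dict[str, dict[str, int]] = {}
    all_families: list[pp.ParalogFamily] = []
    all_calls: list[pp.LSPCall] = []
    totals: dict[str, int] = {}

    fam_a, calls_a, counts_a, total_a = _direction_pass(
        "a", config.seed_a, config.seed_b, config, store, gene_index, drops
    )
    stage_counts["a"] = counts_a
    totals["a"] = total_a
    all_families.extend(fam_a)
    all_calls.extend(calls_a)

    fam_b, calls_b, counts_b, total_b = _direction_pass(
        "b", config.seed_b, config.seed_a, config, store, gene_index, drops
    )
    totals["b"] = total_b
    # drop direction-b rediscoveries of direction-a families (shared duplicates)
    a_support: set[frozenset] = {
        frozenset(f.supporting_genes.get(config.seed_b, [])) for f in fam_a
    }
    kept_b, kept_calls_b = [], []
    for fam, call in zip(fam_b, calls_b):
        if frozenset(fam.seed_pair) in a_support:
            drops.append(
                pp.DropRecord("b:dedup", "|".join(fam.seed_pair), "rediscovered_from_a")
            )
            continue
        kept_b.append(fam)
        kept_calls_b.append(call)
    counts_b["families"] = len(kept_b)
    stage_counts["b"] = counts_b
    all_families.extend(kept_b)
    all_calls.extend(kept_calls_b)

    # verification of LSP calls
    synteny_scores: list[vf.SyntenyScore] = []
    newicks: dict[str, str] = {}
    if verify:
        rbh_ab = dict(
            hs.reciprocal_best_hits(
                store.get(config.seed_a, config.seed_b),
                store.get(config.seed_b, config.seed_a),
            )
        )
        rbh_ba = {b: a for a, b in rbh_ab.items()}
        fam_by_id = {f.family_id: f for f in all_families}
        for call in all_calls:
            if call.call not in ("A_LSP", "B_LSP"):
                continue
            family = fam_by_id[call.family_id]
            other_seed = config.seed_b if family.seed_species == config.seed_a else config.seed_a
            rbh_map = rbh_ab if family.seed_species == config.seed_a else rbh_ba
            result = _verify_family(
                family, call, config, store, gene_index, proteomes, rbh_map, other_seed
            )
            if result[0] is not None:
                call.verification_status = result[0]
                synteny_scores.extend(result[1])
                newicks[family.family_id] = result[2]

    # chromosome statistics over the direction-a seed genome
    seed_a_genes = gene_index[config.seed_a]
    tsgd_chroms = [
        seed_a_genes[g].chromosome
        for f in fam_a
        for g in f.seed_pair
    ]
    calls_by_fam = {c.family_id: c for c in all_calls}
    lsp_chroms = [
        seed_a_genes[g].chromosome
        for f in fam_a
        if calls_by_fam[f.family_id].call == "A_LSP"
        for g in f.seed_pair
    ]
    chrom_stats = rs.chromosome_table(tsgd_chroms, lsp_chroms)
    per = chrom_stats.per_chromosome
    if len(per) >= 3:
        x = [per[c][0] for c in sorted(per)]
        y = [per[c][1] for c in sorted(per)]
        try:
            rho, p_perm = rs.spearman(x, y, n_permutations=n_permutations, seed=config.seed)
            chrom_stats.rho = rho
            chrom_stats.p_perm = p_perm
        except ValueError:
            pass

    # enrichment of LSP seed genes (direction a) against the annotation
    enrichment: list[rs.EnrichmentRow] = []
    if annotation:
        ann = dict(annotation)
        if slim_table:
            ann = rs.map_to_slim(ann, slim_table)
        study = [
            g
            for f in fam_a
            if calls_by_fam[f.family_id].call == "A_LSP"
            for g in f.seed_pair
            if g in ann
        ]
        if study:
            enrichment, _ = rs.hypergeometric_enrichment(study, ann, min_genes=0)

    lsp_fam_counts = {
        "a": sum(1 for c in all_calls if c.call == "A_LSP"),
        "b": sum(1 for c in all_calls if c.call == "B_LSP"),
    }
    summary = pp.summarize_panel(
        tsgd_gene_counts={"a": 2 * len(fam_a), "b": 2 * len(kept_b) + 2 * sum(
            1 for f in fam_a if calls_by_fam[f.family_id].call == "shared_duplicate"
        )},
        lsp_family_counts=lsp_fam_counts,
        lsp_gene_counts={"a": 2 * lsp_fam_counts["a"], "b": 2 * lsp_fam_counts["b"]},
        # directions with zero positive hits have no meaningful denominator
        totals={d: t for d, t in totals.items() if t > 0},
    )
    return ResultBundle(
        tsgd_families=all_families,
        lsp_calls=all_calls,
        chromosome_stats=chrom_stats,
        enrichment=enrichment,
        summary=summary,
        stage_counts=stage_counts,
        drops=drops,
        synteny=synteny_scores,
        newicks=newicks,
    )


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_results(bundle: ResultBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_tsv(
        out / "tsgd_pairs.tsv",
        ("family_id", "seed_species", "gene_1", "gene_2", "chromosome_1", "chromosome_2", "outgroup_orthologs"),
        [
            (
                f.family_id,
                f.seed_species,
                f.seed_pair[0],
                f.seed_pair[1],
                f.seed_chromosomes[0],
                f.seed_chromosomes[1],
                ";".join(f"{k}={v}" for k, v in sorted(f.outgroup_orthologs.items())),
            )
            for f in bundle.tsgd_families
        ],
    )
    fam_by_id = {f.family_id: f for f in bundle.tsgd_families}
    write_tsv(
        out / "lsp_calls.tsv",
        ("family_id", "call", "copy_numbers", "supporting_genes", "verification_status"),
        [
            (
                c.family_id,
                c.call,
                ";".join(
                    f"{s}={n}" for s, n in sorted(fam_by_id[c.family_id].copy_number.items())
                ),
                ";".join(
                    f"{s}={','.join(g)}"
                    for s, g in sorted(fam_by_id[c.family_id].supporting_genes.items())
                ),
                c.verification_status,
            )
            for c in bundle.lsp_calls
        ],
    )
    cs = bundle.chromosome_stats
    write_tsv(
        out / "chromosome_stats.tsv",
        ("chromosome", "tsgd_count", "lsp_count", "ratio"),
        [
            (c, t, l, f"{(l / t):.6f}" if t else "NA")
            for c, (t, l) in sorted(cs.per_chromosome.items())
        ],
    )
    write_tsv(
        out / "enrichment.tsv",
        ("term_id", "term_name", "study_count", "background_count", "p_value", "q_value", "gene_ids"),
        [
            (
                r.term_id,
                r.term_name,
                r.study_count,
                r.background_count,
                f"{r.p_value:.6g}",
                f"{r.q_value:.6g}",
                ",".join(r.gene_ids),
            )
            for r in bundle.enrichment
        ],
    )
    write_tsv(
        out / "verification.tsv",
        ("family_id", "verification_status", "species_pair", "window", "shared_fraction"),
        [
            (
                s.family_id,
                bundle.calls_by_family()[s.family_id].verification_status,
                f"{s.species_pair[0]}|{s.species_pair[1]}",
                s.window,
                f"{s.shared_fraction:.4f}",
            )
            for s in bundle.synteny
        ],
    )
    with open(out / "trees.nwk", "w") as fh:
        for fid, nwk in sorted(bundle.newicks.items()):
            fh.write(f"{fid}\t{nwk}\n")
    write_tsv(
        out / "drops.tsv",
        ("stage", "item", "reason"),
        [(d.stage, d.item, d.reason) for d in bundle.drops],
    )
    s = bundle.summary
    write_json(
        out / "summary.json",
        {
            "totals": s.totals,
            "tsgd_gene_counts": s.tsgd_gene_counts,
            "tsgd_gene_pct": s.tsgd_gene_pct,
            "lsp_family_counts": s.lsp_family_counts,
            "lsp_gene_counts": s.lsp_gene_counts,
            "lsp_gene_pct": s.lsp_gene_pct,
            "stage_counts": bundle.stage_counts,
            "spearman_rho": cs.rho,
            "spearman_p_perm": cs.p_perm,
            "mean_lsp_ratio": cs.mean_ratio,
            "se_lsp_ratio": cs.se_ratio,
        },
    )
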