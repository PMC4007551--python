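"""Simulate a post-WGD proteome panel with ground-truth retention labels.

One ancestral gene per family passes through a whole-genome duplication;
retained pairs may collapse back to singletons on either lineage's stem
branch (the systematic-retention signature) or in individual species
(noise). Peptides evolve under a uniform-rate Poisson substitution model
with no indels; the two post-WGD copies of a family occupy a chromosome
pair fixed at duplication time and shared by all descendant species, and
families are laid out along chromosomes in family-index order so that
neighbourhoods are conserved for synteny scoring. Outgroups never
duplicate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .io_formats import AMINO_ACIDS, Gene, PanelConfig, write_proteome, write_tsv

TRUE_CLASSES = ("A_LSP", "B_LSP", "shared_duplicate", "shared_singleton", "noisy")

_GENE_SPACING = 10_000


@dataclass
class SimConfig:
    species_panel: PanelConfig
    n_families: int = 100
    n_chromosomes_per_species: int = 10
    peptide_length: int = 300
    wgd_retention_prob: float = 0.5
    loss_prob_a: float = 0.3
    loss_prob_b: float = 0.3
    per_species_loss_prob: float = 0.0
    divergence_pre_split: float = 0.05
    divergence_post_split: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        if self.n_chromosomes_per_species < 1:
            raise ValueError("n_chromosomes_per_species must be positive")
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be positive")
        for name in ("wgd_retention_prob", "loss_prob_a", "loss_prob_b", "per_species_loss_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        for name in ("divergence_pre_split", "divergence_post_split"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        data = dict(data)
        panel = data.pop("species_panel")
        if isinstance(panel, Mapping):
            panel = PanelConfig.from_dict(panel)
        known = {f.name for f in dataclasses.fields(cls)} - {"species_panel"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
        return cls(species_panel=panel, **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SyntheticTruth:
    family_id: str
    post_wgd_state: str  # retained_pair | singleton
    lineage_a_state: str  # duplicate | singleton | absent
    lineage_b_state: str
    per_species_copy_number: dict[str, int]
    true_class: str

    def __post_init__(self) -> None:
        if self.true_class not in TRUE_CLASSES:
            raise ValueError(f"unknown true_class {self.true_class!r}")


def random_peptide(length: int, rng: np.random.Generator) -> str:
    """A random peptide over the 20 canonical residues (uniform background)."""
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_peptide(sequence: str, expected_distance: float, rng: np.random.Generator) -> str:
    """Apply a Poisson(expected_distance) number of substitution events per site.

    Each event replaces the residue with one of the other 19, drawn
    uniformly; at large distances site identity converges to ~1/20.
    Length is preserved (no indels).
    """
    if expected_distance < 0:
        raise ValueError("expected_distance must be >= 0")
    if expected_distance == 0:
        return sequence
    n_events = rng.poisson(expected_distance, size=len(sequence))
    residues = list(sequence)
    for i in np.flatnonzero(n_events):
        for _ in range(n_events[i]):
            current = residues[i]
            choices = [a for a in AMINO_ACIDS if a != current]
            residues[i] = choices[rng.integers(len(choices))]
    return "".join(residues)


def _classify(copy_numbers: Mapping[str, int], panel: PanelConfig) -> str:
    a = [copy_numbers[s] for s in panel.lineage_a]
    b = [copy_numbers[s] for s in panel.lineage_b]
    if all(c == 2 for c in a) and all(c == 1 for c in b):
        return "A_LSP"
    if all(c == 1 for c in a) and all(c == 2 for c in b):
        return "B_LSP"
    if all(c == 2 for c in a + b):
        return "shared_duplicate"
    if all(c == 1 for c in a + b):
        return "shared_singleton"
    return "noisy"


@dataclass
class SimulatedPanel:
    proteomes: dict[str, list[Gene]]
    truth: list[SyntheticTruth]
    config: SimConfig = field(repr=False)


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Generate per-species proteomes plus the ground-truth retention table."""
    panel = config.species_panel
    rng = np.random.default_rng(config.seed)
    n_chrom = config.n_chromosomes_per_species
    chromosomes = [f"chr{i + 1}" for i in range(n_chrom)]
    width = max(4, len(str(config.n_families)))

    families = []
    for idx in range(config.n_families):
        fid = f"F{idx:0{width}d}"
        ancestor = random_peptide(config.peptide_length, rng)
        retained = rng.random() < config.wgd_retention_prob
        if retained and n_chrom < 2:
            raise ValueError(
                "n_chromosomes_per_species must be >= 2 to place a retained pair "
                "on distinct chromosomes"
            )
        if retained:
            chrom_pair = tuple(rng.choice(n_chrom, size=2, replace=False))
        else:
            chrom_pair = (int(rng.integers(n_chrom)),) * 2
        # copy sequences at the lineage split (pre-split divergence per copy)
        copy_seqs = {
            1: mutate_peptide(ancestor, config.divergence_pre_split, rng),
            2: mutate_peptide(ancestor, config.divergence_pre_split, rng)
            if retained
            else None,
        }
        loss_a = retained and rng.random() < config.loss_prob_a
        loss_b = retained and rng.random() < config.loss_prob_b
        # stem losses drop one copy for the whole lineage, chosen once
        kept_after_stem = {}
        for lineage, lost in (("a", loss_a), ("b", loss_b)):
            if not retained:
                kept_after_stem[lineage] = (1,)
            elif lost:
                kept_after_stem[lineage] = (int(rng.integers(1, 3)),)
            else:
                kept_after_stem[lineage] = (1, 2)
        families.append(
            {
                "fid": fid,
                "ancestor": ancestor,
                "retained": retained,
                "chrom_pair": chrom_pair,
                "copy_seqs": copy_seqs,
                "kept_after_stem": kept_after_stem,
            }
        )

    proteomes: dict[str, list[Gene]] = {s: [] for s in panel.all_species}
    per_family_species_copies: dict[str, dict[str, list[int]]] = {
        f["fid"]: {} for f in families
    }

    for species in panel.all_species:
        if species in panel.outgroups:
            group = "og"
        elif species in panel.lineage_a:
            group = "a"
        else:
            group = "b"
        # per-chromosome running order index for gene placement
        chrom_rank: dict[str, int] = {c: 0 for c in chromosomes}
        for fam in families:
            fid = fam["fid"]
            if group == "og":
                kept = (1,)
            else:
                kept = list(fam["kept_after_stem"][group])
                if (
                    kept
                    and config.per_species_loss_prob > 0
                    and rng.random() < config.per_species_loss_prob
                ):
                    kept.pop(int(rng.integers(len(kept))))
                kept = tuple(kept)
            per_family_species_copies[fid][species] = list(kept)
            for copy in kept:
                base = fam["copy_seqs"][copy] if group != "og" else fam["ancestor"]
                peptide = mutate_peptide(base, config.divergence_post_split, rng)
                chrom = chromosomes[fam["chrom_pair"][copy - 1]]
                rank = chrom_rank[chrom]
                chrom_rank[chrom] += 1
                start = rank * _GENE_SPACING + 1
                proteomes[species].append(
                    Gene(
                        gene_id=f"{fid}c{copy}_{species}",
                        species=species,
                        chromosome=chrom,
                        start=start,
                        end=start + 3 * len(peptide) - 1,
                        strand="+",
                        peptide=peptide,
                    )
                )

    truth = []
    for fam in families:
        fid = fam["fid"]
        copies = per_family_species_copies[fid]
        copy_numbers = {s: len(c) for s, c in copies.items()}
        state = {}
        for lineage, species_list in (("a", panel.lineage_a), ("b", panel.lineage_b)):
            stem = fam["kept_after_stem"][lineage]
            state[lineage] = "duplicate" if len(stem) == 2 else "singleton"
        truth.append(
            SyntheticTruth(
                family_id=fid,
                post_wgd_state="retained_pair" if fam["retained"] else "singleton",
                lineage_a_state=state["a"],
                lineage_b_state=state["b"],
                per_species_copy_number=copy_numbers,
                true_class=_classify(
                    {s: copy_numbers[s] for s in panel.ingroup_species}, panel
                ),
            )
        )
    for species in proteomes:
        proteomes[species].sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return SimulatedPanel(proteomes=proteomes, truth=truth, config=config)


TRUTH_COLUMNS = (
    "family_id",
    "post_wgd_state",
    "lineage_a_state",
    "lineage_b_state",
    "true_class",
    "per_species_copy_number",
)


def write_panel(panel: SimulatedPanel, out_dir: str | Path) -> None:
    """Write per-species FASTA + gene-map files and the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for species, genes in sorted(panel.proteomes.items()):
        write_proteome(genes, out / f"{species}.faa", out / f"{species}.genemap.tsv")
    rows = []
    for t in panel.truth:
        cn = ";".join(f"{s}={c}" for s, c in sorted(t.per_species_copy_number.items()))
        rows.append(
            (t.family_id, t.post_wgd_state, t.lineage_a_state, t.lineage_b_state, t.true_class, cn)
        )
    write_tsv(out / "truth.tsv", TRUTH_COLUMNS, rows)
    panel.config.species_panel.to_yaml(out / "panel.yaml")


def read_truth(path: str | Path) -> list[SyntheticTruth]:
    truths = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"{path}: unexpected truth-table header")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            cn = {}
            if parts[5]:
                for item in parts[5].split(";"):
                    s, c = item.split("=")
                    cn[s] = int(c)
            truths.append(
                SyntheticTruth(
                    family_id=parts[0],
                    post_wgd_state=parts[1],
                    lineage_a_state=parts[2],
                    lineage_b_state=parts[3],
                    per_species_copy_number=cn,
                    true_class=parts[4],
                )
            )
    return truths
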