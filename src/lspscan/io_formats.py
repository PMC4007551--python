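"""On-disk formats: proteome FASTA + gene-map TSV, tabular hit files, configs, results.

Coordinates are 1-based inclusive in files (the common gene-map dialect) and
kept that way on the :class:`Gene` objects; any half-open arithmetic is done
locally where needed.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

GENEMAP_COLUMNS = ("gene_id", "species", "chromosome", "start", "end", "strand")

DEFAULT_SCAFFOLD_PATTERN = r"(?i)^(scaffold|contig|un|random|chrUn)"


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene: location on a chromosome plus its peptide."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str
    peptide: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise FormatError("gene_id must be non-empty")
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"{self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: strand must be '+' or '-'")
        if len(self.peptide) < 1:
            raise FormatError(f"{self.gene_id}: empty peptide")
        bad = set(self.peptide) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"{self.gene_id}: invalid residue(s) {sorted(bad)} in peptide"
            )


@dataclass
class PanelConfig:
    """Two-lineage panel definition plus the thresholds of the calling cascade."""

    lineage_a: list[str]
    lineage_b: list[str]
    outgroups: list[str]
    seed_a: str
    seed_b: str
    evalue_cutoff: float = 1e-80
    coverage_min: float = 0.5
    length_ratio_max: float = 2.0
    synteny_window: int = 4
    seed: int = 0
    exclude_unplaced: bool = True
    scaffold_pattern: str = DEFAULT_SCAFFOLD_PATTERN
    allow_missing_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("lineage_a", "lineage_b", "outgroups"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        groups = [set(self.lineage_a), set(self.lineage_b), set(self.outgroups)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = groups[i] & groups[j]
                if overlap:
                    raise ValueError(
                        f"species groups must be disjoint; shared: {sorted(overlap)}"
                    )
        if self.seed_a not in self.lineage_a:
            raise ValueError(f"seed_a {self.seed_a!r} not in lineage_a")
        if self.seed_b not in self.lineage_b:
            raise ValueError(f"seed_b {self.seed_b!r} not in lineage_b")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if not 0 < self.coverage_min <= 1:
            raise ValueError("coverage_min must be in (0,1]")
        if self.length_ratio_max <= 1:
            raise ValueError("length_ratio_max must be > 1")
        if self.synteny_window < 1:
            raise ValueError("synteny_window must be positive")

    @property
    def all_species(self) -> list[str]:
        return list(self.lineage_a) + list(self.lineage_b) + list(self.outgroups)

    @property
    def ingroup_species(self) -> list[str]:
        return list(self.lineage_a) + list(self.lineage_b)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PanelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown panel config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise FormatError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def is_unplaced(chromosome: str, pattern: str = DEFAULT_SCAFFOLD_PATTERN) -> bool:
    return re.match(pattern, chromosome) is not None


# ---------------------------------------------------------------------------
# Proteome FASTA + gene-map TSV
# ---------------------------------------------------------------------------

def read_genemap(path: str | Path) -> dict[str, dict]:
    """Parse a gene-map TSV (header: gene_id species chromosome start end strand)."""
    rows: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != GENEMAP_COLUMNS:
            raise FormatError(
                f"{path}: expected header {' '.join(GENEMAP_COLUMNS)}, got {' '.join(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(GENEMAP_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected {len(GENEMAP_COLUMNS)} columns")
            rec = dict(zip(GENEMAP_COLUMNS, parts))
            try:
                rec["start"] = int(rec["start"])
                rec["end"] = int(rec["end"])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if rec["gene_id"] in rows:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {rec['gene_id']!r}")
            rows[rec["gene_id"]] = rec
    return rows


def read_proteome(fasta_path: str | Path, genemap_path: str | Path, species: str) -> list[Gene]:
    """Load one species' proteome, joining FASTA records to gene-map rows.

    Every FASTA record must have exactly one gene-map row and vice versa.
    Returns genes sorted by (chromosome, start, gene_id).
    """
    genemap = read_genemap(genemap_path)
    genes: list[Gene] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        gid = record.id
        if gid in seen:
            raise FormatError(f"{fasta_path}: duplicate FASTA record {gid!r}")
        seen.add(gid)
        row = genemap.get(gid)
        if row is None:
            raise FormatError(f"{fasta_path}: record {gid!r} missing from gene map {genemap_path}")
        if row["species"] != species:
            raise FormatError(
                f"{genemap_path}: gene {gid!r} maps to species {row['species']!r}, expected {species!r}"
            )
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{fasta_path}: record {gid!r} has an empty sequence")
        genes.append(
            Gene(
                gene_id=gid,
                species=species,
                chromosome=row["chromosome"],
                start=row["start"],
                end=row["end"],
                strand=row["strand"],
                peptide=seq,
            )
        )
    missing = set(genemap) - seen
    if missing:
        raise FormatError(
            f"{genemap_path}: gene(s) absent from FASTA {fasta_path}: {sorted(missing)[:5]}"
        )
    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def write_proteome(genes: Sequence[Gene], fasta_path: str | Path, genemap_path: str | Path) -> None:
    ordered = sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    records = [
        SeqRecord(Seq(g.peptide), id=g.gene_id, description="") for g in ordered
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(genemap_path, "w") as fh:
        fh.write("\t".join(GENEMAP_COLUMNS) + "\n")
        for g in ordered:
            fh.write(
                f"{g.gene_id}\t{g.species}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# 12-column tabular hit files (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

HIT_COLUMNS = 12


def read_hit_rows(path: str | Path) -> list[dict]:
    """Parse the 12-column tabular dialect into plain row dicts.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, qstart, qend, sstart, send, evalue, bitscore.
    """
    rows: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {HIT_COLUMNS} tab-separated columns, got {len(parts)}"
                )
            try:
                evalue = float(parts[10])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable E-value {parts[10]!r}") from exc
            if evalue < 0:
                raise FormatError(f"{path}:{lineno}: negative E-value")
            try:
                rows.append(
                    {
                        "query_id": parts[0],
                        "subject_id": parts[1],
                        "identity_pct": float(parts[2]),
                        "aln_length": int(parts[3]),
                        "mismatches": int(parts[4]),
                        "gap_opens": int(parts[5]),
                        "qstart": int(parts[6]),
                        "qend": int(parts[7]),
                        "sstart": int(parts[8]),
                        "send": int(parts[9]),
                        "evalue": evalue,
                        "bitscore": float(parts[11]),
                    }
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed numeric field") from exc
    return rows


def format_evalue(evalue: float) -> str:
    if evalue == 0:
        return "0.0"
    return f"{evalue:.3g}"


def write_hit_rows(rows: Iterable[Mapping], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r["query_id"],
                        r["subject_id"],
                        f"{r['identity_pct']:.2f}",
                        str(r["aln_length"]),
                        str(r["mismatches"]),
                        str(r["gap_opens"]),
                        str(r["qstart"]),
                        str(r["qend"]),
                        str(r["sstart"]),
                        str(r["send"]),
                        format_evalue(r["evalue"]),
                        f"{r['bitscore']:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation / slim tables and result writers
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a gene→GO-term TSV (two columns, no header required)."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected gene_id<TAB>term_id")
            ann.setdefault(parts[0], set()).add(parts[1])
    return ann


def read_slim_table(path: str | Path) -> dict[str, set[str]]:
    """Read a fine-term→slim-term TSV (two columns)."""
    table: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected term_id<TAB>slim_id")
            table.setdefault(parts[0], set()).add(parts[1])
    return table


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_json(path: str | Path, payload: Mapping) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
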