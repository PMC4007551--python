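"""Desk-scale confirmation of candidate LSP families.

Two independent checks:

* a duplication-topology test — neighbor joining on Poisson-corrected
  pairwise protein distances, rooted on an outgroup gene; the family passes
  when the duplication node precedes the within-lineage speciations
  (copy-1 genes form one clade, copy-2 genes another);
* a synteny score — the fraction of flanking-gene orthologs shared between
  a gene's neighbourhood and its counterpart's neighbourhood.

This is deliberately lightweight machinery: the question answered is purely
topological, so no Bayesian/ML tree inference is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import biotite.sequence as _bseq
import biotite.sequence.align as _balign
import numpy as np

from .homology_search import _DEFAULT_BMATRIX, GAP_EXTEND, GAP_OPEN
from .io_formats import Gene

# -ln(1-p) diverges as p -> 1; distances are capped at p = P_CAP
P_CAP = 0.95
MAX_DISTANCE = -math.log(1.0 - P_CAP)

ZERO_BRANCH_TOL = 1e-9


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites over globally aligned (non-gap) columns."""
    if len(seq_a) == len(seq_b):
        aligned = list(zip(seq_a, seq_b))
    else:
        aln = _balign.align_optimal(
            _bseq.ProteinSequence(seq_a),
            _bseq.ProteinSequence(seq_b),
            _DEFAULT_BMATRIX,
            gap_penalty=(-(GAP_OPEN + GAP_EXTEND), -GAP_EXTEND),
            local=False,
            max_number=1,
        )[0]
        aligned = [
            (seq_a[qi], seq_b[si]) for qi, si in aln.trace if qi != -1 and si != -1
        ]
    if not aligned:
        raise ValueError("no aligned sites between the two sequences")
    diffs = sum(1 for a, b in aligned if a != b)
    return diffs / len(aligned)


def protein_distance(seq_a: str, seq_b: str) -> float:
    """Poisson-corrected distance d = -ln(1 - p), capped at p = 0.95."""
    p = p_distance(seq_a, seq_b)
    if p >= P_CAP:
        return MAX_DISTANCE
    return -math.log(1.0 - p)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceTree:
    """Unrooted tree as an undirected adjacency map over integer node ids.

    Leaves carry labels; internal ids are unlabeled. Branch lengths are
    clamped at zero.
    """

    adjacency: dict[int, list[tuple[int, float]]]
    leaf_labels: dict[int, str]

    def leaves(self) -> set[str]:
        return set(self.leaf_labels.values())

    def _node_of(self, label: str) -> int:
        for node, lab in self.leaf_labels.items():
            if lab == label:
                return node
        raise KeyError(f"leaf {label!r} not in tree")

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions (as frozensets of leaf labels, smaller side)."""
        all_leaves = frozenset(self.leaf_labels.values())
        result: set[frozenset] = set()
        for a in self.adjacency:
            for b, _ in self.adjacency[a]:
                if a < b:
                    side = self._leafset_beyond(b, a)
                    if 1 < len(side) < len(all_leaves) - 1:
                        other = all_leaves - side
                        result.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return result

    def _leafset_beyond(self, start: int, blocked: int) -> frozenset:
        seen = {blocked, start}
        stack = [start]
        labels = []
        while stack:
            node = stack.pop()
            if node in self.leaf_labels:
                labels.append(self.leaf_labels[node])
            for nb, _ in self.adjacency[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return frozenset(labels)

    def to_newick(self, root_label: str | None = None) -> str:
        if root_label is None:
            root = min(self.leaf_labels)
        else:
            root = self._node_of(root_label)
        def render(node: int, parent: int) -> str:
            children = [(nb, ln) for nb, ln in self.adjacency[node] if nb != parent]
            if not children:
                return self.leaf_labels[node]
            inner = ",".join(f"{render(nb, node)}:{ln:.6f}" for nb, ln in children)
            name = self.leaf_labels.get(node, "")
            return f"({inner}){name}"
        (first, ln0), = [e for e in self.adjacency[root]]
        return f"({self.leaf_labels[root]}:{ln0:.6f},{render(first, root)}:0.0);"


def neighbor_joining(distance_matrix: np.ndarray, labels: list[str]) -> DistanceTree:
    """Standard neighbor-joining agglomeration (Saitou & Nei / Studier-Keppler).

    Requires a symmetric matrix with zero diagonal over >= 3 taxa; on
    additive matrices the generating topology is recovered exactly.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix shape does not match label count")
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if len(set(labels)) != n:
        raise ValueError("leaf labels must be unique")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")

    adjacency: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n)}
    leaf_labels = {i: lab for i, lab in enumerate(labels)}
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    next_id = n

    def get(i: int, j: int) -> float:
        return dist[(i, j)] if (i, j) in dist else dist[(j, i)]

    while len(active) > 3:
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        m = len(active)
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        u = next_id
        next_id += 1
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        adjacency[u] = []
        adjacency[u].append((i, li))
        adjacency[i].append((u, li))
        adjacency[u].append((j, lj))
        adjacency[j].append((u, lj))
        for k in active:
            if k in (i, j):
                continue
            dist[(u, k)] = 0.5 * (get(i, k) + get(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (get(i, j) + get(i, k) - get(j, k))
    lj = 0.5 * (get(i, j) + get(j, k) - get(i, k))
    lk = 0.5 * (get(i, k) + get(j, k) - get(i, j))
    center = next_id
    adjacency[center] = []
    for node, ln in ((i, li), (j, lj), (k, lk)):
        ln = max(ln, 0.0)
        adjacency[center].append((node, ln))
        adjacency[node].append((center, ln))
    return DistanceTree(adjacency=adjacency, leaf_labels=leaf_labels)


def tree_from_genes(genes: list[Gene]) -> DistanceTree:
    """NJ tree over genes from Poisson-corrected pairwise distances."""
    labels = [g.gene_id for g in genes]
    n = len(genes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = protein_distance(genes[i].peptide, genes[j].peptide)
    return neighbor_joining(d, labels)


# ---------------------------------------------------------------------------
# Duplication topology test
# ---------------------------------------------------------------------------

@dataclass
class _RNode:
    label: str | None = None
    children: list[tuple["_RNode", float]] = field(default_factory=list)

    def leafset(self) -> frozenset:
        if not self.children:
            return frozenset([self.label])
        out = frozenset()
        for c, _ in self.children:
            out |= c.leafset()
        return out


def _root_at_leaf(tree: DistanceTree, leaf_label: str) -> _RNode:
    root_node = tree._node_of(leaf_label)

    def build(node: int, parent: int) -> _RNode:
        rn = _RNode(label=tree.leaf_labels.get(node))
        for nb, ln in tree.adjacency[node]:
            if nb != parent:
                rn.children.append((build(nb, node), ln))
        return rn

    (first, _), = tree.adjacency[root_node]
    return build(first, root_node)


def _prune(node: _RNode, keep: set[str]) -> _RNode | None:
    """Restrict to ``keep`` leaves, suppressing unary nodes (lengths summed)."""
    if not node.children:
        return node if node.label in keep else None
    new_children = []
    for child, ln in node.children:
        pruned = _prune(child, keep)
        if pruned is None:
            continue
        if pruned.label is None and len(pruned.children) == 1:
            gchild, gln = pruned.children[0]
            new_children.append((gchild, ln + gln))
        else:
            new_children.append((pruned, ln))
    if not new_children:
        return None
    rn = _RNode(label=node.label)
    rn.children = new_children
    return rn


def _contract_zero_edges(node: _RNode) -> _RNode:
    """Merge children attached by ~zero-length internal edges (soft polytomies)."""
    new_children: list[tuple[_RNode, float]] = []
    for child, ln in node.children:
        child = _contract_zero_edges(child)
        if child.children and ln <= ZERO_BRANCH_TOL:
            new_children.extend(child.children)
        else:
            new_children.append((child, ln))
    rn = _RNode(label=node.label)
    rn.children = new_children
    return rn


def _is_resolvable_clade(root: _RNode, target: frozenset) -> bool:
    """Can ``target`` be a clade in some resolution of this (polytomous) tree?"""
    if len(target) <= 1:
        return True

    def visit(node: _RNode) -> bool:
        inside = []
        ok_here = True
        for child, _ in node.children:
            ls = child.leafset()
            if ls <= target:
                inside.append(ls)
            elif ls & target:
                ok_here = False
        if ok_here and inside and frozenset().union(*inside) == target:
            return True
        return any(visit(child) for child, _ in node.children)

    full = root.leafset()
    if not target <= full:
        return False
    if target == full:
        return True
    return visit(root)


def duplication_topology_test(
    tree: DistanceTree,
    copy1_leaves: set[str],
    copy2_leaves: set[str],
    outgroup_leaf: str,
) -> bool:
    """Does duplication precede the within-lineage speciations?

    The tree is rooted on ``outgroup_leaf`` and restricted to the duplicate
    gene copies; the test passes iff the copy-1 genes and the copy-2 genes
    each form a clade (near-zero internal branches are treated as soft
    polytomies and any resolution may satisfy the test).
    """
    if outgroup_leaf not in tree.leaves():
        raise ValueError(f"outgroup leaf {outgroup_leaf!r} not in tree")
    if copy1_leaves & copy2_leaves:
        raise ValueError("copy-1 and copy-2 leaf sets overlap")
    rooted = _root_at_leaf(tree, outgroup_leaf)
    pruned = _prune(rooted, set(copy1_leaves) | set(copy2_leaves))
    if pruned is None:
        raise ValueError("no duplicate-copy leaves present in tree")
    pruned = _contract_zero_edges(pruned)
    return _is_resolvable_clade(pruned, frozenset(copy1_leaves)) and _is_resolvable_clade(
        pruned, frozenset(copy2_leaves)
    )


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------

@dataclass
class SyntenyScore:
    family_id: str
    species_pair: tuple[str, str]
    window: int
    shared_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0,1]")


def neighborhood(genome: list[Gene], gene_id: str, window: int) -> list[str]:
    """Up to ``window`` flanking gene ids on each side along the chromosome."""
    by_chrom: dict[str, list[Gene]] = {}
    for g in genome:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g.start, g.gene_id))
        for idx, g in enumerate(genes):
            if g.gene_id == gene_id:
                lo = max(0, idx - window)
                flank = genes[lo:idx] + genes[idx + 1 : idx + 1 + window]
                return [x.gene_id for x in flank]
    raise KeyError(f"gene {gene_id!r} not found in genome")


def synteny_fraction(
    gene_x: str,
    gene_y: str,
    genome_x: list[Gene],
    genome_y: list[Gene],
    ortholog_map: dict[str, str],
    window: int,
) -> float:
    """Fraction of x's flanking genes whose orthologs flank y.

    Normalized by the achievable maximum (the smaller of the two truncated
    neighbourhood sizes); 0.0 when either neighbourhood is empty.
    """
    nb_x = neighborhood(genome_x, gene_x, window)
    nb_y = set(neighborhood(genome_y, gene_y, window))
    denom = min(len(nb_x), len(nb_y))
    if denom == 0:
        return 0.0
    mapped = {ortholog_map[g] for g in nb_x if g in ortholog_map}
    shared = len(mapped & nb_y)
    return min(1.0, shared / denom)


def synteny_score(
    family_id: str,
    copy_gene_ids: list[str],
    ortholog_gene_id: str,
    genome_x: list[Gene],
    genome_y: list[Gene],
    species_pair: tuple[str, str],
    ortholog_map: dict[str, str],
    window: int,
) -> list[SyntenyScore]:
    """Per-paralog-copy neighbourhood overlap against the singleton ortholog."""
    scores = []
    for gid in copy_gene_ids:
        frac = synteny_fraction(
            gid, ortholog_gene_id, genome_x, genome_y, ortholog_map, window
        )
        scores.append(
            SyntenyScore(
                family_id=family_id,
                species_pair=species_pair,
                window=window,
                shared_fraction=frac,
            )
        )
    return scores
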