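import itertools
import math

import numpy as np
import pytest

from lspscan.io_formats import Gene
from lspscan.verification import (
    DistanceTree,
    duplication_topology_test,
    neighbor_joining,
    neighborhood,
    protein_distance,
    synteny_fraction,
    tree_from_genes,
)


class TestProteinDistance:
    def test_identical_is_zero(self):
        assert protein_distance("ACDEFGHIKL", "ACDEFGHIKL") == 0.0

    def test_closed_form_ten_percent(self):
        # 1 difference in 10 aligned sites: d = -ln(0.9)
        a = "ACDEFGHIKL"
        b = "ACDEFGHIKW"
        assert protein_distance(a, b) == pytest.approx(-math.log(0.9))

    def test_monotone_in_p(self):
        base = "A" * 20
        dists = []
        for k in range(0, 15):
            other = "W" * k + "A" * (20 - k)
            dists.append(protein_distance(base, other))
        assert all(x < y for x, y in zip(dists, dists[1:]))

    def test_cap_applied_at_saturation(self):
        d = protein_distance("A" * 50, "W" * 50)
        assert d == pytest.approx(-math.log(0.05))


def _additive_distances(branch_lengths):
    """Distances for topology ((A,B),(C,D)) with lengths (a, b, c, d, internal)."""
    a, b, c, d, e = branch_lengths
    return {
        ("A", "B"): a + b,
        ("A", "C"): a + e + c,
        ("A", "D"): a + e + d,
        ("B", "C"): b + e + c,
        ("B", "D"): b + e + d,
        ("C", "D"): c + d,
    }


def _matrix(dists, labels):
    n = len(labels)
    m = np.zeros((n, n))
    for (x, y), v in dists.items():
        i, j = labels.index(x), labels.index(y)
        m[i, j] = m[j, i] = v
    return m


def _quartet_lstsq_residual(dists, labels, split):
    """Least-squares fit of 5 branch lengths for quartet split ((p,q),(r,s))."""
    (p, q), (r, s) = split
    order = [p, q, r, s]
    pairs = list(itertools.combinations(order, 2))
    # columns: t_p, t_q, t_r, t_s, internal
    design, target = [], []
    for x, y in pairs:
        row = [0.0] * 5
        row[order.index(x)] = 1.0
        row[order.index(y)] = 1.0
        same_side = {x, y} in ({p, q}, {r, s})
        if not same_side:
            row[4] = 1.0
        design.append(row)
        key = (x, y) if (x, y) in dists else (y, x)
        target.append(dists[key])
    sol, *_ = np.linalg.lstsq(np.array(design), np.array(target), rcond=None)
    residual = np.array(design) @ sol - np.array(target)
    return float(np.abs(residual).max())


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        m = _matrix({("A", "B"): 3.0, ("A", "C"): 4.0, ("B", "C"): 5.0}, labels)
        tree = neighbor_joining(m, labels)
        # three-point solution: a=1, b=2, c=3
        lengths = {}
        for node, lab in tree.leaf_labels.items():
            (nb, ln), = tree.adjacency[node]
            lengths[lab] = ln
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_quartet_recovery_with_lstsq_oracle(self):
        labels = ["A", "B", "C", "D"]
        dists = _additive_distances((1.0, 2.0, 3.0, 4.0, 1.5))
        tree = neighbor_joining(_matrix(dists, labels), labels)
        assert tree.splits() == {frozenset({"A", "B"})}
        # oracle: only the generating split fits the additive matrix exactly
        splits = [
            (("A", "B"), ("C", "D")),
            (("A", "C"), ("B", "D")),
            (("A", "D"), ("B", "C")),
        ]
        residuals = {s: _quartet_lstsq_residual(dists, labels, s) for s in splits}
        assert residuals[(("A", "B"), ("C", "D"))] == pytest.approx(0.0, abs=1e-9)
        for s in splits[1:]:
            assert residuals[s] > 0.1

    def test_taxon_order_permutation_invariance(self):
        rng = np.random.default_rng(8)
        labels = ["A", "B", "C", "D", "E"]
        # random additive tree: caterpillar (((A,B),C),D),E with random lengths
        t = rng.uniform(0.5, 2.0, size=8)
        d = {
            ("A", "B"): t[0] + t[1],
            ("A", "C"): t[0] + t[5] + t[2],
            ("B", "C"): t[1] + t[5] + t[2],
            ("A", "D"): t[0] + t[5] + t[6] + t[3],
            ("B", "D"): t[1] + t[5] + t[6] + t[3],
            ("C", "D"): t[2] + t[6] + t[3],
            ("A", "E"): t[0] + t[5] + t[6] + t[4],
            ("B", "E"): t[1] + t[5] + t[6] + t[4],
            ("C", "E"): t[2] + t[6] + t[4],
            ("D", "E"): t[3] + t[4],
        }
        reference = neighbor_joining(_matrix(d, labels), labels).splits()
        for perm in itertools.permutations(labels):
            perm = list(perm)
            assert neighbor_joining(_matrix(d, perm), perm).splits() == reference

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(m, ["A", "B", "C"])

    def test_nonzero_diagonal_rejected(self):
        m = np.array([[0.5, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            neighbor_joining(m, ["A", "B", "C"])

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(np.zeros((2, 2)), ["A", "B"])

    def test_newick_parses_with_dendropy(self):
        import dendropy

        labels = ["A", "B", "C", "D"]
        tree = neighbor_joining(
            _matrix(_additive_distances((1, 2, 3, 4, 1.5)), labels), labels
        )
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {lf.taxon.label for lf in t.leaf_node_iter()} == set(labels)


def _tree_from_shape(dists, labels):
    return neighbor_joining(_matrix(dists, labels), labels)


class TestDuplicationTopologyTest:
    def _ohnolog_tree(self):
        # (OG,((A1,B1),(A2,B2))): duplication before speciation
        d = {
            ("A1", "B1"): 0.2,
            ("A2", "B2"): 0.2,
            ("A1", "A2"): 0.8,
            ("A1", "B2"): 0.8,
            ("B1", "A2"): 0.8,
            ("B1", "B2"): 0.8,
            ("OG", "A1"): 1.5,
            ("OG", "B1"): 1.5,
            ("OG", "A2"): 1.5,
            ("OG", "B2"): 1.5,
        }
        return _tree_from_shape(d, ["A1", "B1", "A2", "B2", "OG"])

    def _independent_dup_tree(self):
        # (OG,((A1,A2),(B1,B2))): two recent species-specific duplications
        d = {
            ("A1", "A2"): 0.2,
            ("B1", "B2"): 0.2,
            ("A1", "B1"): 0.8,
            ("A1", "B2"): 0.8,
            ("A2", "B1"): 0.8,
            ("A2", "B2"): 0.8,
            ("OG", "A1"): 1.5,
            ("OG", "A2"): 1.5,
            ("OG", "B1"): 1.5,
            ("OG", "B2"): 1.5,
        }
        return _tree_from_shape(d, ["A1", "A2", "B1", "B2", "OG"])

    def test_textbook_ohnolog_topology_passes(self):
        assert duplication_topology_test(
            self._ohnolog_tree(), {"A1", "B1"}, {"A2", "B2"}, "OG"
        )

    def test_independent_duplication_fails(self):
        assert not duplication_topology_test(
            self._independent_dup_tree(), {"A1", "B1"}, {"A2", "B2"}, "OG"
        )

    def test_missing_outgroup_errors(self):
        with pytest.raises(ValueError, match="outgroup"):
            duplication_topology_test(self._ohnolog_tree(), {"A1"}, {"A2"}, "ZZ")

    def test_overlapping_copy_sets_error(self):
        with pytest.raises(ValueError, match="overlap"):
            duplication_topology_test(self._ohnolog_tree(), {"A1"}, {"A1"}, "OG")

    def test_singleton_leaves_are_transparent(self):
        # a singleton-species gene nested next to copy 1 must not break the test
        d = {
            ("A1", "S"): 0.2,
            ("B1", "S"): 0.2,
            ("A1", "B1"): 0.2,
            ("A2", "B2"): 0.2,
        }
        for x in ("A1", "B1", "S"):
            for y in ("A2", "B2"):
                d[(x, y)] = 0.8
        for x in ("A1", "B1", "S", "A2", "B2"):
            d[("OG", x)] = 1.5
        tree = _tree_from_shape(d, ["A1", "B1", "S", "A2", "B2", "OG"])
        assert duplication_topology_test(tree, {"A1", "B1"}, {"A2", "B2"}, "OG")


def _chrom_genome(species, ids, chrom="chr1"):
    return [
        Gene(g, species, chrom, 1 + i * 1000, 500 + i * 1000, "+", "ACDE")
        for i, g in enumerate(ids)
    ]


class TestSynteny:
    def test_neighborhood_window_and_truncation(self):
        genome = _chrom_genome("x", ["g1", "g2", "g3", "g4", "g5"])
        assert neighborhood(genome, "g3", 2) == ["g1", "g2", "g4", "g5"]
        assert neighborhood(genome, "g1", 2) == ["g2", "g3"]

    def test_identical_neighborhoods_score_one(self):
        gx = _chrom_genome("x", ["x1", "x2", "x3", "x4", "x5"])
        gy = _chrom_genome("y", ["y1", "y2", "y3", "y4", "y5"])
        omap = {f"x{i}": f"y{i}" for i in range(1, 6)}
        assert synteny_fraction("x3", "y3", gx, gy, omap, 2) == 1.0

    def test_disjoint_neighborhoods_score_zero(self):
        gx = _chrom_genome("x", ["x1", "x2", "x3", "x4", "x5"])
        gy = _chrom_genome("y", ["y1", "y2", "y3", "y4", "y5"])
        omap = {f"x{i}": f"z{i}" for i in range(1, 6)}  # orthologs elsewhere
        assert synteny_fraction("x3", "y3", gx, gy, omap, 2) == 0.0

    def test_half_shared_hand_enumeration(self):
        # 4 achievable flanking genes, exactly 2 shared -> 0.5
        gx = _chrom_genome("x", ["x1", "x2", "x3", "x4", "x5"])
        gy = _chrom_genome("y", ["y1", "y2", "y3", "y4", "y5"])
        omap = {"x1": "y1", "x2": "z9", "x4": "y4", "x5": "z8"}
        assert synteny_fraction("x3", "y3", gx, gy, omap, 2) == 0.5

    def test_symmetry_under_bijective_map(self):
        gx = _chrom_genome("x", ["x1", "x2", "x3", "x4", "x5", "x6"])
        gy = _chrom_genome("y", ["y2", "y1", "y3", "y5", "y4", "y6"])
        omap = {f"x{i}": f"y{i}" for i in range(1, 7)}
        inv = {v: k for k, v in omap.items()}
        for w in (1, 2, 3):
            assert synteny_fraction("x3", "y3", gx, gy, omap, w) == pytest.approx(
                synteny_fraction("y3", "x3", gy, gx, inv, w)
            )

    def test_missing_gene_errors(self):
        gx = _chrom_genome("x", ["x1"])
        with pytest.raises(KeyError):
            neighborhood(gx, "nope", 2)


class TestTreeFromGenes:
    def test_distance_tree_over_genes(self):
        genes = [
            Gene("a", "s1", "chr1", 1, 9, "+", "ACDEFGHIKL"),
            Gene("b", "s2", "chr1", 1, 9, "+", "ACDEFGHIKW"),
            Gene("c", "s3", "chr1", 1, 9, "+", "ACDEFGHYKW"),
            Gene("d", "s4", "chr1", 1, 9, "+", "PPPPPGHYKW"),
        ]
        tree = tree_from_genes(genes)
        assert tree.leaves() == {"a", "b", "c", "d"}
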