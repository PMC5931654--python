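"""Similarity coefficients, UPGMA clustering, and Newick serialization."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from p8barcode.cluster import (
    Dendrogram,
    SimilarityMatrix,
    cophenetic_distances,
    similarity,
    similarity_range,
    upgma,
    write_newick,
)
from p8barcode.matrix import BinaryMatrix, build_matrix
from p8barcode.scan import SiteProfile


def _profile(name, length=100, **sites):
    return SiteProfile(taxon_name=name, accession=name, p8_length=length,
                       sites={k: tuple(v) for k, v in sites.items()})


def _bm(rows, taxa=None):
    rows = np.asarray(rows, dtype=np.uint8)
    taxa = taxa or tuple(f"t{i}" for i in range(rows.shape[0]))
    features = tuple(("E", j + 1) for j in range(rows.shape[1]))
    return BinaryMatrix(taxa=tuple(taxa), features=features, cells=rows)


class TestSimilarity:
    @pytest.mark.parametrize("coeff", ["simple_matching", "jaccard", "dice"])
    def test_identical_rows_similarity_one(self, coeff):
        bm = _bm([[1, 0, 1], [1, 0, 1]])
        assert similarity(bm, coeff).values[0, 1] == 1.0

    def test_worked_three_feature_example(self):
        bm = _bm([[1, 0, 1], [1, 1, 0]])
        assert similarity(bm, "simple_matching").values[0, 1] == pytest.approx(1 / 3)
        assert similarity(bm, "jaccard").values[0, 1] == pytest.approx(1 / 3)
        assert similarity(bm, "dice").values[0, 1] == pytest.approx(1 / 2)

    def test_fewer_than_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            similarity(_bm([[1, 0]]))

    def test_allzero_pair_defined_as_identical(self):
        bm = _bm([[0, 0], [0, 0], [1, 1]])
        for coeff in ("simple_matching", "jaccard", "dice"):
            v = similarity(bm, coeff).values
            assert v[0, 1] == 1.0
            if coeff in ("jaccard", "dice"):
                assert v[0, 2] == 0.0

    def test_simple_matching_invariant_under_feature_permutation(self):
        rng = np.random.default_rng(0)
        cells = rng.integers(0, 2, size=(6, 12))
        bm = _bm(cells)
        perm = rng.permutation(12)
        bm_p = _bm(cells[:, perm])
        assert np.allclose(
            similarity(bm).values, similarity(bm_p).values
        )

    def test_matrix_is_valid_similarity(self, table1):
        bm = build_matrix(table1, ["AgsI", "ApoI", "TspDTI", "VspI"])
        sim = similarity(bm)
        v = sim.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert v.min() >= 0 and v.max() <= 1


class TestSimilarityRange:
    def test_all_identical(self):
        sim = similarity(_bm([[1, 0], [1, 0], [1, 0]]))
        assert similarity_range(sim) == (1.0, 1.0)

    def test_two_taxon_third(self):
        sim = similarity(_bm([[1, 0, 1], [1, 1, 0]]))
        lo, hi = similarity_range(sim)
        assert lo == pytest.approx(1 / 3) and hi == pytest.approx(1 / 3)

    def test_matches_brute_force_extrema(self):
        rng = np.random.default_rng(3)
        cells = rng.integers(0, 2, size=(10, 20))
        sim = similarity(_bm(cells))
        pairs = [
            sim.values[i, j]
            for i, j in itertools.combinations(range(10), 2)
        ]
        assert similarity_range(sim) == (min(pairs), max(pairs))


def naive_upgma_cophenetic(dist):
    """Independent O(n^3) agglomeration: cluster distance recomputed each
    step as the unweighted mean of original leaf-pair distances."""
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                mi, mj = sorted((min(clusters[a]), min(clusters[b])))
                cand = (d, mi, mj, a, b)
                if best is None or d < best[0] - 1e-9 or (
                    d <= best[0] + 1e-9 and (mi, mj) < best[1:3]
                ):
                    best = cand
        d, _, _, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return coph


def _random_similarity(rng, n, binary=False):
    if binary:
        cells = rng.integers(0, 2, size=(n, rng.integers(3, 10)))
        return similarity(_bm(cells))
    v = rng.uniform(0, 1, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    taxa = tuple(f"t{i}" for i in range(n))
    return SimilarityMatrix(taxa=taxa, values=v, coefficient_name="simple_matching")


class TestUpgma:
    def test_two_identical_taxa_join_at_zero(self):
        sim = similarity(_bm([[1, 0], [1, 0]]))
        tree = upgma(sim)
        assert tree.root.join_height == 0.0
        assert sorted(tree.leaf_names()) == ["t0", "t1"]

    def test_three_taxon_hand_computed_heights(self):
        # d(AB)=0.1, d(AC)=d(BC)=0.4: AB joins at 0.1, C joins at 0.4
        v = 1 - np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.4], [0.4, 0.4, 0.0]])
        sim = SimilarityMatrix(taxa=("A", "B", "C"), values=v,
                               coefficient_name="simple_matching")
        tree = upgma(sim)
        assert tree.root.join_height == pytest.approx(0.4)
        inner = [c for c in tree.root.children if not c.is_leaf]
        assert len(inner) == 1
        assert inner[0].join_height == pytest.approx(0.1)
        assert sorted(l.taxon for l in inner[0].leaves()) == ["A", "B"]

    def test_leaf_count_equals_taxa_count(self, table1):
        bm = build_matrix(table1, ["AgsI"])
        tree = upgma(similarity(bm))
        assert sorted(tree.leaf_names()) == sorted(bm.taxa)

    def test_ultrametric_heights_nondecreasing_to_root(self):
        rng = np.random.default_rng(11)
        sim = _random_similarity(rng, 12)
        tree = upgma(sim)

        def check(node):
            if node.is_leaf:
                return
            for child in node.children:
                assert child.join_height <= node.join_height + 1e-12
                check(child)

        check(tree.root)

    def test_cophenetic_equals_merge_heights(self):
        rng = np.random.default_rng(12)
        sim = _random_similarity(rng, 8, binary=True)
        tree = upgma(sim)
        taxa, coph = cophenetic_distances(tree)
        # every leaf pair coalesces exactly once, at its merge distance
        assert coph.shape == (8, 8)
        assert (coph >= 0).all() and np.allclose(coph, coph.T)
        assert coph.max() == pytest.approx(tree.root.join_height)

    def test_agrees_with_naive_reference_on_small_matrices(self):
        rng = np.random.default_rng(99)
        for trial in range(200):
            n = int(rng.integers(2, 7))
            sim = _random_similarity(rng, n, binary=bool(trial % 2))
            tree = upgma(sim)
            _, coph = cophenetic_distances(tree)
            ref = naive_upgma_cophenetic(1.0 - sim.values)
            assert np.allclose(coph, ref), f"trial {trial}, n={n}"

    def test_agrees_with_scipy_average_linkage(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            sim = _random_similarity(rng, n)  # continuous: ties negligible
            dist = 1.0 - sim.values
            _, coph = cophenetic_distances(upgma(sim))
            z = linkage(squareform(dist, checks=False), method="average")
            ref = squareform(cophenet(z))
            assert np.allclose(coph, ref)

    def test_deterministic_under_ties(self):
        # four taxa, all pairwise distances equal: repeated runs identical
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        sim = SimilarityMatrix(taxa=("a", "b", "c", "d"), values=v,
                               coefficient_name="simple_matching")
        first = write_newick(upgma(sim))
        assert all(write_newick(upgma(sim)) == first for _ in range(5))


class TestNewick:
    def test_two_leaf_midpoint_split(self):
        v = np.array([[1.0, 0.8], [0.8, 1.0]])
        sim = SimilarityMatrix(taxa=("A", "B"), values=v,
                               coefficient_name="simple_matching")
        assert write_newick(upgma(sim)) == "(A:0.1,B:0.1);"

    def test_label_with_spaces_quoted(self):
        v = np.array([[1.0, 0.8], [0.8, 1.0]])
        sim = SimilarityMatrix(taxa=("Aerides rosea", "B"), values=v,
                               coefficient_name="simple_matching")
        assert "'Aerides rosea'" in write_newick(upgma(sim))

    def test_round_trip_preserves_topology_and_heights(self):
        rng = np.random.default_rng(5)
        sim = _random_similarity(rng, 7)
        tree = upgma(sim)
        taxa, coph = cophenetic_distances(tree)
        parsed = dendropy.Tree.get(data=write_newick(tree), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        labels = {t.label: t for t in parsed.taxon_namespace}
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                d = pdm.patristic_distance(labels[taxa[i]], labels[taxa[j]])
                assert d == pytest.approx(coph[i, j], abs=1e-9)

    def test_fixture_tree_parses_with_98_leaves(self, table1):
        bm = build_matrix(table1, ["VspI"])
        newick = write_newick(upgma(similarity(bm)))
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert len(parsed.leaf_nodes()) == 98
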