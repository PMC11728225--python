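"""Genetic distances, UPGMA trees and PCA."""

import math

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from ssrkit import (
    DistanceMatrix,
    GenotypeMatrix,
    allele_frequencies,
    nei_distance_matrix,
    nei_standard_distance,
    pca,
    shared_allele_distance,
    simulate_genotypes,
    upgma,
)
from ssrkit.clustering import NEI_DISTANCE_CAP


def test_nei_identical_populations_zero():
    f = {"L1": {100: 0.5, 103: 0.5}, "L2": {200: 1.0}}
    assert nei_standard_distance(f, f) == pytest.approx(0.0)


def test_nei_disjoint_support_capped():
    fA = {"L1": {100: 1.0}}
    fB = {"L1": {103: 1.0}}
    assert nei_standard_distance(fA, fB) == NEI_DISTANCE_CAP


def test_nei_hand_computed_value():
    fA = {"L1": {100: 0.5, 103: 0.5}}
    fB = {"L1": {100: 0.9, 103: 0.1}}
    expected = -math.log(0.5 / math.sqrt(0.5 * 0.82))
    assert nei_standard_distance(fA, fB) == pytest.approx(expected)
    assert expected == pytest.approx(0.247, abs=5e-4)


def test_nei_symmetry_on_random_frequencies():
    rng = np.random.default_rng(2)
    for _ in range(20):
        fA = {"L1": dict(zip([100, 103, 106], rng.dirichlet([1, 1, 1])))}
        fB = {"L1": dict(zip([100, 103, 106], rng.dirichlet([1, 1, 1])))}
        assert nei_standard_distance(fA, fB) == pytest.approx(
            nei_standard_distance(fB, fA)
        )


def test_nei_population_matrix(two_pool_sim):
    gm, _ = two_pool_sim
    freqs = allele_frequencies(gm, by_population=True)
    dm = nei_distance_matrix(freqs.by_population)
    assert dm.labels == ["pop1", "pop2"]
    assert dm.values[0, 1] > 0


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([(191, 203)], [(191, 203)], 0.0),
        ([(191, 191)], [(203, 203)], 1.0),
        ([(191, 203)], [(191, 191)], 0.5),
        ([(191, 203), None], [(191, 203), (100, 100)], 0.0),  # missing locus skipped
    ],
)
def test_shared_allele_distance(a, b, expected):
    assert shared_allele_distance(a, b) == pytest.approx(expected)


def test_shared_allele_distance_undefined_without_common_loci():
    assert shared_allele_distance([None], [(100, 100)]) is None


def test_upgma_three_leaves_hand_tree():
    dm = DistanceMatrix(
        labels=["A", "B", "C"],
        values=np.array([[0, 2, 8], [2, 0, 8], [8, 8, 0]], dtype=float),
    )
    assert upgma(dm).to_newick() == "((A:1,B:1):3,C:4);"


def test_upgma_two_leaves_cherry():
    dm = DistanceMatrix(labels=["X", "Y"], values=np.array([[0, 3.0], [3.0, 0]]))
    root = upgma(dm)
    assert root.height == 1.5
    assert root.to_newick() == "(X:1.5,Y:1.5);"


def test_upgma_matches_scipy_average_linkage():
    rng = np.random.default_rng(8)
    for _ in range(5):
        n = 8
        X = rng.random((n, 4))
        D = squareform(np.round(squareform(
            np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
        ), 6))
        labels = [f"t{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(labels=labels, values=D))
        coph_ours = tree.cophenetic_matrix(labels)
        Z = average(squareform(D))
        coph_scipy = squareform(cophenet(Z))
        assert np.allclose(coph_ours, coph_scipy, atol=1e-9)


def test_upgma_recovers_ultrametric_input():
    """UPGMA applied to cophenetic distances of an ultrametric tree returns
    the same tree (same cophenetic matrix)."""
    dm = DistanceMatrix(
        labels=list("ABCDE"),
        values=np.array(
            [
                [0, 2, 6, 6, 10],
                [2, 0, 6, 6, 10],
                [6, 6, 0, 4, 10],
                [6, 6, 4, 0, 10],
                [10, 10, 10, 10, 0],
            ],
            dtype=float,
        ),
    )
    tree = upgma(dm)
    assert np.allclose(tree.cophenetic_matrix(dm.labels), dm.values)


def test_newick_round_trip_preserves_topology_and_heights():
    rng = np.random.default_rng(21)
    n = 6
    X = rng.random((n, 3))
    D = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    np.fill_diagonal(D, 0)
    labels = [f"t{i}" for i in range(n)]
    tree = upgma(DistanceMatrix(labels=labels, values=D))
    dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    pdm = dt.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in dt.taxon_namespace}
    coph = tree.cophenetic_matrix(labels)
    for i in range(n):
        for j in range(i + 1, n):
            assert pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]]) == pytest.approx(
                coph[i, j], abs=1e-6
            )


def test_upgma_rejects_nan():
    vals = np.zeros((2, 2))
    dm = DistanceMatrix(labels=["a", "b"], values=vals)
    dm.values[0, 1] = dm.values[1, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        upgma(dm)


def test_distance_matrix_tsv_round_trip(tmp_path):
    dm = DistanceMatrix(
        labels=["A", "B"], values=np.array([[0, 0.25], [0.25, 0]])
    )
    back = DistanceMatrix.from_tsv(dm.to_tsv(tmp_path / "d.tsv"))
    assert back.labels == dm.labels
    assert np.allclose(back.values, dm.values)


# -- PCA ----------------------------------------------------------------------


def test_pca_fraction_properties(two_pool_sim):
    gm, _ = two_pool_sim
    _, frac = pca(gm)
    assert np.all(frac[:-1] >= frac[1:] - 1e-12)
    assert 0 <= frac.sum() <= 1 + 1e-9


def test_pca_separates_divergent_pools(two_pool_sim):
    gm, truth = two_pool_sim
    coords, _ = pca(gm)
    pc1 = coords[:, 0]
    group = (truth.pool_of_origin == 1).astype(float)
    r = np.corrcoef(pc1, group)[0, 1]
    assert abs(r) > 0.9


def test_pca_duplicated_accession_identical_coordinates():
    gm, _ = simulate_genotypes(K=1, n_loci=8, alleles_per_locus=4, n_per_pop=[10], seed=4)
    dup = GenotypeMatrix(
        accessions=gm.accessions + [("dup", "p1")],
        loci=gm.loci,
        calls=gm.calls + [list(gm.calls[0])],
    )
    coords, _ = pca(dup)
    assert np.allclose(coords[0], coords[-1], atol=1e-9)


def test_pca_rejects_monomorphic_matrix():
    gm = GenotypeMatrix(
        accessions=[("a", "p"), ("b", "p")],
        loci=["L1", "L2"],
        calls=[[(100, 100), (200, 200)], [(100, 100), (200, 200)]],
    )
    with pytest.raises(ValueError, match="polymorphic"):
        pca(gm)
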