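"""Distance matrices, UPGMA agglomeration, Newick export, family recovery."""

import io

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from tvcurve import (
    DistanceMatrix,
    SimilarityConfig,
    ValidationError,
    encode_tvcurve,
    generate_families,
    multiscale_similarity,
    pairwise_distance_matrix,
    planted_family_labels,
    similarity_to_distance,
    to_newick,
    upgma,
)

from .conftest import random_record
from .oracles import oracle_upgma_merges


def random_ultrametric(rng, n):
    """Random ultrametric matrix built from a random merge history."""
    labels = [f"t{i}" for i in range(n)]
    clusters = [[lab] for lab in labels]
    D = np.zeros((n, n))
    index = {lab: i for i, lab in enumerate(labels)}
    height = 0.0
    while len(clusters) > 1:
        height += float(rng.uniform(0.1, 1.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                D[index[a], index[b]] = D[index[b], index[a]] = height
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return labels, D


class TestDistanceMatrix:
    def test_symmetry_zero_diagonal_and_consistency(self, backend, rng):
        records = [random_record(rng, 20, f"r{i}") for i in range(4)]
        cfg = SimilarityConfig()
        mat = pairwise_distance_matrix(records, backend, cfg)
        assert np.array_equal(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0)
        curves = [encode_tvcurve(r) for r in records]
        for i in range(4):
            for j in range(i + 1, 4):
                want = similarity_to_distance(
                    multiscale_similarity(curves[i], curves[j], cfg)
                )
                assert mat.values[i, j] == want

    def test_duplicated_record_has_zero_distance(self, backend, rng):
        rec = random_record(rng, 25, "orig")
        twin = rec.with_structure(rec.structure)
        records = [rec, twin.__class__(id="copy", sequence=rec.sequence,
                                       structure=rec.structure),
                   random_record(rng, 25, "other")]
        mat = pairwise_distance_matrix(records, backend)
        assert mat.values[0, 1] == 0.0

    def test_fewer_than_three_records_rejected(self, backend, rng):
        records = [random_record(rng, 20, f"r{i}") for i in range(2)]
        with pytest.raises(ValidationError, match="at least three"):
            pairwise_distance_matrix(records, backend)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0]]))
        with pytest.raises(ValidationError, match="diagonal"):
            DistanceMatrix(labels=["a", "b"], values=np.array([[1.0, 1], [1, 0]]))


class TestUpgma:
    def test_two_leaves_split_the_distance(self):
        mat = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 0.4], [0.4, 0]]))
        tree = upgma(mat)
        assert tree.root.height == pytest.approx(0.2)
        assert to_newick(tree) == "(A:0.200000,B:0.200000);"

    def test_ultrametric_input_recovered_exactly(self, rng):
        """UPGMA is exact on ultrametric matrices: cophenetic == input."""
        for _ in range(50):
            n = int(rng.integers(3, 11))
            labels, D = random_ultrametric(rng, n)
            tree = upgma(DistanceMatrix(labels=labels, values=D))
            coph = tree.cophenetic_matrix(labels)
            assert np.max(np.abs(coph - D)) <= 1e-12

    def test_merge_heights_monotone(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            tree = upgma(DistanceMatrix(labels=[f"x{i}" for i in range(n)], values=D))
            heights = [h for _, _, h in tree.merges]
            assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_matches_brute_force_reaveraging_oracle(self, rng):
        """Size-weighted averaging must equal re-averaging raw leaf entries."""
        for _ in range(25):
            n = int(rng.integers(4, 9))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            labels = [f"x{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels=labels, values=D))
            want = oracle_upgma_merges(labels, D.tolist())
            assert len(tree.merges) == len(want)
            for (la, lb, h), (wa, wb, wh) in zip(tree.merges, want):
                assert {frozenset(la), frozenset(lb)} == {
                    frozenset(wa), frozenset(wb)
                }
                assert h == pytest.approx(wh, abs=1e-12)

    def test_cophenetic_agrees_with_scipy_average_linkage(self, rng):
        """Independent cross-check against SciPy's UPGMA (average linkage)."""
        for _ in range(10):
            n = int(rng.integers(4, 10))
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            labels = [f"x{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(labels=labels, values=D))
            coph_mine = tree.cophenetic_matrix(labels)
            Z = average(squareform(D, checks=False))
            coph_scipy = squareform(cophenet(Z))
            assert np.allclose(coph_mine, coph_scipy, atol=1e-10)

    def test_tie_break_on_label_pairs(self):
        # all distances equal: first merge must be the lexicographically
        # smallest label pair
        D = np.full((3, 3), 0.5)
        np.fill_diagonal(D, 0)
        tree = upgma(DistanceMatrix(labels=["c", "a", "b"], values=D))
        assert tree.merges[0][:2] == (("a",), ("b",))


class TestNewick:
    def test_roundtrip_through_dendropy(self, rng):
        n = 6
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"leaf{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(labels=labels, values=D))
        newick = to_newick(tree, precision=9)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(labels)
        pdm = parsed.phylogenetic_distance_matrix()
        coph = tree.cophenetic_matrix(labels)
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                got = pdm.patristic_distance(taxa[a], taxa[labels[j]])
                assert got == pytest.approx(coph[i, j], abs=1e-6)

    def test_labels_with_spaces_quoted(self):
        D = np.full((2, 2), 0.2)
        np.fill_diagonal(D, 0)
        tree = upgma(DistanceMatrix(labels=["leaf one", "b"], values=D))
        assert "'leaf one'" in to_newick(tree)


class TestFamilyRecovery:
    def test_planted_families_recovered(self, backend):
        """Four planted families of 20 members each must map onto the four
        clusters obtained by cutting the UPGMA tree at its three deepest
        merges (adjusted Rand >= 0.9)."""
        records = generate_families(seed=1)
        truth = planted_family_labels(records)
        mat = pairwise_distance_matrix(records, backend)
        tree = upgma(mat)
        assignment = tree.cut(4)
        predicted = [assignment[r.id] for r in records]
        ari = adjusted_rand_score(truth, predicted)
        assert ari >= 0.9
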