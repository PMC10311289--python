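import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pockmol.fixtures import make_pocket_fixture, pocket_to_pdb
from pockmol.pocket_graphs import (
    Atom,
    GraphConfig,
    PocketParseError,
    Residue,
    atom_feature_vector,
    atom_graph_config,
    build_graph,
    embed_graph_nodes,
    laplacian_positional_features,
    normalized_laplacian,
    parse_pocket,
    pocket_from_json,
    pocket_to_json,
    rbf_centers,
    rbf_encode,
    residue_centroid,
    residue_graph_config,
    symmetrized_adjacency,
)

ONE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""


def _atom(element="C", coords=(0.0, 0.0, 0.0), mass=12.011, backbone=False):
    return Atom(element=element, coords=coords, mass=mass, is_backbone=backbone)


class TestParsePocket:
    def test_one_residue_four_atoms(self):
        pocket = parse_pocket(ONE_RESIDUE_PDB)
        assert pocket.n_residues == 1
        assert pocket.n_atoms == 4
        assert all(a.is_backbone for a in pocket.residues[0].atoms)

    def test_unsupported_element_excluded_with_warning(self):
        text = ONE_RESIDUE_PDB.replace(
            "ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O",
            "ATOM      4 SE   ALA A   1       1.251   2.390   0.000  1.00  0.00          SE",
        )
        with pytest.warns(UserWarning, match="[Ss]e"):
            pocket = parse_pocket(text)
        assert pocket.n_atoms == 3

    def test_no_atom_records_is_structured_error(self):
        with pytest.raises(PocketParseError):
            parse_pocket("REMARK nothing here\nEND\n")

    def test_fixture_roundtrip_through_writer(self):
        pocket, pdb_text = make_pocket_fixture(seed=4, n_residues=5)
        assert parse_pocket(pdb_text) == pocket

    def test_json_roundtrip(self):
        pocket, _ = make_pocket_fixture(seed=4, n_residues=3)
        assert pocket_from_json(pocket_to_json(pocket)) == pocket


class TestResidueCentroid:
    def test_equal_masses_symmetric(self):
        res = Residue("GLY", atoms=(
            _atom(coords=(0.0, 0.0, 0.0)),
            _atom(coords=(2.0, 0.0, 0.0)),
        ))
        np.testing.assert_allclose(residue_centroid(res), [1.0, 0.0, 0.0])

    def test_mass_weighted(self):
        # masses 12 and 1 at x=0 and x=13 -> weighted mean x = 13/13 = 1
        res = Residue("GLY", atoms=(
            _atom("C", (0.0, 0.0, 0.0), 12.0),
            _atom("H", (13.0, 0.0, 0.0), 1.0),
        ))
        np.testing.assert_allclose(residue_centroid(res), [1.0, 0.0, 0.0])

    def test_single_atom_identity(self):
        res = Residue("GLY", atoms=(_atom(coords=(5.0, 5.0, 5.0)),))
        np.testing.assert_allclose(residue_centroid(res), [5.0, 5.0, 5.0])


class TestBuildGraph:
    def test_nearest_by_inspection(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        g = build_graph(pts, np.eye(3), k_neighbors=1)
        assert g.neighborhoods[:, 0].tolist() == [1, 0, 1]

    def test_k_clamped_to_n_minus_1(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        g = build_graph(pts, np.eye(2), k_neighbors=48)
        assert g.k == 1

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            build_graph(np.zeros((1, 3)), np.eye(1), 1)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            pts = rng.normal(size=(n, 3)) * 10
            k = int(rng.integers(1, 8))
            g = build_graph(pts, np.eye(n), k)
            for i in range(n):
                dists = np.linalg.norm(pts - pts[i], axis=1)
                expected = sorted(
                    (d, j) for j, d in enumerate(dists) if j != i
                )[: min(k, n - 1)]
                assert g.neighborhoods[i].tolist() == [j for _, j in expected]
                np.testing.assert_allclose(
                    g.edge_distances[i], [d for d, _ in expected])

    def test_distances_are_euclidean(self, rng):
        pts = rng.normal(size=(10, 3))
        g = build_graph(pts, np.eye(10), 3)
        for i in range(10):
            for slot, j in enumerate(g.neighborhoods[i]):
                assert g.edge_distances[i, slot] == pytest.approx(
                    np.linalg.norm(pts[i] - pts[j]))


class TestAtomFeatures:
    def test_backbone_carbon(self):
        vec = atom_feature_vector(_atom("C", backbone=True))
        assert vec.tolist() == [0, 1, 0, 0, 0, 0, 1]

    def test_side_chain_oxygen(self):
        vec = atom_feature_vector(_atom("O", mass=15.999))
        assert vec.tolist() == [0, 0, 0, 1, 0, 0, 0]

    @pytest.mark.parametrize("element", ["H", "C", "N", "O", "S", "P"])
    def test_one_hot_sums_to_one(self, element):
        vec = atom_feature_vector(_atom(element, mass=1.0))
        assert vec[:6].sum() == 1


class TestRbfEncode:
    def test_center_hits_one(self):
        cfg = residue_graph_config()
        centers, _ = rbf_centers(cfg)
        out = rbf_encode(centers[10], cfg)
        assert out[10] == pytest.approx(1.0)

    def test_one_width_away(self):
        cfg = residue_graph_config()
        centers, width = rbf_centers(cfg)
        out = rbf_encode(centers[7] + width, cfg)
        assert out[7] == pytest.approx(np.exp(-0.5))

    def test_default_length_64(self):
        assert rbf_encode(3.0, residue_graph_config()).shape == (64,)
        assert rbf_encode(3.0, atom_graph_config()).shape == (64,)

    def test_strictly_decreasing_away_from_center(self):
        cfg = residue_graph_config()
        centers, _ = rbf_centers(cfg)
        ds = centers[20] + np.linspace(0, 5, 30)
        vals = np.array([rbf_encode(d, cfg)[20] for d in ds])
        assert np.all(np.diff(vals) < 0)

    def test_components_nonnegative_and_positive_near_center(self, rng):
        # exact zeros only from float underflow far from a center
        cfg = atom_graph_config()
        d = rng.uniform(0, cfg.rbf_max, size=17)
        out = rbf_encode(d, cfg)
        assert np.all(out >= 0)
        centers, _ = rbf_centers(cfg)
        nearest = np.abs(d[:, None] - centers).argmin(axis=1)
        assert np.all(out[np.arange(17), nearest] > 0)


class TestLaplacian:
    def test_eigenvalue_range_random_graphs(self, rng):
        cfg = residue_graph_config(n_eigenvectors=4)
        for _ in range(20):
            n = int(rng.integers(4, 25))
            pts = rng.normal(size=(n, 3)) * 8
            g = build_graph(pts, np.eye(n), k_neighbors=3)
            pos = laplacian_positional_features(g, cfg)
            assert pos.eigenvalues[0] == pytest.approx(0.0, abs=1e-10)
            assert np.all(pos.eigenvalues >= -1e-10)
            assert np.all(pos.eigenvalues <= 2.0 + 1e-10)

    def test_complete_graph_closed_form(self):
        # complete unit-weight graph on n nodes: nonzero eigenvalues n/(n-1)
        n = 4
        A = np.ones((n, n)) - np.eye(n)
        L = normalized_laplacian(A)
        vals = np.linalg.eigvalsh(L)
        np.testing.assert_allclose(vals[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(vals[1:], n / (n - 1), atol=1e-12)

    def test_two_node_graph_eigenvalues(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        g = build_graph(pts, np.eye(2), 1)
        pos = laplacian_positional_features(g, residue_graph_config())
        np.testing.assert_allclose(pos.eigenvalues, [0.0, 2.0], atol=1e-12)

    def test_isolated_node_errors(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        with pytest.raises(ValueError, match="isolated"):
            normalized_laplacian(A)

    def test_padding_when_few_nodes(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        g = build_graph(pts, np.eye(2), 1)
        pos = laplacian_positional_features(g, residue_graph_config(n_eigenvectors=8))
        assert pos.vectors.shape == (2, 8)
        assert np.all(pos.vectors[:, 1:] == 0)  # only one nontrivial eigenvector

    def test_retained_vectors_orthonormal(self, rng):
        pts = rng.normal(size=(20, 3)) * 5
        g = build_graph(pts, np.eye(20), 4)
        pos = laplacian_positional_features(g, residue_graph_config(n_eigenvectors=6))
        gram = pos.vectors.T @ pos.vectors
        np.testing.assert_allclose(gram, np.eye(6), atol=1e-8)

    def test_permutation_equivariance(self, rng):
        pts = rng.normal(size=(12, 3)) * 5
        cfg = residue_graph_config(n_eigenvectors=3)
        g = build_graph(pts, np.eye(12), 4)
        pos = laplacian_positional_features(g, cfg)
        perm = rng.permutation(12)
        g2 = build_graph(pts[perm], np.eye(12), 4)
        pos2 = laplacian_positional_features(g2, cfg)
        np.testing.assert_allclose(pos2.vectors, pos.vectors[perm], atol=1e-8)

    def test_sign_flip_augmentation(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        g = build_graph(pts, np.eye(10), 3)
        cfg = residue_graph_config(n_eigenvectors=4)
        base = laplacian_positional_features(g, cfg)
        flipped = laplacian_positional_features(
            g, cfg, sign_flip_rng=np.random.default_rng(0))
        signs = []
        for j in range(4):
            ratio = flipped.vectors[:, j] / np.where(
                base.vectors[:, j] == 0, 1.0, base.vectors[:, j])
            signs.append(np.sign(ratio[np.abs(base.vectors[:, j]) > 1e-9][0]))
            np.testing.assert_allclose(np.abs(flipped.vectors[:, j]),
                                       np.abs(base.vectors[:, j]), atol=1e-12)
        assert set(signs) <= {-1.0, 1.0}

    def test_symmetrized_adjacency_is_symmetric(self, rng):
        pts = rng.normal(size=(15, 3)) * 6
        g = build_graph(pts, np.eye(15), 3)
        A = symmetrized_adjacency(g, sigma=5.0)
        np.testing.assert_allclose(A, A.T)
        assert np.all(np.diag(A) == 0)


class TestEmbedGraphNodes:
    def _graph_and_pos(self, rng, n=9):
        pts = rng.normal(size=(n, 3)) * 4
        g = build_graph(pts, rng.normal(size=(n, 5)), 3)
        pos = laplacian_positional_features(
            g, residue_graph_config(n_eigenvectors=4))
        return g, pos

    def test_zero_positional_weights(self, rng):
        g, pos = self._graph_and_pos(rng)
        w0 = rng.normal(size=(5, 7))
        out = embed_graph_nodes(g, pos, w0, np.zeros((4, 7)))
        np.testing.assert_allclose(out, g.node_features @ w0)

    def test_zero_node_weights(self, rng):
        g, pos = self._graph_and_pos(rng)
        wp = rng.normal(size=(4, 7))
        out = embed_graph_nodes(g, pos, np.zeros((5, 7)), wp)
        np.testing.assert_allclose(out, pos.vectors @ wp)

    def test_matches_two_term_oracle(self, rng):
        g, pos = self._graph_and_pos(rng)
        w0, wp = rng.normal(size=(5, 7)), rng.normal(size=(4, 7))
        out = embed_graph_nodes(g, pos, w0, wp)
        np.testing.assert_allclose(
            out, g.node_features @ w0 + pos.vectors @ wp, atol=1e-12)

    def test_superposition(self, rng):
        g, pos = self._graph_and_pos(rng)
        w0a, w0b = rng.normal(size=(5, 7)), rng.normal(size=(5, 7))
        wp = rng.normal(size=(4, 7))
        lhs = embed_graph_nodes(g, pos, w0a + w0b, wp * 2)
        rhs = (embed_graph_nodes(g, pos, w0a, wp)
               + embed_graph_nodes(g, pos, w0b, wp))
        np.testing.assert_allclose(lhs, rhs, atol=1e-6)

    def test_shape_mismatch_errors(self, rng):
        g, pos = self._graph_and_pos(rng)
        with pytest.raises(ValueError):
            embed_graph_nodes(g, pos, np.zeros((4, 7)), np.zeros((4, 7)))


class TestGraphArrayContainer:
    def test_roundtrip(self, rng, tmp_path):
        from pockmol.pocket_graphs import load_graph_arrays, save_graph_arrays

        g = build_graph(rng.normal(size=(8, 3)) * 5, rng.normal(size=(8, 7)), 3)
        pos = laplacian_positional_features(
            g, residue_graph_config(n_eigenvectors=4))
        path = tmp_path / "graph.npz"
        save_graph_arrays(path, g, pos)
        g2, pos2 = load_graph_arrays(path)
        np.testing.assert_array_equal(g2.node_features, g.node_features)
        np.testing.assert_array_equal(g2.neighborhoods, g.neighborhoods)
        np.testing.assert_array_equal(g2.edge_distances, g.edge_distances)
        np.testing.assert_array_equal(pos2.vectors, pos.vectors)


class TestGraphConfig:
    def test_invalid_rbf_range(self):
        with pytest.raises(ValueError):
            GraphConfig(rbf_min=5.0, rbf_max=5.0)

    def test_defaults_follow_runs(self):
        assert residue_graph_config().k_neighbors == 30
        assert atom_graph_config().k_neighbors == 48
        assert residue_graph_config().laplacian_sigma == 30.0
        assert atom_graph_config().laplacian_sigma == 15.0
        assert atom_graph_config().rbf_max == 15.0


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_knn_property_random_seeds(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 30))
    pts = rng.normal(size=(n, 3))
    k = int(rng.integers(1, 6))
    g = build_graph(pts, np.eye(n), k)
    assert g.neighborhoods.shape[1] == min(k, n - 1)
    for i in range(n):
        assert i not in g.neighborhoods[i]  # no self-edges
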