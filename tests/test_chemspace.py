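"""Chemical-space analysis: embeddings, tree map, PMI shapes, summaries."""

import numpy as np
import pytest

from focuslib.chemspace import (
    DescriptorMatrix,
    ParameterError,
    build_descriptor_matrix,
    diversity_summary,
    fingerprint,
    pca_embed,
    shape_triple,
    tanimoto,
    tree_embed,
    tsne_embed,
)

from conftest import record


def matrix_from(X, labels=None):
    X = np.asarray(X, dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return DescriptorMatrix(
        X=(X - mu) / sd, labels=labels or ["x"] * len(X), columns=tuple("abcdef")
    )


class TestFingerprints:
    def test_identical_structures_have_tanimoto_one(self):
        a, b = fingerprint(record("CCO")), fingerprint(record("OCC"))
        assert list(a.GetOnBits()) == list(b.GetOnBits())
        assert tanimoto(a, b) == 1.0

    def test_dissimilar_molecules_near_zero(self):
        a = fingerprint(record("C"))
        b = fingerprint(record("c1ccc2nc3ccccc3nc2c1"))
        assert tanimoto(a, b) < 0.05

    def test_tanimoto_is_symmetric(self, panel):
        fps = [fingerprint(r) for r in panel]
        for i in range(0, len(fps), 3):
            for j in range(1, len(fps), 4):
                assert tanimoto(fps[i], fps[j]) == pytest.approx(tanimoto(fps[j], fps[i]))


class TestPcaEmbed:
    def test_single_variance_direction_explains_everything(self):
        X = np.zeros((10, 6))
        X[:, 2] = np.arange(10)
        emb = pca_embed(matrix_from(X))
        assert emb.explained_variance[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(42)
        matrix = matrix_from(rng.normal(size=(50, 6)))
        emb = pca_embed(matrix)
        # independent oracle: eigenvectors of the covariance matrix
        cov = np.cov(matrix.X, rowvar=False, ddof=1)
        eigenvalues, eigenvectors = np.linalg.eigh(cov)
        order = np.argsort(eigenvalues)[::-1][:2]
        for k, col in enumerate(order):
            v = eigenvectors[:, col]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            expected = matrix.X @ v
            assert np.allclose(emb.coords[:, k], expected, atol=1e-8)

    def test_duplicated_rows_map_to_identical_coordinates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 6))
        X[5] = X[2]
        emb = pca_embed(matrix_from(X))
        assert np.allclose(emb.coords[5], emb.coords[2])

    def test_row_order_invariance_up_to_sign_convention(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 6))
        perm = rng.permutation(20)
        a = pca_embed(matrix_from(X)).coords
        b = pca_embed(matrix_from(X[perm])).coords
        assert np.allclose(a[perm], b, atol=1e-8)

    def test_too_few_rows(self):
        with pytest.raises(ParameterError):
            pca_embed(matrix_from(np.zeros((2, 6))))

    def test_descriptor_matrix_is_column_standardized(self, panel):
        matrix = build_descriptor_matrix({"panel": panel})
        assert np.allclose(matrix.X.mean(axis=0), 0.0, atol=1e-12)
        stds = matrix.X.std(axis=0)
        assert np.all((np.isclose(stds, 1.0)) | (np.isclose(stds, 0.0)))
        assert matrix.labels == ["panel"] * len(panel)


class TestTsneEmbed:
    def _clusters(self, n_per=60, seed=5):
        rng = np.random.default_rng(seed)
        a = rng.normal(loc=0.0, scale=0.5, size=(n_per, 6))
        b = rng.normal(loc=8.0, scale=0.5, size=(n_per, 6))
        labels = ["a"] * n_per + ["b"] * n_per
        return matrix_from(np.vstack([a, b]), labels), labels

    def test_deterministic_under_fixed_seed(self):
        matrix, _ = self._clusters(n_per=40)
        first = tsne_embed(matrix, perplexity=10, seed=7).coords
        second = tsne_embed(matrix, perplexity=10, seed=7).coords
        assert np.array_equal(first, second)

    def test_well_separated_clusters_keep_neighbourhoods(self):
        matrix, labels = self._clusters()
        emb = tsne_embed(matrix, perplexity=30, seed=1)
        coords = emb.coords
        same = 0
        total = 0
        for i in range(len(coords)):
            d = np.linalg.norm(coords - coords[i], axis=1)
            nn = np.argsort(d)[1:11]
            same += sum(labels[j] == labels[i] for j in nn)
            total += 10
        assert same / total >= 0.90

    def test_perplexity_must_be_below_row_count(self):
        matrix, _ = self._clusters(n_per=5)
        with pytest.raises(ParameterError):
            tsne_embed(matrix, perplexity=10, seed=0)


class TestTreeEmbed:
    def test_three_compounds_give_two_edges(self):
        fps = [fingerprint(record(s)) for s in ("CCO", "CCN", "CCC")]
        emb = tree_embed(fps, seed=0)
        assert len(emb.edges) == 2
        assert emb.coords.shape == (3, 2)

    def test_two_scaffold_families_cross_once(self):
        # ten decorated benzenes vs ten decorated piperidines
        aryl = [record(f"{'C' * (i + 1)}c1ccccc1") for i in range(10)]
        aliph = [record(f"{'C' * (i + 1)}C1CCNCC1") for i in range(10)]
        fps = [fingerprint(r) for r in aryl + aliph]
        emb = tree_embed(fps, seed=0)
        crossings = sum(1 for i, j, _ in emb.edges if (i < 10) != (j < 10))
        assert crossings == 1

    def test_mst_weight_equals_brute_force_on_small_instances(self, panel):
        import networkx as nx

        fps = [fingerprint(r) for r in panel]
        emb = tree_embed(fps, seed=0)
        g = nx.Graph()
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                g.add_edge(i, j, weight=1.0 - tanimoto(fps[i], fps[j]))
        brute = nx.minimum_spanning_tree(g)
        brute_weight = sum(d["weight"] for _, _, d in brute.edges(data=True))
        assert sum(w for _, _, w in emb.edges) == pytest.approx(brute_weight, abs=1e-9)

    def test_duplicate_fingerprints_joined_at_distance_zero(self):
        fps = [fingerprint(record(s)) for s in ("CCO", "OCC", "c1ccccc1")]
        emb = tree_embed(fps, seed=0)
        zero_edges = [(i, j) for i, j, w in emb.edges if w == 0.0]
        assert ((0, 1) in zero_edges) or ((1, 0) in zero_edges)

    def test_needs_two_compounds(self):
        with pytest.raises(ParameterError):
            tree_embed([fingerprint(record("CCO"))])


class TestShapeTriple:
    def test_near_linear_molecule_sits_at_the_rod_vertex(self):
        st = shape_triple(record("C#CC#C"), n_conformers=3, seed=7)
        assert st.npr1 < 0.05 and st.npr2 > 0.95

    def test_benzene_is_a_planar_symmetric_disc(self):
        st = shape_triple(record("c1ccccc1"), n_conformers=3, seed=7)
        assert st.npr1 == pytest.approx(0.5, abs=0.02)
        assert st.npr2 == pytest.approx(0.5, abs=0.02)

    def test_adamantane_sits_at_the_sphere_corner(self):
        st = shape_triple(record("C1C2CC3CC1CC(C2)C3"), n_conformers=5, seed=7)
        assert st.npr1 >= 0.9 and st.npr2 >= 0.9

    def test_triangle_constraint_holds_across_fixtures(self, panel):
        for rec in panel[:5]:
            st = shape_triple(rec, n_conformers=5, seed=7)
            assert 0.0 <= st.npr1 <= st.npr2 <= 1.0 + 1e-6
            assert st.npr1 + st.npr2 >= 1.0 - 1e-6

    def test_single_heavy_atom_rejected(self):
        with pytest.raises(ParameterError):
            shape_triple(record("C"), n_conformers=1, seed=7)


class TestDiversitySummary:
    def test_constant_vector_has_zero_width_interval(self):
        df = diversity_summary({"lib": {"MW": [5.0, 5.0, 5.0]}})
        row = df.iloc[0]
        assert row["mean"] == row["median"] == 5.0
        assert row["ci_low"] == row["ci_high"] == 5.0

    def test_small_example_statistics(self):
        row = diversity_summary({"lib": {"x": [1, 2, 3, 4, 5]}}).iloc[0]
        assert row["mean"] == 3.0 and row["median"] == 3.0
        assert row["q1"] == 2.0 and row["q3"] == 4.0

    def test_t_interval_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.normal(loc=10.0, scale=2.0, size=1000)
        row = diversity_summary({"lib": {"x": values}}).iloc[0]
        width = row["ci_high"] - row["ci_low"]
        boot_means = [
            rng.choice(values, size=values.size, replace=True).mean()
            for _ in range(2000)
        ]
        boot_width = np.percentile(boot_means, 97.5) - np.percentile(boot_means, 2.5)
        assert width == pytest.approx(boot_width, rel=0.10)

    def test_empty_values_error(self):
        with pytest.raises(ValueError):
            diversity_summary({"lib": {"x": []}})
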