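import numpy as np
import pytest

from connectomotif import (
    DomainError,
    UsageError,
    decompose,
    explained_variance,
    motif_as_matrix,
    prevalence,
    prevalence_change,
    reconstruction_error,
)
from connectomotif.io import feature_index_map, Parcellation, vectorize
from connectomotif.io import ConnectivityMatrix


def anon_index_map(n_features):
    return [(f"r{i}", f"r{i+1}") for i in range(n_features)]


def random_decomposition(rng, n_feat=45, n_col=6):
    M = rng.standard_normal((n_feat, n_col)) * 10
    cols = [(f"s{j}", "a") for j in range(n_col)]
    parc = Parcellation(tuple(f"r{i}" for i in range(10)))
    return M, decompose(M, cols, feature_index_map(parc, "symmetric"))


class TestDecompose:
    def test_single_column_motif_and_weight(self, rng):
        m = np.abs(rng.standard_normal(10)) + 0.1
        dec = decompose(m[:, None], [("s1", "a")], anon_index_map(10))
        assert dec.n_motifs == 1
        np.testing.assert_allclose(dec.singular_values[0], np.linalg.norm(m))
        np.testing.assert_allclose(dec.motifs[:, 0], m / np.linalg.norm(m))
        assert prevalence(dec, 0, "s1", "a") == pytest.approx(1.0)

    def test_full_column_rank_gives_one_motif_per_column(self, rng):
        M = rng.standard_normal((100, 28))
        dec = decompose(M, [(f"s{j}", "a") for j in range(28)],
                        anon_index_map(100))
        assert dec.n_motifs == 28

    def test_singular_values_match_eigen_oracle(self, rng):
        # independent oracle: sigma_k^2 are the eigenvalues of M^T M
        M = rng.standard_normal((6, 4))
        dec = decompose(M, [(f"s{j}", "a") for j in range(4)], anon_index_map(6))
        eigvals = np.sort(np.linalg.eigvalsh(M.T @ M))[::-1]
        np.testing.assert_allclose(dec.singular_values,
                                   np.sqrt(np.clip(eigvals, 0, None)),
                                   atol=1e-10)

    def test_orthonormality_and_reconstruction(self, rng):
        M, dec = random_decomposition(rng)
        gram = dec.motifs.T @ dec.motifs
        assert np.max(np.abs(gram - np.eye(dec.n_motifs))) < 1e-10
        assert reconstruction_error(dec, M) < 1e-10
        assert abs(dec.explained_variance.sum() - 1.0) < 1e-12

    def test_zero_matrix_gives_rank_zero(self):
        dec = decompose(np.zeros((10, 3)),
                        [(f"s{j}", "a") for j in range(3)], anon_index_map(10))
        assert dec.n_motifs == 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(UsageError):
            decompose(np.zeros((10, 0)), [], anon_index_map(10))

    def test_deterministic_repeat(self, rng):
        M, dec1 = random_decomposition(rng)
        dec2 = decompose(M, dec1.column_index, dec1.index_map)
        np.testing.assert_array_equal(dec1.motifs, dec2.motifs)
        np.testing.assert_array_equal(dec1.weights, dec2.weights)

    def test_sign_convention_largest_entry_positive(self, rng):
        _, dec = random_decomposition(rng)
        for k in range(dec.n_motifs):
            i = np.argmax(np.abs(dec.motifs[:, k]))
            assert dec.motifs[i, k] > 0

    def test_rank_truncation_drops_dependent_columns(self, rng):
        base = rng.standard_normal((30, 2))
        M = np.column_stack([base[:, 0], base[:, 1], base @ [1.0, 2.0]])
        dec = decompose(M, [(f"s{j}", "a") for j in range(3)], anon_index_map(30))
        assert dec.n_motifs == 2


class TestExplainedVariance:
    @pytest.mark.parametrize(
        "s,expect",
        [([2, 1], [0.8, 0.2]), ([5], [1.0]), ([3, 0], [1.0, 0.0])],
    )
    def test_squared_fractions(self, s, expect):
        np.testing.assert_allclose(explained_variance(np.array(s, float)), expect)

    def test_all_zero_rejected(self):
        with pytest.raises(DomainError):
            explained_variance(np.zeros(3))

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            explained_variance(np.array([2.0, -1.0]))


class TestPrevalence:
    def test_rank_one_weights_proportional_to_scale(self, rng):
        u = rng.standard_normal(20)
        scales = np.array([1.0, 2.0, 3.0])
        M = u[:, None] * scales[None, :]
        dec = decompose(M, [(f"s{j}", "a") for j in range(3)], anon_index_map(20))
        w = np.array([prevalence(dec, 0, f"s{j}", "a") for j in range(3)])
        ratio = w / scales
        np.testing.assert_allclose(ratio, ratio[0])

    def test_change_zero_for_identical_scans(self, rng):
        cols = rng.standard_normal((15, 2)) * 5
        M = np.column_stack([cols, cols])  # scans a then b, identical
        idx = [("s1", "a"), ("s2", "a"), ("s1", "b"), ("s2", "b")]
        dec = decompose(M, idx, anon_index_map(15))
        for k in range(dec.n_motifs):
            assert prevalence_change(dec, k, "s1") == pytest.approx(0.0, abs=1e-12)

    def test_change_matches_projection_oracle(self, rng):
        # independent oracle: V-entry change = u_k . (col_b - col_a) / sigma_k
        n_feat, n_subj = 40, 5
        Ma = rng.standard_normal((n_feat, n_subj)) * 8
        Mb = Ma + rng.standard_normal((n_feat, n_subj))
        M = np.column_stack([Ma, Mb])
        idx = [(f"s{j}", "a") for j in range(n_subj)] + \
              [(f"s{j}", "b") for j in range(n_subj)]
        dec = decompose(M, idx, anon_index_map(n_feat))
        for k in range(3):
            for j in range(n_subj):
                oracle = float(
                    dec.motifs[:, k] @ (Mb[:, j] - Ma[:, j])
                ) / dec.singular_values[k]
                got = prevalence_change(dec, k, f"s{j}")
                assert got == pytest.approx(oracle, abs=1e-10)

    def test_unknown_column_rejected(self, rng):
        _, dec = random_decomposition(rng)
        from connectomotif import MissingDataError
        with pytest.raises(MissingDataError):
            prevalence(dec, 0, "nobody", "a")


class TestMotifAsMatrix:
    def test_round_trip_single_column(self, rng):
        values = rng.integers(1, 50, size=(6, 6)).astype(float)
        np.fill_diagonal(values, 0)
        mat = ConnectivityMatrix(values, "s1", "a")
        parc = Parcellation(tuple(f"r{i}" for i in range(6)))
        fv = vectorize(mat, "symmetric", parc)
        dec = decompose(fv.entries[:, None], [("s1", "a")],
                        feature_index_map(parc, "symmetric"))
        recovered = motif_as_matrix(dec, 0)
        sym = (values + values.T) / 2
        np.testing.assert_allclose(recovered, sym / np.linalg.norm(fv.entries))

    def test_single_feature_mirrored(self):
        parc = Parcellation(("A", "B", "C"))
        imap = feature_index_map(parc, "symmetric")
        m = np.zeros(3)
        m[imap.index(("A", "B"))] = 0.7
        dec = decompose(m[:, None], [("s1", "a")], imap)
        mat = motif_as_matrix(dec, 0)
        assert mat[0, 1] == pytest.approx(1.0)  # unit-normalized motif
        assert mat[1, 0] == pytest.approx(1.0)
        assert np.count_nonzero(mat) == 2

    def test_unit_sum_of_squares(self, rng):
        _, dec = random_decomposition(rng)
        for k in range(dec.n_motifs):
            mat = motif_as_matrix(dec, k)
            iu = np.triu_indices(mat.shape[0], k=1)
            assert np.sum(mat[iu] ** 2) == pytest.approx(1.0)

    def test_index_out_of_range(self, rng):
        _, dec = random_decomposition(rng)
        with pytest.raises(UsageError):
            motif_as_matrix(dec, dec.n_motifs)
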