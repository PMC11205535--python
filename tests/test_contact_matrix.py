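import numpy as np
import pytest

from nucleoid3d import (
    ContactMatrix,
    distance_decay,
    log_ratio_map,
    read_matrix,
    read_sparse_triplets,
    scn_normalize,
    short_range_frequency,
    short_range_proportion,
)
from nucleoid3d.errors import DimensionError, EmptyMatrixError, MatrixFormatError

from conftest import make_binning
from oracles import (
    decay_reference,
    scn_reference,
    short_range_frequency_reference,
    short_range_proportion_reference,
)


def write(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadMatrix:
    def test_symmetric_input_kept(self, tmp_path):
        p = write(tmp_path, "1\t2\n2\t1\n")
        M = read_matrix(p, make_binning(2))
        assert np.allclose(M.values, [[1, 2], [2, 1]])

    def test_asymmetric_input_symmetrized_with_warning(self, tmp_path):
        p = write(tmp_path, "1\t4\n2\t1\n")
        with pytest.warns(UserWarning, match="symmetrizing"):
            M = read_matrix(p, make_binning(2))
        assert np.allclose(M.values, [[1, 3], [3, 1]])

    def test_non_square_rejected(self, tmp_path):
        p = write(tmp_path, "1\t2\n2\t1\n3\t4\n")
        with pytest.raises(MatrixFormatError):
            read_matrix(p, make_binning(2))

    def test_negative_entries_rejected(self, tmp_path):
        p = write(tmp_path, "1\t-2\n-2\t1\n")
        with pytest.raises(ValueError):
            read_matrix(p, make_binning(2))

    def test_size_mismatch_with_binning(self, tmp_path):
        p = write(tmp_path, "1\t2\n2\t1\n")
        with pytest.raises(DimensionError):
            read_matrix(p, make_binning(3))

    def test_coordinate_header_stripped(self, tmp_path):
        p = write(tmp_path, "bin\t0\t5000\n0\t1\t2\n5000\t2\t1\n")
        M = read_matrix(p, make_binning(2))
        assert np.allclose(M.values, [[1, 2], [2, 1]])

    def test_sparse_triplets_mirrored(self, tmp_path):
        p = write(tmp_path, "0\t0\t5\n0\t1\t3\n1\t2\t2\n")
        M = read_sparse_triplets(p, make_binning(3))
        assert M.values[0, 1] == M.values[1, 0] == 3
        assert M.values[1, 2] == M.values[2, 1] == 2
        assert M.values[0, 0] == 5


class TestSCN:
    def test_uniform_matrix_normalizes_to_unit_rows(self):
        M = ContactMatrix(binning=make_binning(2), values=np.ones((2, 2)))
        S = scn_normalize(M, min_coverage_quantile=0.0)
        assert np.allclose(S.values, 1 / np.sqrt(2))
        assert S.normalized

    def test_zero_row_masked_and_finite(self):
        vals = np.array([[0.0, 0, 0], [0, 2, 1], [0, 1, 2]])
        S = scn_normalize(ContactMatrix(binning=make_binning(3), values=vals))
        assert S.mask[0]
        assert np.all(S.values[0] == 0)
        assert np.all(np.isfinite(S.values))

    def test_matches_reference_iteration(self, make_matrix):
        M = make_matrix(5)
        S = scn_normalize(M, min_coverage_quantile=0.0)
        ref = scn_reference(M.values)
        assert np.allclose(S.values, ref, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_row_norms_agree_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(0.5, 4.0, (30, 30))
        M = ContactMatrix(binning=make_binning(30), values=(raw + raw.T) / 2)
        S = scn_normalize(M, min_coverage_quantile=0.0)
        norms = np.linalg.norm(S.values, axis=1)
        assert norms.max() - norms.min() < 1e-6
        assert np.allclose(S.values, S.values.T)
        assert np.all(S.values >= 0)

    def test_all_masked_raises(self):
        M = ContactMatrix(binning=make_binning(2), values=np.zeros((2, 2)))
        with pytest.raises(EmptyMatrixError):
            scn_normalize(M)


class TestDistanceDecay:
    def test_uniform_matrix_flat_profile(self):
        M = ContactMatrix(binning=make_binning(6), values=np.full((6, 6), 3.0))
        prof = distance_decay(M)
        assert np.allclose(prof.mean_frequency, 3.0)

    def test_ring_of_adjacent_contacts(self):
        vals = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            vals[i, j] = vals[j, i] = 2.0
        prof = distance_decay(ContactMatrix(binning=make_binning(4), values=vals))
        assert prof.mean_frequency[1] == 2.0
        assert prof.mean_frequency[0] == 0.0

    def test_zero_separation_is_diagonal_mean(self, make_matrix):
        M = make_matrix(8)
        prof = distance_decay(M)
        assert prof.mean_frequency[0] == pytest.approx(np.diag(M.values).mean())

    def test_matches_double_loop(self, make_matrix):
        M = make_matrix(20)
        prof = distance_decay(M)
        ref = decay_reference(M.values, 20)
        assert np.allclose(prof.mean_frequency, ref, atol=1e-10)


class TestLogRatioMap:
    def test_identical_inputs_give_zero(self, make_matrix):
        M = make_matrix(5)
        rm = log_ratio_map(M, M, pseudocount=0.5)
        assert np.allclose(rm.values, 0.0)

    def test_doubling_gives_one_without_pseudocount(self, make_matrix):
        M = make_matrix(5)
        M2 = ContactMatrix(binning=M.binning, values=2 * M.values)
        rm = log_ratio_map(M2, M, pseudocount=1e-12)
        assert np.allclose(rm.values, 1.0, atol=1e-6)

    def test_zero_vs_three_with_unit_pseudocount(self):
        b = make_binning(2)
        A = ContactMatrix(binning=b, values=np.zeros((2, 2)))
        B = ContactMatrix(binning=b, values=np.full((2, 2), 3.0))
        rm = log_ratio_map(A, B, pseudocount=1.0)
        assert np.allclose(rm.values, -2.0)

    def test_antisymmetry_under_swap(self, make_matrix):
        A, B = make_matrix(6), make_matrix(6)
        fwd = log_ratio_map(A, B, pseudocount=0.7)
        rev = log_ratio_map(B, A, pseudocount=0.7)
        assert np.allclose(fwd.values, -rev.values)

    def test_binning_mismatch(self, make_matrix):
        with pytest.raises(DimensionError):
            log_ratio_map(make_matrix(4), make_matrix(5))

    def test_nonpositive_pseudocount_with_zeros(self):
        b = make_binning(2)
        A = ContactMatrix(binning=b, values=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            log_ratio_map(A, A, pseudocount=0.0)


class TestShortRange:
    def test_uniform_matrix_constant_frequency(self):
        M = ContactMatrix(binning=make_binning(8), values=np.full((8, 8), 2.5))
        prof = short_range_frequency(M, max_distance=15000)
        assert np.allclose(prof.per_bin_frequency, 2.5)

    def test_flank_average(self):
        vals = np.zeros((6, 6))
        vals[2, 3] = vals[3, 2] = 4.0
        vals[2, 1] = vals[1, 2] = 2.0
        M = ContactMatrix(binning=make_binning(6), values=vals)
        prof = short_range_frequency(M, max_distance=10000)
        assert prof.per_bin_frequency[2, 1] == 3.0

    def test_masked_bin_row_is_zero(self, make_matrix):
        M = make_matrix(8)
        mask = np.zeros(8, dtype=bool)
        mask[3] = True
        Mm = ContactMatrix(binning=M.binning, values=M.values, mask=mask)
        prof = short_range_frequency(Mm, max_distance=10000)
        assert np.all(prof.per_bin_frequency[3] == 0)

    def test_excessive_distance_rejected(self, make_matrix):
        with pytest.raises(ValueError):
            short_range_frequency(make_matrix(8), max_distance=30000)

    def test_full_window_proportion_is_one(self, make_matrix):
        M = make_matrix(9)
        prof = short_range_proportion(M, window=4 * 5000)
        assert np.allclose(prof.per_bin_proportion, 1.0)

    def test_uniform_closed_form(self):
        n, w = 11, 3
        M = ContactMatrix(binning=make_binning(n), values=np.ones((n, n)))
        prof = short_range_proportion(M, window=w * 5000)
        assert np.allclose(prof.per_bin_proportion, 2 * w / (n - 1))

    def test_matches_double_loop(self, make_matrix):
        M = make_matrix(8)
        prof = short_range_proportion(M, window=2 * 5000)
        ref = short_range_proportion_reference(M.values, 8, 2)
        assert np.allclose(prof.per_bin_proportion, ref, atol=1e-12)

    def test_frequency_matches_double_loop(self, make_matrix):
        M = make_matrix(20)
        prof = short_range_frequency(M, max_distance=6 * 5000)
        ref = short_range_frequency_reference(M.values, 20, 6)
        assert np.allclose(prof.per_bin_frequency, ref, atol=1e-10)

    def test_proportion_monotone_in_window(self, make_matrix):
        M = make_matrix(16)
        props = [
            short_range_proportion(M, window=w * 5000).per_bin_proportion
            for w in range(1, 8)
        ]
        for a, b in zip(props, props[1:]):
            assert np.all(b >= a - 1e-12)

    def test_zero_coverage_bin_reported_missing(self):
        vals = np.ones((5, 5))
        vals[1, :] = 0.0
        vals[:, 1] = 0.0
        M = ContactMatrix(binning=make_binning(5), values=vals)
        prof = short_range_proportion(M, window=5000)
        assert np.isnan(prof.per_bin_proportion[1])
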