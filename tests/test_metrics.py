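"""Matrix preparation and the normalized-RMSE error metrics."""

import numpy as np
import pytest

from speedcap import (
    DegenerateInputError,
    ECAPMatrix,
    ParameterError,
    StructuralError,
    UndefinedCorrelationError,
    demeaned_correlation,
    epsilon_sym,
    estimate_errors,
    half_mask,
    mean_signed_difference,
    mirror_half,
    rmse_normalized,
    symmetrize,
)


def half_matrix_2x2():
    vals = np.array([[10.0, 5.0], [0.0, 8.0]])
    mask = np.array([[True, True], [False, True]])
    return ECAPMatrix(vals, mask)


class TestMirror:
    def test_copy_semantics(self):
        full = mirror_half(half_matrix_2x2())
        assert full.values[1, 0] == 5.0
        assert full.is_full
        np.testing.assert_array_equal(full.values, full.values.T)

    def test_full_input_is_wrong_operation(self):
        with pytest.raises(StructuralError):
            mirror_half(ECAPMatrix(np.eye(3) + 1.0))

    def test_missing_diagonal_rejected(self):
        mask = half_mask(3)
        mask[1, 1] = False
        with pytest.raises(StructuralError):
            mirror_half(ECAPMatrix(np.ones((3, 3)), mask))

    def test_symmetrize_is_identity_on_mirrored_output(self):
        full = mirror_half(half_matrix_2x2())
        np.testing.assert_array_equal(symmetrize(full).values, full.values)


class TestSymmetrize:
    def test_transpose_average(self):
        out = symmetrize(ECAPMatrix(np.array([[1.0, 3.0], [5.0, 1.0]])))
        np.testing.assert_array_equal(out.values, [[1.0, 4.0], [4.0, 1.0]])

    def test_idempotent_and_diagonal_fixed(self, rng):
        M = ECAPMatrix(rng.uniform(0, 10, size=(6, 6)))
        s1 = symmetrize(M)
        s2 = symmetrize(s1)
        np.testing.assert_array_equal(s1.values, s2.values)
        np.testing.assert_array_equal(np.diag(s1.values), np.diag(M.values))

    def test_half_matrix_rejected(self):
        with pytest.raises(StructuralError):
            symmetrize(half_matrix_2x2())

    def test_closest_symmetric_matrix_in_frobenius_norm(self, rng):
        """The transpose-average is the projection onto symmetric matrices."""
        M = rng.uniform(0, 10, size=(4, 4))
        S_star = symmetrize(ECAPMatrix(M)).values
        d_star = np.linalg.norm(M - S_star)
        for _ in range(200):
            S = rng.uniform(0, 10, size=(4, 4))
            S = 0.5 * (S + S.T)
            assert np.linalg.norm(M - S) >= d_star - 1e-12


class TestNormalizedRMSE:
    def test_identical_matrices_zero(self, rng):
        M = ECAPMatrix(rng.uniform(0, 10, size=(5, 5)))
        assert rmse_normalized(M, M).percent == 0.0

    def test_single_cell_examples(self):
        plain = rmse_normalized([[2.0]], [[4.0]])
        assert plain.percent == pytest.approx(50.0, abs=1e-4)
        corrected = rmse_normalized([[2.0]], [[4.0]], half_sweep_correction=True)
        assert corrected.percent == pytest.approx(35.3553, abs=1e-3)

    def test_symmetry_error_hand_example(self):
        rep = epsilon_sym(np.array([[1.0, 3.0], [5.0, 1.0]]))
        assert rep.percent == pytest.approx(14.1421, abs=1e-3)
        assert rep.normalizer == 5.0

    def test_symmetric_in_arguments_and_scale_invariant(self, rng):
        a = rng.uniform(0, 10, size=(4, 4))
        b = rng.uniform(0, 10, size=(4, 4))
        r1 = rmse_normalized(a, b)
        r2 = rmse_normalized(b, a)
        r3 = rmse_normalized(3.7 * a, 3.7 * b)
        assert r1.percent == pytest.approx(r2.percent)
        assert r1.percent == pytest.approx(r3.percent)

    def test_epsilon_sym_zero_iff_symmetric(self, rng):
        sym = rng.uniform(0, 5, size=(4, 4))
        sym = 0.5 * (sym + sym.T)
        assert epsilon_sym(sym).percent == 0.0
        asym = sym.copy()
        asym[0, 1] += 1.0
        assert epsilon_sym(asym).percent > 0.0

    def test_diagonal_cells_selector(self):
        a = np.array([[1.0, 9.0], [9.0, 2.0]])
        b = np.array([[2.0, 0.0], [0.0, 2.0]])
        rep = rmse_normalized(a, b, cells="diagonal")
        assert rep.n_cells == 2
        # sqrt((1 + 0)/2) / 2
        assert rep.percent == pytest.approx(100 * np.sqrt(0.5) / 2.0)

    def test_zero_normalizer_degenerate(self):
        with pytest.raises(DegenerateInputError):
            rmse_normalized(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_empty_cell_set_rejected(self):
        with pytest.raises(ParameterError):
            rmse_normalized(np.ones((2, 2)), np.ones((2, 2)), cells=np.zeros((2, 2), dtype=bool))


class TestEstimateErrors:
    def test_identical_estimates_zero(self):
        s, e = estimate_errors(np.array([2.0, 3.0]), np.array([2.0, 3.0]),
                               eta_a=np.array([0.5, 0.6]), eta_b=np.array([0.5, 0.6]))
        assert s.value == 0.0 and e.value == 0.0

    def test_sigma_range_percent(self):
        s, _ = estimate_errors(np.array([2.0, 2.0]), np.array([3.0, 3.0]),
                               eta_a=np.array([1.0, 1.0]), eta_b=np.array([1.0, 1.0]))
        assert s.value == pytest.approx(1.0)
        assert s.percent == pytest.approx(20.0)

    def test_eta_hand_example(self):
        _, e = estimate_errors(np.array([2.0, 2.0]), np.array([2.0, 2.0]),
                               eta_a=np.array([0.5, 0.7]), eta_b=np.array([0.6, 0.9]))
        assert e.value == pytest.approx(0.15811, abs=1e-4)
        assert e.percent == pytest.approx(15.81, abs=0.01)

    def test_length_mismatch(self):
        with pytest.raises(StructuralError):
            estimate_errors(np.ones(3), np.ones(4), eta_a=np.ones(3), eta_b=np.ones(4))


class TestSignedDifference:
    def test_identity_and_constant_offset(self):
        assert mean_signed_difference(np.ones(4), np.ones(4)) == 0.0
        assert mean_signed_difference(np.ones(4) + 0.5, np.ones(4)) == pytest.approx(0.5)

    def test_antisymmetric_differences_cancel(self):
        a = np.array([1.0, 2.0])
        b = np.array([2.0, 1.0])
        assert mean_signed_difference(a, b) == 0.0
        s, _ = estimate_errors(np.clip(a, 1, 6), np.clip(b, 1, 6),
                               eta_a=np.ones(2), eta_b=np.ones(2))
        assert s.value > 0.0


class TestDemeanedCorrelation:
    def test_perfect_within_participant_relation(self):
        groups = [(np.arange(5.0), np.arange(5.0) + 10.0),
                  (np.arange(5.0) * 2, np.arange(5.0) * 2 - 30.0)]
        r, df, p = demeaned_correlation(groups)
        assert r == pytest.approx(1.0)
        assert df == 8
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_undefined(self):
        groups = [(np.ones(4), np.arange(4.0)), (np.ones(4) * 7, np.arange(4.0))]
        with pytest.raises(UndefinedCorrelationError):
            demeaned_correlation(groups)

    def test_recovers_within_participant_correlation(self):
        """Strong between-participant offsets do not mask a within-r of 0.7."""
        rng = np.random.default_rng(3)
        rho = 0.7
        groups = []
        for _ in range(25):  # 25 participants x 20 points = 500
            offset = rng.normal(0, 50, size=2)
            x = rng.normal(size=20)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=20)
            groups.append((x + offset[0], y + offset[1]))
        r, df, p = demeaned_correlation(groups)
        assert abs(r - rho) <= 0.1
        assert df == 498

    def test_single_participant_rejected(self):
        with pytest.raises(ParameterError):
            demeaned_correlation([(np.arange(4.0), np.arange(4.0))])
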