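"""Compression and basis-pursuit core: exactness, l1 optimality, determinism."""

import itertools

import numpy as np
import pytest

from cardiocs import prd
from cardiocs.cs import (
    BasisPursuitCodec,
    Measurements,
    basis_pursuit,
    compress,
    reconstruct,
)
from cardiocs.dictionaries import Dictionary
from cardiocs.projections import ProjectionMatrix, gaussian_matrix


def brute_force_min_l1(theta: np.ndarray, y: np.ndarray, kmax: int) -> float:
    """Independent oracle: minimum l1 norm over all exact-feasible supports of size <= kmax."""
    n = theta.shape[1]
    best = np.inf
    for k in range(1, kmax + 1):
        for support in itertools.combinations(range(n), k):
            sub = theta[:, support]
            coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.linalg.norm(y - sub @ coef) <= 1e-9 * max(np.linalg.norm(y), 1):
                best = min(best, np.abs(coef).sum())
    return best


class TestCompress:
    def test_zero_signal(self):
        phi = gaussian_matrix(5, 30, seed=0)
        np.testing.assert_array_equal(compress(np.zeros(30), phi).y, np.zeros(5))

    def test_row_of_ones_sums_the_signal(self):
        phi = ProjectionMatrix(phi=np.ones((1, 300)), kind="gaussian", seed=0)
        y = compress(np.arange(1, 301, dtype=float), phi).y
        assert y[0] == 45150.0  # arithmetic series 1..300

    def test_linearity(self):
        phi = gaussian_matrix(10, 50, seed=1)
        rng = np.random.default_rng(2)
        x1, x2 = rng.standard_normal(50), rng.standard_normal(50)
        lhs = compress(3.0 * x1 + 0.5 * x2, phi).y
        rhs = 3.0 * compress(x1, phi).y + 0.5 * compress(x2, phi).y
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compress(np.zeros(20), gaussian_matrix(5, 30, seed=0))


class TestBasisPursuit:
    def test_zero_measurements_give_zero_code(self, gaussian_dictionary):
        phi = gaussian_matrix(20, 300, seed=0)
        code = basis_pursuit(np.zeros(20), phi, gaussian_dictionary)
        np.testing.assert_allclose(code.alpha, 0.0, atol=1e-9)

    def test_one_sparse_recovery(self, gaussian_dictionary):
        phi = gaussian_matrix(20, 300, seed=1)
        a0 = np.zeros(700)
        a0[42] = 3.7
        x = gaussian_dictionary.atoms @ a0
        code = basis_pursuit(compress(x, phi), phi, gaussian_dictionary)
        assert np.max(np.abs(code.alpha - a0)) <= 1e-5
        assert code.residual_norm <= 1e-6

    def test_l1_optimality_against_support_enumeration(self):
        """BP attains (or beats) the best exact k-sparse l1 norm on tiny instances."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            n_atoms, m, k = 12, 6, 2
            d = Dictionary(atoms=rng.standard_normal((8, n_atoms)), kind="mega").normalize()
            phi = gaussian_matrix(m, 8, seed=trial)
            a0 = np.zeros(n_atoms)
            sup = rng.choice(n_atoms, k, replace=False)
            a0[sup] = rng.standard_normal(k) + np.sign(rng.standard_normal(k))
            y = compress(d.atoms @ a0, phi)
            code = basis_pursuit(y, phi, d)
            theta = phi.phi @ d.atoms
            oracle = brute_force_min_l1(theta, y.y, kmax=3)
            assert np.abs(code.alpha).sum() <= oracle + 1e-6

    def test_determinism_of_repeated_solves(self, gaussian_dictionary):
        phi = gaussian_matrix(20, 300, seed=3)
        rng = np.random.default_rng(6)
        y = compress(gaussian_dictionary.atoms[:, :3] @ rng.standard_normal(3), phi)
        a = basis_pursuit(y, phi, gaussian_dictionary).alpha
        b = basis_pursuit(y, phi, gaussian_dictionary).alpha
        scale = max(np.abs(a).max(), 1e-12)
        assert np.max(np.abs(a - b)) / scale <= 1e-7

    def test_relaxed_mode_bounds_residual(self, gaussian_dictionary):
        phi = gaussian_matrix(20, 300, seed=4)
        rng = np.random.default_rng(7)
        x = gaussian_dictionary.atoms[:, :2] @ np.array([1.0, -2.0])
        y = compress(x, phi)
        y_noisy = Measurements(y=y.y + 1e-3 * rng.standard_normal(20),
                               phi_id=y.phi_id)
        eps = 0.05
        code = basis_pursuit(y_noisy, phi, gaussian_dictionary, eps=eps)
        assert code.residual_norm <= eps + 1e-9

    def test_phi_binding_enforced(self, gaussian_dictionary):
        phi_a = gaussian_matrix(20, 300, seed=1)
        phi_b = gaussian_matrix(20, 300, seed=2)
        y = compress(np.ones(300), phi_a)
        with pytest.raises(ValueError):
            basis_pursuit(y, phi_b, gaussian_dictionary)


class TestReconstruct:
    def test_unit_coefficient_returns_atom(self):
        d = Dictionary(atoms=np.random.default_rng(0).standard_normal((30, 40)),
                       kind="mega")
        from cardiocs.cs import SparseCode
        alpha = np.zeros(40)
        alpha[7] = 1.0
        code = SparseCode(alpha=alpha, dict_id=d.dict_id, residual_norm=0.0)
        np.testing.assert_array_equal(reconstruct(code, d), d.atoms[:, 7])

    def test_zero_code_returns_zero(self, gaussian_dictionary):
        from cardiocs.cs import SparseCode
        code = SparseCode(alpha=np.zeros(700),
                          dict_id=gaussian_dictionary.dict_id, residual_norm=0.0)
        np.testing.assert_array_equal(reconstruct(code, gaussian_dictionary),
                                      np.zeros(300))

    def test_dictionary_mismatch_rejected(self, gaussian_dictionary):
        from cardiocs.cs import SparseCode
        other = Dictionary(atoms=np.eye(300), kind="patient_raw")
        code = SparseCode(alpha=np.zeros(300), dict_id=other.dict_id,
                          residual_norm=0.0)
        with pytest.raises(ValueError):
            reconstruct(code, gaussian_dictionary)

    def test_dictionary_atom_end_to_end_prd(self, gaussian_dictionary):
        """A signal equal to one dictionary atom survives 15:1 compression."""
        phi = gaussian_matrix(20, 300, seed=9)
        x = gaussian_dictionary.atoms[:, 100] * 2.2
        code = basis_pursuit(compress(x, phi), phi, gaussian_dictionary)
        assert prd(x, reconstruct(code, gaussian_dictionary)) <= 0.1

    def test_normalized_and_unnormalized_reconstructions_agree(self):
        rng = np.random.default_rng(11)
        raw = Dictionary(atoms=rng.standard_normal((30, 60)) * 3.0, kind="mega")
        normed = raw.normalize()
        phi = gaussian_matrix(10, 30, seed=1)
        x = raw.atoms[:, 5] * 0.7
        xa = reconstruct(basis_pursuit(compress(x, phi), phi, raw), raw)
        xb = reconstruct(basis_pursuit(compress(x, phi), phi, normed), normed)
        np.testing.assert_allclose(xa, xb, atol=1e-6)


class TestBasisPursuitCodec:
    def test_sklearn_contract(self):
        from sklearn.base import clone
        codec = BasisPursuitCodec(m=10, matrix="gaussian", seed=1)
        assert clone(codec).get_params() == codec.get_params()

    def test_fit_transform_inverse_roundtrip(self):
        rng = np.random.default_rng(3)
        X_train = rng.standard_normal((60, 30))
        codec = BasisPursuitCodec(m=10, matrix="gaussian", kind="mega", seed=0)
        codec.fit(X_train)
        x = X_train[17] * 1.5
        y = codec.transform(x)
        assert y.shape == (1, 10)
        x_hat = codec.inverse_transform(y)[0]
        assert np.linalg.norm(x - x_hat) / np.linalg.norm(x) <= 1e-5

    def test_optimized_matrix_family(self):
        rng = np.random.default_rng(4)
        codec = BasisPursuitCodec(m=8, matrix="optimized", kind="mega", seed=2)
        codec.fit(rng.standard_normal((50, 20)))
        assert codec.projection_.kind == "dict_optimized"
        assert codec.projection_.phi.shape == (8, 20)
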