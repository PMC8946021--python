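"""Beat classifiers: alpha-max, compressed-domain KNN, MLP."""

import numpy as np
import pytest

from cardiocs.classify import (
    CompressedKNNClassifier,
    MLPBeatClassifier,
    classify_alpha_max,
    collapse_to_binary,
    confusion_matrix_table,
    knn_fit,
    knn_predict,
    mlp_fit,
    mlp_predict,
)
from cardiocs.cs import Measurements, SparseCode, basis_pursuit, compress
from cardiocs.dictionaries import build_mega
from cardiocs.projections import gaussian_matrix


@pytest.fixture(scope="module")
def mega(patterns_by_class):
    return build_mega(patterns_by_class["centered"], per_class=40, seed=2)


@pytest.fixture(scope="module")
def holdout(patterns_by_class, mega):
    """Centered patterns not consumed by the mega-dictionary, with labels."""
    used = {}
    for c, j in mega.consumed["selected"]:
        used.setdefault(c, set()).add(j)
    out = []
    for c, plist in patterns_by_class["centered"].items():
        for j, p in enumerate(plist):
            if j not in used.get(c, set()):
                out.append(p)
    return out


class TestAlphaMax:
    def test_unit_coefficient_returns_atom_class(self, mega):
        alpha = np.zeros(mega.n_atoms)
        alpha[85] = 1.0
        code = SparseCode(alpha=alpha, dict_id=mega.dict_id, residual_norm=0.0)
        assert classify_alpha_max(code, mega) == mega.atom_meta[85]["class_label"]

    def test_zero_alpha_is_unclassifiable(self, mega):
        code = SparseCode(alpha=np.zeros(mega.n_atoms), dict_id=mega.dict_id,
                          residual_norm=0.0)
        assert classify_alpha_max(code, mega) is None

    def test_tie_breaks_toward_lowest_atom_index(self, mega):
        alpha = np.zeros(mega.n_atoms)
        alpha[10] = -2.0
        alpha[200] = 2.0
        code = SparseCode(alpha=alpha, dict_id=mega.dict_id, residual_norm=0.0)
        assert classify_alpha_max(code, mega) == mega.atom_meta[10]["class_label"]

    def test_end_to_end_on_held_out_beats(self, mega, holdout):
        """Compressed held-out beats are classified by their largest coefficient."""
        phi = gaussian_matrix(20, 301, seed=1)
        rng = np.random.default_rng(0)
        sample = rng.choice(len(holdout), size=40, replace=False)
        hits = 0
        for i in sample:
            p = holdout[i]
            code = basis_pursuit(compress(p, phi), phi, mega)
            hits += classify_alpha_max(code, mega) == p.class_label
        assert hits / len(sample) >= 0.8


class TestCompressedKNN:
    def test_training_set_is_compressed_mega(self, mega):
        phi = gaussian_matrix(20, 301, seed=3)
        model = knn_fit(mega, phi, k=1)
        assert model._knn._fit_X.shape == (mega.n_atoms, 20)
        assert model.phi_id_ == phi.phi_id

    def test_nearest_neighbor_of_training_vector_is_itself(self, mega):
        phi = gaussian_matrix(20, 301, seed=3)
        model = knn_fit(mega, phi, k=1)
        atoms = mega.atoms * mega.column_norms
        j = 77
        y = Measurements(y=phi.phi @ atoms[:, j], phi_id=phi.phi_id)
        assert knn_predict(model, y) == mega.atom_meta[j]["class_label"]

    def test_predictions_invariant_to_training_order(self, mega):
        phi = gaussian_matrix(20, 301, seed=4)
        atoms = (mega.atoms * mega.column_norms)
        X = (phi.phi @ atoms).T
        y = mega.class_labels
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(y))
        queries = X[rng.choice(len(y), 100, replace=False)] * 1.01
        a = CompressedKNNClassifier(k=1).fit(X, y).predict(queries)
        b = CompressedKNNClassifier(k=1).fit(X[perm], y[perm]).predict(queries)
        np.testing.assert_array_equal(a, b)

    def test_noiseless_holdout_is_separable(self, mega, holdout):
        phi = gaussian_matrix(20, 301, seed=6)
        model = knn_fit(mega, phi, k=1)
        ms = [compress(p, phi) for p in holdout[:100]]
        pred = model.predict_measurements(ms)
        truth = np.array([p.class_label for p in holdout[:100]])
        assert np.mean(pred == truth) >= 0.95

    def test_degenerate_k_votes_majority(self):
        X = np.vstack([np.zeros((5, 3)), np.ones((3, 3))])
        y = np.array([2] * 5 + [7] * 3)
        model = CompressedKNNClassifier(k=8).fit(X, y)
        assert model.predict([[0.5, 0.5, 0.5]])[0] == 2

    def test_phi_binding_enforced(self, mega):
        phi_a = gaussian_matrix(20, 301, seed=7)
        phi_b = gaussian_matrix(20, 301, seed=8)
        model = knn_fit(mega, phi_a)
        ms = Measurements(y=np.zeros(20), phi_id=phi_b.phi_id)
        with pytest.raises(ValueError):
            model.predict_measurements([ms])

    def test_pattern_domain_refuses_measurements(self, mega):
        model = knn_fit(mega, phi=None)
        assert model.domain == "pattern"
        with pytest.raises(ValueError):
            model.predict_measurements([Measurements(y=np.zeros(20), phi_id="x")])

    def test_noise_degrades_accuracy_on_average(self, mega, holdout):
        """More measurement noise, lower mean accuracy (10-seed average)."""
        phi = gaussian_matrix(20, 301, seed=9)
        model = knn_fit(mega, phi, k=1)
        beats = holdout[:60]
        clean = np.vstack([compress(p, phi).y for p in beats])
        truth = np.array([p.class_label for p in beats])
        scale = np.linalg.norm(clean) / np.sqrt(clean.size)
        accs = []
        for snr_db in (np.inf, 20.0, 6.0):
            noise = 0.0 if np.isinf(snr_db) else scale * 10 ** (-snr_db / 20)
            seed_accs = []
            for s in range(10):
                rng = np.random.default_rng(s)
                pred = model.predict(clean + noise * rng.standard_normal(clean.shape))
                seed_accs.append(np.mean(pred == truth))
            accs.append(np.mean(seed_accs))
        assert accs[0] >= accs[1] >= accs[2]


class TestMLP:
    def test_separable_two_class_problem(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((60, 5)) + 4,
                       rng.standard_normal((60, 5)) - 4])
        y = np.array([0] * 60 + [1] * 60)
        model = mlp_fit(X, y, seed=1)
        assert np.mean(model.predict(X) == y) >= 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((80, 4))
        y = (X[:, 0] > 0).astype(int)
        a = MLPBeatClassifier(seed=3).fit(X, y).predict(X)
        b = MLPBeatClassifier(seed=3).fit(X, y).predict(X)
        np.testing.assert_array_equal(a, b)

    def test_default_architecture(self):
        model = MLPBeatClassifier()
        assert model.hidden_units == 10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mlp_fit(np.zeros((5, 2)), np.ones(5))

    def test_functional_predict_wrapper(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.standard_normal((30, 3)) + 3,
                       rng.standard_normal((30, 3)) - 3])
        y = np.array([1] * 30 + [2] * 30)
        model = mlp_fit(X, y, seed=0)
        assert mlp_predict(model, X[0]) in (1, 2)


class TestEvaluationHelpers:
    def test_binary_collapse(self):
        labels = np.array([1, 3, 1, 8])
        np.testing.assert_array_equal(collapse_to_binary(labels), [0, 1, 0, 1])

    def test_confusion_rows_sum_to_class_counts(self):
        y_true = np.array([1, 1, 2, 2, 2, 3])
        y_pred = np.array([1, 2, 2, 2, 3, 3])
        cm = confusion_matrix_table(y_true, y_pred, classes=[1, 2, 3])
        np.testing.assert_array_equal(cm.sum(axis=1).to_numpy(), [2, 3, 1])
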