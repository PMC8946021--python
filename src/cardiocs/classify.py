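"""Beat classification for dictionary selection and reconstruction quality checks.

Three classifiers:

* **alpha-max** — after basis pursuit against the class-balanced
  mega-dictionary, the beat is assigned the class of the atom carrying the
  largest |coefficient|;
* **KNN** — k-nearest neighbours (default k=1, Euclidean) trained either on
  the *compressed* mega-dictionary atoms (``domain="compressed"``, used to
  pick the pathology-specific dictionary before reconstruction) or on the raw
  atoms (``domain="pattern"``, used to grade reconstructed beats);
* **MLP** — a single-hidden-layer perceptron (10 units, SGD backpropagation)
  as a second opinion on reconstruction quality.

KNN/MLP models trained on compressed atoms are bound to the sensing matrix
that compressed them; classifying measurements taken under a different matrix
is an error.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from cardiocs.cs import Measurements, SparseCode
from cardiocs.dictionaries import Dictionary
from cardiocs.projections import ProjectionMatrix

logger = logging.getLogger(__name__)


def classify_alpha_max(code: SparseCode, mega: Dictionary) -> int | None:
    """Class of the mega-dictionary atom with the largest |alpha|; None if alpha = 0.

    Ties are broken toward the lowest atom index (logged).
    """
    if code.dict_id != mega.dict_id:
        raise ValueError("sparse code was not solved against this mega-dictionary")
    a = np.abs(code.alpha)
    if not np.any(a > 0):
        logger.info("alpha-max: all-zero coefficients, beat unclassifiable")
        return None
    best = int(np.argmax(a))  # argmax returns the first (lowest-index) maximiser
    if np.sum(a == a[best]) > 1:
        logger.debug("alpha-max: tie at |alpha|=%g broken toward atom %d", a[best], best)
    label = mega.atom_meta[best].get("class_label")
    if label is None:
        raise ValueError(f"mega-dictionary atom {best} has no class label")
    return int(label)


class CompressedKNNClassifier(BaseEstimator, ClassifierMixin):
    """KNN beat classifier, optionally operating in the compressed domain.

    Parameters
    ----------
    k : int
        Neighbour count (default 1: nearest compressed atom).
    domain : {"compressed", "pattern"}
        Whether the model expects m-length measurement vectors or full-length
        (reconstructed) patterns.
    """

    def __init__(self, k: int = 1, domain: str = "compressed"):
        self.k = k
        self.domain = domain

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 1 or len(X) != len(y):
            raise ValueError("X and y must be aligned and non-empty")
        self._knn = KNeighborsClassifier(n_neighbors=self.k)
        self._knn.fit(X, y)
        self.classes_ = self._knn.classes_
        self.n_features_in_ = X.shape[1]
        self.phi_id_ = None
        return self

    @classmethod
    def from_dictionary(cls, mega: Dictionary, phi: ProjectionMatrix | None = None,
                        k: int = 1) -> "CompressedKNNClassifier":
        """Train on the mega-dictionary atoms: compressed under ``phi`` when given.

        Atoms enter training on the original amplitude scale (column norms
        are undone for normalized dictionaries).
        """
        labels = mega.class_labels
        if np.any(labels < 0):
            raise ValueError("mega-dictionary atoms must carry class labels")
        atoms = mega.atoms
        if mega.normalized and mega.column_norms is not None:
            atoms = atoms * mega.column_norms
        if phi is not None:
            model = cls(k=k, domain="compressed")
            model.fit((phi.phi @ atoms).T, labels)
            model.phi_id_ = phi.phi_id
        else:
            model = cls(k=k, domain="pattern")
            model.fit(atoms.T, labels)
        return model

    def predict(self, X):
        check_is_fitted(self, "_knn")
        return self._knn.predict(np.asarray(X, dtype=float))

    def predict_measurements(self, measurements: list[Measurements]) -> np.ndarray:
        """Classify compressed beats, enforcing the sensing-matrix binding."""
        check_is_fitted(self, "_knn")
        if self.domain != "compressed":
            raise ValueError("model was trained on patterns, not measurements")
        for ms in measurements:
            if self.phi_id_ is not None and ms.phi_id != self.phi_id_:
                raise ValueError("measurements acquired under a different "
                                 "projection matrix than the classifier was trained with")
        return self.predict(np.vstack([ms.y for ms in measurements]))


class MLPBeatClassifier(BaseEstimator, ClassifierMixin):
    """Single-hidden-layer perceptron (10 units) trained by SGD backpropagation."""

    def __init__(self, hidden_units: int = 10, lr: float = 0.01,
                 max_epochs: int = 500, seed: int = 0):
        self.hidden_units = hidden_units
        self.lr = lr
        self.max_epochs = max_epochs
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes to train the MLP")
        import warnings
        from sklearn.exceptions import ConvergenceWarning
        self._mlp = MLPClassifier(hidden_layer_sizes=(self.hidden_units,),
                                  solver="sgd", learning_rate_init=self.lr,
                                  max_iter=self.max_epochs,
                                  random_state=self.seed)
        with warnings.catch_warnings():
            warnings.filterwarnings("always", category=ConvergenceWarning)
            self._mlp.fit(X, y)
        if self._mlp.n_iter_ >= self.max_epochs:
            logger.warning("MLP did not converge within %d epochs", self.max_epochs)
        self.classes_ = self._mlp.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "_mlp")
        return self._mlp.predict(np.asarray(X, dtype=float))


def collapse_to_binary(labels: np.ndarray, normal_class: int = 1) -> np.ndarray:
    """Map an 8-class labelling to normal (0) vs abnormal (1)."""
    labels = np.asarray(labels)
    return (labels != normal_class).astype(int)


def confusion_matrix_table(y_true, y_pred, classes=None):
    """Confusion matrix as a DataFrame whose rows sum to per-class test counts."""
    import pandas as pd
    from sklearn.metrics import confusion_matrix

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    idx = [f"class{c}" for c in classes]
    return pd.DataFrame(cm, index=idx, columns=idx)


# -- thin functional wrappers -------------------------------------------------

def knn_fit(mega: Dictionary, phi: ProjectionMatrix | None = None,
            k: int = 1) -> CompressedKNNClassifier:
    return CompressedKNNClassifier.from_dictionary(mega, phi, k=k)


def knn_predict(model: CompressedKNNClassifier, y: Measurements) -> int:
    return int(model.predict_measurements([y])[0])


def mlp_fit(train_x, labels, hidden_units: int = 10, seed: int = 0) -> MLPBeatClassifier:
    return MLPBeatClassifier(hidden_units=hidden_units, seed=seed).fit(train_x, labels)


def mlp_predict(model: MLPBeatClassifier, x) -> int:
    return int(model.predict(np.atleast_2d(x))[0])
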