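"""Compressive acquisition and basis-pursuit reconstruction.

Acquisition takes ``m`` linear projections of an N-sample frame or pattern,
``y = phi @ x``. Reconstruction recovers sparse coefficients by basis pursuit,

    min ||alpha||_1   subject to   y = Theta alpha,      Theta = phi @ atoms,

solved as a linear program by splitting ``alpha = u - v`` with ``u, v >= 0``
(HiGHS interior point / simplex via :func:`scipy.optimize.linprog`). The
equality-constrained form assumes noiseless measurements; a relaxed mode
bounds each residual component by ``eps / sqrt(m)`` instead, which keeps the
problem a linear program while guaranteeing ``||y - Theta alpha||_2 <= eps``.

The reconstruction is ``x_hat = atoms @ alpha``; when the dictionary columns
were l2-normalized, the coefficients absorb the norms, so ``x_hat`` is always
on the original amplitude scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from sklearn.base import BaseEstimator, TransformerMixin

from cardiocs.dictionaries import Dictionary
from cardiocs.preprocess import CardiacPattern, Frame
from cardiocs.projections import ProjectionMatrix, gaussian_matrix, optimized_matrix


class BasisPursuitError(RuntimeError):
    """Raised when the LP solver fails or the solution is infeasible."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


@dataclass
class Measurements:
    """Compressed measurements of one frame/pattern, bound to the Phi that took them."""

    y: np.ndarray
    phi_id: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 1:
            raise ValueError("y must be a vector")


@dataclass
class SparseCode:
    """Recovered coefficient vector, bound to its dictionary."""

    alpha: np.ndarray
    dict_id: str
    residual_norm: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)


def _as_vector(x) -> np.ndarray:
    if isinstance(x, (Frame, CardiacPattern)):
        return x.x
    return np.asarray(x, dtype=float)


def compress(x, phi: ProjectionMatrix, source_id: str = "") -> Measurements:
    """Acquire ``y = phi @ x`` from a Frame, CardiacPattern or plain vector."""
    v = _as_vector(x)
    if len(v) != phi.N:
        raise ValueError(f"signal length {len(v)} does not match phi.N={phi.N}")
    return Measurements(y=phi.phi @ v, phi_id=phi.phi_id, source_id=source_id)


def basis_pursuit(y: Measurements | np.ndarray, phi: ProjectionMatrix,
                  dictionary: Dictionary, tol: float = 1e-8,
                  eps: float | None = None) -> SparseCode:
    """Solve basis pursuit for the measurements against ``phi @ atoms``.

    Parameters
    ----------
    tol : float
        LP feasibility/optimality tolerance passed to HiGHS.
    eps : float, optional
        If given, replace the equality constraint by the relaxed residual
        bound ``||y - Theta alpha||_2 <= eps`` (useful for noisy recordings).
    """
    yv = y.y if isinstance(y, Measurements) else np.asarray(y, dtype=float)
    if isinstance(y, Measurements) and y.phi_id != phi.phi_id:
        raise ValueError("measurements were acquired under a different projection matrix")
    if phi.N != dictionary.frame_length:
        raise ValueError(f"phi.N={phi.N} does not match dictionary frame length "
                         f"{dictionary.frame_length}")
    if len(yv) != phi.m:
        raise ValueError(f"measurement length {len(yv)} does not match phi.m={phi.m}")

    theta = phi.phi @ dictionary.atoms
    m, n = theta.shape
    c = np.ones(2 * n)
    split = np.hstack([theta, -theta])
    options = {"primal_feasibility_tolerance": max(tol, 1e-11),
               "dual_feasibility_tolerance": max(tol, 1e-11),
               "presolve": True}
    if eps is None:
        res = linprog(c, A_eq=split, b_eq=yv, bounds=(0, None),
                      method="highs", options=options)
    else:
        bound = eps / np.sqrt(m)
        A_ub = np.vstack([split, -split])
        b_ub = np.hstack([yv + bound, bound - yv])
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None),
                      method="highs", options=options)
    if not res.success:
        residual = None
        if res.x is not None:
            alpha_try = res.x[:n] - res.x[n:]
            residual = float(np.linalg.norm(yv - theta @ alpha_try))
        raise BasisPursuitError(
            f"basis pursuit LP failed (status {res.status}): {res.message}",
            residual_norm=residual)
    alpha = res.x[:n] - res.x[n:]
    residual = float(np.linalg.norm(yv - theta @ alpha))
    return SparseCode(alpha=alpha, dict_id=dictionary.dict_id, residual_norm=residual)


def reconstruct(code: SparseCode, dictionary: Dictionary) -> np.ndarray:
    """Synthesise ``x_hat = atoms @ alpha``; errors if the dictionary does not match."""
    if code.dict_id != dictionary.dict_id:
        raise ValueError("sparse code was solved against a different dictionary")
    return dictionary.atoms @ code.alpha


class BasisPursuitCodec(BaseEstimator, TransformerMixin):
    """Compressed-sensing codec with a scikit-learn transformer interface.

    ``fit(X)`` treats the rows of ``X`` as dictionary atoms (training frames
    or cardiac patterns), builds the sensing matrix — i.i.d. Gaussian,
    symmetric Bernoulli, or dictionary-optimized — and stores both.
    ``transform(X)`` compresses rows to ``m`` measurements each and
    ``inverse_transform(Y)`` reconstructs via basis pursuit.

    Parameters
    ----------
    m : int
        Number of measurements per frame.
    matrix : {"gaussian", "bernoulli", "optimized"}
        Sensing-matrix family; "optimized" multiplies a Gaussian base by the
        transpose of a random square atom selection.
    kind : str
        Dictionary kind tag recorded on the fitted dictionary.
    tol, eps : float
        Solver tolerances, see :func:`basis_pursuit`.
    seed : int
        Seed for the sensing matrix and atom selection.
    """

    def __init__(self, m: int = 20, matrix: str = "gaussian",
                 kind: str = "patient_raw", tol: float = 1e-8,
                 eps: float | None = None, seed: int = 0):
        self.m = m
        self.matrix = matrix
        self.kind = kind
        self.tol = tol
        self.eps = eps
        self.seed = seed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_atoms, frame_length)")
        dictionary = Dictionary(atoms=X.T, kind=self.kind,
                                atom_meta=[{} for _ in range(X.shape[0])])
        self.dictionary_ = dictionary.normalize()
        N = X.shape[1]
        if self.matrix == "gaussian":
            self.projection_ = gaussian_matrix(self.m, N, self.seed)
        elif self.matrix == "bernoulli":
            from cardiocs.projections import bernoulli_symmetric_matrix
            self.projection_ = bernoulli_symmetric_matrix(self.m, N, self.seed)
        elif self.matrix == "optimized":
            base = gaussian_matrix(self.m, N, self.seed)
            self.projection_ = optimized_matrix(base, self.dictionary_, self.seed)
        else:
            raise ValueError(f"unknown matrix family {self.matrix!r}")
        return self

    def transform(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.projection_.phi.T

    def inverse_transform(self, Y) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        out = np.empty((Y.shape[0], self.dictionary_.frame_length))
        for i, yv in enumerate(Y):
            code = basis_pursuit(yv, self.projection_, self.dictionary_,
                                 tol=self.tol, eps=self.eps)
            out[i] = reconstruct(code, self.dictionary_)
        return out
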