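"""Sensing (projection) matrices.

Three constructions: i.i.d. Gaussian, symmetric 0/1 Bernoulli (each row's
second half mirrors its first, which halves the random bits needed and eases
hardware implementation), and a dictionary-optimized variant formed as the
product of a random matrix with the transpose of a square matrix of randomly
selected dictionary atoms, which lowers reconstruction error for signals
sparse in that dictionary.

Rows of the matrix are the sampling vectors: ``y = phi @ x`` takes ``m``
scalar products of the signal. No row rescaling or centering is applied.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from cardiocs.dictionaries import Dictionary

KINDS = ("gaussian", "bernoulli_sym", "dict_optimized")


@dataclass
class ProjectionMatrix:
    """An m x N sensing operator with provenance (kind, seed, source dictionary)."""

    phi: np.ndarray
    kind: str
    seed: int
    dict_ref: str | None = None

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.ndim != 2:
            raise ValueError("phi must be a 2-D matrix")
        if self.m >= self.N:
            raise ValueError(f"sensing matrix must be compressive (m={self.m} < N={self.N})")
        if self.kind not in KINDS:
            raise ValueError(f"unknown projection kind {self.kind!r}")
        if self.kind == "dict_optimized" and self.dict_ref is None:
            raise ValueError("dict_optimized matrices must reference their dictionary")

    @property
    def m(self) -> int:
        return self.phi.shape[0]

    @property
    def N(self) -> int:
        return self.phi.shape[1]

    @property
    def phi_id(self) -> str:
        h = hashlib.sha1(self.phi.tobytes()).hexdigest()[:12]
        return f"{self.kind}-{self.m}x{self.N}-{h}"


def _check_shape(m: int, N: int) -> None:
    if not (0 < m < N):
        raise ValueError(f"need 0 < m < N, got m={m}, N={N}")


def gaussian_matrix(m: int, N: int, seed: int = 0) -> ProjectionMatrix:
    """i.i.d. standard-normal sensing matrix."""
    _check_shape(m, N)
    rng = np.random.default_rng(seed)
    return ProjectionMatrix(phi=rng.standard_normal((m, N)), kind="gaussian", seed=seed)


def bernoulli_symmetric_matrix(m: int, N: int, seed: int = 0,
                               p: float = 0.5) -> ProjectionMatrix:
    """0/1 Bernoulli matrix whose rows are palindromic.

    The first ``ceil(N/2)`` entries of each row are i.i.d. Bernoulli(p); the
    remaining entries mirror them (for odd N the centre entry belongs to the
    generated half). All-zero rows are redrawn.
    """
    _check_shape(m, N)
    if not (0 <= p <= 1):
        raise ValueError("p must be a probability")
    rng = np.random.default_rng(seed)
    half = (N + 1) // 2
    phi = np.empty((m, N))
    for i in range(m):
        while True:
            row_half = (rng.random(half) < p).astype(float)
            if row_half.any() or p == 0:
                break
        phi[i, :half] = row_half
        phi[i, half:] = row_half[: N - half][::-1]
    return ProjectionMatrix(phi=phi, kind="bernoulli_sym", seed=seed)


def optimized_matrix(base: ProjectionMatrix, dictionary: Dictionary,
                     seed: int = 0) -> ProjectionMatrix:
    """Dictionary-optimized sensing matrix: ``base.phi @ D.T``.

    ``D`` is an N x N matrix whose columns are N distinct atoms selected
    uniformly at random from the dictionary. A selection that is singular to
    working precision is redrawn once before failing.
    """
    N = base.N
    if dictionary.frame_length != N:
        raise ValueError(f"dictionary frame length {dictionary.frame_length} != N={N}")
    if dictionary.n_atoms < N:
        raise ValueError(f"dictionary must supply at least N={N} atoms, "
                         f"has {dictionary.n_atoms}")
    rng = np.random.default_rng(seed)
    for attempt in range(2):
        cols = np.sort(rng.choice(dictionary.n_atoms, size=N, replace=False))
        D = dictionary.atoms[:, cols]
        if np.linalg.matrix_rank(D) == N:
            return ProjectionMatrix(phi=base.phi @ D.T, kind="dict_optimized",
                                    seed=seed, dict_ref=dictionary.dict_id)
    raise ValueError("atom selection singular to working precision (twice)")
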