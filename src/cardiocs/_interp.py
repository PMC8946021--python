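"""Shared resampling primitive: cubic-spline resampling of a segment to a fixed length."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def resample_to(y: np.ndarray, n_out: int) -> np.ndarray:
    """Resample ``y`` onto ``n_out`` evenly spaced points spanning the same support.

    The first and last samples are preserved exactly (the spline interpolates
    its knots), which is what makes R-wave centering reversible at the shared
    R knot.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1-D segment")
    if len(y) < 2:
        raise ValueError("segment must have at least 2 samples")
    if n_out < 2:
        raise ValueError("n_out must be at least 2")
    if len(y) == n_out:
        return y.copy()
    x_in = np.linspace(0.0, 1.0, len(y))
    x_out = np.linspace(0.0, 1.0, n_out)
    return CubicSpline(x_in, y)(x_out)
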