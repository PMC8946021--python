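"""Distortion and compression scoring.

PRD  = 100 * sqrt( sum (x - x_hat)^2 / sum x^2 )
PRDN = 100 * sqrt( sum (x - x_hat)^2 / sum (x - mean(x))^2 )
CR   = (n_samples * bits_orig) / (m_measurements * bits_comp)
QS   = CR / PRD

PRDN removes the original's mean from the denominator, so PRDN >= PRD with
equality iff the original has zero mean. Both are invariant to a common
rescaling of original and reconstruction. Aggregation over records uses the
unweighted mean of per-record means; a frame-weighted variant is also
computed and kept alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def prd(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Percentage root-mean-square difference, in percent."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have the same shape")
    energy = float(np.sum(x ** 2))
    if energy == 0:
        raise ValueError("PRD undefined for a zero-energy original")
    return 100.0 * float(np.sqrt(np.sum((x - x_hat) ** 2) / energy))


def prdn(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean-removed (normalized) PRD, in percent."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat must have the same shape")
    denom = float(np.sum((x - np.mean(x)) ** 2))
    if denom == 0:
        raise ValueError("PRDN undefined for a constant original")
    return 100.0 * float(np.sqrt(np.sum((x - x_hat) ** 2) / denom))


def compression_ratio(n_samples: int, m_measurements: int,
                      bits_orig: int = 11, bits_comp: int = 11) -> float:
    """Bit-count compression ratio of original vs compressed representation."""
    if n_samples <= 0 or m_measurements <= 0 or bits_orig <= 0 or bits_comp <= 0:
        raise ValueError("all arguments must be positive")
    return (n_samples * bits_orig) / (m_measurements * bits_comp)


def quality_score(cr: float, prd_value: float) -> float:
    """Quality score QS = CR / PRD."""
    if prd_value <= 0:
        raise ValueError("QS undefined for PRD <= 0")
    return cr / prd_value


@dataclass
class DistortionReport:
    """PRD/PRDN/CR/QS bundle, per frame and aggregated."""

    prd: float
    prdn: float
    cr: float
    qs: float
    n: int = 0                       # window length the metrics refer to
    record_id: str = ""
    per_frame: list[tuple] = field(default_factory=list)  # (frame_id, prd, prdn)

    @classmethod
    def from_frames(cls, originals, reconstructions, cr: float,
                    record_id: str = "") -> "DistortionReport":
        """Score a sequence of (original, reconstruction) pairs; means over frames."""
        per_frame = []
        for i, (x, xh) in enumerate(zip(originals, reconstructions)):
            per_frame.append((i, prd(x, xh), prdn(x, xh)))
        if not per_frame:
            raise ValueError("no frames to score")
        mean_prd = float(np.mean([p for _, p, _ in per_frame]))
        mean_prdn = float(np.mean([q for _, _, q in per_frame]))
        return cls(prd=mean_prd, prdn=mean_prdn, cr=cr,
                   qs=quality_score(cr, mean_prd), n=len(originals[0]),
                   record_id=record_id, per_frame=per_frame)


def aggregate(reports: list[DistortionReport]) -> DistortionReport:
    """Average over records: unweighted mean of per-record mean PRD/PRDN.

    The frame-weighted alternative (pooling all frames) is retained in the
    ``per_frame`` list of the result so either convention can be read off.
    """
    if not reports:
        raise ValueError("nothing to aggregate")
    mean_prd = float(np.mean([r.prd for r in reports]))
    mean_prdn = float(np.mean([r.prdn for r in reports]))
    cr = float(np.mean([r.cr for r in reports]))
    pooled = [(f"{r.record_id}:{fid}", p, q)
              for r in reports for fid, p, q in r.per_frame]
    return DistortionReport(prd=mean_prd, prdn=mean_prdn, cr=cr,
                            qs=quality_score(cr, mean_prd),
                            n=reports[0].n, record_id="<aggregate>",
                            per_frame=pooled)


def report_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a results table with the standard column layout."""
    df = pd.DataFrame(rows)
    cols = [c for c in ("method", "dictionary", "centered", "matrix",
                        "cr_label", "cr", "avg_prd", "avg_prdn", "qs")
            if c in df.columns]
    return df[cols + [c for c in df.columns if c not in cols]]
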