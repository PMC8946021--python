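"""R-peak detection, framing, beat segmentation and reversible R-wave centering.

Two framings of a record feed the two compression schemes:

* fixed 300-sample, non-overlapping **frames** taken directly from the signal
  (classical compressed sensing; the R wave can fall anywhere in a frame);
* 301-sample **cardiac patterns**, one per beat, delimited by the midpoints of
  the two adjacent RR intervals and resampled by cubic-spline interpolation to
  the fixed length. A pattern can additionally be R-wave *centered*: the left
  and right sub-segments around the R sample are resampled independently so
  the R peak lands on index 150 (sample 151 in 1-based counting). Centering is
  reversible given the original left/right sub-segment lengths, which are kept
  in the pattern's reversal metadata.

R-peak detection is a Pan-Tompkins-style pipeline (band-pass 5-15 Hz ->
derivative -> squaring -> moving-window integration -> adaptive threshold with
a 0.2 s refractory period). When a record carries annotations, they can be
used verbatim instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from cardiocs._interp import resample_to
from cardiocs.io import EcgRecord

logger = logging.getLogger(__name__)

FRAME_LEN = 300
PATTERN_LEN = 301
R_CENTER = 150  # 0-based target index of the R peak after centering
REFRACTORY_S = 0.2


@dataclass
class Frame:
    """A raw 300-sample slice of the signal (no beat alignment)."""

    x: np.ndarray
    record_id: str = ""
    start_index: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if len(self.x) != FRAME_LEN:
            raise ValueError(f"frame must have {FRAME_LEN} samples, got {len(self.x)}")


@dataclass
class ReversalMeta:
    """What is needed to undo resampling/centering of a cardiac pattern."""

    orig_start: int      # raw-signal index of the segment start (inclusive)
    orig_end: int        # raw-signal index of the segment end (inclusive)
    orig_r: int          # raw-signal index of the R peak
    left_len: int | None = None   # samples in [0..r] of the uncentered pattern
    right_len: int | None = None  # samples in [r..300] of the uncentered pattern


@dataclass
class CardiacPattern:
    """One beat resampled to 301 samples, optionally R-centered."""

    x: np.ndarray
    r_index_in_pattern: int
    class_label: int | None = None
    reversal_meta: ReversalMeta | None = None
    centered: bool = False
    record_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if len(self.x) != PATTERN_LEN:
            raise ValueError(f"pattern must have {PATTERN_LEN} samples, got {len(self.x)}")
        if self.centered and self.r_index_in_pattern != R_CENTER:
            raise ValueError("centered pattern must have its R index at 150")


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(record: EcgRecord, use_annotations: bool = False) -> np.ndarray:
    """Detect R peaks; returns strictly increasing 0-based sample indices.

    With ``use_annotations=True`` and annotations present, the annotated
    indices are returned verbatim (exact reproduction mode).
    """
    if use_annotations and record.annotations:
        return record.r_indices
    x = record.samples
    fs = record.fs
    if len(x) <= fs:
        raise ValueError("need at least one second of signal")
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    nyq = fs / 2.0
    b, a = butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    filtered = filtfilt(b, a, x)
    squared = np.gradient(filtered) ** 2
    win = max(int(round(0.15 * fs)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, props = find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        return np.array([], dtype=int)
    heights = mwi[cand]
    # QRS integration peaks sit well above P/T-wave and noise peaks; anchoring
    # the threshold on the upper quartile keeps it inside the QRS cluster
    threshold = 0.25 * np.percentile(heights, 75)
    cand = cand[heights > threshold]

    # refine each detection to the raw-signal maximum in a +-100 ms window
    half = int(round(0.1 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, len(x))
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    # deduplicate and re-enforce the refractory period on refined indices
    out: list[int] = []
    for p in sorted(set(peaks)):
        if out and p - out[-1] < refractory:
            if x[p] > x[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# Framing and segmentation
# ---------------------------------------------------------------------------

def frame_signal(record: EcgRecord, frame_len: int = FRAME_LEN) -> list[Frame]:
    """Tile the signal prefix with consecutive non-overlapping frames."""
    n = len(record.samples)
    if n < frame_len:
        raise ValueError(f"record shorter than one frame ({n} < {frame_len})")
    n_frames = n // frame_len
    dropped = n - n_frames * frame_len
    if dropped:
        logger.debug("frame_signal: dropping trailing %d samples", dropped)
    return [
        Frame(x=record.samples[i * frame_len:(i + 1) * frame_len],
              record_id=record.record_id, start_index=i * frame_len)
        for i in range(n_frames)
    ]


def segment_patterns(record: EcgRecord, r_peaks: np.ndarray,
                     labels: np.ndarray | None = None) -> list[CardiacPattern]:
    """Cut one cardiac pattern per interior beat and resample each to 301 samples.

    Beat *i* spans ``[mid(R_{i-1}, R_i), mid(R_i, R_{i+1})]`` of the raw
    signal (inclusive bounds). The first and last beats lack an adjacent
    half-interval and are dropped. ``labels`` must align with ``r_peaks``.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < 3:
        logger.warning("segment_patterns: need at least 3 R peaks, got %d", len(r_peaks))
        return []
    if labels is not None and len(labels) != len(r_peaks):
        raise ValueError("labels must align with r_peaks")
    x = record.samples
    patterns = []
    for i in range(1, len(r_peaks) - 1):
        start = (r_peaks[i - 1] + r_peaks[i]) // 2
        end = (r_peaks[i] + r_peaks[i + 1]) // 2
        seg = x[start:end + 1]
        resampled = resample_to(seg, PATTERN_LEN)
        r_in = int(round((r_peaks[i] - start) / (end - start) * (PATTERN_LEN - 1)))
        patterns.append(CardiacPattern(
            x=resampled,
            r_index_in_pattern=r_in,
            class_label=None if labels is None else int(labels[i]),
            reversal_meta=ReversalMeta(orig_start=int(start), orig_end=int(end),
                                       orig_r=int(r_peaks[i])),
            centered=False,
            record_id=record.record_id,
        ))
    return patterns


def pattern_to_raw_length(p: CardiacPattern) -> np.ndarray:
    """Resample a (non-centered) pattern back to its original raw span length."""
    if p.reversal_meta is None:
        raise ValueError("pattern has no reversal metadata")
    n_raw = p.reversal_meta.orig_end - p.reversal_meta.orig_start + 1
    return resample_to(p.x, n_raw)


# ---------------------------------------------------------------------------
# R-wave centering (reversible)
# ---------------------------------------------------------------------------

def center_pattern(p: CardiacPattern) -> CardiacPattern:
    """Resample the two sub-segments around the R sample so R lands on index 150.

    The left segment ``x[0..r]`` maps onto 151 samples and the right segment
    ``x[r..300]`` onto 151 samples sharing the R knot, whose amplitude is
    preserved exactly. The original sub-segment lengths are stored so
    :func:`uncenter_pattern` can invert the transform.
    """
    if p.centered:
        raise ValueError("pattern is already centered")
    r = p.r_index_in_pattern
    if not (0 < r < PATTERN_LEN - 1):
        raise ValueError(f"R index {r} at pattern boundary: centering is degenerate")
    left = resample_to(p.x[: r + 1], R_CENTER + 1)
    right = resample_to(p.x[r:], PATTERN_LEN - R_CENTER)
    out = np.concatenate([left, right[1:]])
    meta = p.reversal_meta if p.reversal_meta is not None else ReversalMeta(0, 0, 0)
    meta = replace(meta, left_len=r + 1, right_len=PATTERN_LEN - r)
    return CardiacPattern(x=out, r_index_in_pattern=R_CENTER,
                          class_label=p.class_label, reversal_meta=meta,
                          centered=True, record_id=p.record_id)


def uncenter_pattern(p: CardiacPattern) -> CardiacPattern:
    """Invert :func:`center_pattern` using the stored left/right lengths."""
    if not p.centered:
        raise ValueError("pattern is not centered")
    meta = p.reversal_meta
    if meta is None or meta.left_len is None or meta.right_len is None:
        raise ValueError("missing reversal metadata (left_len/right_len)")
    left = resample_to(p.x[: R_CENTER + 1], meta.left_len)
    right = resample_to(p.x[R_CENTER:], meta.right_len)
    out = np.concatenate([left, right[1:]])
    return CardiacPattern(x=out, r_index_in_pattern=meta.left_len - 1,
                          class_label=p.class_label,
                          reversal_meta=replace(meta, left_len=None, right_len=None),
                          centered=False, record_id=p.record_id)
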