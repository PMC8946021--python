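"""Construction of the reconstruction dictionaries.

Three families are supported, mirroring how the compression schemes use them:

* **patient_raw** — the first consecutive 300-sample frames of a patient's own
  record (no beat alignment); the consumed prefix is recorded so that test
  material is drawn strictly from the remainder.
* **patient_pattern** — the patient's first beats as 301-sample cardiac
  patterns, centered or not.
* **mega** — a class-balanced pool (per-class quota from each of the 8 beat
  classes) used both for reconstruction and for training the compressed-domain
  classifier.
* **class_specific** — one dictionary per beat class.

Atoms are l2-normalized by default (solver conditioning); the original column
norms are retained. Train/test disjointness is a first-class concern: every
builder records the identities of the atoms it consumed so callers can exclude
them from test sets.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from cardiocs.io import EcgRecord
from cardiocs.preprocess import (
    FRAME_LEN,
    PATTERN_LEN,
    CardiacPattern,
    center_pattern,
    detect_r_peaks,
    frame_signal,
    segment_patterns,
)

logger = logging.getLogger(__name__)

KINDS = ("patient_raw", "patient_pattern", "mega", "class_specific")


@dataclass
class Dictionary:
    """An atom matrix (frame_length x n_atoms) with per-atom provenance.

    ``atom_meta`` holds one dict per atom with keys ``class_label``,
    ``record_id`` and ``source_index`` (the frame/beat index the atom came
    from in its source record).
    """

    atoms: np.ndarray
    kind: str
    atom_meta: list[dict] = field(default_factory=list)
    normalized: bool = False
    column_norms: np.ndarray | None = None
    consumed: dict = field(default_factory=dict)  # exclusion bookkeeping

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2:
            raise ValueError("atoms must be a 2-D matrix (frame_length x n_atoms)")
        if self.kind not in KINDS:
            raise ValueError(f"unknown dictionary kind {self.kind!r}")
        if self.atom_meta and len(self.atom_meta) != self.n_atoms:
            raise ValueError("atom_meta length must equal n_atoms")

    @property
    def frame_length(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def is_overcomplete(self) -> bool:
        return self.n_atoms >= self.frame_length

    @property
    def dict_id(self) -> str:
        h = hashlib.sha1(self.atoms.tobytes()).hexdigest()[:12]
        return f"{self.kind}-{self.n_atoms}-{h}"

    @property
    def class_labels(self) -> np.ndarray:
        return np.array([m.get("class_label", -1) if m else -1 for m in self.atom_meta])

    def normalize(self) -> "Dictionary":
        """Return a copy with unit-l2-norm columns (norms retained)."""
        norms = np.linalg.norm(self.atoms, axis=0)
        if np.any(norms == 0):
            raise ValueError("cannot normalize: dictionary contains zero atoms")
        return Dictionary(atoms=self.atoms / norms, kind=self.kind,
                          atom_meta=list(self.atom_meta), normalized=True,
                          column_norms=norms, consumed=dict(self.consumed))


def _check_atoms(matrix: np.ndarray, what: str) -> None:
    flat = np.ptp(matrix, axis=0) == 0
    if np.any(flat):
        raise ValueError(f"{what}: zero-variance atom(s) at column(s) "
                         f"{np.where(flat)[0][:5].tolist()}")


def _require_overcomplete(n_atoms: int, frame_length: int, what: str) -> None:
    # The reconstruction-grade dictionaries are all overcomplete; degenerate
    # smaller ones are permitted (for diagnostics) but flagged.
    if n_atoms < frame_length:
        logger.warning("%s: dictionary is undercomplete (n_atoms=%d < frame_length=%d)",
                       what, n_atoms, frame_length)


def build_patient_raw(record: EcgRecord, n_atoms: int = 700,
                      frame_len: int = FRAME_LEN, normalized: bool = True) -> Dictionary:
    """Patient-specific dictionary of the record's first raw frames.

    The default 300 x 700 shape corresponds to roughly the first six minutes
    of a 360 Hz recording; ``consumed["prefix_samples"]`` marks where test
    material may start.
    """
    _require_overcomplete(n_atoms, frame_len, "build_patient_raw")
    needed = n_atoms * frame_len
    if len(record.samples) < needed:
        raise ValueError(f"record too short for {n_atoms} frames of {frame_len}: "
                         f"need {needed} samples, have {len(record.samples)}")
    frames = frame_signal(record, frame_len)[:n_atoms]
    atoms = np.column_stack([f.x for f in frames])
    _check_atoms(atoms, "build_patient_raw")
    meta = [{"class_label": None, "record_id": record.record_id, "source_index": i}
            for i in range(n_atoms)]
    d = Dictionary(atoms=atoms, kind="patient_raw", atom_meta=meta,
                   consumed={"record_id": record.record_id, "prefix_samples": needed})
    return d.normalize() if normalized else d


def build_patient_patterns(record: EcgRecord, n_beats: int = 700,
                           centered: bool = False, normalized: bool = True,
                           use_annotations: bool = True) -> Dictionary:
    """Patient-specific dictionary of the record's first ``n_beats`` cardiac patterns."""
    _require_overcomplete(n_beats, PATTERN_LEN, "build_patient_patterns")
    r = detect_r_peaks(record, use_annotations=use_annotations)
    if len(r) < n_beats + 2:
        raise ValueError(f"need at least {n_beats + 2} detected beats "
                         f"(boundary beats are dropped), have {len(r)}")
    labels = record.labels if record.annotations else None
    patterns = segment_patterns(record, r, labels)[:n_beats]
    if centered:
        patterns = [center_pattern(p) for p in patterns]
    atoms = np.column_stack([p.x for p in patterns])
    _check_atoms(atoms, "build_patient_patterns")
    meta = [{"class_label": p.class_label, "record_id": record.record_id,
             "source_index": i + 1}  # +1: beat 0 was dropped as a boundary beat
            for i, p in enumerate(patterns)]
    d = Dictionary(atoms=atoms, kind="patient_pattern", atom_meta=meta,
                   consumed={"record_id": record.record_id,
                             "beat_indices": list(range(1, n_beats + 1))})
    return d.normalize() if normalized else d


def _sample_per_class(patterns_by_class: dict[int, list[CardiacPattern]],
                      quota: int, rng: np.random.Generator,
                      what: str) -> dict[int, np.ndarray]:
    chosen = {}
    for c in sorted(patterns_by_class):
        pool = patterns_by_class[c]
        if len(pool) < quota:
            raise ValueError(f"{what}: class {c} supplies only {len(pool)} "
                             f"patterns, need {quota}")
        chosen[c] = rng.choice(len(pool), size=quota, replace=False)
    return chosen


def build_mega(patterns_by_class: dict[int, list[CardiacPattern]],
               per_class: int = 184, seed: int = 0,
               normalized: bool = True) -> Dictionary:
    """Class-balanced mega-dictionary: ``per_class`` patterns from each of 8 classes.

    The default quota of 184 per class yields 1472 atoms. Selected pattern
    identities are recorded in ``consumed["selected"]`` as (class, index)
    pairs for test-set exclusion.
    """
    if len(patterns_by_class) != 8:
        raise ValueError(f"mega-dictionary needs all 8 classes, got "
                         f"{sorted(patterns_by_class)}")
    rng = np.random.default_rng(seed)
    chosen = _sample_per_class(patterns_by_class, per_class, rng, "build_mega")
    cols, meta, selected = [], [], []
    for c in sorted(chosen):
        for j in sorted(chosen[c]):
            p = patterns_by_class[c][j]
            cols.append(p.x)
            meta.append({"class_label": c, "record_id": p.record_id,
                         "source_index": int(j)})
            selected.append((c, int(j)))
    atoms = np.column_stack(cols)
    _require_overcomplete(atoms.shape[1], atoms.shape[0], "build_mega")
    _check_atoms(atoms, "build_mega")
    d = Dictionary(atoms=atoms, kind="mega", atom_meta=meta,
                   consumed={"selected": selected})
    return d.normalize() if normalized else d


def build_class_dictionaries(patterns_by_class: dict[int, list[CardiacPattern]],
                             n_atoms: int = 700, seed: int = 0,
                             normalized: bool = True) -> dict[int, Dictionary]:
    """One single-class dictionary of ``n_atoms`` patterns per beat class."""
    rng = np.random.default_rng(seed)
    chosen = _sample_per_class(patterns_by_class, n_atoms, rng,
                               "build_class_dictionaries")
    out = {}
    for c in sorted(chosen):
        idx = sorted(chosen[c])
        cols = [patterns_by_class[c][j].x for j in idx]
        atoms = np.column_stack(cols)
        _require_overcomplete(atoms.shape[1], atoms.shape[0],
                              f"build_class_dictionaries[class {c}]")
        _check_atoms(atoms, f"build_class_dictionaries[class {c}]")
        meta = [{"class_label": c,
                 "record_id": patterns_by_class[c][j].record_id,
                 "source_index": int(j)} for j in idx]
        d = Dictionary(atoms=atoms, kind="class_specific", atom_meta=meta,
                       consumed={"selected": [(c, int(j)) for j in idx]})
        out[c] = d.normalize() if normalized else d
    return out
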