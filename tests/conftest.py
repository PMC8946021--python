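"""Shared fixtures: synthetic records, dictionaries, and helpers.

Everything is generated programmatically; the expensive shared objects are
session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiocs import SynthConfig, generate_record
from cardiocs.dictionaries import Dictionary
from cardiocs.io import EcgRecord


def balanced_config(n_per_class: int, seed: int, **kw) -> SynthConfig:
    """A SynthConfig whose class sequence has exactly n_per_class beats per class."""
    rng = np.random.default_rng(seed)
    seq = np.tile(np.arange(1, 9), n_per_class)
    rng.shuffle(seq)
    return SynthConfig(n_beats=8 * n_per_class, seed=seed,
                       class_sequence=[int(c) for c in seq], **kw)


@pytest.fixture(scope="session")
def clean_record() -> EcgRecord:
    """200 noise-free beats: exact R amplitudes, exact detection."""
    return generate_record(SynthConfig(n_beats=200, seed=11, noise_sd=0.0,
                                       baseline_wander_amplitude=0.0))


@pytest.fixture(scope="session")
def noisy_record() -> EcgRecord:
    """500 beats with realistic noise and baseline wander."""
    return generate_record(SynthConfig(n_beats=500, seed=12, noise_sd=0.06,
                                       baseline_wander_amplitude=0.05))


@pytest.fixture(scope="session")
def study_record() -> EcgRecord:
    """Balanced 8x350-beat record used by the dictionary/pipeline tests."""
    return generate_record(balanced_config(350, seed=5))


@pytest.fixture(scope="session")
def gaussian_dictionary() -> Dictionary:
    """A 300 x 700 normalized random dictionary for sparse-recovery tests."""
    rng = np.random.default_rng(0)
    return Dictionary(atoms=rng.standard_normal((300, 700)),
                      kind="patient_raw",
                      atom_meta=[{} for _ in range(700)]).normalize()


@pytest.fixture(scope="session")
def patterns_by_class(study_record):
    """Centered-and-uncentered pattern pools of the study record, keyed by class."""
    from cardiocs.preprocess import center_pattern, detect_r_peaks, segment_patterns

    r = detect_r_peaks(study_record, use_annotations=True)
    pats = segment_patterns(study_record, r, study_record.labels)
    out = {"plain": {}, "centered": {}}
    for p in pats:
        out["plain"].setdefault(p.class_label, []).append(p)
    for c, plist in out["plain"].items():
        out["centered"][c] = [center_pattern(p) for p in plist]
    return out
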