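"""Reading and writing single-lead ECG records.

Two on-disk representations are supported:

* CSV (``sample_index,amplitude``) with a JSON sidecar carrying the sampling
  frequency, bit depth and ground-truth annotations — the native format of the
  synthetic generator.
* WFDB (``.hea`` header + ``.dat`` signal, formats 16 and 212, plus MIT-format
  ``.atr``/``.ann`` annotation files). The reader/writer here is a minimal,
  self-contained implementation of the subset of the WFDB format needed for
  single/dual-lead Holter records such as the MIT-BIH Arrhythmia Database;
  annotation *writing* is out of scope.

All sample indices are 0-based throughout the package. WFDB annotation sample
numbers are already 0-based and pass through unchanged.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Default beat-symbol -> class-id mapping (MIT-BIH beat annotation symbols).
#: The eight-class scheme is configurable via a YAML file because different
#: studies group the pathological beat types differently.
DEFAULT_CLASS_MAP: dict[str, int] = {
    "N": 1,  # normal
    "L": 2,  # left bundle branch block
    "R": 3,  # right bundle branch block
    "V": 4,  # premature ventricular contraction
    "A": 5,  # atrial premature
    "/": 6,  # paced
    "F": 7,  # fusion of ventricular and normal
    "E": 8,  # ventricular escape
}

# MIT annotation code -> symbol, for the beat codes we may encounter.
_MIT_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 35: "n",
    38: "f", 25: "x", 30: "|", 31: "~", 32: "+", 33: '"',
}


@dataclass
class EcgRecord:
    """A sampled single-lead ECG with optional beat annotations.

    Parameters
    ----------
    samples : ndarray
        Amplitudes, in millivolts unless ``units == "adu"``.
    fs : float
        Sampling frequency in Hz.
    bits_per_sample : int
        Quantisation depth of the source signal; used only for
        compression-ratio bookkeeping.
    annotations : list of (r_index, class_label) or None
        0-based R-peak sample indices with integer class labels,
        strictly increasing.
    """

    samples: np.ndarray
    fs: float
    bits_per_sample: int = 11
    record_id: str = ""
    annotations: list[tuple[int, int]] | None = None
    units: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.annotations is not None:
            idx = np.array([a[0] for a in self.annotations])
            if len(idx) and (np.any(np.diff(idx) <= 0)
                             or idx[0] < 0 or idx[-1] >= len(self.samples)):
                raise ValueError("annotation indices must be strictly increasing "
                                 "and within [0, len(samples))")

    @property
    def r_indices(self) -> np.ndarray:
        if self.annotations is None:
            return np.array([], dtype=int)
        return np.array([a[0] for a in self.annotations], dtype=int)

    @property
    def labels(self) -> np.ndarray:
        if self.annotations is None:
            return np.array([], dtype=int)
        return np.array([a[1] for a in self.annotations], dtype=int)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


# ---------------------------------------------------------------------------
# CSV + JSON sidecar
# ---------------------------------------------------------------------------

def write_csv_record(record: EcgRecord, path: str | Path) -> tuple[Path, Path]:
    """Write ``path`` (CSV: sample_index,amplitude) and ``path.with_suffix('.json')``."""
    path = Path(path)
    df = pd.DataFrame({"sample_index": np.arange(len(record.samples)),
                       "amplitude": record.samples})
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact roundtrip
    sidecar = path.with_suffix(".json")
    meta = {
        "fs": record.fs,
        "bits_per_sample": record.bits_per_sample,
        "record_id": record.record_id,
        "units": record.units,
        "r_indices": [int(a[0]) for a in (record.annotations or [])],
        "class_labels": [int(a[1]) for a in (record.annotations or [])],
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return path, sidecar


def read_csv_record(path: str | Path, fs: float | None = None,
                    sidecar: str | Path | None = None) -> EcgRecord:
    """Read a CSV record, taking ``fs`` and annotations from the sidecar if given.

    A sidecar named ``<path stem>.json`` is picked up automatically when present.
    """
    path = Path(path)
    if sidecar is None:
        candidate = path.with_suffix(".json")
        sidecar = candidate if candidate.exists() else None
    meta = json.loads(Path(sidecar).read_text()) if sidecar is not None else {}

    df = pd.read_csv(path, float_precision="round_trip")
    col = df.columns[-1]
    values = pd.to_numeric(df[col], errors="coerce")
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise ValueError(f"non-numeric amplitude at CSV row {row} of {path}")

    fs = meta.get("fs", fs)
    if fs is None:
        raise ValueError("fs must be given either directly or via a sidecar")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    ann = None
    if meta.get("r_indices"):
        labels = meta.get("class_labels") or [0] * len(meta["r_indices"])
        ann = list(zip(meta["r_indices"], labels))
    return EcgRecord(
        samples=values.to_numpy(dtype=float),
        fs=float(fs),
        bits_per_sample=int(meta.get("bits_per_sample", 11)),
        record_id=str(meta.get("record_id", path.stem)),
        annotations=ann,
        units=str(meta.get("units", "mV")),
    )


# ---------------------------------------------------------------------------
# WFDB (minimal: header, signal formats 16 and 212, MIT annotation reader)
# ---------------------------------------------------------------------------

def load_class_map(path: str | Path | None) -> dict[str, int]:
    if path is None:
        return dict(DEFAULT_CLASS_MAP)
    raw = yaml.safe_load(Path(path).read_text())
    return {str(k): int(v) for k, v in raw.items()}


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    name = rec_fields[0].split("/")[0]
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    nsamp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    signals = []
    for ln in lines[1:1 + nsig]:
        f = ln.split()
        gain_field = f[2] if len(f) > 2 else "200"
        # gain may carry "(baseline)/units", e.g. "200(1024)/mV"
        baseline = None
        gain_part = gain_field.split("/")[0]
        if "(" in gain_part:
            gain_str, base_str = gain_part.split("(")
            baseline = int(base_str.rstrip(")"))
            gain = float(gain_str)
        else:
            gain = float(gain_part)
        if gain == 0:
            gain = 200.0
        adc_res = int(f[3]) if len(f) > 3 else 12
        adc_zero = int(f[4]) if len(f) > 4 else 0
        signals.append({
            "file": f[0],
            "format": int(f[1].split("x")[0].split(":")[0].split("+")[0]),
            "gain": gain,
            "baseline": baseline if baseline is not None else adc_zero,
            "adc_res": adc_res,
        })
    return name, nsig, fs, nsamp, signals


def _read_format16(dat: bytes, nsig: int) -> np.ndarray:
    a = np.frombuffer(dat, dtype="<i2")
    a = a[: (len(a) // nsig) * nsig]
    return a.reshape(-1, nsig)


def _read_format212(dat: bytes, nsig: int) -> np.ndarray:
    """Unpack 12-bit two's-complement pairs (3 bytes -> 2 samples)."""
    b = np.frombuffer(dat, dtype=np.uint8)
    b = b[: (len(b) // 3) * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    s0 = np.where(s0 > 2047, s0 - 4096, s0)
    s1 = np.where(s1 > 2047, s1 - 4096, s1)
    flat = np.empty(2 * len(b), dtype=np.int32)
    flat[0::2] = s0
    flat[1::2] = s1
    flat = flat[: (len(flat) // nsig) * nsig]
    return flat.reshape(-1, nsig)


def read_wfdb(path: str | Path, lead: int = 0,
              class_map: dict[str, int] | None = None,
              annotator: str = "atr") -> EcgRecord:
    """Read one lead of a WFDB record (``path`` without extension, or the .hea file).

    Beat annotations are taken from ``<record>.<annotator>`` when present;
    symbols are mapped through ``class_map`` (default: :data:`DEFAULT_CLASS_MAP`)
    and unmapped symbols are dropped with a log message.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    name, nsig, fs, nsamp, signals = _parse_header(hea)
    if not (0 <= lead < nsig):
        raise ValueError(f"lead {lead} out of range for {nsig}-signal record")

    sig = signals[lead]
    dat_path = hea.parent / sig["file"]
    if not dat_path.exists():
        raise FileNotFoundError(f"WFDB signal file not found: {dat_path}")
    raw = dat_path.read_bytes()
    if sig["format"] == 16:
        mat = _read_format16(raw, nsig)
    elif sig["format"] == 212:
        mat = _read_format212(raw, nsig)
    else:
        raise ValueError(f"unsupported WFDB signal format {sig['format']}")
    if nsamp:
        mat = mat[:nsamp]
    adu = mat[:, lead].astype(float)
    mv = (adu - sig["baseline"]) / sig["gain"]

    annotations = None
    ann_path = hea.with_suffix(f".{annotator}")
    if ann_path.exists():
        cmap = class_map if class_map is not None else DEFAULT_CLASS_MAP
        pairs = []
        n_dropped = 0
        for t, symbol in _read_mit_annotations(ann_path.read_bytes()):
            if symbol in cmap and 0 <= t < len(mv):
                pairs.append((int(t), int(cmap[symbol])))
            else:
                n_dropped += 1
        if n_dropped:
            logger.info("dropped %d unmapped/out-of-range annotations in %s",
                        n_dropped, ann_path.name)
        # enforce strict increase (duplicate sample numbers are collapsed)
        annotations = []
        for p in pairs:
            if not annotations or p[0] > annotations[-1][0]:
                annotations.append(p)
    return EcgRecord(samples=mv, fs=fs, bits_per_sample=signals[lead]["adc_res"],
                     record_id=name, annotations=annotations or None, units="mV")


def _read_mit_annotations(buf: bytes):
    """Yield (sample_index, symbol) from an MIT-format annotation byte stream."""
    t = 0
    i = 0
    n = len(buf)
    while i + 1 < n:
        word = buf[i] | (buf[i + 1] << 8)
        i += 2
        code = word >> 10
        interval = word & 0x3FF
        if word == 0:            # EOF
            break
        if code == 59:           # SKIP: 4-byte interval follows (PDP-11 order)
            if i + 3 >= n:
                break
            interval = ((buf[i] | (buf[i + 1] << 8)) << 16) | (buf[i + 2] | (buf[i + 3] << 8))
            i += 4
            t += interval
            continue
        if code == 63:           # AUX: skip `interval` bytes (+ pad to even)
            i += interval + (interval & 1)
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN: modifier, no time advance
            continue
        t += interval
        symbol = _MIT_CODE_TO_SYMBOL.get(code)
        if symbol is not None:
            yield t, symbol


def write_wfdb(record: EcgRecord, directory: str | Path,
               gain: float = 200.0, baseline: int = 0) -> Path:
    """Write ``record`` as a format-16 WFDB pair ``<record_id>.hea``/``.dat``.

    Amplitudes are quantised to ADC units with the given gain (adu/mV);
    round-trip accuracy is therefore 1/gain mV. Returns the header path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id or "record"
    adu = np.clip(np.round(record.samples * gain + baseline),
                  -32768, 32767).astype("<i2")
    dat = directory / f"{name}.dat"
    dat.write_bytes(adu.tobytes())
    hea = directory / f"{name}.hea"
    fs_str = f"{record.fs:g}"
    hea.write_text(
        f"{name} 1 {fs_str} {len(adu)}\n"
        f"{name}.dat 16 {gain:g}({baseline})/mV {record.bits_per_sample} "
        f"{baseline} {int(adu[0]) if len(adu) else 0} 0 0 ECG\n"
    )
    return hea
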