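"""Read/write EEG recordings and corpus manifests; resample to the working rate.

Supported formats
-----------------
* EDF (16-bit European Data Format): read through :mod:`mne`, written by a
  minimal built-in writer (one data record spanning the recording,
  per-channel physical range fitted to the signal).  EDF stores samples as
  16-bit integers, so a write/read round trip is exact only up to one
  quantization step, ``(phys_max - phys_min) / (2^16 - 1)`` per channel.
* Delimited text (``.csv``/``.tsv``/``.txt``): one column per channel; the
  sampling rate comes from a JSON sidecar or the ``fs_hint`` argument.
* NumPy binary (``.npy``) with a JSON sidecar ``{"fs": ..., "label": ...}``.

The manifest is a TSV with columns
``recording_id, label, duration_s, fs, path``.
"""

from __future__ import annotations

import json
import math
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import CLASS_ORDER, Recording

MANIFEST_COLUMNS = ["recording_id", "label", "duration_s", "fs", "path"]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _format_float(x: float, width: int) -> str:
    """Most precise decimal representation of ``x`` that fits ``width`` chars."""
    for prec in range(7, -1, -1):
        s = f"{x:.{prec}f}".rstrip("0").rstrip(".")
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {x} in {width} chars")


def _fit_bound(x: float, width: int, round_up: bool) -> float:
    """Round ``x`` outward to a value representable in ``width`` chars."""
    for prec in range(6, -1, -1):
        scale = 10**prec
        v = math.ceil(x * scale) / scale if round_up else math.floor(x * scale) / scale
        s = f"{v:.{prec}f}".rstrip("0").rstrip(".")
        if len(s) <= width:
            return float(s)
    raise ValueError(f"cannot represent bound {x} in {width} chars")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as a single-data-record 16-bit EDF file (µV)."""
    path = Path(path)
    n_ch, n_samp = rec.signal.shape
    record_duration = n_samp / rec.fs
    header = b""
    header += _edf_field("0", 8)                       # version
    header += _edf_field(rec.recording_id[:80], 80)    # patient id (reused)
    header += _edf_field(rec.label or "X", 80)         # recording id field
    header += _edf_field("01.01.00", 8)                # start date
    header += _edf_field("00.00.00", 8)                # start time
    header += _edf_field(str(256 + 256 * n_ch), 8)     # header bytes
    header += _edf_field("", 44)                       # reserved
    header += _edf_field("1", 8)                       # number of records
    header += _edf_field(_format_float(record_duration, 8), 8)
    header += _edf_field(str(n_ch), 4)

    raw_min = rec.signal.min(axis=1)
    raw_max = rec.signal.max(axis=1)
    flat = raw_max - raw_min < 1e-12
    raw_min = np.where(flat, raw_min - 1.0, raw_min)
    raw_max = np.where(flat, raw_max + 1.0, raw_max)
    phys_min = np.array([_fit_bound(v, 8, round_up=False) for v in raw_min])
    phys_max = np.array([_fit_bound(v, 8, round_up=True) for v in raw_max])

    def per_channel(values, width):
        return b"".join(_edf_field(v, width) for v in values)

    header += per_channel([f"EEG {i:03d}" for i in range(n_ch)], 16)  # labels
    header += per_channel([""] * n_ch, 80)                            # transducer
    header += per_channel(["uV"] * n_ch, 8)                           # dimension
    header += per_channel([_format_float(v, 8) for v in phys_min], 8)
    header += per_channel([_format_float(v, 8) for v in phys_max], 8)
    header += per_channel(["-32768"] * n_ch, 8)                       # digital min
    header += per_channel(["32767"] * n_ch, 8)                        # digital max
    header += per_channel([""] * n_ch, 80)                            # prefilter
    header += per_channel([str(n_samp)] * n_ch, 8)                    # samples/record
    header += per_channel([""] * n_ch, 32)                            # reserved

    scale = (phys_max - phys_min) / 65535.0
    digital = np.round((rec.signal - phys_min[:, None]) / scale[:, None]) - 32768
    digital = np.clip(digital, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())  # channel-sequential within the record


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # volts
    label_field = None
    try:
        with open(path, "rb") as fh:
            head = fh.read(256)
        label_field = head[88:168].decode("ascii", "ignore").strip() or None
    except OSError:  # pragma: no cover
        label_field = None
    label = label_field if label_field in CLASS_ORDER else None
    return Recording(signal=data * 1e6, fs=float(raw.info["sfreq"]),
                     label=label, recording_id=path.stem)


# ---------------------------------------------------------------------------
# Generic read/write
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording; the format follows the file extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".edf":
        write_edf(rec, path)
        return
    sidecar = {"fs": rec.fs, "label": rec.label, "recording_id": rec.recording_id}
    if ext == ".npy":
        np.save(path, rec.signal)
    elif ext in {".csv", ".tsv", ".txt"}:
        sep = "," if ext == ".csv" else "\t"
        np.savetxt(path, rec.signal.T, delimiter=sep)
    else:
        raise ValueError(f"unknown recording format {ext!r}")
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_recording(path: str | Path, fs_hint: float | None = None) -> Recording:
    """Read a recording from EDF, delimited text, or .npy (+ JSON sidecar).

    ``fs_hint`` supplies the sampling rate when no sidecar is present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if ext == ".edf":
        return _read_edf(path)

    fs = fs_hint
    label = None
    rec_id = path.stem
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs", fs)
        label = meta.get("label")
        rec_id = meta.get("recording_id", rec_id)
    if ext == ".npy":
        signal = np.load(path)
    elif ext in {".csv", ".tsv", ".txt"}:
        sep = "," if ext == ".csv" else None
        signal = np.loadtxt(path, delimiter=sep).T  # columns are channels
        signal = np.atleast_2d(signal)
    else:
        raise ValueError(f"unknown recording format {ext!r}")
    if fs is None:
        raise ValueError("sampling rate unknown: supply a sidecar or fs_hint")
    return Recording(signal=signal, fs=float(fs), label=label, recording_id=rec_id)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample_recording(rec: Recording, target_fs: float = 250.0) -> Recording:
    """Polyphase resampling (anti-aliased) to ``target_fs``.

    Identity when the rate already matches.  The output length is
    ``round(n_samples * target_fs / fs)``.
    """
    from scipy.signal import resample_poly

    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if math.isclose(rec.fs, target_fs):
        return Recording(signal=rec.signal.copy(), fs=rec.fs, label=rec.label,
                         recording_id=rec.recording_id)
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    out = resample_poly(rec.signal, up, down, axis=1)
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    if out.shape[1] > n_out:
        out = out[:, :n_out]
    elif out.shape[1] < n_out:
        out = np.pad(out, ((0, 0), (0, n_out - out.shape[1])), mode="edge")
    return Recording(signal=out, fs=target_fs, label=rec.label,
                     recording_id=rec.recording_id)


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

def write_manifest(recordings: list[Recording], paths: list[str | Path],
                   manifest_path: str | Path) -> pd.DataFrame:
    rows = [
        {"recording_id": r.recording_id, "label": r.label,
         "duration_s": r.duration_s, "fs": r.fs, "path": str(p)}
        for r, p in zip(recordings, paths)
    ]
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(manifest_path, sep="\t", index=False)
    return df


def read_manifest(manifest_path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path, sep="\t")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    if df["recording_id"].duplicated().any():
        raise ValueError("manifest recording_id values must be unique")
    bad = set(df["label"].dropna()) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"manifest contains unknown labels {sorted(bad)}")
    return df


def load_corpus(manifest_path: str | Path, fs_hint: float | None = None) -> list[Recording]:
    """Load every recording listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    recordings = []
    for row in df.itertuples():
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        rec = read_recording(p, fs_hint=fs_hint or row.fs)
        rec.label = row.label
        rec.recording_id = row.recording_id
        recordings.append(rec)
    return recordings
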