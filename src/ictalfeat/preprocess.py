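"""Broadband filtering, five-band decomposition, and sliding-window segmentation.

The processing order is: resample to the working rate, broadband bandpass
(0.5-100 Hz), decomposition into the five clinical bands with zero-phase
linear-phase FIR filters, then segmentation of the continuous filtered
record into 1 s windows with a 0.5 s step.  Filtering happens before
slicing so segment boundaries carry no extra edge transients.

FIR design is delegated to MNE's windowed-sinc (Hamming) filters, whose
default transition bandwidths are ``min(max(0.25 * f_edge, 2 Hz), f_edge)``
at the low edge and ``min(max(0.25 * f_edge, 2 Hz), nyquist - f_edge)`` at
the high edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import Recording


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges ({self.low_hz}, {self.high_hz})")


#: The five clinical bands, with the gaps (7-8, 12-13 Hz) left as printed.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
)

BAND_ORDER: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


@dataclass
class SegmentedBands:
    """Per-band segmented signal: ``bands[name]`` is segments x channels x samples."""

    bands: dict[str, np.ndarray]
    window_s: float
    step_s: float
    fs: float
    segment_start_times: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.segment_start_times)


def _filter(data: np.ndarray, fs: float, low: float | None, high: float | None) -> np.ndarray:
    import mne

    return mne.filter.filter_data(data, sfreq=fs, l_freq=low, h_freq=high,
                                  verbose="error")


def broadband_filter(rec: Recording, low: float = 0.5, high: float = 100.0) -> Recording:
    """Zero-phase FIR bandpass over the analysis band (default 0.5-100 Hz)."""
    if high >= rec.fs / 2:
        raise ValueError(f"high edge {high} Hz is at/above Nyquist ({rec.fs / 2} Hz)")
    filtered = _filter(rec.signal, rec.fs, low, high)
    return Recording(signal=filtered, fs=rec.fs, label=rec.label,
                     recording_id=rec.recording_id)


def decompose_bands(rec: Recording,
                    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                    ) -> dict[str, Recording]:
    """Filter the continuous record into one zero-phase FIR signal per band."""
    out: dict[str, Recording] = {}
    for band in bands:
        if band.high_hz >= rec.fs / 2:
            raise ValueError(
                f"band {band.name} high edge {band.high_hz} Hz is at/above "
                f"Nyquist ({rec.fs / 2} Hz)")
        filtered = _filter(rec.signal, rec.fs, band.low_hz, band.high_hz)
        out[band.name] = Recording(signal=filtered, fs=rec.fs, label=rec.label,
                                   recording_id=rec.recording_id)
    return out


def segment_signal(rec: Recording, window_s: float = 1.0,
                   step_s: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Slice into overlapping windows; trailing partial windows are dropped.

    Returns ``(segments, start_times)`` with segments shaped
    ``n_segments x channels x window_samples`` and
    ``n_segments = floor((n_samples - window) / step) + 1``.
    """
    window = int(round(window_s * rec.fs))
    step = int(round(step_s * rec.fs))
    if rec.n_samples < window:
        raise ValueError("too short to segment")
    if step < 1:
        raise ValueError("step must be at least one sample")
    n_segments = (rec.n_samples - window) // step + 1
    starts = np.arange(n_segments) * step
    segments = np.stack([rec.signal[:, s:s + window] for s in starts])
    return segments, starts / rec.fs


def segment_bands(band_recs: dict[str, Recording], window_s: float = 1.0,
                  step_s: float = 0.5) -> SegmentedBands:
    """Segment each band-filtered record with a shared window grid."""
    bands = {}
    start_times = None
    fs = None
    for name, rec in band_recs.items():
        segments, starts = segment_signal(rec, window_s, step_s)
        bands[name] = segments
        start_times = starts
        fs = rec.fs
    if start_times is None:
        raise ValueError("no bands supplied")
    return SegmentedBands(bands=bands, window_s=window_s, step_s=step_s,
                          fs=fs, segment_start_times=start_times)


def preprocess_recording(rec: Recording, *, target_fs: float = 250.0,
                         broadband: tuple[float, float] = (0.5, 100.0),
                         bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                         window_s: float = 1.0, step_s: float = 0.5,
                         ) -> SegmentedBands:
    """Full preprocessing chain: resample, broadband filter, band split, segment."""
    from .io import resample_recording

    rec = resample_recording(rec, target_fs)
    rec = broadband_filter(rec, *broadband)
    band_recs = decompose_bands(rec, bands)
    return segment_bands(band_recs, window_s, step_s)
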