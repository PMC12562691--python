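"""Core container for a labeled multichannel EEG recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six seizure-type codes, alphabetical (the fixed class order used
#: throughout for confusion matrices and probability columns).
CLASS_ORDER: tuple[str, ...] = ("ABSZ", "CPSZ", "FNSZ", "GNSZ", "TCSZ", "TNSZ")


@dataclass
class Recording:
    """One seizure EEG recording: ``signal`` is channels x samples in microvolts.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    fs : float
        Sampling rate in Hz.
    label : str or None
        Seizure-type code (one of :data:`CLASS_ORDER`), or None for
        unlabeled data.
    recording_id : str
        Opaque identifier used as the CV grouping key.
    """

    signal: np.ndarray
    fs: float
    label: str | None = None
    recording_id: str = field(default="rec")

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise ValueError("signal must be a channels x samples array")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.label is not None and self.label not in CLASS_ORDER:
            raise ValueError(
                f"unknown seizure-type label {self.label!r}; expected one of {CLASS_ORDER}"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs
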