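"""Synthetic ictal-EEG generator.

Real seizure corpora are access-restricted, so this module provides a
labeled stand-in with just enough electrophysiological structure for the
downstream pipeline to be exercised end to end: each seizure-type profile
pins a different distribution of power across the five clinical bands
(delta 1-4, theta 4-7, alpha 8-12, beta 13-30, gamma 30-80 Hz), optionally
adds a spike-wave train (the absence-seizure stand-in uses the classic
3 Hz fundamental) and Poisson-timed gamma bursts, and overlays white
sensor noise.  Channels share a common process (mixing weight 0.5) so that
channel averaging is not a no-op.

The profiles are deliberately simple signal models, not clinically
validated templates; they exist so that every extracted feature carries
class information and the classifiers have something to learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import CLASS_ORDER, Recording

BAND_EDGES: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 7.0),
    ("alpha", 8.0, 12.0),
    ("beta", 13.0, 30.0),
    ("gamma", 30.0, 80.0),
)


@dataclass
class SeizureTypeProfile:
    """Spectral recipe for one seizure type.

    ``band_power`` holds the five relative band-power weights
    (delta, theta, alpha, beta, gamma); they must sum to 1.
    ``spike_wave_hz`` adds a sharpened periodic transient at that
    fundamental, ``burst_rate`` is the expected number of gamma bursts per
    second, ``amplitude_uv`` the RMS scale of the oscillatory part and
    ``noise_sd_uv`` the additive white-noise SD, all in microvolts.
    """

    label: str
    band_power: tuple[float, float, float, float, float]
    spike_wave_hz: float | None = None
    burst_rate: float = 0.0
    amplitude_uv: float = 50.0
    noise_sd_uv: float = 5.0

    def __post_init__(self) -> None:
        bp = np.asarray(self.band_power, dtype=float)
        if bp.shape != (5,) or np.any(bp < 0):
            raise ValueError("band_power must be 5 nonnegative weights")
        if abs(bp.sum() - 1.0) > 1e-9:
            raise ValueError("band_power must sum to 1")
        if self.burst_rate < 0 or self.amplitude_uv < 0 or self.noise_sd_uv < 0:
            raise ValueError("rates and scales must be nonnegative")
        if self.spike_wave_hz is not None and self.spike_wave_hz <= 0:
            raise ValueError("spike_wave_hz must be positive")
        self.band_power = tuple(float(v) for v in bp)


def default_profiles() -> list[SeizureTypeProfile]:
    """One profile per seizure-type code, pairwise distinct in band power.

    The ABSZ stand-in carries the 3 Hz spike-wave fundamental with
    delta/theta dominance; the TNSZ stand-in is gamma-dominant with a high
    burst rate.
    """
    return [
        SeizureTypeProfile("ABSZ", (0.45, 0.30, 0.10, 0.10, 0.05),
                           spike_wave_hz=3.0, amplitude_uv=80.0, noise_sd_uv=6.0),
        SeizureTypeProfile("CPSZ", (0.20, 0.35, 0.25, 0.12, 0.08),
                           spike_wave_hz=6.0, amplitude_uv=55.0, noise_sd_uv=5.0),
        SeizureTypeProfile("FNSZ", (0.32, 0.23, 0.20, 0.15, 0.10),
                           amplitude_uv=60.0, noise_sd_uv=5.0),
        SeizureTypeProfile("GNSZ", (0.18, 0.20, 0.27, 0.22, 0.13),
                           burst_rate=0.3, amplitude_uv=70.0, noise_sd_uv=5.0),
        SeizureTypeProfile("TCSZ", (0.14, 0.14, 0.18, 0.34, 0.20),
                           burst_rate=1.0, amplitude_uv=95.0, noise_sd_uv=8.0),
        SeizureTypeProfile("TNSZ", (0.08, 0.10, 0.14, 0.26, 0.42),
                           burst_rate=2.5, amplitude_uv=50.0, noise_sd_uv=4.0),
    ]


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        low: float, high: float) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to [low, high] Hz via rFFT masking."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _spike_wave(rng: np.random.Generator, t: np.ndarray, f0: float) -> np.ndarray:
    """Sawtooth-sharpened sinusoid at fundamental ``f0`` (unit RMS)."""
    phase = rng.uniform(0, 2 * np.pi)
    # first four harmonics with 1/h decay -> spiky periodic transient
    x = sum((1.0 / h) * np.sin(2 * np.pi * h * f0 * t + h * phase) for h in range(1, 5))
    return x / np.sqrt(np.mean(x**2))


def _gamma_bursts(rng: np.random.Generator, t: np.ndarray, fs: float,
                  rate: float, amplitude: float) -> np.ndarray:
    """Gaussian-windowed 40-70 Hz tones at Poisson event times."""
    duration = t[-1] + 1.0 / fs
    n_events = rng.poisson(rate * duration)
    x = np.zeros_like(t)
    for _ in range(n_events):
        t0 = rng.uniform(0, duration)
        f = rng.uniform(40.0, 70.0)
        width = 0.05  # burst envelope SD, seconds
        env = np.exp(-0.5 * ((t - t0) / width) ** 2)
        x += amplitude * env * np.sin(2 * np.pi * f * (t - t0))
    return x


def _one_draw(rng: np.random.Generator, profile: SeizureTypeProfile,
              n: int, fs: float, t: np.ndarray) -> np.ndarray:
    """One realization of the oscillatory process (no sensor noise)."""
    x = np.zeros(n)
    for (name, low, high), w in zip(BAND_EDGES, profile.band_power):
        if w > 0:
            x += profile.amplitude_uv * np.sqrt(w) * _band_limited_noise(rng, n, fs, low, high)
    if profile.spike_wave_hz is not None:
        x += 0.9 * profile.amplitude_uv * _spike_wave(rng, t, profile.spike_wave_hz)
    if profile.burst_rate > 0:
        x += _gamma_bursts(rng, t, fs, profile.burst_rate, 0.6 * profile.amplitude_uv)
    return x


def simulate_recording(profile: SeizureTypeProfile, duration_s: float,
                       fs: float = 250.0, n_channels: int = 2,
                       seed: int = 0) -> Recording:
    """Simulate one labeled multichannel recording.

    Deterministic for fixed arguments.  Each channel mixes a common
    process with an independent draw (weight 0.5 each), so channels are
    correlated but not identical.
    """
    if duration_s < 1.0:
        raise ValueError("too short to segment: duration must be at least 1 s")
    if fs < 200:
        raise ValueError("sampling rate must be at least 200 Hz")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    common = _one_draw(rng, profile, n, fs, t)
    channels = np.empty((n_channels, n))
    for ch in range(n_channels):
        own = _one_draw(rng, profile, n, fs, t)
        channels[ch] = 0.5 * common + 0.5 * own
        if profile.noise_sd_uv > 0:
            channels[ch] += rng.normal(0, profile.noise_sd_uv, n)
    return Recording(signal=channels, fs=fs, label=profile.label,
                     recording_id=f"{profile.label}_seed{seed}")


def simulate_corpus(profiles: list[SeizureTypeProfile],
                    counts_per_class: dict[str, int],
                    duration_range_s: tuple[float, float] = (14.66, 60.0),
                    fs: float = 250.0, n_channels: int = 2,
                    seed: int = 0) -> list[Recording]:
    """Simulate an imbalanced labeled corpus.

    ``counts_per_class`` maps seizure-type code to the number of
    recordings; durations are drawn uniformly from ``duration_range_s``.
    Per-recording seeds are derived as ``seed + index`` so corpora of any
    size are reproducible.
    """
    if not counts_per_class:
        raise ValueError("counts_per_class is empty")
    by_label = {p.label: p for p in profiles}
    for lab, cnt in counts_per_class.items():
        if lab not in by_label:
            raise ValueError(f"no profile for label {lab!r}")
        if cnt < 1:
            raise ValueError(f"count for {lab!r} must be >= 1")
    dur_rng = np.random.default_rng(seed)
    lo, hi = duration_range_s
    recordings: list[Recording] = []
    index = 0
    for lab in sorted(counts_per_class):
        profile = by_label[lab]
        for i in range(counts_per_class[lab]):
            duration = float(dur_rng.uniform(lo, hi))
            rec = simulate_recording(profile, duration, fs=fs,
                                     n_channels=n_channels, seed=seed + index)
            rec.recording_id = f"{lab}_{i:04d}"
            recordings.append(rec)
            index += 1
    return recordings


#: Per-class recording counts of the study corpus this generator emulates.
PAPER_CLASS_COUNTS: dict[str, int] = {
    "FNSZ": 100, "ABSZ": 78, "CPSZ": 100, "TCSZ": 47, "GNSZ": 100, "TNSZ": 47,
}
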