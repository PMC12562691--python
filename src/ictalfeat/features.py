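"""The 13 per-band segment features and the 65-column feature matrix.

For every 1 s band-filtered segment the following are computed per channel
and averaged across channels:

* population mean, variance, skewness and *excess* kurtosis;
* sample entropy SampEn(m=2, r=0.2*SD) with Chebyshev distance and
  self-matches excluded (Richman-Moorman convention);
* five wavelet energies from a 4-level Daubechies-4 decomposition
  (E0 = level-4 approximation, E1..E4 = detail levels coarse to fine);
* the rescaled-range Hurst exponent over block sizes 2..20;
* Hjorth mobility and complexity.

Band-major ordering over (delta, theta, alpha, beta, gamma) yields the
65-dimensional feature vector per segment.  Degenerate (constant) segments
map to fixed conventional values so the matrix stays finite: moments
``(mean, 0, 0, 0)``, SampEn 0, Hurst 0.5, Hjorth ``(0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .preprocess import BAND_ORDER, SegmentedBands

FEATURE_ORDER: tuple[str, ...] = (
    "mean", "variance", "skewness", "kurtosis", "sample_entropy",
    "wavelet_energy_0", "wavelet_energy_1", "wavelet_energy_2",
    "wavelet_energy_3", "wavelet_energy_4",
    "hurst", "hjorth_mobility", "hjorth_complexity",
)


def feature_names(bands: tuple[str, ...] = BAND_ORDER) -> list[str]:
    """Band-major feature-column names, e.g. ``gamma_hjorth_complexity``."""
    return [f"{band}_{feat}" for band in bands for feat in FEATURE_ORDER]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampEnConfig:
    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1 or self.r_factor <= 0:
            raise ValueError("need m >= 1 and r_factor > 0")


@dataclass(frozen=True)
class HurstConfig:
    max_lag: int = 20
    min_lag: int = 2

    def __post_init__(self) -> None:
        if not 2 <= self.min_lag < self.max_lag:
            raise ValueError("need 2 <= min_lag < max_lag")


# ---------------------------------------------------------------------------
# Individual features
# ---------------------------------------------------------------------------

def stat_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, variance, skewness, excess kurtosis of a window."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    d = x - mu
    var = np.mean(d**2)
    if var <= 0:
        return float(mu), 0.0, 0.0, 0.0
    skew = np.mean(d**3) / var**1.5
    kurt = np.mean(d**4) / var**2 - 3.0
    return float(mu), float(var), float(skew), float(kurt)


def sample_entropy(x: np.ndarray, cfg: SampEnConfig = SampEnConfig()) -> float:
    """SampEn(m, r) in nats; r = r_factor * SD(x), Chebyshev distance.

    Template matching uses the N-m templates of length m and the N-m
    templates of length m+1, pairs counted once (i < j), self-matches
    excluded.  If no (m+1)-matches exist the Richman-Moorman cap
    ``ln((N-m)(N-m-1)) - ln 2`` is returned; a constant window returns 0.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    m = cfg.m
    if n <= m + 1:
        raise ValueError("window too short for the embedding dimension")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = cfg.r_factor * sd
    cap = np.log((n - m) * (n - m - 1)) - np.log(2.0)

    from numpy.lib.stride_tricks import sliding_window_view
    from scipy.spatial.distance import pdist

    tm1 = sliding_window_view(x, m + 1)          # (n-m) templates, length m+1
    tm = tm1[:, :m]                              # aligned length-m templates
    # condensed pairwise Chebyshev distances (each unordered pair once)
    match_m = pdist(tm, "chebyshev") <= r
    b = int(np.count_nonzero(match_m))
    if b == 0:
        return float(cap)
    dlast = pdist(tm1[:, -1:], "chebyshev")
    a = int(np.count_nonzero(match_m & (dlast <= r)))
    if a == 0:
        return float(cap)
    return float(-np.log(a / b))


def wavelet_energies(x: np.ndarray, mode: str = "symmetric") -> np.ndarray:
    """Energies of the 5 coefficient sets of a 4-level db4 decomposition.

    ``E0`` is the level-4 approximation energy; ``E1..E4`` are detail
    energies from coarsest (level 4) to finest (level 1).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("need at least 16 samples for a 4-level db4 transform")
    coeffs = pywt.wavedec(x, "db4", mode=mode, level=4)
    return np.array([float(np.sum(c**2)) for c in coeffs])


def hurst_rs(x: np.ndarray, cfg: HurstConfig = HurstConfig()) -> float:
    """Rescaled-range Hurst exponent.

    For each block size tau in ``min_lag..max_lag`` the signal is split
    into non-overlapping blocks; per block, R is the range of the
    cumulative mean-deviation sums and S the population SD; R/S is
    averaged over blocks with S > 0.  H is the least-squares slope of
    log mean(R/S) against log tau, clipped to [0, 1.5].  A constant
    signal returns 0.5 by convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= cfg.max_lag:
        raise ValueError("signal shorter than max_lag")
    log_tau, log_rs = [], []
    for tau in range(cfg.min_lag, cfg.max_lag + 1):
        n_blocks = n // tau
        blocks = x[: n_blocks * tau].reshape(n_blocks, tau)
        mean = blocks.mean(axis=1, keepdims=True)
        dev = np.cumsum(blocks - mean, axis=1)
        r = dev.max(axis=1) - dev.min(axis=1)
        s = blocks.std(axis=1)
        keep = s > 0
        if not np.any(keep):
            continue
        rs = float(np.mean(r[keep] / s[keep]))
        if rs > 0:
            log_tau.append(np.log(tau))
            log_rs.append(np.log(rs))
    if len(log_tau) < 2:
        return 0.5
    slope = np.polyfit(log_tau, log_rs, 1)[0]
    return float(np.clip(slope, 0.0, 1.5))


def hjorth(x: np.ndarray) -> tuple[float, float]:
    """Hjorth mobility and complexity (population variances of differences).

    Mobility = sqrt(Var(diff1)/Var(x)); Complexity =
    sqrt(Var(diff2)/Var(diff1)) / Mobility.  Zero-variance inputs map the
    affected outputs to 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    var0 = np.var(x)
    if var0 <= 0:
        return 0.0, 0.0
    d1 = np.diff(x)
    var1 = np.var(d1)
    mobility = float(np.sqrt(var1 / var0))
    if var1 <= 0:
        return mobility, 0.0
    d2 = np.diff(d1)
    var2 = np.var(d2)
    complexity = float(np.sqrt(var2 / var1) / mobility)
    return mobility, complexity


def segment_features(x: np.ndarray, sampen_cfg: SampEnConfig,
                     hurst_cfg: HurstConfig, wavelet_mode: str) -> np.ndarray:
    """The 13 features of one single-channel band segment, in canonical order."""
    mu, var, skew, kurt = stat_moments(x)
    se = sample_entropy(x, sampen_cfg)
    we = wavelet_energies(x, wavelet_mode)
    h = hurst_rs(x, hurst_cfg)
    mob, comp = hjorth(x)
    return np.array([mu, var, skew, kurt, se, *we, h, mob, comp])


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Segments x features, with per-segment labels and recording ids."""

    values: np.ndarray
    names: list[str]
    labels: np.ndarray
    group_ids: np.ndarray
    start_times: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.group_ids = np.asarray(self.group_ids)
        if self.values.shape[1] != len(self.names):
            raise ValueError("values/names width mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.start_times is None:
            self.start_times = np.full(len(self.values), np.nan)

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "start_s", self.start_times)
        df.insert(0, "label", self.labels)
        df.insert(0, "recording_id", self.group_ids)
        return df

    @classmethod
    def concat(cls, matrices: list["FeatureMatrix"]) -> "FeatureMatrix":
        if not matrices:
            raise ValueError("nothing to concatenate")
        names = matrices[0].names
        for m in matrices[1:]:
            if m.names != names:
                raise ValueError("feature-name mismatch")
        return cls(values=np.vstack([m.values for m in matrices]),
                   names=list(names),
                   labels=np.concatenate([m.labels for m in matrices]),
                   group_ids=np.concatenate([m.group_ids for m in matrices]),
                   start_times=np.concatenate([m.start_times for m in matrices]))


def extract_features(seg_bands: SegmentedBands, label: str | None = None,
                     recording_id: str = "rec", *,
                     sampen_cfg: SampEnConfig = SampEnConfig(),
                     hurst_cfg: HurstConfig = HurstConfig(),
                     wavelet_mode: str = "symmetric",
                     channel_agg: str = "mean") -> FeatureMatrix:
    """Compute the per-band features for every segment of one recording.

    Features are computed per channel then aggregated across channels
    (``mean`` by default, ``median``, or ``single:<index>``).
    """
    band_names = [b for b in BAND_ORDER if b in seg_bands.bands]
    if not band_names:
        band_names = list(seg_bands.bands)
    n_seg = seg_bands.n_segments
    if n_seg < 1:
        raise ValueError("no segments to extract features from")
    names = feature_names(tuple(band_names))
    values = np.empty((n_seg, len(names)))
    for bi, band in enumerate(band_names):
        segs = seg_bands.bands[band]  # seg x ch x samples
        for si in range(n_seg):
            per_channel = np.stack([
                segment_features(segs[si, ch], sampen_cfg, hurst_cfg, wavelet_mode)
                for ch in range(segs.shape[1])
            ])
            nf = len(FEATURE_ORDER)
            values[si, bi * nf:(bi + 1) * nf] = _aggregate(per_channel, channel_agg)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values produced")
    return FeatureMatrix(values=values, names=names,
                         labels=np.full(n_seg, label, dtype=object),
                         group_ids=np.full(n_seg, recording_id, dtype=object),
                         start_times=np.asarray(seg_bands.segment_start_times))


def _aggregate(per_channel: np.ndarray, channel_agg: str) -> np.ndarray:
    if channel_agg == "mean":
        return per_channel.mean(axis=0)
    if channel_agg == "median":
        return np.median(per_channel, axis=0)
    if channel_agg.startswith("single:"):
        return per_channel[int(channel_agg.split(":", 1)[1])]
    raise ValueError(f"unknown channel aggregation {channel_agg!r}")


def standardize(fm: FeatureMatrix, fit_rows: np.ndarray | None = None,
                ) -> tuple[FeatureMatrix, np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring with parameters fitted on ``fit_rows`` only.

    Returns ``(standardized_matrix, means, sds, constant_mask)``.  Columns
    whose fitted SD is below 1e-12 are set to 0 and flagged in
    ``constant_mask`` so downstream selection cannot divide by zero.
    """
    if fit_rows is None:
        fit_rows = np.arange(fm.n_segments)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("empty fit set")
    sub = fm.values[fit_rows]
    means = sub.mean(axis=0)
    sds = sub.std(axis=0)
    constant = sds < 1e-12
    safe = np.where(constant, 1.0, sds)
    z = (fm.values - means) / safe
    z[:, constant] = 0.0
    out = FeatureMatrix(values=z, names=list(fm.names), labels=fm.labels,
                        group_ids=fm.group_ids, start_times=fm.start_times)
    return out, means, sds, constant


def apply_standardization(fm: FeatureMatrix, means: np.ndarray, sds: np.ndarray,
                          constant: np.ndarray) -> FeatureMatrix:
    """Apply previously fitted z-scoring parameters to held-out rows."""
    safe = np.where(constant, 1.0, sds)
    z = (fm.values - means) / safe
    z[:, constant] = 0.0
    return FeatureMatrix(values=z, names=list(fm.names), labels=fm.labels,
                         group_ids=fm.group_ids, start_times=fm.start_times)
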