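"""Time-domain, frequency-domain and wavelet features of averaged ERP epochs.

For each channel, six time-domain features are measured on the signal
X(t) restricted to the P300 window [t1, t2]:

    MAA = max X(t)                 maximum amplitude (uV)
    MIA = min X(t)                 minimum amplitude (uV)
    LAT = argmax-time of X(t)      latency of the maximum (ms, earliest tie)
    RLM = MAA / LAT                ratio of maximum to latency (uV/ms)
    PA  = sum (X + |X|) / 2        positive area (summed positive samples)
    DPN = MAA - MIA                peak-to-trough difference (uV)

plus two frequency-domain features of the window's power spectral
density Y(f):

    MF = argmax_f Y(f)             peak frequency (Hz, lowest tie)
    AF = sum f Y(f) / sum Y(f)     spectral centroid over [0, min(125, fs/2)] Hz

and 23 wavelet features: the delta-band (deepest approximation)
coefficients of a five-level quadratic B-spline DWT of the full
post-stimulus epoch, padded/truncated to fixed length.  That makes 31
features per channel and 62 x 31 = 1922 per sample under the default
montage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthcohort import EpochSet
from .wavelet import FilterBank, build_bspline_bank, delta_coefficients, dwt_multilevel

__all__ = [
    "P300Window",
    "FeatureTable",
    "TIME_FEATURES",
    "FREQ_FEATURES",
    "FEATURE_NAMES",
    "time_features",
    "power_spectrum",
    "freq_features",
    "extract_sample",
    "build_feature_table",
]

TIME_FEATURES = ("MAA", "MIA", "LAT", "RLM", "PA", "DPN")
FREQ_FEATURES = ("MF", "AF")
N_WAVELET = 23
FEATURE_NAMES: tuple[str, ...] = TIME_FEATURES + FREQ_FEATURES + tuple(
    f"W{i:02d}" for i in range(N_WAVELET)
)
N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES)  # 31
AF_UPPER_HZ = 125.0  # spectral-centroid integration limit


@dataclass(frozen=True)
class P300Window:
    """Post-stimulus analysis window [t1, t2] in ms (default 250-500 ms)."""

    t1: float = 250.0
    t2: float = 500.0

    def __post_init__(self) -> None:
        if not 0 <= self.t1 < self.t2:
            raise ValueError("need 0 <= t1 < t2")
        if self.t1 <= 0:
            raise ValueError("latency ratio undefined at onset: t1 must be > 0")


@dataclass
class FeatureTable:
    """Samples x features matrix with per-column (channel, feature) metadata."""

    matrix: np.ndarray
    columns: list[tuple[str, str]]
    labels: np.ndarray
    subject_id: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column metadata must match matrix width")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("labels must match sample count")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channel_slice(self, channel: str) -> np.ndarray:
        """Column indices of one channel's 31 features."""
        idx = [i for i, (ch, _) in enumerate(self.columns) if ch == channel]
        if not idx:
            raise ValueError(f"unknown channel {channel!r}")
        return np.asarray(idx)

    def restrict(self, channels) -> "FeatureTable":
        idx = np.concatenate([self.channel_slice(ch) for ch in channels])
        return FeatureTable(
            matrix=self.matrix[:, idx],
            columns=[self.columns[i] for i in idx],
            labels=self.labels.copy(),
            subject_id=self.subject_id.copy(),
            channel_names=tuple(channels),
        )

    def as_sequences(self) -> np.ndarray:
        """(samples, channels, 31) view for sequence classifiers."""
        return self.matrix.reshape(self.n_samples, self.n_channels, N_FEATURES_PER_CHANNEL)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[f"{ch}.{ft}" for ch, ft in self.columns])
        df["label"] = self.labels
        df["subject_id"] = self.subject_id
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        subjects = df.pop("subject_id").to_numpy()
        columns = [tuple(c.split(".", 1)) for c in df.columns]
        channels = list(dict.fromkeys(ch for ch, _ in columns))
        return cls(df.to_numpy(float), columns, labels, subjects, tuple(channels))


def time_features(x: np.ndarray, times: np.ndarray):
    """(MAA, MIA, LAT, RLM, PA, DPN) of the windowed signal ``x``.

    ``times`` are the sample times in ms from stimulus onset; ties for the
    maximum resolve to the earliest sample.  Works on a trailing sample
    axis of any shape.
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    if x.shape[-1] == 0 or x.shape[-1] != times.shape[-1]:
        raise ValueError("window must be nonempty and match times")
    if times[0] <= 0:
        raise ValueError("latency ratio undefined at onset: window must start after 0 ms")
    maa = x.max(axis=-1)
    mia = x.min(axis=-1)
    lat = times[np.argmax(x, axis=-1)]
    rlm = maa / lat
    pa = ((x + np.abs(x)) / 2.0).sum(axis=-1)
    dpn = maa - mia
    return maa, mia, lat, rlm, pa, dpn


def power_spectrum(x: np.ndarray, fs: float):
    """Single-taper periodogram of the window: (freqs, Y) with Y >= 0.

    Density scaling, so sum(Y) * df recovers the window's power
    (Parseval).  The mean is kept: for an ERP window the DC/near-DC mass
    is exactly the delta-band content the centroid should see.  Runs
    along the trailing axis.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 8:
        raise ValueError(f"window too short for a spectrum: {x.shape[-1]} < 8 samples")
    freqs, pxx = sps.periodogram(x, fs=fs, detrend=False, axis=-1)
    return freqs, pxx


def freq_features(Y: np.ndarray, freqs: np.ndarray):
    """(MF, AF): peak frequency and spectral centroid of a spectrum.

    MF takes the lowest frequency on ties; AF integrates over
    [0, min(125, fs/2)] Hz.  An all-zero spectrum has no centroid.
    """
    Y = np.asarray(Y, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if Y.shape[-1] == 0:
        raise ValueError("empty spectrum")
    band = freqs <= AF_UPPER_HZ
    Yb = Y[..., band]
    fb = freqs[band]
    total = Yb.sum(axis=-1)
    if np.any(total <= 0):
        raise ValueError("degenerate spectrum: no power, centroid undefined")
    mf = freqs[np.argmax(Y, axis=-1)]
    af = (fb * Yb).sum(axis=-1) / total
    return mf, af


def _channel_features(
    data: np.ndarray, times: np.ndarray, fs: float, window: P300Window, bank: FilterBank
) -> np.ndarray:
    """Vectorised core: (..., samples) epoch data -> (..., 31) features."""
    wmask = (times >= window.t1) & (times <= window.t2)
    if not wmask.any():
        raise ValueError(f"P300 window {window} contains no samples")
    seg = data[..., wmask]
    tseg = times[wmask]
    maa, mia, lat, rlm, pa, dpn = time_features(seg, tseg)
    freqs, pxx = power_spectrum(seg, fs)
    mf, af = freq_features(pxx, freqs)
    post = data[..., times >= 0]
    dec = dwt_multilevel(post, bank, levels=5, fs=fs)
    wav = delta_coefficients(dec, N_WAVELET)
    return np.stack([maa, mia, lat, rlm, pa, dpn, mf, af], axis=-1).astype(float), wav


def extract_sample(
    avg_epoch: np.ndarray,
    times: np.ndarray,
    fs: float = 250.0,
    window: P300Window | None = None,
    bank: FilterBank | None = None,
) -> np.ndarray:
    """Feature vector of one averaged epoch (channels x samples) -> (C*31,).

    Channels are concatenated in montage order: for each channel the six
    time features, two frequency features and 23 delta-band wavelet
    coefficients, in that fixed order.
    """
    avg_epoch = np.asarray(avg_epoch, dtype=float)
    if avg_epoch.ndim != 2:
        raise ValueError("avg_epoch must be (channels, samples)")
    window = window or P300Window()
    bank = bank or build_bspline_bank()
    scalar, wav = _channel_features(avg_epoch, np.asarray(times, float), fs, window, bank)
    return np.concatenate([scalar, wav], axis=-1).reshape(-1)


def build_feature_table(
    epochs: EpochSet,
    window: P300Window | None = None,
    bank: FilterBank | None = None,
) -> FeatureTable:
    """Extract the full samples x (channels*31) table from averaged epochs."""
    window = window or P300Window()
    bank = bank or build_bspline_bank()
    scalar, wav = _channel_features(
        epochs.data.astype(float), epochs.times, epochs.fs, window, bank
    )
    feats = np.concatenate([scalar, wav], axis=-1)  # (n, C, 31)
    n = feats.shape[0]
    columns = [(ch, ft) for ch in epochs.channel_names for ft in FEATURE_NAMES]
    return FeatureTable(
        matrix=feats.reshape(n, -1),
        columns=columns,
        labels=epochs.group.copy(),
        subject_id=epochs.subject_id.copy(),
        channel_names=tuple(epochs.channel_names),
    )
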