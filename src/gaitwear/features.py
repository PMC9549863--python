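"""Per-window feature extraction and per-subject standardization.

Each sensor contributes 134 features per window:

* for each tri-axial channel (posture acceleration, activity acceleration,
  filtered gyro): 13 per-axis statistics — mean, variance (population),
  min, max, range, median, interquartile range, RMS, skewness, kurtosis
  (excess), spectral energy, spectral entropy, dominant frequency — times
  3 axes, plus the 3 pairwise inter-axis Pearson correlations: 42 per
  channel, 126 total;
* for the filtered barometric altitude: mean, variance, min, max, range,
  least-squares slope, net change (last − first), RMS of first
  differences: 8.

Spectral features use the magnitude spectrum of the unpadded 128-sample
window with a Hann taper; the DC bin is excluded from energy, entropy and
the dominant-frequency search (bin resolution fs/128 ≈ 0.39 Hz at 50 Hz).

Features are standardized within subject to zero mean and unit variance
using the population (1/n) variance; a zero-variance feature maps to 0.
Because normalization is strictly within-subject it leaks nothing across
subjects under leave-one-subject-out evaluation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocessing import FilterConfig, DEFAULT_FILTERS, FilteredChannels, preprocess_stream
from .recordings import RecordingSession, resolve_locations
from .windows import DEFAULT_WINDOW, LabeledWindow

TRIAXIAL_CHANNELS = ("posture_acc", "activity_acc", "gyro_filt")
AXES = ("x", "y", "z")
AXIS_STATS = ("mean", "var", "min", "max", "range", "median", "iqr", "rms",
              "skew", "kurtosis", "spec_energy", "spec_entropy", "dom_freq")
CORR_PAIRS = (("x", "y"), ("x", "z"), ("y", "z"))
BARO_STATS = ("mean", "var", "min", "max", "range", "slope", "net_change",
              "diff_rms")

FEATURES_PER_SENSOR = (len(AXIS_STATS) * 3 + len(CORR_PAIRS)) * len(TRIAXIAL_CHANNELS) \
    + len(BARO_STATS)  # 42*3 + 8 = 134

_EPS = 1e-12


def sensor_feature_names() -> list[str]:
    """The 134 per-sensor feature names, in extraction order."""
    names: list[str] = []
    for channel in TRIAXIAL_CHANNELS:
        for axis in AXES:
            names.extend(f"{channel}_{axis}_{stat}" for stat in AXIS_STATS)
        names.extend(f"{channel}_corr_{a}{b}" for a, b in CORR_PAIRS)
    names.extend(f"baro_{stat}" for stat in BARO_STATS)
    return names


def feature_registry() -> pd.DataFrame:
    """Machine-readable table of the per-sensor features (name, channel, stat)."""
    rows = []
    for name in sensor_feature_names():
        if name.startswith("baro_"):
            rows.append({"name": name, "channel": "baro_filt",
                         "axis": "", "stat": name.removeprefix("baro_")})
        else:
            channel = next(c for c in TRIAXIAL_CHANNELS if name.startswith(c))
            rest = name.removeprefix(channel + "_")
            if rest.startswith("corr_"):
                rows.append({"name": name, "channel": channel,
                             "axis": rest.removeprefix("corr_"), "stat": "corr"})
            else:
                axis, stat = rest.split("_", 1)
                rows.append({"name": name, "channel": channel,
                             "axis": axis, "stat": stat})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vectorized statistics (windows stacked on axis 0)

def _axis_features(w: np.ndarray, fs: float) -> np.ndarray:
    """13 statistics per window for one axis. w: (n_windows, W)."""
    n, W = w.shape
    mean = w.mean(axis=1)
    var = w.var(axis=1)
    mn = w.min(axis=1)
    mx = w.max(axis=1)
    rng = mx - mn
    med = np.median(w, axis=1)
    q75, q25 = np.percentile(w, [75, 25], axis=1)
    iqr = q75 - q25
    rms = np.sqrt(np.mean(w ** 2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant windows: scipy warns about precision; moments default to 0
        warnings.simplefilter("ignore", RuntimeWarning)
        sk = np.nan_to_num(stats.skew(w, axis=1, bias=True))
        ku = np.nan_to_num(stats.kurtosis(w, axis=1, fisher=True, bias=True))
    taper = np.hanning(W)
    spec = np.abs(np.fft.rfft(w * taper, axis=1)) ** 2
    power = spec[:, 1:]  # DC excluded
    total = power.sum(axis=1)
    energy = total / W
    safe_total = np.where(total > _EPS, total, 1.0)
    p = power / safe_total[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        ent = -np.sum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    ent = np.where(total > _EPS, ent, 0.0)
    dom = np.where(total > _EPS,
                   (np.argmax(power, axis=1) + 1) * fs / W, 0.0)
    return np.column_stack([mean, var, mn, mx, rng, med, iqr, rms, sk, ku,
                            energy, ent, dom])


def _pairwise_corr(w3: np.ndarray) -> np.ndarray:
    """Pearson correlations of axis pairs. w3: (n, W, 3) -> (n, 3).

    A constant axis yields correlation 0 (flagged convention).
    """
    c = w3 - w3.mean(axis=1, keepdims=True)
    sd = c.std(axis=1)
    out = np.empty((w3.shape[0], len(CORR_PAIRS)))
    pair_idx = {"x": 0, "y": 1, "z": 2}
    for k, (a, b) in enumerate(CORR_PAIRS):
        i, j = pair_idx[a], pair_idx[b]
        cov = np.mean(c[:, :, i] * c[:, :, j], axis=1)
        denom = sd[:, i] * sd[:, j]
        out[:, k] = np.where(denom > _EPS, cov / np.where(denom > _EPS, denom, 1.0), 0.0)
    return out


def _baro_features(w: np.ndarray, fs: float) -> np.ndarray:
    """8 statistics per window for the barometric channel. w: (n, W)."""
    n, W = w.shape
    mean = w.mean(axis=1)
    var = w.var(axis=1)
    mn = w.min(axis=1)
    mx = w.max(axis=1)
    rng = mx - mn
    t = np.arange(W) / fs
    tc = t - t.mean()
    slope = (w - mean[:, None]) @ tc / np.sum(tc ** 2)
    net = w[:, -1] - w[:, 0]
    diff_rms = np.sqrt(np.mean(np.diff(w, axis=1) ** 2, axis=1))
    return np.column_stack([mean, var, mn, mx, rng, slope, net, diff_rms])


def _windowed(x: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    """Stack window slices: (N, ...) -> (n_windows, window, ...)."""
    idx = starts[:, None] + np.arange(window)[None, :]
    return x[idx]


def extract_windowed_sensor_features(channels: FilteredChannels,
                                     starts: np.ndarray,
                                     window: int = DEFAULT_WINDOW) -> np.ndarray:
    """134-feature rows for every window start of one sensor."""
    starts = np.asarray(starts, dtype=int)
    fs = channels.sample_rate_hz
    blocks: list[np.ndarray] = []
    for name in TRIAXIAL_CHANNELS:
        sig = getattr(channels, name)
        w3 = _windowed(sig, starts, window)
        blocks.extend(_axis_features(w3[:, :, ax], fs) for ax in range(3))
        blocks.append(_pairwise_corr(w3))
    blocks.append(_baro_features(_windowed(channels.baro_filt, starts, window), fs))
    out = np.concatenate(blocks, axis=1)
    assert out.shape[1] == FEATURES_PER_SENSOR
    return out


def extract_sensor_features(channels: FilteredChannels, fs: float | None = None
                            ) -> np.ndarray:
    """The 134-feature vector of a single window-length channel slice."""
    n = len(channels)
    if fs is not None and fs != channels.sample_rate_hz:
        channels = dataclasses.replace(channels, sample_rate_hz=fs)
    return extract_windowed_sensor_features(channels, np.array([0]), window=n)[0]


# ---------------------------------------------------------------------------
# Feature matrices

@dataclasses.dataclass
class FeatureMatrix:
    """Windows x features matrix with name and subject provenance."""

    values: np.ndarray
    feature_names: list[str]
    subject_ids: np.ndarray
    windows: list[LabeledWindow] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values shape inconsistent with feature_names")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        return df


def extract_features(session: RecordingSession, config_id: str,
                     windows: list[LabeledWindow],
                     filter_config: FilterConfig = DEFAULT_FILTERS,
                     preprocessed: dict[str, FilteredChannels] | None = None
                     ) -> FeatureMatrix:
    """Concatenate per-sensor feature blocks in canonical sensor order.

    For the unilateral configurations (C/D) the resolved physical side
    differs per subject, so feature names use side-neutral roles ("wrist",
    "ankle") to keep columns aligned across subjects.
    """
    locations = resolve_locations(config_id, session.affected_side)
    starts = np.asarray([w.start for w in windows], dtype=int)
    wlen = windows[0].length if windows else DEFAULT_WINDOW
    per_sensor = sensor_feature_names()
    names: list[str] = []
    blocks: list[np.ndarray] = []
    for loc in locations:
        label = loc.split("_")[0] if config_id in ("C", "D") else loc
        names.extend(f"{label}_{n}" for n in per_sensor)
        if preprocessed is not None and loc in preprocessed:
            channels = preprocessed[loc]
        else:
            channels = preprocess_stream(session.streams[loc], filter_config)
        if len(windows) == 0:
            blocks.append(np.empty((0, FEATURES_PER_SENSOR)))
        else:
            blocks.append(extract_windowed_sensor_features(channels, starts, wlen))
    values = (np.concatenate(blocks, axis=1) if blocks
              else np.empty((len(windows), 0)))
    subject_ids = np.asarray([session.subject_id] * len(windows), dtype=object)
    return FeatureMatrix(values=values, feature_names=names,
                         subject_ids=subject_ids, windows=list(windows))


# ---------------------------------------------------------------------------
# Per-subject standardization

@dataclasses.dataclass
class StandardizationStats:
    """Per-subject mean and population SD per feature."""

    mean: dict
    std: dict


def _subject_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sigma = np.sqrt(np.mean((x - mu) ** 2, axis=0))  # population (1/n)
    return mu, sigma


def standardize_per_subject(matrix: FeatureMatrix
                            ) -> tuple[FeatureMatrix, StandardizationStats]:
    """Zero-mean/unit-variance per subject; zero-variance features map to 0."""
    values = matrix.values.copy()
    means: dict = {}
    stds: dict = {}
    for subject in pd.unique(matrix.subject_ids):
        mask = matrix.subject_ids == subject
        if mask.sum() < 2:
            raise ValueError(
                f"subject {subject!r} has fewer than 2 windows; cannot standardize")
        mu, sigma = _subject_stats(values[mask])
        means[subject] = mu
        stds[subject] = sigma
        safe = np.where(sigma > 0, sigma, 1.0)
        std_block = (values[mask] - mu) / safe
        std_block[:, sigma == 0] = 0.0
        values[mask] = std_block
    out = FeatureMatrix(values=values, feature_names=list(matrix.feature_names),
                        subject_ids=matrix.subject_ids.copy(),
                        windows=matrix.windows)
    return out, StandardizationStats(mean=means, std=stds)


class SubjectStandardizer(BaseEstimator, TransformerMixin):
    """Group-wise (per-subject) standardizer with the estimator interface.

    ``fit(X, subject_ids=...)`` learns per-subject means and population
    SDs; ``transform`` standardizes rows using their subject's statistics.
    Unknown subjects at transform time raise.
    """

    def fit(self, X, y=None, *, subject_ids=None):
        X = np.asarray(X, dtype=float)
        if subject_ids is None:
            raise ValueError("subject_ids is required")
        subject_ids = np.asarray(subject_ids, dtype=object)
        self.mean_: dict = {}
        self.std_: dict = {}
        for subject in pd.unique(subject_ids):
            block = X[subject_ids == subject]
            if len(block) < 2:
                raise ValueError(
                    f"subject {subject!r} has fewer than 2 windows; cannot standardize")
            self.mean_[subject], self.std_[subject] = _subject_stats(block)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, subject_ids=None):
        X = np.asarray(X, dtype=float)
        if subject_ids is None:
            raise ValueError("subject_ids is required")
        subject_ids = np.asarray(subject_ids, dtype=object)
        out = np.empty_like(X)
        for subject in pd.unique(subject_ids):
            if subject not in self.mean_:
                raise ValueError(f"unseen subject {subject!r}")
            mask = subject_ids == subject
            mu, sigma = self.mean_[subject], self.std_[subject]
            safe = np.where(sigma > 0, sigma, 1.0)
            block = (X[mask] - mu) / safe
            block[:, sigma == 0] = 0.0
            out[mask] = block
        return out

    def fit_transform(self, X, y=None, *, subject_ids=None):
        return self.fit(X, subject_ids=subject_ids).transform(
            X, subject_ids=subject_ids)
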