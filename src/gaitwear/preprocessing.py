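"""Decompose raw sensor streams into the four filtered time-series.

Each sensor yields posture acceleration (gravity / orientation band),
activity acceleration (body-movement band), low-passed angular rate, and a
despiked low-passed barometric altitude. All filters are order-2
Butterworth applied forward-backward (zero phase); the posture/activity
split sits at 0.5 Hz and the upper movement band at 11 Hz — standard
choices for 50 Hz human-activity data, kept in one config block so they
are auditable and overridable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, signal

from .recordings import SensorStream


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    """Filter constants (Hz unless noted). Defaults suit 50 Hz streams."""

    posture_cutoff_hz: float = 0.5
    activity_band_hz: tuple[float, float] = (0.5, 11.0)
    gyro_cutoff_hz: float = 11.0
    baro_cutoff_hz: float = 0.5
    baro_median_window_s: float = 0.5
    order: int = 2


DEFAULT_FILTERS = FilterConfig()

#: Shortest segment that can be filtered stably (samples).
MIN_SAMPLES = 25


@dataclasses.dataclass
class FilteredChannels:
    """The four derived per-sensor time-series."""

    posture_acc: np.ndarray   # N x 3, m/s^2
    activity_acc: np.ndarray  # N x 3, m/s^2
    gyro_filt: np.ndarray     # N x 3, deg/s
    baro_filt: np.ndarray     # N, meters
    sample_rate_hz: float

    def __len__(self) -> int:
        return len(self.baro_filt)


def _check_length(x: np.ndarray) -> None:
    if len(x) < MIN_SAMPLES:
        raise ValueError(f"segment too short: {len(x)} < {MIN_SAMPLES} samples")


def _zero_phase(sos: np.ndarray, x: np.ndarray, fs: float,
                lowest_cutoff_hz: float) -> np.ndarray:
    # odd-reflection padding of ~3 filter time constants keeps ramps and
    # edges sane; scipy's default pad is far too short for sub-Hz cutoffs
    padlen = min(len(x) - 1, max(9, int(round(3 * fs / lowest_cutoff_hz))))
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def decompose_acceleration(accel: np.ndarray, fs: float,
                           config: FilterConfig = DEFAULT_FILTERS
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Split raw acceleration into posture (gravity) and activity bands.

    Posture: zero-phase low-pass at ``posture_cutoff_hz``. Activity:
    zero-phase band-pass over ``activity_band_hz``. Both preserve length.
    """
    accel = np.asarray(accel, dtype=float)
    _check_length(accel)
    if not fs > 2 * config.activity_band_hz[1]:
        raise ValueError("sampling rate must exceed twice the upper cutoff")
    sos_lo = signal.butter(config.order, config.posture_cutoff_hz,
                           btype="lowpass", fs=fs, output="sos")
    sos_bp = signal.butter(config.order, config.activity_band_hz,
                           btype="bandpass", fs=fs, output="sos")
    return (_zero_phase(sos_lo, accel, fs, config.posture_cutoff_hz),
            _zero_phase(sos_bp, accel, fs, config.activity_band_hz[0]))


def filter_gyro(gyro: np.ndarray, fs: float,
                config: FilterConfig = DEFAULT_FILTERS) -> np.ndarray:
    """Zero-phase low-pass of angular rate at ``gyro_cutoff_hz``."""
    gyro = np.asarray(gyro, dtype=float)
    _check_length(gyro)
    sos = signal.butter(config.order, config.gyro_cutoff_hz,
                        btype="lowpass", fs=fs, output="sos")
    return _zero_phase(sos, gyro, fs, config.gyro_cutoff_hz)


def filter_baro(baro_alt: np.ndarray, fs: float,
                config: FilterConfig = DEFAULT_FILTERS) -> np.ndarray:
    """Despike (0.5 s moving median) then zero-phase low-pass altitude.

    The moving median removes the step artifacts of the altimeter's 10-cm
    quantization; the low-pass keeps slow ramps (stair bouts) intact, so
    net altitude change over an interval survives within a few cm.
    """
    baro_alt = np.asarray(baro_alt, dtype=float).reshape(-1)
    _check_length(baro_alt)
    win = max(3, int(round(config.baro_median_window_s * fs)) | 1)
    # odd (anti-symmetric) extension keeps ramps unbiased at the edges
    k = win // 2
    left = 2 * baro_alt[0] - baro_alt[k:0:-1]
    right = 2 * baro_alt[-1] - baro_alt[-2:-k - 2:-1]
    padded = np.concatenate([left, baro_alt, right])
    despiked = ndimage.median_filter(padded, size=win, mode="nearest")[k:-k]
    sos = signal.butter(config.order, config.baro_cutoff_hz,
                        btype="lowpass", fs=fs, output="sos")
    return _zero_phase(sos, despiked, fs, config.baro_cutoff_hz)


def preprocess_stream(stream: SensorStream,
                      config: FilterConfig = DEFAULT_FILTERS) -> FilteredChannels:
    """Compute all four filtered series for one sensor stream."""
    fs = stream.sample_rate_hz
    posture, activity = decompose_acceleration(stream.accel, fs, config)
    return FilteredChannels(
        posture_acc=posture,
        activity_acc=activity,
        gyro_filt=filter_gyro(stream.gyro, fs, config),
        baro_filt=filter_baro(stream.baro_alt, fs, config),
        sample_rate_hz=fs)
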