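"""Filtering and window segmentation for raw EMG."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class WindowSpec:
    """Overlapping analysis windows.

    ``overlap_ms`` is the literal overlap between consecutive windows, so
    the hop is ``window_ms - overlap_ms`` (200/50 ms -> 150 ms hop).  Some
    of the myoelectric literature instead quotes the *increment*; pass
    ``overlap_ms = window_ms - increment_ms`` to get that convention.
    Sample counts are floored so a window never exceeds the requested
    duration.
    """

    fs: float
    window_ms: float = 200.0
    overlap_ms: float = 50.0

    def __post_init__(self):
        if not 0 <= self.overlap_ms < self.window_ms:
            raise ValueError("need 0 <= overlap_ms < window_ms")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.window_samples < 2:
            raise ValueError("window shorter than 2 samples")
        if self.step_samples < 1:
            raise ValueError("step shorter than 1 sample")

    @property
    def window_samples(self) -> int:
        return int(np.floor(self.window_ms * self.fs / 1000.0))

    @property
    def step_samples(self) -> int:
        return int(np.floor((self.window_ms - self.overlap_ms)
                            * self.fs / 1000.0))

    def n_windows(self, n_samples: int) -> int:
        if n_samples < self.window_samples:
            raise ValueError(
                f"{n_samples} samples is shorter than one "
                f"{self.window_samples}-sample window")
        return (n_samples - self.window_samples) // self.step_samples + 1


def _as_2d(samples: np.ndarray) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("samples must be 1-D or time x channels")
    return x


def bandpass_filter(samples: np.ndarray, fs: float, low: float = 20.0,
                    high: float = 500.0, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward application squares the magnitude response (the
    analysis is offline, so linear phase costs nothing); the effective
    roll-off is therefore twice the nominal order.
    """
    x = _as_2d(samples)
    if not 0 < low < high < fs / 2:
        raise ValueError("need 0 < low < high < fs/2")
    sos = signal.butter(order, (low, high), btype="bandpass", fs=fs,
                        output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[0] <= padlen:
        raise ValueError(
            f"recording of {x.shape[0]} samples is shorter than the filter "
            f"warm-up length {padlen}")
    y = signal.sosfiltfilt(sos, x, axis=0)
    return y if np.asarray(samples).ndim == 2 else y[:, 0]


def notch_filter(samples: np.ndarray, fs: float, freq: float = 50.0,
                 q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch for power-line interference."""
    x = _as_2d(samples)
    if not 0 < freq < fs / 2:
        raise ValueError("need 0 < freq < fs/2")
    if q <= 0:
        raise ValueError("q must be positive")
    b, a = signal.iirnotch(freq, q, fs=fs)
    padlen = 3 * max(len(a), len(b))
    if x.shape[0] <= padlen:
        raise ValueError("recording shorter than the filter warm-up length")
    y = signal.filtfilt(b, a, x, axis=0)
    return y if np.asarray(samples).ndim == 2 else y[:, 0]


def segment_windows(samples: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Slice a recording into overlapping windows.

    Returns an array of shape ``(n_windows, window_samples, n_channels)``;
    the trailing remainder that does not fill a window is discarded.
    """
    x = _as_2d(samples)
    n = x.shape[0]
    w, s = spec.window_samples, spec.step_samples
    count = spec.n_windows(n)
    view = np.lib.stride_tricks.sliding_window_view(x, w, axis=0)
    # view: (n - w + 1, channels, w) -> stride and reorder
    return np.ascontiguousarray(view[::s][:count].transpose(0, 2, 1))
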