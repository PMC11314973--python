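"""Hudgins time-domain features plus Willison amplitude.

Five per-window, per-channel descriptors: mean absolute value (MAV),
waveform length (WL), zero crossings (ZC), slope sign changes (SSC) and
Willison amplitude (WAMP).  MAV and WL scale linearly with signal
amplitude; the three counts are scale-free at ``eps = 0`` and otherwise
gated by an amplitude threshold.  Because amplitude units are arbitrary,
the package derives ``eps`` from the rest-class signal RMS rather than
using a fixed absolute value (see :func:`rest_rms_eps`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

FEATURE_NAMES = ("MAV", "WL", "ZC", "SSC", "WAMP")
LABEL_COLUMNS = ("subject", "factor_kind", "factor_level", "motion", "trial")

#: default eps as a fraction of the rest-class per-channel RMS
DEFAULT_EPS_SCALE = 0.01


def _check_window(x, min_len: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D window")
    if x.shape[0] < min_len:
        raise ValueError(f"window must have at least {min_len} samples")
    return x


def mav(x) -> float:
    """Mean absolute value: ``(1/N) * sum |x_i|``."""
    return float(np.mean(np.abs(_check_window(x, 1))))


def wl(x) -> float:
    """Waveform length: ``sum |x_{i+1} - x_i|``."""
    return float(np.sum(np.abs(np.diff(_check_window(x, 2)))))


def zc(x, eps: float = 0.0) -> int:
    """Zero crossings: sign changes whose step also clears ``eps``."""
    x = _check_window(x, 2)
    if eps < 0:
        raise ValueError("eps must be >= 0")
    sign_change = np.sign(x[:-1]) != np.sign(x[1:])
    big_step = np.abs(np.diff(x)) >= eps
    return int(np.count_nonzero(sign_change & big_step))


def ssc(x, eps: float = 0.0) -> int:
    """Slope sign changes, product form:

    counts interior samples where ``(x_i - x_{i-1}) * (x_i - x_{i+1}) >= eps``.
    """
    x = _check_window(x, 3)
    prod = (x[1:-1] - x[:-2]) * (x[1:-1] - x[2:])
    return int(np.count_nonzero(prod >= eps))


def wamp(x, eps: float = 0.0) -> int:
    """Willison amplitude: consecutive-sample differences >= ``eps``."""
    x = _check_window(x, 2)
    return int(np.count_nonzero(np.abs(np.diff(x)) >= eps))


def _features_block(wins: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """Vectorized feature block for ``(n_windows, N, C)`` window stacks.

    Returns ``(n_windows, 5 * C)`` in feature-major column order, the same
    arithmetic as the scalar functions above applied per window/channel.
    """
    if wins.ndim != 3:
        raise ValueError("expected (n_windows, window_samples, n_channels)")
    n_win, n_samp, n_ch = wins.shape
    if n_samp < 3:
        raise ValueError("windows must have at least 3 samples")
    eps = np.broadcast_to(np.asarray(eps, dtype=float), (n_ch,))
    if np.any(eps < 0):
        raise ValueError("eps must be >= 0")

    diff = np.diff(wins, axis=1)
    absdiff = np.abs(diff)
    out = np.empty((n_win, 5, n_ch))
    out[:, 0] = np.mean(np.abs(wins), axis=1)                      # MAV
    out[:, 1] = np.sum(absdiff, axis=1)                            # WL
    sign_change = np.sign(wins[:, :-1]) != np.sign(wins[:, 1:])
    out[:, 2] = np.count_nonzero(sign_change & (absdiff >= eps), axis=1)  # ZC
    prod = (wins[:, 1:-1] - wins[:, :-2]) * (wins[:, 1:-1] - wins[:, 2:])
    out[:, 3] = np.count_nonzero(prod >= eps, axis=1)              # SSC
    out[:, 4] = np.count_nonzero(absdiff >= eps, axis=1)           # WAMP
    return out.reshape(n_win, 5 * n_ch)


def feature_columns(n_channels: int) -> list:
    """Feature-major column names: MAV_ch1..MAV_chC, WL_ch1, ..."""
    return [f"{feat}_ch{c + 1}" for feat in FEATURE_NAMES
            for c in range(n_channels)]


def rest_rms_eps(rest_samples, scale: float = DEFAULT_EPS_SCALE) -> np.ndarray:
    """Per-channel threshold: ``scale`` x RMS of the filtered rest signal.

    ``rest_samples`` is a (time x channels) array, typically the baseline
    rest-class recordings concatenated.  Computed once per dataset and
    recorded in the provenance so counts are comparable across records.
    """
    x = np.asarray(rest_samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("expected a time x channels rest signal")
    return scale * np.sqrt(np.mean(x ** 2, axis=0))


def extract_features(windows: np.ndarray, labels, eps=0.0) -> pd.DataFrame:
    """Assemble the labeled feature matrix.

    Parameters
    ----------
    windows : (n_windows, window_samples, n_channels) array
    labels : DataFrame (or dict of columns) with one row per window,
        carrying the LABEL_COLUMNS subset that is known.
    eps : scalar or per-channel array threshold for ZC/SSC/WAMP.

    Returns a DataFrame of label columns followed by the ``5 * C``
    feature-major feature columns; empty input yields an empty frame with
    the full schema.
    """
    wins = np.asarray(windows, dtype=float)
    if wins.ndim == 2:  # single channel convenience
        wins = wins[:, :, None]
    labels = pd.DataFrame(labels)
    n_ch = wins.shape[2] if wins.size or wins.ndim == 3 else 1
    cols = feature_columns(n_ch)
    if wins.shape[0] == 0:
        return pd.DataFrame(columns=list(labels.columns) + cols)
    if len(labels) != wins.shape[0]:
        raise ValueError(
            f"{len(labels)} label rows for {wins.shape[0]} windows")
    values = _features_block(wins, eps)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite feature values")
    out = labels.reset_index(drop=True).copy()
    out[cols] = values
    return out


def feature_column_names(df: pd.DataFrame) -> list:
    """The feature columns of a labeled feature table, in stored order."""
    return [c for c in df.columns
            if any(c.startswith(f + "_ch") for f in FEATURE_NAMES)]
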