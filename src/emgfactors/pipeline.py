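"""End-to-end in-memory pipeline: synthesize -> filter -> windows -> features.

The on-disk route (manifest + per-record CSV) lives in :mod:`emgfactors.io`;
this module is the streaming equivalent used by the experiment driver and
the test-bench, so a full multi-subject campaign never holds raw signals
for more than one recording at a time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import DEFAULT_EPS_SCALE, extract_features, rest_rms_eps
from .preprocess import WindowSpec, bandpass_filter, notch_filter, segment_windows
from .simulate import (GeneratorConfig, Recording, iter_dataset,
                       simulate_recording, subject_seed_from_id)

REST_MOTION = "RT"
BASELINE_LEVEL = "P1"


def filter_recording(rec: Recording, low: float = 20.0, high: float = 500.0,
                     order: int = 3, notch_freq: float = 50.0,
                     notch_q: float = 30.0) -> np.ndarray:
    """Standard conditioning: band-pass then power-line notch."""
    y = bandpass_filter(rec.samples, rec.fs, low=low, high=high, order=order)
    return notch_filter(y, rec.fs, freq=notch_freq, q=notch_q)


def rest_eps_for_dataset(config: GeneratorConfig, subject_ids,
                         eps_scale: float = DEFAULT_EPS_SCALE) -> np.ndarray:
    """Per-channel ZC/SSC/WAMP threshold from the baseline rest signal.

    Uses the filtered rest-motion recordings of the baseline condition,
    pooled over subjects and repetitions — computed once per dataset so
    the counts stay comparable across records.
    """
    if REST_MOTION not in config.motions:
        raise ValueError("dataset has no rest motion to derive eps from")
    chunks = []
    for sid in subject_ids:
        sseed = subject_seed_from_id(sid)
        for trial in range(1, config.n_trials + 1):
            rec = simulate_recording(config, REST_MOTION, "position",
                                     BASELINE_LEVEL, trial,
                                     subject_seed=sseed, subject_id=sid)
            chunks.append(filter_recording(rec))
    return rest_rms_eps(np.concatenate(chunks, axis=0), scale=eps_scale)


def recording_features(rec: Recording, window: WindowSpec, eps) -> pd.DataFrame:
    """Filter, window and featurize one recording."""
    wins = segment_windows(filter_recording(rec), window)
    labels = pd.DataFrame({
        "subject": rec.subject_id,
        "factor_kind": rec.factor_kind,
        "factor_level": rec.factor_level,
        "motion": rec.motion,
        "trial": rec.trial_index,
    }, index=range(wins.shape[0]))
    return extract_features(wins, labels, eps=eps)


def compute_features(config: GeneratorConfig, subject_ids,
                     window: WindowSpec | None = None,
                     eps_scale: float = DEFAULT_EPS_SCALE,
                     eps=None) -> pd.DataFrame:
    """Feature table for a full synthetic campaign.

    Rows keep the within-recording window order (required by the
    block-fold construction); ``eps`` overrides the rest-RMS rule when
    given explicitly.
    """
    if window is None:
        window = WindowSpec(fs=config.fs)
    if eps is None:
        eps = rest_eps_for_dataset(config, subject_ids, eps_scale=eps_scale)
    parts = [recording_features(rec, window, eps)
             for rec in iter_dataset(config, subject_ids)]
    return pd.concat(parts, ignore_index=True)


def features_from_recordings(recordings, window: WindowSpec,
                             eps=None,
                             eps_scale: float = DEFAULT_EPS_SCALE
                             ) -> pd.DataFrame:
    """Same as :func:`compute_features` but for already-loaded recordings
    (e.g. read back from a dataset directory)."""
    recordings = list(recordings)
    if eps is None:
        rest = [filter_recording(r) for r in recordings
                if r.motion == REST_MOTION and r.factor_level == BASELINE_LEVEL]
        if not rest:
            raise ValueError("no baseline rest recordings to derive eps from")
        eps = rest_rms_eps(np.concatenate(rest, axis=0), scale=eps_scale)
    parts = [recording_features(rec, window, eps) for rec in recordings]
    return pd.concat(parts, ignore_index=True)
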