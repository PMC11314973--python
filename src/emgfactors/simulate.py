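"""Synthetic multichannel surface-EMG generator.

Emulates a forearm recording session with a circumferential ring of
electrodes: seven hand/wrist motions, four repetitions of ~5 s each,
recorded under four limb-position conditions (P1--P4) and four
electrode-shift conditions (S1--S4) that share the baseline P1 == S0.

The signal model is amplitude-modulated band-limited Gaussian noise:
per channel, zero-mean noise band-limited to 20--450 Hz is scaled to a
motion- and channel-specific RMS target.  A limb position multiplies
each channel by a level-specific gain (log-normal, spread ``delta``);
an electrode shift mixes each channel with its ring neighbour
(convex weight ``lam``) and attenuates it (factor ``alpha``).  This is
not a motor-unit simulator: it reproduces the *feature-space* structure
of the factors (systematic, level-specific distribution shifts with
exchangeable repetitions within a level), which is what the downstream
analysis measures.

Amplitudes are in arbitrary normalized units; no calibration is implied.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

MOTIONS = ("CH", "OH", "FL", "EX", "PN", "SN", "RT")

#: Channel roles on the circumferential forearm ring (two extensor sites,
#: two flexor sites, pronator, supinator).
CHANNEL_ROLES = (
    "extensor_carpi_ulnaris",
    "extensor_carpi_radialis",
    "flexor_carpi_radialis",
    "flexor_carpi_ulnaris",
    "pronator",
    "supinator",
)

# Motion x channel RMS activation targets (arbitrary units).  Rows follow
# MOTIONS.  Synergist muscles overlap between related motions (close hand
# shares flexors with wrist flexion, open hand shares extensors with wrist
# extension), which is what makes between-condition transfer fragile.
DEFAULT_ACTIVATION = (
    (0.6, 0.5, 1.8, 1.6, 0.5, 0.4),   # CH  close hand
    (1.6, 1.5, 0.5, 0.4, 0.4, 0.5),   # OH  open hand
    (0.3, 0.3, 2.0, 1.9, 0.6, 0.3),   # FL  wrist flexion
    (2.0, 1.8, 0.3, 0.3, 0.3, 0.5),   # EX  wrist extension
    (0.5, 0.4, 0.7, 0.5, 1.8, 0.4),   # PN  pronation
    (0.4, 0.5, 0.4, 0.6, 0.4, 1.8),   # SN  supination
    (0.05, 0.05, 0.05, 0.05, 0.05, 0.05),  # RT  rest
)

_KIND_CODE = {"position": 0, "shift": 1}
# Seed-stream tags so the per-recording, per-level-gain and subject streams
# never collide.
_TAG_RECORDING = 11
_TAG_POSITION_GAIN = 23


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic recording campaign.

    Position level ``k`` applies per-channel gains ``exp(delta_k * z)``
    with ``z ~ N(0, 1)`` drawn once per (subject, level); electrode-shift
    level ``k`` applies the ring-mixing matrix
    ``M = alpha_k * ((1 - lam_k) * I + lam_k * Nbr)``.
    Baseline levels are pinned: ``delta_1 = 0`` (P1) and
    ``lam_0 = 0, alpha_0 = 1`` (S0).
    """

    n_channels: int = 6
    fs: float = 2148.0
    trial_duration: float = 5.0
    n_trials: int = 4
    motions: tuple = MOTIONS
    activation: tuple = DEFAULT_ACTIVATION
    #: log-normal channel-gain spread per position level (P1..P4)
    position_gain_sd: tuple = (0.0, 0.4, 0.4, 0.4)
    #: neighbour mixing weight per shift level (S0..S4)
    shift_mixing: tuple = (0.0, 0.2, 0.35, 0.25, 0.45)
    #: attenuation per shift level (S0..S4)
    shift_attenuation: tuple = (1.0, 0.93, 0.86, 0.90, 0.80)
    #: SD of the per-trial multiplicative (log-normal) gain jitter
    trial_jitter_sd: float = 0.0
    #: RMS of the additive wide-band sensor noise floor
    sensor_noise_rms: float = 0.01
    #: source band limits in Hz
    band: tuple = (20.0, 450.0)
    seed: int = 0

    @property
    def position_levels(self) -> tuple:
        return tuple(f"P{i + 1}" for i in range(len(self.position_gain_sd)))

    @property
    def shift_levels(self) -> tuple:
        return tuple(f"S{i}" for i in range(len(self.shift_mixing)))

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.trial_duration)

    def activation_matrix(self) -> np.ndarray:
        return np.asarray(self.activation, dtype=float)

    def validate(self) -> None:
        act = self.activation_matrix()
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if len(self.motions) == 0:
            raise ValueError("at least one motion must be configured")
        if len(set(self.motions)) != len(self.motions):
            raise ValueError("duplicate motion labels")
        if act.shape != (len(self.motions), self.n_channels):
            raise ValueError(
                f"activation must be {len(self.motions)} x {self.n_channels}, "
                f"got {act.shape}"
            )
        if np.any(act < 0):
            raise ValueError("activation entries must be >= 0")
        if "RT" in self.motions and len(self.motions) > 1:
            rt = act[self.motions.index("RT")]
            others = np.delete(act, self.motions.index("RT"), axis=0)
            if not np.all(rt[None, :] < others.max(axis=1)[:, None]):
                raise ValueError(
                    "rest activation must be elementwise below every other "
                    "motion's peak activation"
                )
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        low, high = self.band
        if not 0 < low < high < self.fs / 2:
            raise ValueError("band must satisfy 0 < low < high < fs/2")
        if self.position_gain_sd[0] != 0.0:
            raise ValueError("baseline position level P1 must have gain spread 0")
        if any(d < 0 for d in self.position_gain_sd):
            raise ValueError("position gain spreads must be >= 0")
        if self.shift_mixing[0] != 0.0 or self.shift_attenuation[0] != 1.0:
            raise ValueError("baseline shift level S0 must have lam=0, alpha=1")
        if len(self.shift_mixing) != len(self.shift_attenuation):
            raise ValueError("shift_mixing and shift_attenuation lengths differ")
        if any(not 0.0 <= l <= 1.0 for l in self.shift_mixing):
            raise ValueError("shift mixing weights must lie in [0, 1]")
        if any(not 0.0 < a <= 1.0 for a in self.shift_attenuation):
            raise ValueError("shift attenuations must lie in (0, 1]")
        if self.trial_jitter_sd < 0:
            raise ValueError("trial_jitter_sd must be >= 0")
        if self.sensor_noise_rms < 0:
            raise ValueError("sensor_noise_rms must be >= 0")


def null_factor_config(**overrides) -> GeneratorConfig:
    """Config with every factor effect switched off (all levels i.i.d.)."""
    base = dict(
        position_gain_sd=(0.0, 0.0, 0.0, 0.0),
        shift_mixing=(0.0, 0.0, 0.0, 0.0, 0.0),
        shift_attenuation=(1.0, 1.0, 1.0, 1.0, 1.0),
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@dataclass(frozen=True)
class Recording:
    """One trial of multichannel raw EMG with its design labels."""

    samples: np.ndarray  # time x channels
    fs: float
    motion: str
    factor_kind: str  # "position" | "shift"
    factor_level: str  # P1..P4 / S0..S4
    trial_index: int  # 1..n_trials
    subject_id: str


def subject_seed_from_id(subject_id: str) -> int:
    """Stable 31-bit integer derived from the subject label."""
    return zlib.crc32(subject_id.encode("utf-8")) & 0x7FFFFFFF


def canonical_condition(config: GeneratorConfig, factor_kind: str,
                        factor_level: str) -> tuple:
    """Map (shift, S0) onto the identical baseline (position, P1)."""
    if factor_kind not in _KIND_CODE:
        raise ValueError(f"unknown factor kind {factor_kind!r}")
    if factor_kind == "shift":
        if factor_level not in config.shift_levels:
            raise ValueError(f"unknown shift level {factor_level!r}")
        if factor_level == "S0":
            return "position", "P1"
    else:
        if factor_level not in config.position_levels:
            raise ValueError(f"unknown position level {factor_level!r}")
    return factor_kind, factor_level


def position_gains(config: GeneratorConfig, subject_seed: int,
                   level: str) -> np.ndarray:
    """Per-channel gain vector of one limb-position level.

    Drawn once per (subject, level) so the level is a fixed condition for
    that subject across motions and repetitions; the baseline P1 is the
    identity.
    """
    idx = config.position_levels.index(level)
    delta = config.position_gain_sd[idx]
    if delta == 0.0:
        return np.ones(config.n_channels)
    ss = np.random.SeedSequence(
        entropy=(config.seed, _TAG_POSITION_GAIN, subject_seed, idx))
    z = np.random.default_rng(ss).standard_normal(config.n_channels)
    return np.exp(delta * z)


def shift_mixing_matrix(config: GeneratorConfig, level: str) -> np.ndarray:
    """Ring-mixing matrix of one electrode-shift level.

    ``out_c = alpha * ((1 - lam) * src_c + lam * src_{c+1})`` where channel
    ``c + 1`` is the adjacent electrode on the circumferential ring (the
    muscle the displaced electrode slides toward); the attenuation models
    the amplitude loss of moving off the innervation zone.
    """
    idx = config.shift_levels.index(level)
    lam = config.shift_mixing[idx]
    alpha = config.shift_attenuation[idx]
    c = config.n_channels
    nbr = np.roll(np.eye(c), 1, axis=1)  # nbr[c, c+1 mod C] = 1
    return alpha * ((1.0 - lam) * np.eye(c) + lam * nbr)


def _bandlimited_noise(rng: np.random.Generator, n: int, channels: int,
                       band: tuple, fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` per channel."""
    white = rng.standard_normal((n, channels))
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    src = signal.sosfiltfilt(sos, white, axis=0)
    rms = np.sqrt(np.mean(src ** 2, axis=0))
    return src / rms


def simulate_recording(config: GeneratorConfig, motion: str, factor_kind: str,
                       factor_level: str, trial_index: int,
                       subject_seed: int = 0,
                       subject_id: str = "sub01") -> Recording:
    """Generate one trial.

    Deterministic for a fixed ``(config.seed, subject_seed, condition,
    motion, trial_index)``; different conditions, motions and repetitions
    use independent noise streams, emulating independently recorded
    sessions.
    """
    config.validate()
    kind, level = canonical_condition(config, factor_kind, factor_level)
    if motion not in config.motions:
        raise ValueError(f"unknown motion {motion!r}")
    if not 1 <= trial_index <= config.n_trials:
        raise ValueError(f"trial_index must be in 1..{config.n_trials}")
    midx = config.motions.index(motion)
    levels = (config.position_levels if kind == "position"
              else config.shift_levels)
    lidx = levels.index(level)

    n = config.n_samples
    ss = np.random.SeedSequence(entropy=(
        config.seed, _TAG_RECORDING, subject_seed, _KIND_CODE[kind], lidx,
        midx, trial_index))
    rng = np.random.default_rng(ss)

    src = _bandlimited_noise(rng, n, config.n_channels, config.band, config.fs)
    jitter = float(np.exp(config.trial_jitter_sd * rng.standard_normal()))

    amp = config.activation_matrix()[midx] * jitter
    if kind == "position":
        amp = amp * position_gains(config, subject_seed, level)
        out = src * amp
    else:
        out = (src * amp) @ shift_mixing_matrix(config, level).T
    if config.sensor_noise_rms > 0:
        out = out + config.sensor_noise_rms * rng.standard_normal(out.shape)

    return Recording(samples=out, fs=config.fs, motion=motion,
                     factor_kind=kind, factor_level=level,
                     trial_index=trial_index, subject_id=subject_id)


def design_grid(config: GeneratorConfig, subject_ids: list) -> list:
    """Enumerate the full recording design as label tuples.

    Per subject: every position level x motion x trial plus every
    non-baseline shift level x motion x trial (S0 is the P1 data, so it
    appears once, under its canonical position label).
    """
    if len(subject_ids) == 0:
        raise ValueError("subject list must be nonempty")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    config.validate()
    rows = []
    for sid in subject_ids:
        for level in config.position_levels:
            for motion in config.motions:
                for trial in range(1, config.n_trials + 1):
                    rows.append((sid, "position", level, motion, trial))
        for level in config.shift_levels:
            if level == "S0":
                continue
            for motion in config.motions:
                for trial in range(1, config.n_trials + 1):
                    rows.append((sid, "shift", level, motion, trial))
    return rows


def iter_dataset(config: GeneratorConfig, subject_ids: list):
    """Yield every Recording of the design grid, one at a time."""
    for sid, kind, level, motion, trial in design_grid(config, subject_ids):
        yield simulate_recording(config, motion, kind, level, trial,
                                 subject_seed=subject_seed_from_id(sid),
                                 subject_id=sid)


def simulate_dataset(config: GeneratorConfig, subject_ids: list):
    """Materialize the full dataset plus its manifest.

    Returns ``(recordings, manifest)`` where the manifest is a plain dict
    (JSON-serializable) indexing every record.  Memory scales with
    subjects x 224 recordings; use :func:`iter_dataset` for streaming.
    """
    recordings = list(iter_dataset(config, subject_ids))
    manifest = build_manifest(config, recordings)
    return recordings, manifest


def record_key(rec: Recording) -> tuple:
    return (rec.subject_id, rec.factor_kind, rec.factor_level, rec.motion,
            rec.trial_index)


def record_relpath(rec: Recording) -> str:
    return (f"signals/{rec.subject_id}_{rec.factor_kind}_{rec.factor_level}_"
            f"{rec.motion}_t{rec.trial_index}.csv")


def build_manifest(config: GeneratorConfig, recordings: list) -> dict:
    keys = [record_key(r) for r in recordings]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (subject, kind, level, motion, trial) key")
    return {
        "fs": config.fs,
        "n_channels": config.n_channels,
        "records": [
            {
                "subject_id": r.subject_id,
                "factor_kind": r.factor_kind,
                "factor_level": r.factor_level,
                "motion": r.motion,
                "trial_index": r.trial_index,
                "fs": r.fs,
                "n_samples": int(r.samples.shape[0]),
                "path": record_relpath(r),
            }
            for r in recordings
        ],
    }


def stressed_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study conditions (factor effects on)."""
    return replace(GeneratorConfig(seed=seed), **overrides)
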