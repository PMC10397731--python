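"""Synthetic multichannel EEG with known dominant-rhythm ground truth.

Each trial x channel is built from five phase-continuous band carriers
whose amplitudes follow a per-timestamp schedule: the scheduled dominant
band plays at ``amp_dominant``, the others at ``amp_background``, plus
white Gaussian noise.  One designated channel carries a class-conditional
3-symbol code motif planted into its schedule, giving exactly one
(channel, code) feature a class-separated expected count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .sequencing import ALPHABET, BandPartition
from .timefreq import SignalSegment

__all__ = [
    "RhythmSchedule",
    "SynthConfig",
    "SynthDataset",
    "random_schedule",
    "plant_motif",
    "synth_segment",
    "synth_dataset",
]

DEFAULT_CARRIERS = {"D": 2.0, "T": 6.0, "A": 10.0, "B": 20.0, "G": 40.0}


@dataclass(frozen=True)
class RhythmSchedule:
    """Ground-truth dominant band per 0.2 s timestamp."""

    symbols: str
    interval: float = 0.2

    def __post_init__(self) -> None:
        bad = set(self.symbols) - set(ALPHABET)
        if bad:
            raise ConfigError(f"schedule symbols outside alphabet: {sorted(bad)}")
        if not self.symbols:
            raise ConfigError("schedule must contain at least one timestamp")

    @property
    def duration(self) -> float:
        return len(self.symbols) * self.interval

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults target a 128 Hz, 30 s, 8-channel design."""

    fs: float = 128.0
    duration: float = 30.0
    n_channels: int = 8
    channels: tuple[str, ...] = ()
    carriers: dict = field(default_factory=lambda: dict(DEFAULT_CARRIERS))
    amp_dominant: float = 10.0
    amp_background: float = 1.0
    noise_sd: float = 0.5
    planted_channel: str = "FP1"
    planted_code: str = "TGB"
    r0: float = 0.05
    r1: float = 0.35
    interval: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            names = ("FP1", "FP2", "F3", "F4", "C3", "C4", "O1", "O2",
                     "T7", "T8", "P3", "P4", "CP1", "CP2", "PO3", "PO4")
            if self.n_channels <= len(names):
                chans = names[: self.n_channels]
            else:
                chans = names + tuple(
                    f"X{i}" for i in range(self.n_channels - len(names))
                )
            object.__setattr__(self, "channels", chans)
        else:
            object.__setattr__(self, "channels", tuple(self.channels))
            object.__setattr__(self, "n_channels", len(self.channels))
        bands = BandPartition()
        for sym, f0 in self.carriers.items():
            lo, hi = bands.interval(ALPHABET.index(sym))
            if not (lo < f0 < hi):
                raise ConfigError(
                    f"carrier {f0} Hz for band {sym!r} lies outside ({lo}, {hi}) Hz"
                )
        if not (0.0 <= self.r0 <= 1.0 and 0.0 <= self.r1 <= 1.0):
            raise ConfigError("motif insertion rates must lie in [0, 1]")
        if not self.amp_dominant > self.amp_background >= 0:
            raise ConfigError("require amp_dominant > amp_background >= 0")
        if len(self.planted_code) != 3 or set(self.planted_code) - set(ALPHABET):
            raise ConfigError(f"planted code must be a 3-symbol code, got {self.planted_code!r}")

    @property
    def n_stamps(self) -> int:
        return int(np.floor(self.duration / self.interval + 1e-9))


@dataclass(frozen=True)
class SynthDataset:
    """Trials x channels of segments plus labels and ground-truth schedules."""

    config: SynthConfig
    segments: dict  # (trial_id, channel) -> SignalSegment
    labels: dict  # trial_id -> class label
    schedules: dict  # (trial_id, channel) -> RhythmSchedule

    @property
    def trial_ids(self) -> list[str]:
        return sorted(self.labels, key=lambda t: int(t.split("-")[-1]))

    @property
    def channels(self) -> tuple[str, ...]:
        return self.config.channels


def random_schedule(
    n_stamps: int,
    rng: np.random.Generator,
    interval: float = 0.2,
    min_run: int = 2,
) -> RhythmSchedule:
    """Piecewise-stationary random schedule: uniform bands in runs of ``min_run``.

    A dwell of at least two timestamps (0.4 s) keeps every scheduled band
    resolvable by the time-frequency stage; a 0.2 s burst of the 2 Hz delta
    carrier covers only 0.4 cycles and cannot be localised inside its band.
    Pass ``min_run=1`` for fully independent timestamps.
    """
    if min_run < 1:
        raise ConfigError("min_run must be at least 1")
    syms: list[str] = []
    while len(syms) < n_stamps:
        syms.extend(ALPHABET[rng.integers(len(ALPHABET))] * min_run)
    return RhythmSchedule("".join(syms[:n_stamps]), interval)


def plant_motif(
    schedule: RhythmSchedule, motif: str, rate: float, rng: np.random.Generator
) -> RhythmSchedule:
    """Overwrite 3-symbol windows with ``motif`` at per-position rate ``rate``.

    Positions are visited left to right; an accepted insertion occupies the
    next three symbols, and overlapping insertion attempts are skipped.
    """
    sym = list(schedule.symbols)
    draws = rng.random(len(sym))
    i = 0
    while i <= len(sym) - 3:
        if draws[i] < rate:
            sym[i: i + 3] = motif
            i += 3
        else:
            i += 1
    return RhythmSchedule("".join(sym), schedule.interval)


def synth_segment(
    schedule: RhythmSchedule,
    cfg: SynthConfig,
    rng: np.random.Generator,
    channel: str = "",
    trial_id: str = "",
    subject_id: str = "synth",
) -> SignalSegment:
    """Render a schedule to samples: five carriers with scheduled amplitudes.

    Carriers run phase-continuously over the whole segment; only their
    amplitudes switch at timestamp edges.
    """
    n_samples = int(round(schedule.duration * cfg.fs))
    t = np.arange(n_samples) / cfg.fs
    # dominant-band index per sample
    stamp = np.minimum(
        np.floor(t / schedule.interval + 1e-9).astype(int), len(schedule) - 1
    )
    sched_idx = np.array([ALPHABET.index(s) for s in schedule.symbols])[stamp]
    x = np.zeros(n_samples)
    for b, sym in enumerate(ALPHABET):
        amp = np.where(sched_idx == b, cfg.amp_dominant, cfg.amp_background)
        x += amp * np.sin(2 * np.pi * cfg.carriers[sym] * t)
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd, size=n_samples)
    return SignalSegment(x, cfg.fs, channel=channel, trial_id=trial_id, subject_id=subject_id)


def synth_dataset(
    cfg: SynthConfig,
    n_trials_per_class: int = 20,
    classes: tuple[str, ...] = ("class0", "class1"),
    seed: int | None = None,
) -> SynthDataset:
    """Generate a labelled multichannel dataset with one planted feature.

    Non-planted channels get class-independent random schedules; the
    planted channel's schedule receives the planted motif at rate ``r1``
    for the last class and ``r0`` otherwise.
    """
    if len(classes) not in (2, 3):
        raise ConfigError("two or three classes are supported")
    if cfg.planted_channel not in cfg.channels:
        raise ConfigError(
            f"planted channel {cfg.planted_channel!r} not among {cfg.channels}"
        )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    segments: dict = {}
    labels: dict = {}
    schedules: dict = {}
    trial = 0
    for cls in classes:
        rate = cfg.r1 if cls == classes[-1] else cfg.r0
        for _ in range(n_trials_per_class):
            tid = f"trial-{trial:03d}"
            labels[tid] = cls
            for ch in cfg.channels:
                sched = random_schedule(cfg.n_stamps, rng, cfg.interval)
                if ch == cfg.planted_channel:
                    sched = plant_motif(sched, cfg.planted_code, rate, rng)
                schedules[tid, ch] = sched
                segments[tid, ch] = synth_segment(
                    sched, cfg, rng, channel=ch, trial_id=tid
                )
            trial += 1
    return SynthDataset(config=cfg, segments=segments, labels=labels, schedules=schedules)
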