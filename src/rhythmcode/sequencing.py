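"""Dominant-rhythm sequencing of time-frequency planes.

Partitions the frequency axis into the five canonical EEG bands and the
time axis into 0.2 s timestamps, averages (clipped) power per band x
timestamp box, and emits one symbol per timestamp: the band with maximal
mean power.  Sequences are strings over the alphabet ``{D,T,A,B,G}`` for
delta/theta/alpha/beta/gamma.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ConfigError, InvalidInputError
from .timefreq import (
    SignalSegment,
    SmoothingSpec,
    TimeFrequencyPlane,
    blocked_rspwvd,
)

__all__ = [
    "ALPHABET",
    "BAND_NAMES",
    "BandPartition",
    "TimestampGrid",
    "BandPowerTable",
    "RhythmSequence",
    "band_power",
    "dominant_sequence",
    "sequence_trial",
    "write_sequences",
    "read_sequences",
]

#: symbol order mirrors the ascending band order delta < theta < alpha < beta < gamma
ALPHABET = "DTABG"
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: analysis window: trials longer than this keep only their final portion
ANALYSIS_WINDOW_S = 30.0


@dataclass(frozen=True)
class BandPartition:
    """Five contiguous frequency bands; half-open except the closed top edge."""

    edges: tuple[float, ...] = (0.0, 4.0, 8.0, 13.0, 30.0, 50.0)

    def __post_init__(self) -> None:
        if len(self.edges) != 6:
            raise ConfigError("exactly five bands (six edges) are required")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ConfigError("band edges must be strictly ascending")

    def interval(self, i: int) -> tuple[float, float]:
        return self.edges[i], self.edges[i + 1]

    def membership(self, freqs: np.ndarray) -> list[np.ndarray]:
        """Boolean bin-membership mask per band, by bin-centre frequency.

        Bands are half-open ``[lo, hi)``; the top band is closed at its
        upper edge.
        """
        masks = []
        for i in range(5):
            lo, hi = self.interval(i)
            if i < 4:
                masks.append((freqs >= lo) & (freqs < hi))
            else:
                masks.append((freqs >= lo) & (freqs <= hi))
        return masks


@dataclass(frozen=True)
class TimestampGrid:
    """Uniform partition of a segment's duration into fixed intervals."""

    interval: float
    n_stamps: int

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ConfigError("timestamp interval must be positive")
        if self.n_stamps < 1:
            raise ConfigError("grid must contain at least one timestamp")

    @classmethod
    def for_duration(cls, duration: float, interval: float = 0.2) -> "TimestampGrid":
        n = int(np.floor(duration / interval + 1e-9))
        if n < 1:
            raise InvalidInputError(
                f"duration {duration} s is shorter than one {interval} s timestamp"
            )
        return cls(interval=interval, n_stamps=n)

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.n_stamps + 1) * self.interval


@dataclass(frozen=True)
class BandPowerTable:
    """Mean (clipped) power per timestamp x band; bands in ascending order."""

    values: np.ndarray  # (n_stamps, 5)
    grid: TimestampGrid

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 5:
            raise InvalidInputError(f"band-power table must be (n, 5), got {values.shape}")
        if values.shape[0] != self.grid.n_stamps:
            raise InvalidInputError("table rows must match the timestamp grid")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class RhythmSequence:
    """Dominant-band symbol string, one symbol per timestamp."""

    symbols: str
    interval: float = 0.2
    channel: str = ""
    trial_id: str = ""
    subject_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.symbols) - set(ALPHABET)
        if bad:
            raise InvalidInputError(f"symbols outside alphabet {ALPHABET!r}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)


def band_power(
    plane: TimeFrequencyPlane,
    bands: BandPartition | None = None,
    grid: TimestampGrid | None = None,
) -> BandPowerTable:
    """Average clipped plane power over each timestamp x band box.

    Negative plane values (possible for a quadratic distribution) are
    clipped to zero before averaging.  Box membership is by bin centre:
    time in ``[edge_i, edge_{i+1})``, frequency per the band partition.
    """
    bands = bands or BandPartition()
    if grid is None:
        duration = plane.times[-1] - plane.times[0] + (plane.times[1] - plane.times[0])
        grid = TimestampGrid.for_duration(duration)
    if bands.edges[-1] > plane.freqs[-1] + 1e-9:
        raise ConfigError(
            f"top band edge {bands.edges[-1]} Hz exceeds the plane's maximum "
            f"frequency {plane.freqs[-1]:.3f} Hz"
        )
    t0 = plane.times[0]
    values = np.clip(plane.values, 0.0, None)
    freq_masks = bands.membership(plane.freqs)
    for name, mask in zip(BAND_NAMES, freq_masks):
        if not mask.any():
            raise ConfigError(f"no frequency bins fall inside the {name} band")
    # timestamp index per time bin, relative to the plane's start
    stamp = np.floor((plane.times - t0) / grid.interval + 1e-9).astype(int)
    table = np.zeros((grid.n_stamps, 5))
    in_range = (stamp >= 0) & (stamp < grid.n_stamps)
    if not in_range.any():
        raise InvalidInputError("plane does not cover the timestamp grid")
    counts = np.bincount(stamp[in_range], minlength=grid.n_stamps)
    if np.any(counts == 0):
        raise InvalidInputError("a timestamp contains no time bins")
    for b, mask in enumerate(freq_masks):
        band_sum = values[mask][:, in_range].sum(axis=0)
        table[:, b] = np.bincount(
            stamp[in_range], weights=band_sum, minlength=grid.n_stamps
        ) / (counts * mask.sum())
    return BandPowerTable(table, grid)


def dominant_sequence(table: BandPowerTable, **meta) -> RhythmSequence:
    """Symbol per timestamp: the band of maximal power, ties to the lower band."""
    values = table.values
    if np.any(~np.isfinite(values).any(axis=1)):
        raise InvalidInputError("band-power table contains all-non-finite rows")
    # np.argmax returns the first maximum, i.e. the lowest-frequency band on ties
    idx = np.nanargmax(values, axis=1)
    symbols = "".join(ALPHABET[i] for i in idx)
    return RhythmSequence(symbols, interval=table.grid.interval, **meta)


def sequence_trial(
    seg: SignalSegment,
    spec: SmoothingSpec | None = None,
    bands: BandPartition | None = None,
    interval: float = 0.2,
    block_s: float = 2.0,
    analysis_window_s: float | None = ANALYSIS_WINDOW_S,
    label: str | None = None,
) -> RhythmSequence:
    """End-to-end sequencing of one trial x channel segment.

    Applies the analysis-window rule (keep only the final
    ``analysis_window_s`` seconds; shorter trials are rejected), computes
    the blocked RSPWVD, and converts it to a dominant-rhythm sequence.
    Pass ``analysis_window_s=None`` to sequence the full segment.
    """
    if analysis_window_s is not None:
        if seg.duration < analysis_window_s - 1e-9:
            raise InvalidInputError(
                f"trial {seg.trial_id or '?'} lasts {seg.duration:.2f} s, shorter "
                f"than the {analysis_window_s:.0f} s analysis window"
            )
        if seg.duration > analysis_window_s:
            seg = seg.tail(analysis_window_s)
    plane = blocked_rspwvd(seg, spec=spec, block_s=block_s, interval=interval)
    duration = plane.times.size / seg.fs
    grid = TimestampGrid.for_duration(duration, interval)
    table = band_power(plane, bands, grid)
    return dominant_sequence(
        table,
        channel=seg.channel,
        trial_id=seg.trial_id,
        subject_id=seg.subject_id,
        label=label,
    )


# ---------------------------------------------------------------------------
# FASTA-like sequence I/O
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(
    r">(?P<subject>[^|]*)\|(?P<trial>[^|]*)\|(?P<channel>[^|]*)\|"
    r"(?P<label>[^|]*)\|interval=(?P<interval>[0-9.eE+-]+)$"
)


def write_sequences(seqs: Iterable[RhythmSequence], path: str | Path) -> None:
    """Write sequences in a FASTA-like text format (round-trip exact)."""
    with open(path, "w") as fh:
        for s in seqs:
            label = "" if s.label is None else s.label
            fh.write(
                f">{s.subject_id}|{s.trial_id}|{s.channel}|{label}"
                f"|interval={s.interval:g}\n{s.symbols}\n"
            )


def read_sequences(path: str | Path) -> list[RhythmSequence]:
    """Read sequences written by :func:`write_sequences`."""
    out: list[RhythmSequence] = []
    header = None
    body: list[str] = []

    def flush() -> None:
        if header is None:
            return
        m = _HEADER_RE.match(header)
        if m is None:
            raise InvalidInputError(f"malformed sequence header: {header!r}")
        out.append(
            RhythmSequence(
                symbols="".join(body),
                interval=float(m["interval"]),
                channel=m["channel"],
                trial_id=m["trial"],
                subject_id=m["subject"],
                label=m["label"] or None,
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header, body = line, []
            else:
                body.append(line)
        flush()
    return out
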