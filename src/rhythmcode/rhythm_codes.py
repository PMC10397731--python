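"""Rhythm-code (3-mer) count features over the five-symbol rhythm alphabet.

A rhythm code is an ordered triple of rhythm symbols; with five rhythms
there are exactly 5**3 = 125 codes.  Codes are counted with a sliding
window of length 3 and stride 1, without any canonicalisation: a length-L
sequence yields L-2 windows.  Codes are indexed base-5 with D=0, T=1,
A=2, B=3, G=4, so DDD -> 0 and GGG -> 124.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError, TooShortSequenceError
from .sequencing import ALPHABET, RhythmSequence

__all__ = [
    "N_CODES",
    "ALL_CODES",
    "code_index",
    "code_symbols",
    "rhythm_type_count",
    "extract_codes",
    "CodeFeatureVector",
    "FeatureTable",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
]

N_CODES = 125

_SYM_TO_IDX = {s: i for i, s in enumerate(ALPHABET)}


def code_index(code: str) -> int:
    """Base-5 positional index of a 3-symbol code (DDD=0 ... GGG=124)."""
    if len(code) != 3:
        raise InvalidInputError(f"a rhythm code has exactly 3 symbols, got {code!r}")
    try:
        b1, b2, b3 = (_SYM_TO_IDX[s] for s in code)
    except KeyError as exc:
        raise InvalidInputError(
            f"symbol {exc.args[0]!r} outside alphabet {ALPHABET!r} in code {code!r}"
        ) from None
    return 25 * b1 + 5 * b2 + b3


def code_symbols(index: int) -> str:
    """Inverse of :func:`code_index`."""
    if not 0 <= index < N_CODES:
        raise InvalidInputError(f"code index must be in [0, {N_CODES}), got {index}")
    return ALPHABET[index // 25] + ALPHABET[(index // 5) % 5] + ALPHABET[index % 5]


#: all 125 codes in index order
ALL_CODES = tuple(code_symbols(i) for i in range(N_CODES))


def rhythm_type_count(code: str) -> int:
    """Number of distinct rhythms in a code: 1, 2 or 3."""
    code_index(code)  # validates
    return len(set(code))


@dataclass(frozen=True)
class CodeFeatureVector:
    """125 non-negative counts of 3-symbol codes for one sequence."""

    counts: np.ndarray
    subject_id: str = ""
    trial_id: str = ""
    channel: str = ""
    seq_length: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_CODES,):
            raise InvalidInputError(f"count vector must have {N_CODES} entries")
        if np.any(counts < 0):
            raise InvalidInputError("counts must be non-negative")
        if self.seq_length and counts.sum() != self.seq_length - 2:
            raise InvalidInputError(
                f"counts sum to {counts.sum()} but a length-{self.seq_length} "
                f"sequence has {self.seq_length - 2} windows"
            )
        object.__setattr__(self, "counts", counts)


def extract_codes(seq: RhythmSequence) -> CodeFeatureVector:
    """Count every length-3, stride-1 window of the sequence.

    A length-L sequence yields exactly L-2 windows; codes that never occur
    keep an explicit zero count.
    """
    s = seq.symbols
    if len(s) < 3:
        raise TooShortSequenceError(
            f"sequence of length {len(s)} is too short for 3-symbol codes"
        )
    idx = np.array([_SYM_TO_IDX[c] for c in s], dtype=np.int64)
    window_idx = 25 * idx[:-2] + 5 * idx[1:-1] + idx[2:]
    counts = np.bincount(window_idx, minlength=N_CODES)
    return CodeFeatureVector(
        counts,
        subject_id=seq.subject_id,
        trial_id=seq.trial_id,
        channel=seq.channel,
        seq_length=len(s),
    )


@dataclass(frozen=True)
class FeatureTable:
    """Per-trial code counts, one column per (channel, code) pair.

    ``data`` columns are named ``<CHANNEL>:<CODE>`` (e.g. ``FP1:TGB``) in
    channel order then code-index order; the index holds trial ids.
    """

    data: pd.DataFrame
    labels: pd.Series
    channels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.channels) * N_CODES:
            raise InvalidInputError(
                f"expected {len(self.channels) * N_CODES} columns for "
                f"{len(self.channels)} channels, got {self.data.shape[1]}"
            )
        if not self.data.index.equals(self.labels.index):
            raise InvalidInputError("labels must be indexed by the same trials as data")

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def trial_ids(self) -> list[str]:
        return list(self.data.index)

    def feature(self, channel: str, code: str) -> np.ndarray:
        """Per-trial counts of one (channel, code) feature."""
        return self.data[f"{channel}:{code}"].to_numpy()


def build_feature_table(
    sequences: Iterable[RhythmSequence],
    labels: Mapping[str, str] | None = None,
    subject_id: str = "",
) -> FeatureTable:
    """Assemble a trials x (channels x 125 codes) table from sequences.

    Every trial must provide the same channel set and sequence length;
    ragged inputs raise an error naming the offending trials.  Labels come
    either from the mapping or from the sequences themselves.
    """
    by_trial: dict[str, dict[str, RhythmSequence]] = {}
    seq_labels: dict[str, str] = {}
    for seq in sequences:
        by_trial.setdefault(seq.trial_id, {})[seq.channel] = seq
        if seq.label is not None:
            seq_labels[seq.trial_id] = seq.label
    if not by_trial:
        raise InvalidInputError("no sequences supplied")
    trial_ids = sorted(by_trial)
    channel_sets = {tid: tuple(sorted(chs)) for tid, chs in by_trial.items()}
    reference = channel_sets[trial_ids[0]]
    offenders = [tid for tid in trial_ids if channel_sets[tid] != reference]
    if offenders:
        raise InvalidInputError(
            f"inconsistent channel sets across trials; offenders: {offenders}"
        )
    lengths = {len(s) for chs in by_trial.values() for s in chs.values()}
    if len(lengths) > 1:
        raise InvalidInputError(f"sequence lengths differ across trials: {sorted(lengths)}")
    # preserve first-seen channel order rather than sorting
    channels = tuple(dict.fromkeys(s.channel for s in by_trial[trial_ids[0]].values()))
    columns = [f"{ch}:{code}" for ch in channels for code in ALL_CODES]
    rows = np.empty((len(trial_ids), len(columns)), dtype=np.int64)
    for i, tid in enumerate(trial_ids):
        rows[i] = np.concatenate(
            [extract_codes(by_trial[tid][ch]).counts for ch in channels]
        )
    data = pd.DataFrame(rows, index=pd.Index(trial_ids, name="trial"), columns=columns)
    if labels is None:
        labels = seq_labels
    missing = [tid for tid in trial_ids if tid not in labels]
    if missing:
        raise InvalidInputError(f"trials without labels: {missing}")
    label_series = pd.Series(
        [labels[tid] for tid in trial_ids], index=data.index, name="label"
    )
    return FeatureTable(data=data, labels=label_series, channels=channels, subject_id=subject_id)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV dump: subject,trial,label then one integer column per feature."""
    out = table.data.copy()
    out.insert(0, "label", table.labels)
    out.insert(0, "trial", table.data.index)
    out.insert(0, "subject", table.subject_id)
    out.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a table written by :func:`write_feature_table` (bit-exact)."""
    df = pd.read_csv(path, dtype={"subject": str, "trial": str, "label": str})
    subject = str(df["subject"].iloc[0]) if len(df) else ""
    data = df.drop(columns=["subject", "trial", "label"])
    data.index = pd.Index(df["trial"], name="trial")
    data = data.astype(np.int64)
    labels = pd.Series(df["label"].to_numpy(), index=data.index, name="label")
    channels = tuple(dict.fromkeys(c.split(":")[0] for c in data.columns))
    return FeatureTable(data=data, labels=labels, channels=channels, subject_id=subject)
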