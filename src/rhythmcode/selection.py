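"""Two-phase selection of the single optimal channel-specific feature.

Phase one keeps, per channel, the code with the highest LOTO-CV accuracy;
phase two keeps the best channel-specific feature overall.  A one-way
ANOVA screen reports (but does not enforce) the statistical significance
of each selected feature, and summaries tally selected features by scalp
region and by number of distinct rhythms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    IncompleteEvaluationError,
    InvalidInputError,
    UnmappedChannelError,
)
from .evaluation import AccuracyRecord
from .rhythm_codes import N_CODES, code_index, rhythm_type_count

__all__ = [
    "REGIONS",
    "ChannelSpecificFeature",
    "SelectionReport",
    "best_code_per_channel",
    "optimal_feature",
    "anova_screen",
    "scalp_region",
    "summarize",
    "select_features",
]

REGIONS = ("frontal", "central", "parietal", "temporal", "occipital")

# longest-prefix mapping; midline 'Z' suffixes and digits are ignored
_PREFIX_REGION = {
    "FP": "frontal",
    "AF": "frontal",
    "FT": "temporal",
    "TP": "temporal",
    "FC": "central",
    "CP": "parietal",
    "PO": "occipital",
    "F": "frontal",
    "C": "central",
    "P": "parietal",
    "T": "temporal",
    "O": "occipital",
}


@dataclass(frozen=True)
class ChannelSpecificFeature:
    """The best-scoring code on one channel, with its ANOVA screen."""

    channel: str
    code: str
    classifier: str
    accuracy: float
    anova_f: float = float("nan")
    anova_p: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.anova_p <= 0.05


@dataclass(frozen=True)
class SelectionReport:
    """Per-channel winners, the single optimal feature, and tallies."""

    per_channel: tuple[ChannelSpecificFeature, ...]
    optimal: ChannelSpecificFeature
    region_tally: dict = field(default_factory=dict)
    rhythm_type_tally: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "optimal": asdict(self.optimal),
            "per_channel": [asdict(f) for f in self.per_channel],
            "region_tally": self.region_tally,
            "rhythm_type_tally": self.rhythm_type_tally,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def summary_text(self) -> str:
        lines = [
            f"optimal feature: {self.optimal.channel}:{self.optimal.code} "
            f"({self.optimal.classifier}, accuracy {self.optimal.accuracy:.3f}, "
            f"ANOVA p {self.optimal.anova_p:.3g})",
            "per-channel winners:",
        ]
        for f in self.per_channel:
            flag = "" if f.significant else "  [p > 0.05]"
            lines.append(
                f"  {f.channel}: {f.code} acc {f.accuracy:.3f} p {f.anova_p:.3g}{flag}"
            )
        return "\n".join(lines)


def best_code_per_channel(records: Sequence[AccuracyRecord]) -> ChannelSpecificFeature:
    """Argmax by accuracy over one channel's 125 codes; ties to lowest code index."""
    if not records:
        raise IncompleteEvaluationError("no accuracy records supplied")
    channels = {r.channel for r in records}
    if len(channels) != 1:
        raise InvalidInputError(f"records span multiple channels: {sorted(channels)}")
    codes = {r.code for r in records}
    if len(codes) < N_CODES:
        raise IncompleteEvaluationError(
            f"channel {next(iter(channels))!r} has {len(codes)} of {N_CODES} codes evaluated"
        )
    best = max(records, key=lambda r: (r.accuracy, -code_index(r.code)))
    return ChannelSpecificFeature(
        channel=best.channel,
        code=best.code,
        classifier=best.classifier,
        accuracy=best.accuracy,
    )


def optimal_feature(
    features: Sequence[ChannelSpecificFeature],
    channel_order: Sequence[str] | None = None,
) -> ChannelSpecificFeature:
    """Argmax by accuracy across channels.

    Ties prefer the channel appearing earlier in ``channel_order`` (or in
    the given sequence), then the lower code index.
    """
    if not features:
        raise InvalidInputError("no channel-specific features supplied")
    order = list(channel_order) if channel_order is not None else [f.channel for f in features]
    rank = {ch: i for i, ch in enumerate(order)}
    return max(
        features,
        key=lambda f: (f.accuracy, -rank.get(f.channel, len(rank)), -code_index(f.code)),
    )


def anova_screen(values: np.ndarray, labels: Sequence[str]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a feature across label groups.

    Returns (F, p) with (k-1, N-k) degrees of freedom.  Zero between-group
    variance gives F=0, p=1; zero within-group variance with distinct
    group means gives F=inf, p=0.
    """
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise InvalidInputError("ANOVA needs at least two groups")
    parts = [values[[i for i, y in enumerate(labels) if y == g]] for g in groups]
    if any(p.size < 2 for p in parts):
        small = [g for g, p in zip(groups, parts) if p.size < 2]
        raise InvalidInputError(f"groups with fewer than 2 trials: {small}")
    n_total = values.size
    k = len(groups)
    grand = values.mean()
    ss_between = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
    ss_within = sum(((p - p.mean()) ** 2).sum() for p in parts)
    df1, df2 = k - 1, n_total - k
    if ss_between <= 0.0:
        return 0.0, 1.0
    if ss_within <= 0.0:
        return float("inf"), 0.0
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), p


def scalp_region(channel: str) -> str:
    """Map a 10-20/10-10 channel name to one of the five scalp regions."""
    name = channel.strip().upper()
    stem = name.rstrip("0123456789")
    if stem.endswith("Z"):
        stem = stem[:-1]
    for prefix in sorted(_PREFIX_REGION, key=len, reverse=True):
        if stem == prefix:
            return _PREFIX_REGION[prefix]
    raise UnmappedChannelError(f"cannot map channel {channel!r} to a scalp region")


def summarize(features: Iterable[ChannelSpecificFeature]) -> tuple[dict, dict]:
    """Tally selected features by scalp region and by rhythm-type count.

    Returns two dicts of percentages (0-100) that each sum to 100 within
    floating-point rounding.
    """
    features = list(features)
    if not features:
        raise InvalidInputError("no features to summarise")
    region_counts = {r: 0 for r in REGIONS}
    type_counts = {1: 0, 2: 0, 3: 0}
    for f in features:
        region_counts[scalp_region(f.channel)] += 1
        type_counts[rhythm_type_count(f.code)] += 1
    n = len(features)
    regions = {r: 100.0 * c / n for r, c in region_counts.items()}
    types = {k: 100.0 * c / n for k, c in type_counts.items()}
    return regions, types


def select_features(
    records: Sequence[AccuracyRecord],
    table,
    channel_order: Sequence[str] | None = None,
) -> SelectionReport:
    """Full two-phase selection over a set of accuracy records.

    ``records`` must cover all 125 codes for every channel (one classifier
    kind); ``table`` supplies feature values and labels for the ANOVA
    screen.  Screening is reported, not enforced: insignificant features
    are flagged but kept.
    """
    by_channel: dict[str, list[AccuracyRecord]] = {}
    for r in records:
        by_channel.setdefault(r.channel, []).append(r)
    order = list(channel_order) if channel_order is not None else list(by_channel)
    labels = list(table.labels)
    per_channel = []
    for ch in order:
        if ch not in by_channel:
            raise IncompleteEvaluationError(f"no records for channel {ch!r}")
        feat = best_code_per_channel(by_channel[ch])
        f_stat, p = anova_screen(table.feature(feat.channel, feat.code), labels)
        per_channel.append(
            ChannelSpecificFeature(
                channel=feat.channel,
                code=feat.code,
                classifier=feat.classifier,
                accuracy=feat.accuracy,
                anova_f=f_stat,
                anova_p=p,
            )
        )
    best = optimal_feature(per_channel, channel_order=order)
    regions, types = summarize(per_channel)
    return SelectionReport(
        per_channel=tuple(per_channel),
        optimal=best,
        region_tally=regions,
        rhythm_type_tally=types,
    )
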