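"""Dataset I/O, pipeline configuration, and the end-to-end workflow.

The neutral on-disk dialect is one delimited matrix per trial (rows =
samples, cols = channels) plus a JSON sidecar carrying ``fs``, channel
names and per-trial labels.  Labels may be strings (used as-is) or
numeric ratings, which are thresholded at 5 into high/low classes
(rating >= 5 is high).  EDF input is supported when ``pyedflib`` is
installed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError, InvalidInputError
from .evaluation import (
    ClassifierSpec,
    evaluate_table,
    majority_vote_all_features,
    records_to_frame,
)
from .rhythm_codes import build_feature_table, write_feature_table
from .selection import SelectionReport, select_features
from .sequencing import BandPartition, sequence_trial, write_sequences
from .synth import SynthDataset
from .timefreq import SignalSegment, SmoothingSpec

__all__ = [
    "PipelineConfig",
    "threshold_rating",
    "write_dataset",
    "read_trials",
    "read_edf_trials",
    "run_pipeline",
]

RATING_THRESHOLD = 5.0


def threshold_rating(rating: float, high: str = "high", low: str = "low") -> str:
    """Binary class from a 1-9 self-assessment rating (>= 5 is high)."""
    return high if rating >= RATING_THRESHOLD else low


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs; defaults follow the reference design."""

    data_dir: str = ""
    output_dir: str = "out"
    interval: float = 0.2
    analysis_window_s: float | None = 30.0
    block_s: float = 2.0
    band_edges: tuple[float, ...] = (0.0, 4.0, 8.0, 13.0, 30.0, 50.0)
    g_length: int | None = None  # None -> round(block/10), odd
    h_length: int | None = None  # None -> round(block/4), odd
    classifiers: tuple[str, ...] = ("knn", "svm_rbf", "lda", "logreg")
    knn_k: int | None = None  # None -> 3 for <=20 trials, else 5
    selection_classifier: str = "svm_rbf"
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.selection_classifier not in self.classifiers:
            raise ConfigError(
                f"selection classifier {self.selection_classifier!r} is not "
                f"among {self.classifiers}"
            )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("band_edges", "classifiers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def smoothing_spec(self, block_samples: int) -> SmoothingSpec:
        if self.g_length is None and self.h_length is None:
            return SmoothingSpec.default(block_samples)
        from scipy.signal.windows import hamming

        def win(length: int | None, frac: float) -> np.ndarray:
            if length is None:
                length = max(int(round(block_samples * frac)), 1)
                length += length % 2 == 0
            return hamming(length, sym=True) if length > 1 else np.ones(1)

        return SmoothingSpec(g=win(self.g_length, 0.1), h=win(self.h_length, 0.25))


# ---------------------------------------------------------------------------
# dataset dialect: per-trial delimited matrices + JSON sidecar
# ---------------------------------------------------------------------------

def write_dataset(dataset: SynthDataset, directory: str | Path) -> Path:
    """Write a synthetic dataset in the neutral on-disk dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    channels = list(dataset.channels)
    trials = {}
    for tid in dataset.trial_ids:
        matrix = np.column_stack(
            [dataset.segments[tid, ch].samples for ch in channels]
        )
        fname = f"{tid}.tsv"
        np.savetxt(directory / fname, matrix, delimiter="\t", fmt="%.17g")
        trials[tid] = {"file": fname, "label": dataset.labels[tid]}
    sidecar = {
        "fs": dataset.config.fs,
        "channels": channels,
        "subject": "synth",
        "trials": trials,
    }
    with open(directory / "dataset.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return directory


def read_trials(
    directory: str | Path,
) -> tuple[dict[tuple[str, str], SignalSegment], dict[str, str], dict]:
    """Load a dataset directory into segments + labels.

    Returns ``(segments, labels, meta)`` where segments maps
    ``(trial_id, channel)`` to a :class:`SignalSegment` and meta carries
    ``fs``, ``channels`` and ``subject``.  Numeric labels are thresholded
    at 5 into high/low.
    """
    directory = Path(directory)
    sidecar_path = directory / "dataset.json"
    if not sidecar_path.exists():
        raise InvalidInputError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    for key in ("fs", "channels", "trials"):
        if key not in sidecar:
            raise InvalidInputError(f"sidecar lacks required key {key!r}")
    fs = float(sidecar["fs"])
    channels = list(sidecar["channels"])
    subject = str(sidecar.get("subject", ""))
    segments: dict[tuple[str, str], SignalSegment] = {}
    labels: dict[str, str] = {}
    for tid, info in sidecar["trials"].items():
        if "label" not in info:
            raise InvalidInputError(f"trial {tid!r} has no label")
        label = info["label"]
        labels[tid] = (
            threshold_rating(float(label))
            if isinstance(label, (int, float)) and not isinstance(label, bool)
            else str(label)
        )
        matrix = np.loadtxt(directory / info["file"], delimiter="\t", ndmin=2)
        if matrix.shape[1] != len(channels):
            raise InvalidInputError(
                f"trial {tid!r} has {matrix.shape[1]} columns but the sidecar "
                f"declares {len(channels)} channels"
            )
        for j, ch in enumerate(channels):
            segments[tid, ch] = SignalSegment(
                matrix[:, j], fs, channel=ch, trial_id=tid, subject_id=subject
            )
    meta = {"fs": fs, "channels": channels, "subject": subject}
    return segments, labels, meta


def read_edf_trials(path: str | Path, labels: dict[str, str]):  # pragma: no cover
    """Load one EDF recording as a single trial (requires pyedflib)."""
    try:
        import pyedflib
    except ImportError as exc:
        raise ImportError(
            "EDF input requires the optional 'pyedflib' package; install it or "
            "convert the recording to the delimited-matrix + JSON dialect"
        ) from exc
    with pyedflib.EdfReader(str(path)) as reader:
        channels = reader.getSignalLabels()
        fs = reader.getSampleFrequency(0)
        segments = {}
        for j, ch in enumerate(channels):
            segments["trial-000", ch] = SignalSegment(
                reader.readSignal(j), fs, channel=ch, trial_id="trial-000"
            )
    return segments, labels, {"fs": fs, "channels": channels, "subject": ""}


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def _log(fh, message: str) -> None:
    fh.write(message + "\n")


def run_pipeline(
    cfg: PipelineConfig,
    segments: dict[tuple[str, str], SignalSegment] | None = None,
    labels: dict[str, str] | None = None,
    meta: dict | None = None,
) -> SelectionReport:
    """Sequence -> extract -> evaluate -> select -> summarise, with artifacts.

    Inputs come either from ``cfg.data_dir`` or from pre-loaded
    ``segments``/``labels``/``meta``.  Writes sequences (FASTA-like),
    feature and accuracy CSVs, the selection report JSON, and a log with
    versions, seed, and the config hash.  Deterministic for a fixed
    config: rerunning yields byte-identical report JSON.
    """
    if segments is None:
        if not cfg.data_dir:
            raise ConfigError("either a data_dir or in-memory segments are required")
        segments, labels, meta = read_trials(cfg.data_dir)
    assert labels is not None and meta is not None
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bands = BandPartition(edges=tuple(cfg.band_edges))
    fs = float(meta["fs"])
    block_samples = int(round(cfg.block_s * fs))
    spec = cfg.smoothing_spec(block_samples)
    channels = list(meta["channels"])
    trial_ids = sorted(labels)

    with open(out / "pipeline.log", "w") as log:
        _log(log, f"config_hash={cfg.content_hash()}")
        _log(log, f"seed={cfg.seed}")
        _log(log, f"python={sys.version.split()[0]} numpy={np.__version__}")
        _log(log, f"n_trials={len(trial_ids)} n_channels={len(channels)}")

        sequences = []
        for tid in trial_ids:
            for ch in channels:
                try:
                    seq = sequence_trial(
                        segments[tid, ch],
                        spec=spec,
                        bands=bands,
                        interval=cfg.interval,
                        block_s=cfg.block_s,
                        analysis_window_s=cfg.analysis_window_s,
                        label=labels[tid],
                    )
                except Exception as exc:
                    raise InvalidInputError(
                        f"sequencing failed for trial {tid!r} channel {ch!r}: {exc}"
                    ) from exc
                sequences.append(seq)
                _log(log, f"sequence trial={tid} channel={ch} length={len(seq)}")
        write_sequences(sequences, out / "sequences.fasta")

        table = build_feature_table(
            sequences, labels=labels, subject_id=str(meta.get("subject", ""))
        )
        write_feature_table(table, out / "features.csv")
        _log(log, f"features n_columns={table.n_features}")

        n_trials = len(trial_ids)
        k = cfg.knn_k if cfg.knn_k is not None else ClassifierSpec.default_k(n_trials)
        specs = [
            ClassifierSpec(kind=kind, k=k, C=cfg.svm_c) for kind in cfg.classifiers
        ]
        records = evaluate_table(table, specs)
        records_to_frame(records).to_csv(out / "accuracy.csv", index=False)
        _log(log, f"evaluated {len(records)} (feature, classifier) pairs")

        sel_records = [r for r in records if r.classifier == cfg.selection_classifier]
        report = select_features(sel_records, table, channel_order=channels)
        report.to_json(out / "report.json")
        _log(
            log,
            f"optimal channel={report.optimal.channel} code={report.optimal.code} "
            f"accuracy={report.optimal.accuracy:.4f}",
        )
        _, vote_acc = majority_vote_all_features(sel_records, list(table.labels))
        _log(log, f"majority_vote_accuracy={vote_acc:.4f}")
    return report
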