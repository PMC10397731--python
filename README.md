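# rhythmcode

EEG trials are turned into symbol sequences over the five brain rhythms
(δ θ α β γ → `D T A B G`), 3-base "rhythm code" count features are
extracted from those sequences, and a single optimal channel-specific
feature is selected by leave-one-trial-out cross-validation — with a
synthetic EEG generator that makes every stage testable end to end.

Pipeline stages (one module each):

| module          | role |
|-----------------|------|
| `timefreq`      | discrete WVD, smoothed pseudo-WVD (separable time/lag windows), and reassigned SPWVD with exact energy conservation; long segments run in 0.2 s-aligned blocks |
| `sequencing`    | five-band × 0.2 s-timestamp box averages of clipped power, dominant-band argmax, FASTA-like sequence I/O, last-30 s analysis-window rule |
| `rhythm_codes`  | 125-way sliding-window (k=3, stride 1) code counting, feature-table assembly and CSV I/O |
| `evaluation`    | LOTO-CV with k-NN / RBF-SVM (OVO) / LDA (OVO) / multinomial LR on scalar features, plus the all-features majority-vote baseline |
| `selection`     | best code per channel → best channel overall, one-way ANOVA screening (reported, not enforced), scalp-region and rhythm-type summaries |
| `synth`         | phase-continuous five-carrier generator with known dominant-band schedules and class-conditional planted code motifs |
| `workflow_io`   | delimited-matrix + JSON-sidecar dataset dialect, pipeline config, artifacts, logging |

## CLI

```sh
# generate a planted-motif synthetic dataset (8 channels, 20+20 trials)
rhythmcode simulate --out data/ --n-channels 8 --n-trials 20 --seed 1

# full pipeline: sequences, features, accuracies, selection report
rhythmcode run --data data/ --out results/ --block 1.0

# or stage by stage
rhythmcode sequence --data data/ --out seqs.fasta --block 1.0
rhythmcode extract  --sequences seqs.fasta --out features.csv
rhythmcode evaluate --features features.csv --out accuracy.csv
rhythmcode select   --features features.csv --out report.json
```

Input datasets are a directory of per-trial delimited matrices
(rows = samples, cols = channels) plus `dataset.json` declaring `fs`,
channel names and per-trial labels; numeric labels are thresholded at 5
into high/low classes. EDF input works when `pyedflib` is installed.

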