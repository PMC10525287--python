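# remwave

Interpretable REM vs non-REM sleep staging from a single EEG channel.

Clinical sleep scoring assigns each 30 s epoch of a polysomnogram one of
the stages W, R (REM), 1–4, plus movement (M) and not-scored (?) marks.
`remwave` implements a binary REM detector for a single 100 Hz EEG channel
(3000 samples per epoch) that is built for interpretability rather than
leaderboard accuracy, together with the tooling around it: epoch
extraction from PSG/hypnogram text exports, a synthetic EEG generator for
testing, a hyperparameter random search, and a filter-similarity analysis
that asks which learned convolution kernels survive changes of
preprocessing.

## The model

Each epoch `x ∈ ℝ³⁰⁰⁰` is split into the five classical EEG bands with a
5-level discrete wavelet transform (mother wavelet configurable, e.g.
db2).  Level *n* of the DWT halves the effective sample rate,

    fs_n = fs / 2ⁿ            (fs = 100 Hz)

so detail coefficients at levels 1–4 represent Beta2/Beta1/Alpha/Theta
and the remaining low-frequency content at level 5 is Delta; each band is
reconstructed to full length by inverting the transform with every other
band's coefficients zeroed.  One small CNN per band scores single epochs
as REM/non-REM; its kernel spans roughly one period of a representative
in-band frequency *rf*,

    kernel = floor(fs / rf)  →  Delta 35, Theta 19, Alpha 10, Beta1 5, Beta2 2.

The five CNNs' penultimate activations are concatenated per epoch, and a
two-layer bidirectional GRU (104 then 302 units per direction, three
dense layers, softmax) classifies the middle epoch of each consecutive
(previous, target, next) triple — mirroring how human scorers use
context.  Training uses stratified k-fold cross-validation with
validation-loss early stopping and the batch size
`int(R(1−V)/C + 1)` for R records, validation split V and C folds.
The neural-network layer underneath is a small self-contained numpy
engine (`remwave.nn`) with hand-derived gradients, verified against
finite differences in the test suite.

For interpretability, first-layer kernels are extracted from models
trained under different mother wavelets and compared within each band by
Spearman rank correlation; the 95th percentile of all coefficients
serves as a similarity threshold and filters are ranked by how many
cross-model comparisons exceed it — a filter that every preprocessing
rediscovers is likely a real waveform feature (spindle, slow wave), not
an artifact.

## Worked example

```sh
remwave synth --seed 1 --n-epochs 40 --patient 15 --night 2 --out demo
remwave prep --in demo/psg152.txt --hyp demo/hyp152.txt \
             --patient 15 --night 2 --out demo
```

`prep` prints the pre-filter annotation tally (stage, count) and writes
`demo/input152.csv`, one labelled epoch per line:

```
W	3
R	7
1	6
2	8
3	4
4	10
M	2
demo/input152.csv
```

Movement epochs are dropped and all leading wake epochs but the last are
trimmed before the file is written.  Training the full model on a
prepared dataset and printing held-out confusion metrics (REM positive):

```sh
remwave train --data demo/input152.csv --max-epochs 20 --seed 0 --out run
```

```json
{"holdout": {"accuracy": 0.978, "f1": 0.966, "fn": 1, "fp": 0, ...,
             "precision": 1.0, "recall": 0.933, "tn": 83, "tp": 42},
 "normalization": {"normMean": -0.019, "normSTD": 19.3}}
```

(`accuracy` is the fraction of held-out epoch triples whose middle epoch
is scored correctly; `tp/fp/fn/tn` are the REM-positive confusion
counts.  Exact values depend on the dataset size and seed.)  The same
library surface is importable directly — `BandCNNClassifier` and
`SequenceGRUClassifier` are scikit-learn estimators with the usual
`fit`/`predict`/`predict_proba`, and compose with sklearn model
selection.

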