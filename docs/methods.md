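# Methods

## Epoching and labelling

A recording arrives as two text files: a `time_s<TAB>value` PSG trace at
100 Hz and a hypnogram of `onset_s<TAB>duration_s<TAB>stage` annotations
at 30 s spacing with stages in {W, R, 1, 2, 3, 4, M, ?}.  Epoch windows
are half-open `[onset, onset + 30 s)` in 0-based samples; an annotation
whose window runs past the end of the signal is dropped with a warning.
Two filtering rules apply, in this order: movement (M) and not-scored
(?) epochs are skipped, then of the leading run of wake epochs only the
last one — the epoch immediately before the first non-wake epoch — is
kept.  Ordering matters for sequences like `W M ? W 2`: skipping first
makes the second W the final leading-wake epoch, so `W 2` survives.  A
recording that never leaves wake yields zero epochs (the "last wake
before first non-wake" is undefined; dropping everything is the
conservative reading).  Trailing wake epochs are retained — there is no
rule that would remove them.  Surviving epochs are labelled REM (stage
R) or NonREM (everything else) and written to `input{PP}{n}.csv`, label
field first, one epoch per line, with the patient code zero-padded to
two digits.

Normalization is a z-score with the mean and **population** (divide-by-N)
standard deviation pooled over every sample of every retained epoch in
the dataset, i.e. computed across all files including what later becomes
test folds.  That dataset-global convention is deliberate (it matches how
the printed normalization constants of the reference workflow are
produced); computing fold-local parameters is available to callers who
want leak-free normalization, by normalizing per training split before
fitting.

## Wavelet banding

`pywt.wavedec` with symmetric padding gives coefficient lengths
`len_k = floor((len_{k−1} + L − 1)/2)` (L = wavelet filter length),
which for db2 (L = 4) on 3000 samples produces the ladder
1501, 752, 377, 190, 96, 49, 26, 14 at levels 1–8.  The closed-form
recursion in `coefficient_count` and the actual transform are tested
against each other across many lengths and wavelets.

Band mapping on the level-5 decomposition: Beta2 = d1, Beta1 = d2,
Alpha = d3, Theta = d4, and **Delta = cA5 + cD5**.  The inclusion of the
level-5 detail in Delta is a deliberate design choice: cA5 alone covers
only 0–1.56 Hz, so a 2 Hz slow wave — squarely a Delta feature — would
land almost entirely in cD5 (measured: an a5-only reconstruction
captures 4–17% of a 2 Hz tone's energy depending on the wavelet, versus
85–99% for cA5+cD5).  With this mapping the five bands tile the full
0–50 Hz range and their reconstructions sum to the original signal
exactly (linearity of the inverse transform), which is asserted as a
property test.  The "coefficients" representation returns the band's
canonical per-level array (cA5 for Delta, length 96), matching the
per-level ladder above.

The decomposition depth for a 3000-sample epoch is capped at 8: the
level-8 approximation already has only 14 coefficients, and deeper
levels carry no usable band structure.  Only discrete wavelet families
(haar, dbN, symN, coifN, dmey) are accepted; continuous families
(morl, mexh, gausN) have no dyadic decomposition filters and are
rejected with an explicit error rather than silently approximated.
Note that dmey is a truncated FIR approximation of the Meyer wavelet and
reconstructs only to ~1e-2 RMS rather than machine precision; the strict
perfect-reconstruction property is asserted for the orthogonal families.
Passing `none` as the wavelet selects the identity transform (the
no-preprocessing baseline model).

## Models

**Band CNN.**  Conv1D (`n_filters` kernels, valid mode, stride 1) →
tanh → max-pool (2, stride 2) → dense stack with tanh → 2-way softmax.
Kernel sizes default to `floor(100 / rf)` with representative
frequencies 2.8/5.2/10/20/50 Hz, i.e. 35/19/10/5/2 samples.  Each band
CNN is trained independently on single epochs.  The feature tap for the
sequence model is the activation entering the softmax head (the last
hidden dense layer's output); features are frozen once the CNN is
trained.  Fine-tuning the CNNs through the sequence loss is not
implemented — the frozen two-stage scheme keeps the recurrent training
cheap and the CNN filters interpretable as single-epoch feature
detectors, which is the point of the analysis.

**Sequence model.**  Per epoch the five band feature vectors are
concatenated in fixed band order without any rescaling.  Records are
(previous, target, next) triples labelled by the middle epoch; the first
and last epoch of a recording have no complete context and are dropped.
Architecture: BiGRU(104, return sequences) → BiGRU(302) → three dense
layers (defaults 128/64/32, tanh) → softmax.  The GRU uses the classic
formulation (reset gate applied to the previous state before the
candidate's recurrent matmul); recurrent kernels are initialized
orthogonal, input kernels Glorot-uniform.

**Engine.**  No deep-learning framework is used: `remwave.nn` is a
compact numpy engine with hand-derived reverse-mode gradients for every
layer (including backprop-through-time for the bidirectional GRU) and
Adam/RMSprop/SGD updates.  Gradients are validated against central
finite differences to ~1e-6 relative error in the unit tests.  Since the
convolution is always the first trainable layer, it does not propagate a
gradient to its input.

## Training protocol

Stratified C-fold cross-validation (scikit-learn `StratifiedKFold`,
shuffled, seeded).  Within each fold a stratified validation split V
(default 0.1) is carved out of the training portion; early stopping
watches the validation loss with patience 10 (a configurable default —
no principled value exists) and restores the best weights.  The default
batch size is `int(R(1−V)/C + 1)`; training is plain mini-batch descent,
learning rate 3e-3 for the band CNNs and 1e-3 for the sequence model
(tanh networks at these widths train stably in tens of epochs at these
rates).  Per training epoch the full train and validation streams are
scored for loss, accuracy, precision, recall, f1 and ROC-AUC (AUC on a
single-class stream is undefined and recorded as the chance value 0.5).

Test folds report the REM-positive confusion counts and accuracy,
specificity, recall, precision, f1.  Zero-denominator metrics return 0
with a logged warning.  Fold averages are unweighted arithmetic means.

## Random search

Candidates are drawn uniformly from fixed pools: filters {5, 10}, kernel
size {3, 5, 10, 20, 66}, dense depth {1, 2, 3}, widths {16, 32, 64,
128}, optimizer {adam, sgd, rmsprop}, initializers {glorot_uniform,
he_normal, random_normal} × {zeros, random_normal}; activation is always
tanh and the output layer always softmax.  Each candidate is serialized
as a JSON object (`band`, `cnn{filters, kernel_size}`, `dense`,
`activation`, `initializers{kernel, bias}`, `optimizer`) that round-trips
losslessly, and evaluated by the full cross-validation above.  Best
selection is argmax of the mean of any stored metric, ties to the
earliest draw.

## Filter similarity

For each band, every first-layer kernel of every wavelet model is
compared against every kernel of every *other* wavelet model in the same
band by Spearman rank correlation (scipy, average ranks on ties; a
constant kernel yields an undefined correlation, recorded as NaN and
excluded from thresholds).  Signed rho is used, with no shift alignment
or sign canonicalization.  The threshold is the 95th percentile (linear
interpolation between order statistics) of the band's pooled
coefficients — per band by default, because each band's kernel length
sets its own correlation scale: with a 2-sample kernel every
non-constant pair has |rho| = 1, so that band's threshold saturates at
1.0 and, under the strict ">" comparison, no filter can score above it.
A pooled-across-bands threshold is available behind a flag.  Filters are
ranked by the percentage of their cross-model comparisons strictly above
the threshold; ties break by higher mean rho, then (model, index).  The
top five per band are reported.

## Synthetic data

The generator emulates the *shape* of a scored PSG export: 100 Hz trace,
30 s epochs, hypnogram with leading-wake runs, occasional movement
epochs, and class-conditional band-limited content — non-REM epochs get
high-amplitude 0.5–2 Hz slow waves (30 µV default) plus 11–16 Hz
spindle bursts under a Hann envelope, REM epochs low-amplitude 4–7.5 Hz
theta plus a 2–3 Hz sawtooth component, wake epochs 8–12.5 Hz alpha,
all over Gaussian noise (3 µV default).  Default stage mixture: 30% REM
among scored sleep, 2% movement, 3 leading wake epochs.  Amplitudes are
chosen so delta-band power alone separates the classes (a depth-1
threshold reaches ≥95% accuracy), making the learnability tests a test
of the pipeline, not of the task's difficulty.  The stream is keyed by
(seed, patient, night), so multi-recording datasets are reproducible
record by record.

What this generator does **not** model: 1/f background spectra,
K-complex morphology, stage transitions with realistic dwell times,
artifacts, inter-subject variability.  Passing the learnability tests
therefore demonstrates that the pipeline can extract band-power structure
end-to-end; it says nothing about accuracy on real polysomnograms.

## Problem sizes

Test and acceptance runs use a ~500-epoch synthetic dataset, 5-fold
cross-validation for the band CNN, ≤30 training epochs, and a 25%
holdout for the sequence model — small enough to run on one CPU in a few
minutes while keeping both classes populated in every fold.  The
filter-recovery experiment plants a shared motif (σ = 0.05 jitter) into
five 5-filter banks and checks it ranks first in ≥9/10 seeds.

## Known limitations

* The sequence model trains on frozen CNN features; no joint fine-tuning.
* Continuous mother wavelets cannot be used for decomposition (by design).
* The GRU is the classic v1 cell, not the reset-after variant some
  frameworks default to; capacity and behaviour at these sizes are
  equivalent but weights are not interchangeable.
* Dataset-global normalization leaks test-fold statistics by
  construction (kept for fidelity to the reference workflow); use
  per-split normalization when measuring generalization.
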