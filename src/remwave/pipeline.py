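"""End-to-end glue: epoch files -> band CNNs -> sequence model.

Convenience layer used by the command line and the evaluation scripts.
The canonical flow:

1. load one or more ``inputPPn.csv`` epoch files,
2. z-score with dataset-wide normalization parameters,
3. split each epoch into the five DWT bands for the chosen mother
   wavelet (or pass raw epochs through for the ``None`` model),
4. train the five band CNNs independently,
5. freeze their features and train the BiGRU sequence model on
   consecutive epoch triples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .bands import BAND_ORDER, CANONICAL_BANDS, band_signal
from .epochs import EpochRecord, compute_normalization, read_epoch_file
from .models import BandCNNClassifier, SleepSequenceModel, build_sequence_model
from .train_eval import FoldResult, derive_batch_size, evaluate_fold

logger = logging.getLogger(__name__)

__all__ = [
    "load_epoch_files",
    "prepare_band_inputs",
    "train_band_cnns",
    "train_full_model",
    "FullModelResult",
]


def load_epoch_files(paths) -> tuple[list[str], np.ndarray]:
    """Concatenate labels and sample matrices of several epoch files."""
    labels: list[str] = []
    mats = []
    for p in paths:
        lab, X = read_epoch_file(p)
        labels.extend(lab)
        if X.size:
            mats.append(X)
    if not mats:
        raise ValueError("no epochs found in the given files")
    return labels, np.vstack(mats)


def prepare_band_inputs(X: np.ndarray, wavelet: str | None) -> dict:
    """Per-band input matrices (reconstructed representation).

    With ``wavelet`` None/"none" every band model receives the raw
    epochs (the no-preprocessing baseline).
    """
    X = np.asarray(X, dtype=float)
    return {
        band: np.stack([band_signal(row, wavelet, band) for row in X])
        if wavelet and str(wavelet).lower() != "none"
        else X.copy()
        for band in BAND_ORDER
    }


def train_band_cnns(
    band_inputs: dict,
    y,
    seed: int = 0,
    **cnn_overrides,
) -> dict:
    """Train one CNN per band with its Table-style kernel size."""
    out = {}
    n = len(np.asarray(y))
    for i, band in enumerate(BAND_ORDER):
        params = dict(
            n_filters=5,
            kernel_size=CANONICAL_BANDS[band].cnn_kernel_size,
            dense_layers=(64,),
            batch_size=derive_batch_size(n, 0.1, 10),
            random_state=seed + i,
        )
        params.update(cnn_overrides)
        params["kernel_size"] = min(params["kernel_size"], band_inputs[band].shape[1])
        clf = BandCNNClassifier(**params)
        clf.fit(band_inputs[band], y)
        acc = float(np.mean(clf.predict(band_inputs[band]) == np.asarray(y)))
        logger.info("band %s CNN trained; resubstitution accuracy %.3f", band, acc)
        out[band] = clf
    return out


@dataclass
class FullModelResult:
    model: SleepSequenceModel
    band_cnns: dict
    holdout: FoldResult
    normalization: dict = field(default_factory=dict)


def train_full_model(
    X,
    y,
    wavelet: str | None = "db2",
    seed: int = 0,
    holdout_fraction: float = 0.25,
    cnn_overrides: dict | None = None,
    seq_overrides: dict | None = None,
    normalize: bool = True,
) -> FullModelResult:
    """Train the five-band CNN + BiGRU model and score a held-out split.

    The band CNNs train on all epochs (their independent single-epoch
    task); the sequence model's triples are split stratified into
    train/holdout, and the holdout confusion counts are reported.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    norm_info = {}
    if normalize:
        params = compute_normalization(
            [EpochRecord(samples=row, stage="W", index=i) for i, row in enumerate(X)]
        )
        X = params.apply(X)
        norm_info = {"normMean": params.mean, "normSTD": params.sd}
    band_inputs = prepare_band_inputs(X, wavelet)
    band_cnns = train_band_cnns(band_inputs, y, seed=seed, **(cnn_overrides or {}))
    seq_overrides = dict(seq_overrides or {})
    seq_overrides.setdefault("batch_size", derive_batch_size(len(y), 0.1, 10))
    model = build_sequence_model(band_cnns, random_state=seed, **seq_overrides)
    feats = model.featurize(band_inputs)
    triples, y_mid = model.make_triples(feats, y)
    tr, te = train_test_split(
        np.arange(len(y_mid)), test_size=holdout_fraction,
        stratify=y_mid, random_state=seed,
    )
    model.sequence.fit(triples[tr], y_mid[tr])
    holdout = evaluate_fold(model.sequence, (triples[te], y_mid[te]))
    return FullModelResult(
        model=model, band_cnns=band_cnns, holdout=holdout, normalization=norm_info
    )
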