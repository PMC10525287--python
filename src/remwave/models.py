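"""Candidate specs and sklearn-style estimators for the staging models.

Two trainable pieces make up the architecture:

* :class:`BandCNNClassifier` - one shallow CNN per frequency band,
  trained independently on single 30 s epochs to score REM vs non-REM
  (conv -> tanh -> max-pool -> dense stack -> 2-way softmax).
* :class:`SequenceGRUClassifier` - a two-layer bidirectional GRU
  (104 then 302 units per direction) over the three-epoch context
  (previous, target, next), followed by three dense layers and softmax.

:class:`SleepSequenceModel` composes them: the five band CNNs have their
softmax heads removed and their penultimate activations, concatenated
across bands, become the per-epoch feature vector fed to the recurrent
model.  Hyperparameter candidates are described by the JSON-serializable
:class:`CandidateSpec` that the random search draws and the model builder
materializes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from . import nn
from .bands import BAND_ORDER, CANONICAL_BANDS, band_signal
from .train_eval import FitHistory, compute_stream_metrics

__all__ = [
    "CandidateSpec",
    "build_candidate",
    "build_band_cnn",
    "build_sequence_model",
    "BandCNNClassifier",
    "SequenceGRUClassifier",
    "SleepSequenceModel",
    "WaveletBandTransformer",
    "DEFAULT_SEARCH_SPACE",
]

#: Default hyperparameter pools for the random search.
DEFAULT_SEARCH_SPACE = {
    "n_filters": (5, 10),
    "kernel_size": (3, 5, 10, 20, 66),
    "dense_depth": (1, 2, 3),
    "dense_width": (16, 32, 64, 128),
    "activation": ("tanh",),
    "kernel_initializer": ("glorot_uniform", "he_normal", "random_normal"),
    "bias_initializer": ("zeros", "random_normal"),
    "optimizer": ("adam", "sgd", "rmsprop"),
}


@dataclass(frozen=True)
class CandidateSpec:
    """JSON-serializable description of one band-CNN candidate."""

    band: str
    n_filters: int
    kernel_size: int
    dense_layers: tuple
    activation: str = "tanh"
    kernel_initializer: str = "glorot_uniform"
    bias_initializer: str = "zeros"
    optimizer: str = "adam"

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "cnn": {"filters": self.n_filters, "kernel_size": self.kernel_size},
            "dense": list(self.dense_layers),
            "activation": self.activation,
            "initializers": {
                "kernel": self.kernel_initializer,
                "bias": self.bias_initializer,
            },
            "optimizer": self.optimizer,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CandidateSpec":
        unknown = set(d) - {"band", "cnn", "dense", "activation", "initializers", "optimizer"}
        if unknown:
            raise ValueError(f"unknown candidate fields: {sorted(unknown)}")
        return cls(
            band=d["band"],
            n_filters=int(d["cnn"]["filters"]),
            kernel_size=int(d["cnn"]["kernel_size"]),
            dense_layers=tuple(int(w) for w in d["dense"]),
            activation=d.get("activation", "tanh"),
            kernel_initializer=d.get("initializers", {}).get("kernel", "glorot_uniform"),
            bias_initializer=d.get("initializers", {}).get("bias", "zeros"),
            optimizer=d.get("optimizer", "adam"),
        )

    @classmethod
    def from_json(cls, s: str) -> "CandidateSpec":
        return cls.from_dict(json.loads(s))


def build_candidate(rng: np.random.Generator, band: str, space: dict | None = None) -> CandidateSpec:
    """Draw one candidate uniformly from the (default) hyperparameter pools."""
    if band not in CANONICAL_BANDS:
        raise ValueError(f"unknown band {band!r}")
    sp = dict(DEFAULT_SEARCH_SPACE)
    if space:
        sp.update(space)
    depth = int(rng.choice(sp["dense_depth"]))
    dense = tuple(int(rng.choice(sp["dense_width"])) for _ in range(depth))
    return CandidateSpec(
        band=band,
        n_filters=int(rng.choice(sp["n_filters"])),
        kernel_size=int(rng.choice(sp["kernel_size"])),
        dense_layers=dense,
        activation=str(rng.choice(sp["activation"])),
        kernel_initializer=str(rng.choice(sp["kernel_initializer"])),
        bias_initializer=str(rng.choice(sp["bias_initializer"])),
        optimizer=str(rng.choice(sp["optimizer"])),
    )


# ---------------------------------------------------------------------------
# shared training loop

def _encode_labels(y, classes):
    """Map labels to 0/1 with REM (or the last class) as positive."""
    classes = list(classes)
    if "REM" in classes:
        pos = "REM"
    else:
        pos = classes[-1]
    y = np.asarray(y)
    return (y == pos).astype(int), pos


def _fit_network(
    net: nn.Sequential,
    X,
    y01,
    *,
    optimizer: str,
    learning_rate: float,
    batch_size: int | None,
    max_epochs: int,
    validation: tuple | None,
    patience: int,
    rng: np.random.Generator,
) -> FitHistory:
    """Mini-batch training with validation-loss early stopping.

    ``batch_size=None`` trains full-batch.  Stops once the validation loss
    has not improved for ``patience`` consecutive epochs and restores the
    best weights seen.
    """
    n = X.shape[0]
    onehot = np.eye(2)[y01]
    opt = nn.make_optimizer(optimizer, learning_rate)
    bs = n if batch_size is None else max(1, min(int(batch_size), n))
    history = FitHistory()
    best_val = np.inf
    best_weights = None
    stale = 0
    for _epoch in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            logits = net.forward(X[idx])
            loss, _, grad = nn.softmax_cross_entropy(logits, onehot[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged (non-finite loss)")
            net.backward(grad)
            opt.update(net.param_layers())
        row = _stream_row(net, X, y01, prefix="")
        if validation is not None:
            Xv, yv01 = validation
            vrow = _stream_row(net, Xv, yv01, prefix="val_")
            row.update(vrow)
            val_loss = vrow["val_loss"]
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = net.get_weights()
                stale = 0
            else:
                stale += 1
        history.append(row)
        if validation is not None and stale >= patience:
            break
    if best_weights is not None:
        net.set_weights(best_weights)
    return history


def _stream_row(net, X, y01, prefix=""):
    logits = net.forward(X)
    loss, p, _ = nn.softmax_cross_entropy(logits, np.eye(2)[y01])
    metrics = compute_stream_metrics(y01, p[:, 1])
    row = {f"{prefix}loss": float(loss)}
    row.update({f"{prefix}{k}": v for k, v in metrics.items()})
    return row


# ---------------------------------------------------------------------------
# estimators

class BandCNNClassifier(BaseEstimator, ClassifierMixin):
    """Per-band CNN scoring single epochs as REM vs non-REM.

    Architecture: one valid-mode convolution (``n_filters`` kernels of
    ``kernel_size`` samples) with tanh, one max-pool, then a dense stack
    with tanh and a 2-way softmax head.  Training is mini-batch gradient
    descent with validation-loss early stopping (best weights restored).

    Parameters follow the hyperparameter vocabulary of the random search;
    ``batch_size=None`` means full-batch.
    """

    def __init__(
        self,
        n_filters: int = 5,
        kernel_size: int = 35,
        dense_layers: tuple = (64,),
        activation: str = "tanh",
        kernel_initializer: str = "glorot_uniform",
        bias_initializer: str = "zeros",
        optimizer: str = "adam",
        learning_rate: float = 3e-3,
        batch_size: int | None = None,
        max_epochs: int = 30,
        validation_split: float = 0.1,
        patience: int = 10,
        pool_size: int = 2,
        pool_stride: int = 2,
        random_state: int | None = None,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.dense_layers = dense_layers
        self.activation = activation
        self.kernel_initializer = kernel_initializer
        self.bias_initializer = bias_initializer
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_split = validation_split
        self.patience = patience
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.random_state = random_state

    # -- construction -------------------------------------------------
    @classmethod
    def from_candidate(cls, spec: CandidateSpec, **overrides) -> "BandCNNClassifier":
        kw = dict(
            n_filters=spec.n_filters,
            kernel_size=spec.kernel_size,
            dense_layers=spec.dense_layers,
            activation=spec.activation,
            kernel_initializer=spec.kernel_initializer,
            bias_initializer=spec.bias_initializer,
            optimizer=spec.optimizer,
        )
        kw.update(overrides)
        return cls(**kw)

    def _build_net(self, input_length: int, rng) -> nn.Sequential:
        if self.activation != "tanh":
            raise ValueError("only tanh hidden activations are supported")
        if self.kernel_size > input_length:
            raise ValueError(
                f"kernel_size {self.kernel_size} exceeds input length {input_length}"
            )
        layers: list[nn.Layer] = [
            nn.Conv1D(self.n_filters, self.kernel_size, rng,
                      self.kernel_initializer, self.bias_initializer),
            nn.Tanh(),
            nn.MaxPool1D(self.pool_size, self.pool_stride),
            nn.Flatten(),
        ]
        t_conv = input_length - self.kernel_size + 1
        t_pool = (t_conv - self.pool_size) // self.pool_stride + 1
        width = t_pool * self.n_filters
        for w in self.dense_layers:
            layers.append(nn.Dense(width, int(w), rng,
                                   self.kernel_initializer, self.bias_initializer))
            layers.append(nn.Tanh())
            width = int(w)
        layers.append(nn.Dense(width, 2, rng,
                               self.kernel_initializer, self.bias_initializer))
        return nn.Sequential(layers)

    # -- sklearn API --------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D (n_epochs, n_samples), got {X.shape}")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(self.classes_)}")
        y01, self.positive_class_ = _encode_labels(y, self.classes_)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(X.shape[1], rng)
        if self.validation_split and 0.0 < self.validation_split < 1.0:
            Xt, Xv, yt, yv = train_test_split(
                X, y01, test_size=self.validation_split, stratify=y01,
                random_state=int(rng.integers(2**31 - 1)),
            )
            validation = (Xv, yv)
        else:
            Xt, yt, validation = X, y01, None
        self.history_ = _fit_network(
            self.net_, Xt, yt,
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            validation=validation, patience=self.patience, rng=rng,
        )
        self.conv_weights_ = self.net_.layers[0].params["W"].copy()
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        logits = self.net_.forward(np.asarray(X, dtype=float))
        p = nn.softmax(logits)
        # column order follows self.classes_
        pos_col = p[:, 1]
        out = np.empty_like(p)
        for i, c in enumerate(self.classes_):
            out[:, i] = pos_col if c == self.positive_class_ else 1.0 - pos_col
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def features(self, X):
        """Penultimate activations (softmax head removed)."""
        check_is_fitted(self, "net_")
        x = np.asarray(X, dtype=float)
        for layer in self.net_.layers[:-1]:
            x = layer.forward(x)
        return x

    @property
    def feature_dim_(self) -> int:
        check_is_fitted(self, "net_")
        return self.net_.layers[-1].params["W"].shape[0]


def build_band_cnn(spec: CandidateSpec, input_length: int, **overrides) -> BandCNNClassifier:
    """Materialize a candidate spec as an (unfitted) classifier."""
    if spec.kernel_size > input_length:
        raise ValueError(
            f"kernel_size {spec.kernel_size} exceeds input length {input_length}"
        )
    return BandCNNClassifier.from_candidate(spec, **overrides)


class SequenceGRUClassifier(BaseEstimator, ClassifierMixin):
    """BiGRU sequence classifier over three-epoch feature triples.

    Input shape ``(n, 3, d)``: the concatenated band features of the
    previous, target and next epoch.  Two bidirectional GRU layers (104
    and 302 units per direction), three dense layers with tanh, softmax
    output labelling the middle epoch.
    """

    def __init__(
        self,
        gru1_units: int = 104,
        gru2_units: int = 302,
        dense_layers: tuple = (128, 64, 32),
        optimizer: str = "adam",
        learning_rate: float = 1e-3,
        batch_size: int | None = None,
        max_epochs: int = 30,
        validation_split: float = 0.1,
        patience: int = 10,
        random_state: int | None = None,
    ):
        self.gru1_units = gru1_units
        self.gru2_units = gru2_units
        self.dense_layers = dense_layers
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_split = validation_split
        self.patience = patience
        self.random_state = random_state

    def _build_net(self, d_in: int, rng) -> nn.Sequential:
        layers: list[nn.Layer] = [
            nn.BiGRU(d_in, self.gru1_units, rng, return_sequences=True),
            nn.BiGRU(2 * self.gru1_units, self.gru2_units, rng, return_sequences=False),
        ]
        width = 2 * self.gru2_units
        for w in self.dense_layers:
            layers.append(nn.Dense(width, int(w), rng))
            layers.append(nn.Tanh())
            width = int(w)
        layers.append(nn.Dense(width, 2, rng))
        return nn.Sequential(layers)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"X must be 3-D (n, steps, features), got {X.shape}")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(self.classes_)}")
        y01, self.positive_class_ = _encode_labels(y, self.classes_)
        self.n_features_in_ = X.shape[2]
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(X.shape[2], rng)
        if self.validation_split and 0.0 < self.validation_split < 1.0:
            Xt, Xv, yt, yv = train_test_split(
                X, y01, test_size=self.validation_split, stratify=y01,
                random_state=int(rng.integers(2**31 - 1)),
            )
            validation = (Xv, yv)
        else:
            Xt, yt, validation = X, y01, None
        self.history_ = _fit_network(
            self.net_, Xt, yt,
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            batch_size=self.batch_size, max_epochs=self.max_epochs,
            validation=validation, patience=self.patience, rng=rng,
        )
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        logits = self.net_.forward(np.asarray(X, dtype=float))
        p = nn.softmax(logits)
        pos_col = p[:, 1]
        out = np.empty_like(p)
        for i, c in enumerate(self.classes_):
            out[:, i] = pos_col if c == self.positive_class_ else 1.0 - pos_col
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]


class WaveletBandTransformer(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer: raw epochs -> one band's signal.

    ``wavelet="none"`` passes the raw epochs through unchanged.
    """

    def __init__(self, band: str = "Delta", wavelet: str = "db2",
                 representation: str = "reconstructed"):
        self.band = band
        self.wavelet = wavelet
        self.representation = representation

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.stack([
            band_signal(row, self.wavelet, self.band, self.representation)
            for row in X
        ])


class SleepSequenceModel:
    """The full five-band CNN + BiGRU architecture.

    Composes five fitted (or fittable) band CNNs with a sequence
    classifier.  Band CNN features are frozen after their independent
    training; the recurrent part trains on the concatenated features of
    consecutive epoch triples, labelled by the middle epoch.
    """

    def __init__(self, band_cnns: dict, sequence: SequenceGRUClassifier):
        missing = [b for b in BAND_ORDER if b not in band_cnns]
        if missing:
            raise ValueError(f"missing band models: {missing}")
        self.band_cnns = dict(band_cnns)
        self.sequence = sequence

    def featurize(self, band_inputs: dict) -> np.ndarray:
        """Concatenate per-epoch features of the five bands, in band order."""
        feats = []
        n = None
        for b in BAND_ORDER:
            f = self.band_cnns[b].features(band_inputs[b])
            if n is None:
                n = f.shape[0]
            elif f.shape[0] != n:
                raise ValueError("band inputs disagree on epoch count")
            feats.append(f)
        return np.concatenate(feats, axis=1)

    @staticmethod
    def make_triples(features: np.ndarray, y=None):
        """Stack (previous, target, next) epoch windows; edges dropped."""
        n = features.shape[0]
        if n < 3:
            raise ValueError("need at least 3 epochs to form a triple")
        triples = np.stack([features[:-2], features[1:-1], features[2:]], axis=1)
        if y is None:
            return triples
        return triples, np.asarray(y)[1:-1]

    def fit_sequence(self, band_inputs: dict, y):
        feats = self.featurize(band_inputs)
        triples, y_mid = self.make_triples(feats, y)
        self.sequence.fit(triples, y_mid)
        return self

    def predict(self, band_inputs: dict):
        feats = self.featurize(band_inputs)
        return self.sequence.predict(self.make_triples(feats))

    def predict_proba(self, band_inputs: dict):
        feats = self.featurize(band_inputs)
        return self.sequence.predict_proba(self.make_triples(feats))


def build_sequence_model(band_cnns: dict, **seq_params) -> SleepSequenceModel:
    """Assemble the Fig-4-style architecture from five fitted band CNNs."""
    dims = {b: band_cnns[b].feature_dim_ for b in BAND_ORDER if b in band_cnns}
    if len(dims) != 5:
        raise ValueError(f"need all five band models, got {sorted(band_cnns)}")
    return SleepSequenceModel(band_cnns, SequenceGRUClassifier(**seq_params))
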