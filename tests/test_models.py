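"""Candidate specs and the band-CNN / sequence estimators."""

import json

import numpy as np
import pytest

from remwave.models import (
    BandCNNClassifier,
    CandidateSpec,
    DEFAULT_SEARCH_SPACE,
    SequenceGRUClassifier,
    build_band_cnn,
    build_candidate,
    build_sequence_model,
)
from remwave.bands import BAND_ORDER


class TestCandidateSpec:
    def test_json_round_trip_is_byte_identical(self):
        spec = CandidateSpec(band="Delta", n_filters=5, kernel_size=35,
                             dense_layers=(64, 32))
        s1 = spec.to_json()
        s2 = CandidateSpec.from_json(s1).to_json()
        assert s1 == s2

    def test_unknown_fields_rejected(self):
        d = json.loads(CandidateSpec(band="Delta", n_filters=5, kernel_size=3,
                                     dense_layers=(16,)).to_json())
        d["dropout"] = 0.5
        with pytest.raises(ValueError, match="dropout"):
            CandidateSpec.from_dict(d)

    def test_default_draws_stay_in_documented_pools(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            spec = build_candidate(rng, "Theta")
            assert spec.n_filters in (5, 10)
            assert spec.kernel_size in (3, 5, 10, 20, 66)
            assert 1 <= len(spec.dense_layers) <= 3
            assert all(w in (16, 32, 64, 128) for w in spec.dense_layers)
            assert spec.activation == "tanh"
            assert spec.optimizer in DEFAULT_SEARCH_SPACE["optimizer"]

    def test_unknown_band_rejected(self):
        with pytest.raises(ValueError):
            build_candidate(np.random.default_rng(0), "Gamma")


class TestBandCNN:
    def test_softmax_output_normalized(self, small_dataset):
        X, y = small_dataset
        clf = BandCNNClassifier(max_epochs=1, random_state=0).fit(X, y)
        p = clf.predict_proba(X[:5])
        assert p.shape == (5, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_same_spec_same_seed_same_initial_weights(self):
        spec = CandidateSpec(band="Delta", n_filters=5, kernel_size=10,
                             dense_layers=(16,))
        a = build_band_cnn(spec, 100, random_state=3)
        b = build_band_cnn(spec, 100, random_state=3)
        rng_a = np.random.default_rng(3)
        rng_b = np.random.default_rng(3)
        net_a = a._build_net(100, rng_a)
        net_b = b._build_net(100, rng_b)
        for la, lb in zip(net_a.param_layers(), net_b.param_layers()):
            for k in la.params:
                assert np.array_equal(la.params[k], lb.params[k])

    def test_fit_is_deterministic_for_fixed_seed(self, small_dataset):
        X, y = small_dataset
        p1 = BandCNNClassifier(max_epochs=2, random_state=5).fit(X, y).predict_proba(X)
        p2 = BandCNNClassifier(max_epochs=2, random_state=5).fit(X, y).predict_proba(X)
        assert np.array_equal(p1, p2)

    def test_parameter_count_toy_arithmetic(self):
        """conv(2 filters x 3) + dense(4) + head on length-10 input."""
        clf = BandCNNClassifier(n_filters=2, kernel_size=3, dense_layers=(4,),
                                pool_size=2, pool_stride=2, random_state=0)
        net = clf._build_net(10, np.random.default_rng(0))
        # conv out length 8, pooled 4 -> flatten 8; dense 8*4+4; head 4*2+2
        counts = [sum(p.size for p in l.params.values()) for l in net.param_layers()]
        assert counts == [2 * 3 + 2, 8 * 4 + 4, 4 * 2 + 2]

    def test_kernel_larger_than_input_rejected(self):
        spec = CandidateSpec(band="Beta2", n_filters=5, kernel_size=66,
                             dense_layers=(16,))
        with pytest.raises(ValueError, match="kernel_size"):
            build_band_cnn(spec, 50)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 50))
        with pytest.raises(ValueError, match="2 classes"):
            BandCNNClassifier(max_epochs=1).fit(X, ["NonREM"] * 10)

    def test_feature_tap_matches_last_hidden_width(self, small_dataset):
        X, y = small_dataset
        clf = BandCNNClassifier(max_epochs=1, dense_layers=(32, 16),
                                random_state=0).fit(X, y)
        f = clf.features(X[:4])
        assert f.shape == (4, 16)
        assert clf.feature_dim_ == 16

    def test_training_loss_decreases(self, small_dataset):
        X, y = small_dataset
        clf = BandCNNClassifier(max_epochs=8, batch_size=16,
                                validation_split=0.0, random_state=1).fit(X, y)
        losses = [row["loss"] for row in clf.history_.rows]
        assert losses[-1] < losses[0]


class TestSequenceModel:
    def _fitted_bands(self, small_dataset):
        X, y = small_dataset
        cnns = {}
        for i, b in enumerate(BAND_ORDER):
            cnns[b] = BandCNNClassifier(max_epochs=1, dense_layers=(8,),
                                        kernel_size=10,
                                        random_state=i).fit(X, y)
        return cnns, X, y

    def test_output_softmax_and_shape(self, small_dataset):
        cnns, X, y = self._fitted_bands(small_dataset)
        model = build_sequence_model(cnns, max_epochs=1, gru1_units=8,
                                     gru2_units=6, dense_layers=(8,),
                                     random_state=0)
        band_inputs = {b: X for b in BAND_ORDER}
        model.fit_sequence(band_inputs, y)
        p = model.predict_proba(band_inputs)
        assert p.shape == (len(y) - 2, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_band_order_matters(self, small_dataset):
        """Concatenation is ordered: swapping band inputs changes the output."""
        cnns, X, y = self._fitted_bands(small_dataset)
        model = build_sequence_model(cnns, max_epochs=1, gru1_units=8,
                                     gru2_units=6, dense_layers=(8,),
                                     random_state=0)
        band_inputs = {b: X for b in BAND_ORDER}
        model.fit_sequence(band_inputs, y)
        swapped = dict(band_inputs)
        swapped["Delta"], swapped["Beta2"] = (X[::-1].copy(), X[::-1].copy())
        # different inputs to differently-weighted slots -> different features
        assert not np.allclose(model.predict_proba(band_inputs)[:3],
                               model.predict_proba(swapped)[:3])

    def test_gru_dimensions_as_configured(self):
        clf = SequenceGRUClassifier(gru1_units=104, gru2_units=302)
        net = clf._build_net(40, np.random.default_rng(0))
        assert net.layers[0].units == 104
        assert net.layers[1].units == 302
        # bidirectional: dense input is 2 x 302
        assert net.layers[2].params["W"].shape[0] == 604

    def test_triples_drop_edge_epochs(self):
        f = np.arange(20.0).reshape(10, 2)
        y = np.arange(10)
        from remwave.models import SleepSequenceModel

        triples, y_mid = SleepSequenceModel.make_triples(f, y)
        assert triples.shape == (8, 3, 2)
        assert np.array_equal(y_mid, y[1:-1])
        assert np.array_equal(triples[0, 1], f[1])

    def test_missing_band_rejected(self, small_dataset):
        cnns, X, y = self._fitted_bands(small_dataset)
        del cnns["Alpha"]
        with pytest.raises(ValueError, match="Alpha|five"):
            build_sequence_model(cnns)
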