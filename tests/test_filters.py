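"""Spearman filter-similarity analysis: oracle agreement and ranking."""

import numpy as np
import pytest
from scipy import stats

from remwave.filters import (
    FilterBank,
    cross_model_correlations,
    plot_filter_banks,
    rank_filters,
    spearman_rho,
)


def brute_force_spearman(x, y):
    """Independent oracle: explicit average ranks + Pearson correlation."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearmanRho:
    def test_self_correlation(self):
        x = np.array([0.3, -1.2, 2.0, 0.7])
        assert spearman_rho(x, x) == 1.0

    def test_hand_computed_example(self):
        # d^2 = {4, 1, 1}; 1 - 6*6/(3*8) = -0.5
        assert spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_antitone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_constant_vector_flagged_nan(self):
        assert np.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.normal(size=(2, 15))
            assert spearman_rho(x, y) == spearman_rho(y, x)

    def test_brute_force_oracle_agreement_including_ties(self):
        """1000 random pairs, some with ties, agree with the rank+Pearson oracle."""
        rng = np.random.default_rng(1)
        for i in range(1000):
            n = int(rng.integers(3, 40))
            if i % 3 == 0:  # force ties
                x = rng.integers(0, 4, n).astype(float)
                y = rng.integers(0, 4, n).astype(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
            else:
                x, y = rng.normal(size=(2, n))
            assert spearman_rho(x, y) == pytest.approx(brute_force_spearman(x, y),
                                                       abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])


def _random_banks(band, models, n_filters, k, rng):
    return [FilterBank(band=band, wavelet_model=m,
                       filters=rng.normal(size=(n_filters, k)))
            for m in models]


class TestCrossModelCorrelations:
    def test_two_models_ten_filters_each(self):
        rng = np.random.default_rng(0)
        banks = _random_banks("Delta", ["db2", "haar"], 10, 35, rng)
        assert len(cross_model_correlations(banks)) == 100

    def test_three_models_five_filters(self):
        rng = np.random.default_rng(1)
        banks = _random_banks("Theta", ["db2", "haar", "coif4"], 5, 19, rng)
        assert len(cross_model_correlations(banks)) == 75  # C(3,2) x 25

    def test_single_model_yields_no_pairs(self):
        rng = np.random.default_rng(2)
        assert cross_model_correlations(_random_banks("Alpha", ["db2"], 5, 10, rng)) == []

    def test_mismatched_lengths_rejected(self):
        rng = np.random.default_rng(3)
        banks = [FilterBank("Delta", "a", rng.normal(size=(2, 8))),
                 FilterBank("Delta", "b", rng.normal(size=(2, 9)))]
        with pytest.raises(ValueError, match="length"):
            cross_model_correlations(banks)

    def test_no_self_model_pairs(self):
        rng = np.random.default_rng(4)
        banks = _random_banks("Delta", ["m1", "m2"], 3, 12, rng)
        for a, _, b, _, _ in cross_model_correlations(banks):
            assert a != b


class TestRankFilters:
    def test_identical_banks_score_zero_above_threshold(self):
        """All rho = 1 -> threshold 1; strict '>' gives 0% for every filter."""
        base = np.arange(10.0)[None, :] * np.array([[1.0], [2.0], [0.5]])
        banks = [FilterBank("Delta", m, base.copy()) for m in ["a", "b", "c"]]
        reports = rank_filters({"Delta": banks})
        rep = reports["Delta"]
        assert rep.threshold == pytest.approx(1.0)
        assert all(pct == 0.0 for _, _, pct, _, _ in rep.ranking)

    def test_planted_duplicate_ranks_first_across_seeds(self):
        """A filter duplicated across models outranks random ones in >=9/10 seeds."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            motif = rng.normal(size=19)
            banks = []
            for m in ["db2", "haar", "coif4", "sym5"]:
                filt = rng.normal(size=(5, 19))
                filt[2] = motif + rng.normal(0, 0.05, 19)
                banks.append(FilterBank("Theta", m, filt))
            rep = rank_filters({"Theta": banks})["Theta"]
            top_model, top_idx, _, _, _ = rep.ranking[0]
            wins += top_idx == 2
        assert wins >= 9

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        banks = _random_banks("Alpha", ["a", "b", "c"], 4, 10, rng)
        rep1 = rank_filters({"Alpha": banks})["Alpha"]
        scaled = [FilterBank("Alpha", b.wavelet_model, b.filters * 3.7) for b in banks]
        rep2 = rank_filters({"Alpha": scaled})["Alpha"]
        assert [r[:2] for r in rep1.ranking] == [r[:2] for r in rep2.ranking]
        assert rep1.threshold == pytest.approx(rep2.threshold)

    def test_kernel_size_two_saturates(self):
        """With 2-sample kernels every non-constant pair has |rho| = 1."""
        rng = np.random.default_rng(8)
        banks = _random_banks("Beta2", ["a", "b", "c"], 5, 2, rng)
        pairs = cross_model_correlations(banks)
        for *_ids, rho in pairs:
            assert abs(rho) == pytest.approx(1.0)
        rep = rank_filters({"Beta2": banks})["Beta2"]
        assert rep.threshold == pytest.approx(1.0)
        assert all(pct == 0.0 for _, _, pct, _, _ in rep.top5)

    def test_top5_is_head_of_ranking(self):
        rng = np.random.default_rng(9)
        banks = _random_banks("Delta", ["a", "b", "c"], 4, 35, rng)
        rep = rank_filters({"Delta": banks})["Delta"]
        assert rep.top5 == rep.ranking[:5]

    def test_pooled_threshold_shared_across_bands(self):
        rng = np.random.default_rng(10)
        by_band = {
            "Delta": _random_banks("Delta", ["a", "b"], 4, 35, rng),
            "Theta": _random_banks("Theta", ["a", "b"], 4, 19, rng),
        }
        pooled = rank_filters(by_band, pooled_threshold=True)
        assert pooled["Delta"].threshold == pooled["Theta"].threshold
        per_band = rank_filters(by_band, pooled_threshold=False)
        assert per_band["Delta"].threshold != per_band["Theta"].threshold


class TestSerializationAndPlots:
    def test_bank_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        bank = FilterBank("Delta", "db2", rng.normal(size=(5, 35)),
                          provenance={"fold": 3, "f1": 0.91})
        p = tmp_path / "bank.json"
        bank.save(p)
        loaded = FilterBank.load(p)
        assert loaded.band == "Delta" and loaded.wavelet_model == "db2"
        assert np.allclose(loaded.filters, bank.filters)
        assert loaded.provenance["fold"] == 3

    def test_plot_panel_count_and_naming(self, tmp_path):
        rng = np.random.default_rng(1)
        banks = [FilterBank("Delta", m, rng.normal(size=(5, 8)))
                 for m in ["a", "b", "c", "d", "e"]]
        written = plot_filter_banks(banks, tmp_path)
        assert len(written) == 25
        assert (tmp_path / "a_Delta_0.png").exists()

    def test_zero_filter_plots_without_crash(self, tmp_path):
        bank = FilterBank("Beta1", "haar", np.zeros((1, 5)))
        assert len(plot_filter_banks([bank], tmp_path)) == 1
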