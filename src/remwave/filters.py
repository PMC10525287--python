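"""Convolution-filter interpretability via Spearman rank correlation.

The premise: if a first-layer convolution kernel captures a real EEG
feature (a spindle, a K-complex fragment), independently trained models
should rediscover it regardless of which mother wavelet preprocessed the
data.  For each frequency band, every filter of every wavelet model is
rank-correlated against every filter of every *other* wavelet model in
the same band.  The 95th percentile of all those coefficients serves as
a similarity threshold; filters are then ranked by the percentage of
their cross-model comparisons that exceed it (strictly), and the top
five per band are reported.

With a kernel of two samples every non-constant filter pair correlates
at |rho| = 1, so the two-sample band's threshold saturates at 1 and no
comparison can strictly exceed it - its "top" filters all score 0%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "FilterBank",
    "FilterCorrelationReport",
    "spearman_rho",
    "cross_model_correlations",
    "rank_filters",
    "plot_filter_banks",
    "extract_filter_bank",
]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks on ties).

    Returns NaN for a constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class FilterBank:
    """First-layer convolution filters of one trained band model.

    ``wavelet_model`` is the mother wavelet that preprocessed the training
    data, or ``"None"`` for the model trained on raw epochs.  Provenance
    records which cross-validation fold the filters came from (the fold
    with the highest f1) and that fold's f1.
    """

    band: str
    wavelet_model: str
    filters: np.ndarray  # (n_filters, kernel_size)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.filters = np.atleast_2d(np.asarray(self.filters, dtype=float))
        self.wavelet_model = str(self.wavelet_model)

    @property
    def kernel_size(self) -> int:
        return self.filters.shape[1]

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "wavelet_model": self.wavelet_model,
            "filters": self.filters.tolist(),
            "provenance": self.provenance,
        }

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def load(cls, path) -> "FilterBank":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(band=d["band"], wavelet_model=d["wavelet_model"],
                   filters=np.asarray(d["filters"]), provenance=d.get("provenance", {}))


def extract_filter_bank(model, band: str, wavelet_model: str,
                        provenance: dict | None = None) -> FilterBank:
    """Pull the first-layer convolution kernels out of a fitted band CNN."""
    return FilterBank(
        band=band,
        wavelet_model=wavelet_model,
        filters=np.asarray(model.conv_weights_),
        provenance=dict(provenance or {}),
    )


def cross_model_correlations(banks: list[FilterBank]) -> list[tuple]:
    """All-vs-all filter correlations across distinct models of one band.

    Returns ``(model_a, idx_a, model_b, idx_b, rho)`` tuples, one per
    unordered model pair and filter cross product; a filter is never
    compared with filters of its own model.
    """
    if len(banks) < 2:
        return []
    band = banks[0].band
    k = banks[0].kernel_size
    for b in banks:
        if b.band != band:
            raise ValueError(f"mixed bands: {b.band} vs {band}")
        if b.kernel_size != k:
            raise ValueError(
                f"filter length mismatch: {b.wavelet_model} has {b.kernel_size}, expected {k}"
            )
    pairs = []
    for i in range(len(banks)):
        for j in range(i + 1, len(banks)):
            a, b = banks[i], banks[j]
            for ia, fa in enumerate(a.filters):
                for ib, fb in enumerate(b.filters):
                    pairs.append(
                        (a.wavelet_model, ia, b.wavelet_model, ib,
                         spearman_rho(fa, fb))
                    )
    return pairs


@dataclass
class FilterCorrelationReport:
    """Per-band correlation pairs, threshold, and filter ranking."""

    band: str
    pairs: list
    threshold: float
    #: rows of (model, filter_idx, pct_above_threshold, mean_rho, n_comparisons)
    ranking: list

    @property
    def top5(self) -> list:
        return self.ranking[:5]

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "threshold": self.threshold,
            "ranking": [list(r) for r in self.ranking],
            "n_pairs": len(self.pairs),
        }

    def pairs_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.pairs, columns=["model_a", "filter_a", "model_b", "filter_b", "rho"]
        )

    def summary_text(self) -> str:
        lines = [f"{'Freq Band':<10}{'Wavelet':<16}{'95th%':>8}{'% above 95th':>14}"]
        for model, idx, pct, _mean, _n in self.top5:
            lines.append(
                f"{self.band:<10}{str(idx) + 'th ' + model:<16}"
                f"{self.threshold:>8.4f}{pct:>14.2f}"
            )
        return "\n".join(lines)


def _finite_rhos(pairs):
    return np.array([p[4] for p in pairs if np.isfinite(p[4])])


def rank_filters(
    banks_by_band: dict,
    percentile: float = 95.0,
    pooled_threshold: bool = False,
) -> dict:
    """Threshold and rank filters for every band.

    ``banks_by_band`` maps band name to its list of :class:`FilterBank`.
    By default the 95th-percentile threshold is computed per band (each
    band's kernel size sets its own correlation scale); with
    ``pooled_threshold=True`` a single threshold over every band's pooled
    coefficients is used instead.  A filter's score is the percentage of
    its cross-model comparisons whose rho strictly exceeds the threshold.
    Ties rank by higher mean rho, then by (model, filter index).
    """
    all_pairs = {band: cross_model_correlations(banks) for band, banks in banks_by_band.items()}
    pooled = np.concatenate([_finite_rhos(p) for p in all_pairs.values() if p]) \
        if pooled_threshold else None
    if pooled is not None and pooled.size == 0:
        raise ValueError("no finite correlation values to threshold")
    reports = {}
    for band, pairs in all_pairs.items():
        rhos = _finite_rhos(pairs)
        if rhos.size == 0:
            raise ValueError(f"band {band}: no finite correlation values")
        threshold = float(np.percentile(pooled if pooled_threshold else rhos, percentile))
        stats_per_filter: dict[tuple, list] = {}
        for model_a, ia, model_b, ib, rho in pairs:
            for key in ((model_a, ia), (model_b, ib)):
                stats_per_filter.setdefault(key, []).append(rho)
        ranking = []
        for (model, idx), values in stats_per_filter.items():
            finite = [v for v in values if np.isfinite(v)]
            n = len(values)
            above = sum(1 for v in finite if v > threshold)
            pct = 100.0 * above / n if n else 0.0
            mean_rho = float(np.mean(finite)) if finite else float("nan")
            ranking.append((model, idx, pct, mean_rho, n))
        ranking.sort(key=lambda r: (-r[2], -(r[3] if np.isfinite(r[3]) else -np.inf),
                                    r[0], r[1]))
        reports[band] = FilterCorrelationReport(
            band=band, pairs=pairs, threshold=threshold, ranking=ranking
        )
    return reports


def plot_filter_banks(banks: list[FilterBank], out_dir) -> list[Path]:
    """Plot every filter as its own panel; returns the written paths.

    File names are ``{model}_{band}_{filter_idx}.png``.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for bank in banks:
        for idx, w in enumerate(bank.filters):
            fig, ax = plt.subplots(figsize=(3, 2))
            ax.plot(w, marker="o", markersize=2)
            ax.set_title(f"{bank.wavelet_model} {bank.band} #{idx}", fontsize=8)
            ax.set_xlabel("sample")
            fig.tight_layout()
            path = out_dir / f"{bank.wavelet_model}_{bank.band}_{idx}.png"
            fig.savefig(path, dpi=80)
            plt.close(fig)
            written.append(path)
    return written
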