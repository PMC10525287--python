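"""Hyperparameter random search over band-CNN candidates.

Four stages: fix the preprocessing/training parameters, draw candidate
hyperparameter specs uniformly from the documented pools, materialize
each as a network, and train/evaluate it with stratified k-fold
cross-validation.  Every candidate's cross-validation report is kept so
the best model is selectable afterwards by any stored metric (f1 by
default); ties go to the earlier draw.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import CandidateSpec, build_band_cnn, build_candidate
from .train_eval import CVReport, FoldResult, METRIC_NAMES, TrainingConfig, cross_validate

logger = logging.getLogger(__name__)

__all__ = ["SearchRun", "run_search", "select_best"]


@dataclass
class SearchRun:
    """One random-search session: parameters, candidates and their reports."""

    band: str
    preprocessing: dict
    training: dict
    candidates: list = field(default_factory=list)
    results: list = field(default_factory=list)  # CVReport per candidate
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "band": self.band,
            "preprocessing": self.preprocessing,
            "training": self.training,
            "candidates": [c.to_dict() for c in self.candidates],
            "results": [r.to_dict() for r in self.results],
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def save(self, path):
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, s: str) -> "SearchRun":
        d = json.loads(s)
        run = cls(
            band=d["band"],
            preprocessing=d["preprocessing"],
            training=d["training"],
            seed=d["seed"],
        )
        run.candidates = [CandidateSpec.from_dict(c) for c in d["candidates"]]
        for r in d["results"]:
            folds = [
                FoldResult(tp=f["tp"], fp=f["fp"], fn=f["fn"], tn=f["tn"],
                           last_loss=f.get("last_loss", float("nan")))
                for f in r["folds"]
            ]
            run.results.append(CVReport(folds=folds))
        return run

    @classmethod
    def load(cls, path) -> "SearchRun":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def run_search(
    X,
    y,
    band: str,
    n_candidates: int,
    seed: int,
    config: TrainingConfig | None = None,
    preprocessing: dict | None = None,
    space: dict | None = None,
    fit_params: dict | None = None,
    out_dir=None,
) -> SearchRun:
    """Draw and evaluate ``n_candidates`` CNN candidates for one band.

    ``X`` is the band-preprocessed epoch matrix, ``y`` the binary labels.
    Each candidate goes through the full stratified cross-validation of
    :func:`remwave.train_eval.cross_validate`.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0 or len(X) == 0:
        raise ValueError("empty dataset")
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    config = config or TrainingConfig()
    rng = np.random.default_rng(seed)
    run = SearchRun(
        band=band,
        preprocessing=dict(preprocessing or {}),
        training={
            "cvFolds": config.cv_folds,
            "validation_split": config.validation_split,
            "epoch": config.max_epochs,
            "batchSize": config.resolved_batch_size(len(X)),
        },
        seed=seed,
    )
    fit_params = dict(fit_params or {})
    fit_params.setdefault("random_state", seed)
    for i in range(n_candidates):
        spec = build_candidate(rng, band, space=space)
        run.candidates.append(spec)
        model = build_band_cnn(spec, X.shape[1], **fit_params)
        report = cross_validate(model, X, y, config)
        run.results.append(report)
        logger.info("candidate %d/%d %s -> f1 %.4f", i + 1, n_candidates,
                    spec.to_json(), report.averages["f1"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        run.save(out_dir / f"search_{band}_{seed}.json")
    return run


def select_best(run: SearchRun, metric_name: str = "f1") -> tuple[CandidateSpec, CVReport]:
    """Candidate with the highest mean metric; ties go to the first drawn."""
    if not run.results:
        raise ValueError("search run has no results")
    if metric_name not in METRIC_NAMES:
        raise ValueError(
            f"unknown metric {metric_name!r}; choose from {METRIC_NAMES}"
        )
    means = [r.averages[metric_name] for r in run.results]
    best = int(np.argmax(means))  # argmax takes the first maximum
    return run.candidates[best], run.results[best]
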