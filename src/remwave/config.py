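"""Flat key/value run-configuration files.

The on-disk format mirrors the preprocessing/training parameter block a
search run logs::

    dataFiles: input152.csv,input042.csv
    cvFolds: 10
    validation_split: 0.1
    epoch: 100
    batchSize: 381
    normSTD: 19.476
    normMean: 0.0172
    mother wavelet: db2
    decomp level: 5
    frequency band: Delta

Unknown keys are rejected.  Command-line flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["RunConfig", "load_run_config"]

_KEY_MAP = {
    "datafiles": "data_files",
    "cvfolds": "cv_folds",
    "validation_split": "validation_split",
    "epoch": "max_epochs",
    "batchsize": "batch_size",
    "normstd": "norm_std",
    "normmean": "norm_mean",
    "mother wavelet": "mother_wavelet",
    "decomp level": "decomp_level",
    "frequency band": "frequency_band",
    "seed": "seed",
}


@dataclass
class RunConfig:
    data_files: list = field(default_factory=list)
    cv_folds: int = 10
    validation_split: float = 0.1
    max_epochs: int = 100
    batch_size: int | None = None
    norm_std: float | None = None
    norm_mean: float | None = None
    mother_wavelet: str = "db2"
    decomp_level: int = 5
    frequency_band: str = "Delta"
    seed: int = 0

    def snapshot(self) -> str:
        lines = []
        d = asdict(self)
        inverse = {v: k for k, v in _KEY_MAP.items()}
        for attr, value in d.items():
            key = inverse.get(attr, attr)
            if attr == "data_files":
                value = ",".join(value)
            lines.append(f"{key}: {value}")
        return "\n".join(lines) + "\n"

    def write_snapshot(self, path):
        Path(path).write_text(self.snapshot(), encoding="utf-8")


def load_run_config(path, **overrides) -> RunConfig:
    """Parse a key/value config file; keyword arguments win on conflict."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, sep, value = line.partition(":")
        if not sep:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key = key.strip().strip("*").strip().lower()
        if key not in _KEY_MAP:
            raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
        values[_KEY_MAP[key]] = value.strip()
    cfg = RunConfig()
    converters = {
        "data_files": lambda v: [s.strip() for s in v.split(",") if s.strip()],
        "cv_folds": int,
        "validation_split": float,
        "max_epochs": int,
        "batch_size": lambda v: None if v in ("", "None") else int(v),
        "norm_std": lambda v: None if v in ("", "None") else float(v.replace("−", "-")),
        "norm_mean": lambda v: None if v in ("", "None") else float(v.replace("−", "-")),
        "mother_wavelet": str,
        "decomp_level": int,
        "frequency_band": str,
        "seed": int,
    }
    for attr, value in values.items():
        setattr(cfg, attr, converters[attr](value))
    for attr, value in overrides.items():
        if value is not None:
            if not hasattr(cfg, attr):
                raise ValueError(f"unknown configuration attribute {attr!r}")
            setattr(cfg, attr, value)
    return cfg
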