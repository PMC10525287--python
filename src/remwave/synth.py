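"""Synthetic single-channel EEG with hypnogram-style stage labels.

The generator emulates the shape of a polysomnography export: a continuous
100 Hz voltage trace plus one stage annotation every 30 s drawn from
{W, R, 1, 2, 3, 4, M, ?}.  Stage-conditional content is a sum of
band-limited oscillatory bursts with random phase on top of Gaussian
noise:

* non-REM epochs carry high-amplitude 0.5-4 Hz slow waves and brief
  11-16 Hz spindle-like bursts,
* REM epochs are low-amplitude mixed-frequency (4-8 Hz theta plus a
  sawtooth-like 2-3 Hz component),
* wake epochs carry 8-13 Hz alpha,
* movement (M) and not-scored (?) epochs are pure noise - downstream
  processing discards them, so their content never matters.

This is a test harness for the pipeline, not a physiological simulation:
no 1/f background, no K-complex morphology, no inter-epoch continuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal

__all__ = ["SyntheticConfig", "SyntheticRecording", "generate_recording", "write_export_files"]

STAGES = ("W", "R", "1", "2", "3", "4", "M", "?")

#: Per-class oscillation amplitudes (microvolt).  Keys are label classes
#: ("R", "NREM", "W"); inner keys name the oscillatory component.  The
#: defaults put most non-REM power into the Delta band and most REM power
#: into Theta, giving a band-power gap a depth-1 threshold can exploit.
DEFAULT_BAND_AMPLITUDES: dict[str, dict[str, float]] = {
    "R": {"theta": 9.0, "sawtooth": 5.0, "delta": 2.0, "alpha": 1.5},
    "NREM": {"delta": 30.0, "spindle": 8.0, "theta": 2.0},
    "W": {"alpha": 10.0, "beta": 4.0, "delta": 2.0},
}


class ConfigurationError(ValueError):
    """Invalid synthetic-recording configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic recording.

    ``sample_rate * epoch_seconds`` must be an integer (samples per epoch);
    the default 100 Hz x 30 s gives the canonical 3000-sample epoch.
    """

    n_epochs: int = 200
    sample_rate: float = 100.0
    epoch_seconds: float = 30.0
    rem_fraction: float = 0.3
    leading_wake_epochs: int = 3
    movement_fraction: float = 0.02
    band_amplitudes: dict = field(default_factory=lambda: DEFAULT_BAND_AMPLITUDES)
    noise_sd: float = 3.0
    seed: int = 0
    patient_id: int = 15
    night: int = 1

    def __post_init__(self):
        if not 0.0 <= self.rem_fraction <= 1.0:
            raise ConfigurationError(f"rem_fraction outside [0,1]: {self.rem_fraction}")
        if not 0.0 <= self.movement_fraction <= 1.0:
            raise ConfigurationError(
                f"movement_fraction outside [0,1]: {self.movement_fraction}"
            )
        spe = self.sample_rate * self.epoch_seconds
        if abs(spe - round(spe)) > 1e-9:
            raise ConfigurationError(
                f"sample_rate x epoch_seconds = {spe} is not an integer"
            )
        if self.n_epochs < 0:
            raise ConfigurationError("n_epochs must be non-negative")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.sample_rate * self.epoch_seconds))


@dataclass
class SyntheticRecording:
    """A labelled synthetic PSG trace."""

    samples: np.ndarray
    annotations: list  # (onset_s, stage) at epoch_seconds spacing
    patient_id: int
    night: int
    sample_rate: float = 100.0
    epoch_seconds: float = 30.0

    @property
    def stages(self) -> list[str]:
        return [stage for _, stage in self.annotations]


def _draw_stages(config: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    stages = []
    for i in range(config.n_epochs):
        if i < config.leading_wake_epochs:
            stages.append("W")
            continue
        u = rng.random()
        if u < config.movement_fraction:
            stages.append("M")
        elif u < config.movement_fraction + (1 - config.movement_fraction) * config.rem_fraction:
            stages.append("R")
        else:
            stages.append(str(rng.choice(["1", "2", "3", "4"], p=[0.15, 0.45, 0.2, 0.2])))
    return stages


def _burst_envelope(n: int, rng: np.random.Generator, n_bursts: int, burst_len: int) -> np.ndarray:
    """0/1-ish envelope of Hann-windowed bursts at random offsets."""
    env = np.zeros(n)
    for _ in range(n_bursts):
        start = rng.integers(0, max(1, n - burst_len))
        env[start : start + burst_len] += np.hanning(burst_len)
    return env


def _tone(n: int, rate: float, freq: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / rate
    return np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))


def _epoch_signal(stage: str, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.samples_per_epoch
    rate = config.sample_rate
    x = rng.normal(0.0, config.noise_sd, size=n)
    if stage in ("M", "?"):
        return x
    cls = "R" if stage == "R" else ("W" if stage == "W" else "NREM")
    amps = config.band_amplitudes.get(cls, {})
    if amps.get("delta", 0.0):
        x += amps["delta"] * _tone(n, rate, rng.uniform(0.5, 2.0), rng)
    if amps.get("theta", 0.0):
        x += amps["theta"] * _tone(n, rate, rng.uniform(4.0, 7.5), rng)
    if amps.get("alpha", 0.0):
        x += amps["alpha"] * _tone(n, rate, rng.uniform(8.0, 12.5), rng)
    if amps.get("beta", 0.0):
        x += amps["beta"] * _tone(n, rate, rng.uniform(15.0, 30.0), rng)
    if amps.get("spindle", 0.0):
        burst = _burst_envelope(n, rng, n_bursts=3, burst_len=int(0.8 * rate))
        x += amps["spindle"] * burst * _tone(n, rate, rng.uniform(11.0, 16.0), rng)
    if amps.get("sawtooth", 0.0):
        t = np.arange(n) / rate
        f = rng.uniform(2.0, 3.0)
        x += amps["sawtooth"] * sp_signal.sawtooth(
            2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)
        )
    return x


def generate_recording(config: SyntheticConfig) -> SyntheticRecording:
    """Generate one labelled recording.

    The pseudo-random stream is keyed by ``(seed, patient_id, night)`` so a
    multi-recording dataset is reproducible record by record.
    """
    rng = np.random.default_rng([config.seed, config.patient_id, config.night])
    stages = _draw_stages(config, rng)
    chunks = [_epoch_signal(s, config, rng) for s in stages]
    samples = (
        np.concatenate(chunks) if chunks else np.empty(0)
    )
    annotations = [(i * config.epoch_seconds, s) for i, s in enumerate(stages)]
    return SyntheticRecording(
        samples=samples,
        annotations=annotations,
        patient_id=config.patient_id,
        night=config.night,
        sample_rate=config.sample_rate,
        epoch_seconds=config.epoch_seconds,
    )


def write_export_files(rec: SyntheticRecording, out_dir) -> tuple[Path, Path]:
    """Write the PSG / hypnogram text pair mimicking an EDF text export.

    PSG file: a header line, then one ``time_s<TAB>value`` row per sample.
    Hypnogram file: one ``onset_s<TAB>duration_s<TAB>stage`` row per
    annotation.  Both UTF-8 with '.' decimal separator.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = f"{rec.patient_id:02d}{rec.night:d}"
    psg_path = out_dir / f"psg{tag}.txt"
    hyp_path = out_dir / f"hyp{tag}.txt"
    dt = 1.0 / rec.sample_rate
    with psg_path.open("w", encoding="utf-8") as fh:
        fh.write("time_s\tvalue_uv\n")
        for i, v in enumerate(rec.samples):
            fh.write(f"{i * dt:.3f}\t{v:.6f}\n")
    with hyp_path.open("w", encoding="utf-8") as fh:
        for onset, stage in rec.annotations:
            fh.write(f"{onset:.1f}\t{rec.epoch_seconds:.1f}\t{stage}\n")
    return psg_path, hyp_path
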