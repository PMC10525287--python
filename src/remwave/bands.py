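"""Multilevel DWT band machinery for 100 Hz single-channel EEG.

A 30 s epoch sampled at 100 Hz (3000 samples) is split into the five
classical EEG frequency bands by a five-level discrete wavelet transform:
each level halves the effective sample rate, so the detail coefficients at
levels 1..4 cover Beta2, Beta1, Alpha and Theta, while the Delta band is
the low-frequency remainder at level 5 (approximation plus the level-5
detail, i.e. everything below 3.125 Hz).  The per-band CNN kernel size is
chosen so one kernel spans roughly one period of a representative
frequency inside the band: ``kernel = floor(source_rate / rep_freq)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "BAND_ORDER",
    "Decomposition",
    "sample_rate_after_level",
    "cnn_filter_size",
    "coefficient_count",
    "decompose",
    "band_signal",
    "passthrough",
    "max_decomposition_level",
    "resolve_wavelet",
]

#: Depth cap for the default 3000-sample epoch; deeper levels leave too few
#: coefficients to be meaningful for banding.
MAX_LEVEL_DEFAULT = 8


class WaveletError(ValueError):
    """Unsupported mother wavelet or infeasible decomposition request."""


@dataclass(frozen=True)
class BandSpec:
    """One EEG frequency band and its DWT / CNN bookkeeping.

    Parameters
    ----------
    name : str
        Band label (``Delta``, ``Theta``, ``Alpha``, ``Beta1``, ``Beta2``).
    freq_range : tuple of float
        Nominal frequency interval in Hz.
    dwt_level : int
        Decomposition level whose coefficients represent the band.
    representative_freq : float
        Mid-band frequency (Hz) used to size the CNN kernel.
    source_rate : float
        Sample rate of the raw signal in Hz.
    """

    name: str
    freq_range: tuple[float, float]
    dwt_level: int
    representative_freq: float
    source_rate: float = 100.0

    @property
    def nominal_rate(self) -> float:
        """Effective sample rate of this band's coefficients (Hz)."""
        return sample_rate_after_level(self.source_rate, self.dwt_level)

    @property
    def cnn_kernel_size(self) -> int:
        """Convolution kernel length in samples at the source rate."""
        return cnn_filter_size(self.source_rate, self.representative_freq)


BAND_ORDER = ("Delta", "Theta", "Alpha", "Beta1", "Beta2")

CANONICAL_BANDS: dict[str, BandSpec] = {
    "Delta": BandSpec("Delta", (0.0, 3.99), 5, 2.8),
    "Theta": BandSpec("Theta", (4.0, 7.99), 4, 5.2),
    "Alpha": BandSpec("Alpha", (8.0, 13.0), 3, 10.0),
    "Beta1": BandSpec("Beta1", (13.0, 25.0), 2, 20.0),
    "Beta2": BandSpec("Beta2", (25.0, 50.0), 1, 50.0),
}


def sample_rate_after_level(source_rate: float, level: int) -> float:
    """Effective sample rate after ``level`` dyadic decimations.

    Each DWT level downsamples by two, so the rate is
    ``source_rate / 2**level``.
    """
    if level < 0:
        raise ValueError(f"decomposition level must be >= 0, got {level}")
    if source_rate <= 0:
        raise ValueError(f"source_rate must be positive, got {source_rate}")
    return source_rate / 2**level


def cnn_filter_size(source_rate: float, representative_freq: float) -> int:
    """Kernel length (samples) spanning one period of ``representative_freq``.

    Truncates toward zero; never smaller than one sample.
    """
    if representative_freq <= 0:
        raise ValueError(
            f"representative_freq must be positive, got {representative_freq}"
        )
    return max(1, int(source_rate / representative_freq))


def coefficient_count(n: int, filter_len: int, level: int) -> int:
    """Closed-form coefficient count after ``level`` DWT steps.

    Applies the dyadic recursion ``len_k = floor((len_{k-1} + L - 1) / 2)``
    with ``L`` the wavelet filter length, matching the symmetric-padding
    convention of the transform itself.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    length = n
    for _ in range(level):
        length = (length + filter_len - 1) // 2
    return length


def resolve_wavelet(name: str) -> pywt.Wavelet:
    """Map a short wavelet name (case-insensitive) to a discrete wavelet.

    Continuous families (``morl``, ``mexh``, ``gausN``, ...) have no dyadic
    decomposition filters and are rejected with an explicit error.
    """
    key = name.strip().lower()
    if key in ("haar",):
        key = "haar"
    try:
        return pywt.Wavelet(key)
    except ValueError as exc:
        try:
            pywt.ContinuousWavelet(key)
        except ValueError:
            raise WaveletError(f"unknown wavelet name: {name!r}") from exc
        raise WaveletError(
            f"wavelet family {name!r} is continuous and has no discrete "
            "decomposition filters; choose a discrete family "
            "(haar, dbN, symN, coifN, dmey)"
        ) from exc


def max_decomposition_level(n: int, wavelet_name: str, cap: int = MAX_LEVEL_DEFAULT) -> int:
    """Deepest usable level for an ``n``-sample signal, capped at ``cap``."""
    w = resolve_wavelet(wavelet_name)
    return min(cap, pywt.dwt_max_level(n, w.dec_len))


@dataclass
class Decomposition:
    """Multilevel DWT result: ``[cA_level, cD_level, ..., cD_1]``."""

    wavelet_name: str
    level: int
    coefficients: list = field(repr=False)

    @property
    def approximation(self) -> np.ndarray:
        return self.coefficients[0]

    def detail(self, level: int) -> np.ndarray:
        """Detail coefficients at a given level (1 = finest)."""
        if not 1 <= level <= self.level:
            raise ValueError(f"detail level {level} outside 1..{self.level}")
        return self.coefficients[self.level - level + 1]

    def reconstruct(self, keep: set[int] | None = None, length: int | None = None) -> np.ndarray:
        """Inverse transform keeping only the coefficient sets in ``keep``.

        ``keep`` holds indices into :attr:`coefficients` (0 = approximation);
        ``None`` keeps everything.
        """
        if keep is None:
            coeffs = self.coefficients
        else:
            coeffs = [
                c if i in keep else np.zeros_like(c)
                for i, c in enumerate(self.coefficients)
            ]
        out = pywt.waverec(coeffs, self.wavelet_name)
        if length is not None:
            out = out[:length]
        return out


def decompose(signal, wavelet_name: str, level: int) -> Decomposition:
    """Multilevel DWT with symmetric padding.

    Coefficient lengths follow ``len_k = floor((len_{k-1} + L - 1)/2)``
    with ``L`` the wavelet filter length.
    """
    x = np.asarray(signal, dtype=float)
    w = resolve_wavelet(wavelet_name)
    if x.size < w.dec_len:
        raise ValueError(
            f"signal length {x.size} shorter than wavelet filter ({w.dec_len})"
        )
    feasible = max_decomposition_level(x.size, wavelet_name)
    if level > feasible:
        raise WaveletError(
            f"level {level} exceeds feasible depth {feasible} for "
            f"{x.size} samples with {w.name}"
        )
    coeffs = pywt.wavedec(x, w, mode="symmetric", level=level)
    return Decomposition(wavelet_name=w.name, level=level, coefficients=coeffs)


# Coefficient-set indices (into a level-5 decomposition) per band.  Delta is
# the full low-frequency remainder cA5 + cD5 so the five bands tile the
# spectrum and their reconstructions sum back to the input; its canonical
# coefficient array (for the "coefficients" representation) is cA5.
_BAND_KEEP_L5 = {
    "Delta": {0, 1},
    "Theta": {2},
    "Alpha": {3},
    "Beta1": {4},
    "Beta2": {5},
}


def band_signal(
    signal,
    wavelet_name: str,
    band: BandSpec | str,
    representation: str = "reconstructed",
) -> np.ndarray:
    """Extract one frequency band from a signal via the level-5 DWT.

    Parameters
    ----------
    signal : array-like
        Raw epoch samples at the band's source rate.
    wavelet_name : str
        Discrete mother wavelet, or ``"none"`` for the passthrough model
        (reconstructed representation only).
    band : BandSpec or str
        Target band (canonical name accepted).
    representation : {"reconstructed", "coefficients"}
        ``reconstructed`` returns a full-length signal obtained by zeroing
        every other band's coefficients before the inverse transform;
        ``coefficients`` returns the band's canonical coefficient array
        (approximation for Delta, detail at the band's level otherwise).
    """
    if isinstance(band, str):
        band = CANONICAL_BANDS[band]
    x = np.asarray(signal, dtype=float)
    if wavelet_name is None or str(wavelet_name).lower() == "none":
        if representation != "reconstructed":
            raise WaveletError("the passthrough model has no coefficients")
        return passthrough(x)
    if band.dwt_level > 5:
        raise WaveletError(f"band level {band.dwt_level} exceeds the 5-level banding")
    dec = decompose(x, wavelet_name, level=5)
    if representation == "reconstructed":
        return dec.reconstruct(keep=_BAND_KEEP_L5[band.name], length=x.size)
    if representation == "coefficients":
        if band.name == "Delta":
            return dec.approximation
        return dec.detail(band.dwt_level)
    raise ValueError(f"unknown representation {representation!r}")


def passthrough(signal) -> np.ndarray:
    """Identity transform used when the mother wavelet is ``None``."""
    return np.asarray(signal, dtype=float)
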