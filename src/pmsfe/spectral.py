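"""Per-electrode spectral band power for EEG trials.

A trial is a 64-electrode (standard 10-10 montage) segment of EEG. For each
electrode the discrete Fourier transform of the trial is taken and the power
in each of the canonical theta (4-7 Hz), alpha (8-13 Hz) and beta (13-30 Hz)
bands is the sum of squared DFT magnitudes over the bins falling inside the
band. Band edges use the half-open rule [low, high) so that the alpha/beta
boundary bin at 13 Hz is counted once, and the DC bin is never included.

Powers are raw (unnormalized) DFT sums, so their magnitude scales with trial
length and signal units; downstream feature enhancement assumes the working
range documented in docs/methods.md.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "FrequencyBand",
    "TrialRecording",
    "BandPowerSet",
    "THETA",
    "ALPHA",
    "BETA",
    "DEFAULT_BANDS",
    "N_ELECTRODES",
    "compute_band_power",
    "extract_band_power_set",
    "center_spectra",
]

#: electrode count of the standard montage the grid layout expects
N_ELECTRODES = 64

#: lowest band edge in Hz; trials must hold at least two cycles of it
LOWEST_BAND_EDGE_HZ = 4.0

Window = Literal["rect", "hann"]
CenterMode = Literal["dataset_mean", "trial_mean", "none"]


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band with half-open edges [low_hz, high_hz)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"invalid band {self.name}: need 0 < low ({self.low_hz}) "
                f"< high ({self.high_hz})"
            )


THETA = FrequencyBand("theta", 4.0, 7.0)
ALPHA = FrequencyBand("alpha", 8.0, 13.0)
BETA = FrequencyBand("beta", 13.0, 30.0)
DEFAULT_BANDS: tuple[FrequencyBand, FrequencyBand, FrequencyBand] = (THETA, ALPHA, BETA)


@dataclass
class TrialRecording:
    """One labeled EEG trial: an (n_electrodes, n_samples) signal matrix.

    Parameters
    ----------
    signal
        Real matrix, rows are electrodes ordered by montage index 1..64,
        columns are time samples. Microvolt-scale arbitrary units.
    fs
        Sampling rate in Hz.
    subject_id
        Integer >= 1 identifying the recorded subject.
    load_level
        Cognitive workload class in {1, 2, 3, 4} (memory-set sizes 2/4/6/8).
    trial_id
        Integer >= 1, unique within a dataset.
    """

    signal: np.ndarray
    fs: float
    subject_id: int
    load_level: int
    trial_id: int

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.size == 0:
            raise ValueError("signal must be a non-empty 2D (electrodes, samples) matrix")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.load_level not in (1, 2, 3, 4):
            raise ValueError(f"load_level must be in 1..4, got {self.load_level}")
        if self.subject_id < 1 or self.trial_id < 1:
            raise ValueError("subject_id and trial_id must be >= 1")
        min_samples = 2 * self.fs / LOWEST_BAND_EDGE_HZ
        if self.n_samples < min_samples:
            raise ValueError(
                f"trial too short: {self.n_samples} samples < {min_samples:.0f} "
                f"needed for the {LOWEST_BAND_EDGE_HZ} Hz band edge at fs={self.fs}"
            )

    @property
    def n_electrodes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class BandPowerSet:
    """The three 64-long spectral vectors of one trial.

    Entries are raw DFT power sums before any centering; centered copies
    (see :func:`center_spectra`) may be negative.
    """

    theta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    trial_id: int

    def __post_init__(self) -> None:
        for name in ("theta", "alpha", "beta"):
            v = np.asarray(getattr(self, name), dtype=float).ravel()
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} vector contains non-finite values")
            setattr(self, name, v)
        if not (len(self.theta) == len(self.alpha) == len(self.beta)):
            raise ValueError("band vectors must have equal length")

    @property
    def n_electrodes(self) -> int:
        return len(self.theta)

    def stacked(self) -> np.ndarray:
        """All values as a (3, n_electrodes) array in theta/alpha/beta order."""
        return np.stack([self.theta, self.alpha, self.beta])

    def values(self) -> np.ndarray:
        """The trial's 3*n_electrodes values as one flat vector."""
        return self.stacked().ravel()


def compute_band_power(
    trial: TrialRecording,
    band: FrequencyBand,
    window: Window = "rect",
) -> np.ndarray:
    """Band power per electrode: sum of |DFT|^2 over bins with low <= f < high.

    The DC bin is always excluded. With ``window="hann"`` a Hann taper is
    applied before the transform. Raises if the band reaches or exceeds the
    Nyquist frequency.
    """
    if band.high_hz > trial.fs / 2:
        raise ValueError(
            f"band exceeds Nyquist: {band.name} high edge {band.high_hz} Hz "
            f"> fs/2 = {trial.fs / 2} Hz"
        )
    x = trial.signal
    n = trial.n_samples
    if window == "hann":
        x = x * np.hanning(n)
    elif window != "rect":
        raise ValueError(f"unknown window {window!r}")
    spectrum = np.fft.rfft(x, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / trial.fs)
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz) & (freqs > 0)
    return np.sum(np.abs(spectrum[:, mask]) ** 2, axis=1)


def extract_band_power_set(
    trial: TrialRecording,
    bands: Sequence[FrequencyBand] = DEFAULT_BANDS,
    window: Window = "rect",
) -> BandPowerSet:
    """Theta/alpha/beta power vectors of one 64-electrode trial."""
    if trial.n_electrodes != N_ELECTRODES:
        raise ValueError(
            f"expected {N_ELECTRODES} electrodes for the standard montage, "
            f"got {trial.n_electrodes}"
        )
    if len(bands) != 3:
        raise ValueError("exactly three bands (theta, alpha, beta) are required")
    theta, alpha, beta = (compute_band_power(trial, b, window=window) for b in bands)
    return BandPowerSet(theta=theta, alpha=alpha, beta=beta, trial_id=trial.trial_id)


def center_spectra(
    sets: Iterable[BandPowerSet],
    mode: CenterMode = "dataset_mean",
) -> list[BandPowerSet]:
    """Subtract a mean from every spectral value.

    ``dataset_mean`` subtracts one scalar, the grand mean over all values of
    all trials; ``trial_mean`` subtracts each trial's own mean; ``none``
    returns an unchanged copy.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("center_spectra requires a non-empty list of trials")
    if mode == "none":
        return [copy.deepcopy(s) for s in sets]
    if mode == "dataset_mean":
        grand = float(np.mean(np.concatenate([s.values() for s in sets])))
        offsets = [grand] * len(sets)
    elif mode == "trial_mean":
        offsets = [float(np.mean(s.values())) for s in sets]
    else:
        raise ValueError(f"unknown centering mode {mode!r}")
    return [
        BandPowerSet(
            theta=s.theta - off,
            alpha=s.alpha - off,
            beta=s.beta - off,
            trial_id=s.trial_id,
        )
        for s, off in zip(sets, offsets)
    ]
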