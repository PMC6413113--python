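"""Synthetic EEG with load-dependent spectral structure.

Emulates the shape of a Sternberg working-memory EEG dataset: 13 subjects,
64 electrodes at 10-10 locations, four workload levels (memory-set sizes
2/4/6/8), 3.5 s trials (0.5 s presentation + 3 s retention) at 500 Hz.

Each trial is 1/f-shaped broadband noise plus band-limited theta, alpha and
beta oscillations with random frequency (within band) and phase. On the
frontal electrodes - those mapped to the top three grid rows, mirroring the
prefrontal involvement in memory tasks - oscillation amplitude grows
multiplicatively with workload level, with higher bands weighted more, so
higher load enhances power more in higher-frequency bands. A per-subject
lognormal gain models inter-subject amplitude variability.

Signal units are arbitrary; amplitudes default to values that put centered
band powers in the working range of the fixed-slope enhancement sigmoid
(see docs/methods.md for the calibration argument).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .spectral import TrialRecording

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "FRONTAL_ELECTRODES",
    "build_manifest",
    "generate_trials",
    "write_manifest",
]

#: electrodes on the top three grid rows (forehead region) of the layout
FRONTAL_ELECTRODES: tuple[int, ...] = tuple(range(22, 39))

#: trial total of the public Sternberg dataset this generator is shaped after
STERNBERG_TOTAL_TRIALS = 2670


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a synthetic recording session.

    effect_size is the fractional amplitude increase per workload-level
    step on frontal electrodes; band exponents weight it so higher bands
    gain more at higher levels. subject_scale_sd is the sigma of a
    lognormal per-subject gain. noise_sd is the standard deviation of the
    1/f background per electrode, in the same arbitrary units as the
    oscillation amplitudes.
    """

    n_subjects: int = 13
    trials_per_level_per_subject: int = 20
    fs: float = 500.0
    duration_s: float = 3.5
    load_levels: tuple[int, ...] = (1, 2, 3, 4)
    effect_size: float = 0.5
    subject_scale_sd: float = 0.2
    noise_sd: float = 0.01
    base_amplitudes: tuple[float, float, float] = (0.004, 0.006, 0.003)
    band_level_exponents: tuple[float, float, float] = (0.75, 1.0, 1.25)
    band_edges: tuple[tuple[float, float], ...] = ((4.0, 7.0), (8.0, 13.0), (13.0, 30.0))
    frontal_electrodes: tuple[int, ...] = FRONTAL_ELECTRODES
    level1_noise_boost: float = 0.0
    per_cell_counts: Mapping[tuple[int, int], int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_level_per_subject < 1:
            raise ValueError("subject and trial counts must be positive")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if self.effect_size < 0 or self.subject_scale_sd < 0 or self.noise_sd < 0:
            raise ValueError("effect_size, subject_scale_sd, noise_sd must be >= 0")
        if self.level1_noise_boost < 0:
            raise ValueError("level1_noise_boost must be >= 0")
        if any(lv not in (1, 2, 3, 4) for lv in self.load_levels):
            raise ValueError("load levels must be within 1..4")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def cell_count(self, subject: int, level: int) -> int:
        if self.per_cell_counts is not None:
            return int(self.per_cell_counts.get((subject, level), self.trials_per_level_per_subject))
        return self.trials_per_level_per_subject

    @staticmethod
    def sternberg_scale(seed: int = 0, **overrides) -> "SimulationConfig":
        """Preset emulating the 2670-trial, 13-subject dataset shape.

        2670 trials do not divide evenly over the 52 (subject, level)
        cells; the first 18 cells in (subject, level) order receive 52
        trials, the remaining 34 receive 51.
        """
        cells: dict[tuple[int, int], int] = {}
        base, extra = divmod(STERNBERG_TOTAL_TRIALS, 13 * 4)
        idx = 0
        for subject in range(1, 14):
            for level in (1, 2, 3, 4):
                cells[(subject, level)] = base + (1 if idx < extra else 0)
                idx += 1
        return SimulationConfig(
            n_subjects=13, per_cell_counts=cells, seed=seed, **overrides
        )


@dataclass
class SyntheticDataset:
    """Generated trials plus their manifest table."""

    trials: list[TrialRecording]
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["load_level"].to_numpy()

    @property
    def trial_ids(self) -> np.ndarray:
        return self.manifest["trial_id"].to_numpy()


def build_manifest(cfg: SimulationConfig) -> pd.DataFrame:
    """Manifest rows (trial_id, subject_id, load_level, fs, n_samples).

    Purely combinatorial - no signals are materialized - so it also serves
    to inspect large dataset shapes cheaply.
    """
    rows = []
    trial_id = 1
    for subject in range(1, cfg.n_subjects + 1):
        for level in cfg.load_levels:
            for _ in range(cfg.cell_count(subject, level)):
                rows.append((trial_id, subject, level, cfg.fs, cfg.n_samples))
                trial_id += 1
    return pd.DataFrame(
        rows, columns=["trial_id", "subject_id", "load_level", "fs", "n_samples"]
    )


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """1/f-shaped noise with unit variance per row."""
    n = shape[1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.maximum(freqs, 1.0)  # flat below 1 Hz to avoid a DC blowup
    amp[0] = 0.0
    shaped = np.fft.irfft(spectrum * amp, n=n, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def generate_trials(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate the full labeled dataset, deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    manifest = build_manifest(cfg)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    n_elec = 64
    frontal_mask = np.zeros(n_elec, dtype=bool)
    frontal_mask[[e - 1 for e in cfg.frontal_electrodes]] = True
    base_amp = np.asarray(cfg.base_amplitudes)
    exponents = np.asarray(cfg.band_level_exponents)
    subj_gains = np.exp(cfg.subject_scale_sd * rng.standard_normal(cfg.n_subjects))

    trials: list[TrialRecording] = []
    for row in manifest.itertuples(index=False):
        subject, level = int(row.subject_id), int(row.load_level)
        gain = subj_gains[subject - 1]
        load_gain = (1.0 + cfg.effect_size * (level - 1)) ** exponents  # per band
        noise_sd = cfg.noise_sd * gain
        if level == 1 and cfg.level1_noise_boost > 0:
            noise_sd *= 1.0 + cfg.level1_noise_boost
        signal = noise_sd * _pink_noise(rng, (n_elec, n), cfg.fs)
        # band oscillations: random in-band frequency and phase per electrode
        freqs = np.stack(
            [rng.uniform(low, high, size=n_elec) for low, high in cfg.band_edges]
        )
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(len(cfg.band_edges), n_elec))
        amps = base_amp[:, None] * gain * np.where(frontal_mask, load_gain[:, None], 1.0)
        signal = signal + np.einsum(
            "be,ben->en", amps, np.sin(2.0 * np.pi * freqs[:, :, None] * t + phases[:, :, None])
        )
        trials.append(
            TrialRecording(
                signal=signal,
                fs=cfg.fs,
                subject_id=subject,
                load_level=level,
                trial_id=int(row.trial_id),
            )
        )
    return SyntheticDataset(trials=trials, manifest=manifest)


def write_manifest(
    ds: SyntheticDataset,
    out_dir: str | Path,
    fmt: str = "npz",
) -> Path:
    """Write the dataset in the format the reader accepts; returns the manifest path.

    ``fmt="tsv"`` writes one delimited text matrix per trial (rows are
    electrodes) next to a manifest.tsv with a path column; ``fmt="npz"``
    writes a single array container plus the same manifest.tsv.
    """
    from . import io as pmsfe_io  # local import to avoid a cycle

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "tsv":
        return pmsfe_io.write_dataset_tsv(ds, out_dir)
    if fmt == "npz":
        return pmsfe_io.write_dataset_npz(ds, out_dir)
    raise ValueError(f"unknown dataset format {fmt!r}")
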