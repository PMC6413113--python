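"""Reading and writing the pipeline's on-disk artifacts.

The spine of a run is a tab-separated manifest (trial_id, subject_id,
load_level, fs, n_samples, path). Signals live either as one delimited
text matrix per trial (rows = electrodes) or as a single ``.npz`` array
container; band-power tables are long-format TSV or ``.npz``; map tensors
are ``.npz``. All writers accept an optional metadata dict (e.g. the run's
config hash) stored alongside the arrays.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enhance import EnhancedBandSet
from .simulate import SyntheticDataset
from .spectral import BandPowerSet, TrialRecording

__all__ = [
    "write_dataset_tsv",
    "write_dataset_npz",
    "read_dataset",
    "write_band_powers_tsv",
    "read_band_powers_tsv",
    "write_band_sets_npz",
    "read_band_powers_npz",
    "read_enhanced_npz",
    "write_maps_npz",
    "read_maps_npz",
]

MANIFEST_COLUMNS = ["trial_id", "subject_id", "load_level", "fs", "n_samples", "path"]


def _write_manifest_tsv(manifest: pd.DataFrame, path: Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {json.dumps(meta, sort_keys=True)}\n")
        manifest.to_csv(fh, sep="\t", index=False)


def _read_manifest_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_dataset_tsv(ds: SyntheticDataset, out_dir: Path, meta: dict | None = None) -> Path:
    """One text matrix per trial plus manifest.tsv; returns the manifest path."""
    out_dir = Path(out_dir)
    signal_dir = out_dir / "signals"
    signal_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for trial in ds.trials:
        rel = f"signals/trial_{trial.trial_id:05d}.tsv"
        np.savetxt(out_dir / rel, trial.signal, fmt="%.10e", delimiter="\t")
        paths.append(rel)
    manifest = ds.manifest.copy()
    manifest["path"] = paths
    manifest_path = out_dir / "manifest.tsv"
    _write_manifest_tsv(manifest, manifest_path, meta)
    return manifest_path


def write_dataset_npz(ds: SyntheticDataset, out_dir: Path, meta: dict | None = None) -> Path:
    """All signals in one array container plus manifest.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    signals = np.stack([t.signal for t in ds.trials])
    np.savez(
        out_dir / "signals.npz",
        signals=signals,
        trial_id=ds.manifest["trial_id"].to_numpy(),
        meta=json.dumps(meta or {}, sort_keys=True),
    )
    manifest = ds.manifest.copy()
    manifest["path"] = "signals.npz"
    manifest_path = out_dir / "manifest.tsv"
    _write_manifest_tsv(manifest, manifest_path, meta)
    return manifest_path


def read_dataset(path: str | Path) -> SyntheticDataset:
    """Load a dataset from a manifest.tsv (or the directory holding one)."""
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.tsv"
    manifest = _read_manifest_tsv(path)
    base = path.parent
    trials: list[TrialRecording] = []
    container_cache: dict[str, np.lib.npyio.NpzFile] = {}
    for row in manifest.itertuples(index=False):
        rel = str(row.path)
        if rel.endswith(".npz"):
            if rel not in container_cache:
                container_cache[rel] = np.load(base / rel)
            npz = container_cache[rel]
            idx = int(np.where(npz["trial_id"] == row.trial_id)[0][0])
            signal = npz["signals"][idx]
        else:
            signal = np.loadtxt(base / rel, delimiter="\t")
        trials.append(
            TrialRecording(
                signal=signal,
                fs=float(row.fs),
                subject_id=int(row.subject_id),
                load_level=int(row.load_level),
                trial_id=int(row.trial_id),
            )
        )
    return SyntheticDataset(trials=trials, manifest=manifest.drop(columns=["path"]))


def write_band_powers_tsv(sets: Sequence[BandPowerSet], path: str | Path) -> Path:
    """Long-format table: trial_id, band, electrode (1-based), value."""
    rows = []
    for s in sets:
        for band, vec in zip(("theta", "alpha", "beta"), (s.theta, s.alpha, s.beta)):
            for elec, value in enumerate(vec, start=1):
                rows.append((s.trial_id, band, elec, value))
    df = pd.DataFrame(rows, columns=["trial_id", "band", "electrode", "value"])
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.12e")
    return path


def read_band_powers_tsv(path: str | Path) -> list[BandPowerSet]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for trial_id, group in df.groupby("trial_id", sort=True):
        vecs = {}
        for band, sub in group.groupby("band"):
            vecs[band] = sub.sort_values("electrode")["value"].to_numpy()
        out.append(
            BandPowerSet(
                theta=vecs["theta"], alpha=vecs["alpha"], beta=vecs["beta"],
                trial_id=int(trial_id),
            )
        )
    return out


def write_band_sets_npz(
    sets: Sequence[BandPowerSet] | Sequence[EnhancedBandSet],
    path: str | Path,
    meta: dict | None = None,
) -> Path:
    """Array container for raw or enhanced band sets (auto-detected on read)."""
    path = Path(path)
    first = sets[0]
    enhanced = isinstance(first, EnhancedBandSet)
    stack = np.stack([s.stacked() for s in sets])  # (n, 3, 64)
    arrays = dict(
        bands=stack,
        trial_id=np.array([s.trial_id for s in sets]),
        enhanced=np.array(enhanced),
        meta=json.dumps(meta or {}, sort_keys=True),
    )
    if enhanced:
        arrays["degenerate"] = np.array([s.degenerate for s in sets])
    np.savez(path, **arrays)
    return path


def read_band_powers_npz(path: str | Path) -> list[BandPowerSet]:
    npz = np.load(path)
    if bool(npz["enhanced"]):
        raise ValueError(f"{path} holds enhanced sets; use read_enhanced_npz")
    return [
        BandPowerSet(theta=b[0], alpha=b[1], beta=b[2], trial_id=int(tid))
        for b, tid in zip(npz["bands"], npz["trial_id"])
    ]


def read_enhanced_npz(path: str | Path) -> list[EnhancedBandSet]:
    npz = np.load(path)
    if not bool(npz["enhanced"]):
        raise ValueError(f"{path} holds raw sets; use read_band_powers_npz")
    return [
        EnhancedBandSet(
            theta_e=b[0], alpha_e=b[1], beta_e=b[2],
            trial_id=int(tid), degenerate=bool(flag),
        )
        for b, tid, flag in zip(npz["bands"], npz["trial_id"], npz["degenerate"])
    ]


def write_maps_npz(
    maps: np.ndarray,
    manifest: pd.DataFrame,
    path: str | Path,
    meta: dict | None = None,
) -> Path:
    """Map tensor (n_trials, C, H, W) with aligned trial metadata."""
    path = Path(path)
    np.savez(
        path,
        maps=maps,
        trial_id=manifest["trial_id"].to_numpy(),
        subject_id=manifest["subject_id"].to_numpy(),
        load_level=manifest["load_level"].to_numpy(),
        meta=json.dumps(meta or {}, sort_keys=True),
    )
    return path


def read_maps_npz(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    npz = np.load(path)
    manifest = pd.DataFrame(
        {
            "trial_id": npz["trial_id"],
            "subject_id": npz["subject_id"],
            "load_level": npz["load_level"],
        }
    )
    return npz["maps"], manifest
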