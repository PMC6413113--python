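"""Training and evaluation protocols at desk scale.

Implements the experimental harness around PMSFE maps: a stratified 6:2:2
train/validation/test split drawn proportionately within every
(subject, workload-level) cell, stratified 4-fold cross-validation over the
80% train+validation pool, leave-one-subject-out (LOSO) generalization
splits, and a small two-branch classifier honoring the parallel-mechanism
contract: the raw channels [theta, alpha, beta] and the enhanced channels
[theta', alpha', beta'] pass through feature extractors that share no
parameters and meet only at the fully connected classification head.

The classifier is a compact NumPy MLP (per-branch flatten -> hidden ReLU
layers -> concatenation -> softmax over the 4 workload classes) trained
with minibatch SGD, momentum 0.9 and learning rate 0.001 by default, under
cross-entropy loss. It is a desk-scale stand-in for full-size deep CNNs:
the protocols, not their headline accuracies, are what it exercises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .spectral import BandPowerSet

__all__ = [
    "SplitPlan",
    "CVPlan",
    "LosoSplit",
    "ClassifierSpec",
    "EvalReport",
    "make_split",
    "make_cv_folds",
    "make_loso_splits",
    "TwoBranchClassifier",
    "train_classifier",
    "evaluate",
    "apply_trial_gain_jitter",
    "compare_channel_modes",
    "loso_accuracy_table",
]

N_CLASSES = 4


# ---------------------------------------------------------------------------
# split plans


@dataclass
class SplitPlan:
    """Disjoint train/validation/test trial-id sets, stratified per cell."""

    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    ratios: tuple[float, float, float]
    seed: int

    def all_ids(self) -> np.ndarray:
        return np.concatenate([self.train_ids, self.val_ids, self.test_ids])

    @property
    def pool_ids(self) -> np.ndarray:
        """The 80% train+validation pool used for cross-validation."""
        return np.concatenate([self.train_ids, self.val_ids])


@dataclass
class CVPlan:
    """k stratified folds over a trial pool; each fold validates once."""

    folds: list[np.ndarray]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def iter_splits(self):
        """Yield (train_ids, val_ids) with each fold as validation in turn."""
        for i, val in enumerate(self.folds):
            train = np.concatenate([f for j, f in enumerate(self.folds) if j != i])
            yield train, val


@dataclass(frozen=True)
class LosoSplit:
    test_subject: int
    train_ids: np.ndarray
    test_ids: np.ndarray


def _apportion(n: int, ratios: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n items over the ratios."""
    quotas = [n * r for r in ratios]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = np.argsort([-(q - np.floor(q)) for q in quotas], kind="stable")
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def make_split(
    manifest: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitPlan:
    """Stratified 6:2:2 split drawn within every (subject, level) cell.

    Within each cell the trial count per part is the largest-remainder
    apportionment of the ratios, so per-cell proportions match to within
    one trial. Cells with fewer than 3 trials trigger a warning and get a
    best-effort assignment.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for (subject, level), cell in manifest.groupby(["subject_id", "load_level"], sort=True):
        ids = cell["trial_id"].to_numpy().copy()
        if len(ids) < 3:
            warnings.warn(
                f"cell (subject {subject}, level {level}) has only {len(ids)} "
                "trials; 6:2:2 assignment is best-effort"
            )
        rng.shuffle(ids)
        counts = _apportion(len(ids), ratios)
        start = 0
        for part, count in zip(parts, counts):
            part.extend(ids[start : start + count])
            start += count
    return SplitPlan(
        train_ids=np.sort(np.array(parts[0], dtype=int)),
        val_ids=np.sort(np.array(parts[1], dtype=int)),
        test_ids=np.sort(np.array(parts[2], dtype=int)),
        ratios=ratios,
        seed=seed,
    )


def make_cv_folds(pool: pd.DataFrame, k: int = 4, seed: int = 0) -> CVPlan:
    """k stratified folds over a pool manifest, stratified by (subject, level)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = pool["trial_id"].to_numpy()
    strata = (
        pool["subject_id"].astype(str) + ":" + pool["load_level"].astype(str)
    ).to_numpy()
    # fall back to coarser strata when a (subject, level) cell is smaller
    # than k; folds stay a partition either way
    if pd.Series(strata).value_counts().min() < k:
        warnings.warn(
            "some (subject, level) cells have fewer trials than folds; "
            "stratifying by load level only"
        )
        strata = pool["load_level"].to_numpy()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [np.sort(ids[val_idx]) for _, val_idx in skf.split(ids, strata)]
    return CVPlan(folds=folds, seed=seed)


def make_loso_splits(manifest: pd.DataFrame) -> list[LosoSplit]:
    """One split per subject: that subject's trials test, all others train."""
    subjects = np.sort(manifest["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out requires at least 2 subjects")
    splits = []
    for subject in subjects:
        test_mask = manifest["subject_id"] == subject
        splits.append(
            LosoSplit(
                test_subject=int(subject),
                train_ids=np.sort(manifest.loc[~test_mask, "trial_id"].to_numpy()),
                test_ids=np.sort(manifest.loc[test_mask, "trial_id"].to_numpy()),
            )
        )
    return splits


# ---------------------------------------------------------------------------
# two-branch classifier


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training hyperparameters of the desk-scale classifier.

    channel_mode "pmsfe6" feeds channels 1-3 and 4-6 to two parameter-
    disjoint branches; "spectral3" uses a single branch on channels 1-3.
    hidden_sizes describes the per-branch dense ReLU stack.
    """

    channel_mode: str = "pmsfe6"
    hidden_sizes: tuple[int, ...] = (32,)
    lr: float = 0.001
    momentum: float = 0.9
    epochs: int = 150
    batch_size: int = 32
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.channel_mode not in ("pmsfe6", "spectral3"):
            raise ValueError("channel_mode must be 'pmsfe6' or 'spectral3'")
        if self.lr <= 0 or not (0 <= self.momentum < 1):
            raise ValueError("invalid optimizer hyperparameters")

    @property
    def n_branches(self) -> int:
        return 2 if self.channel_mode == "pmsfe6" else 1

    @property
    def n_channels(self) -> int:
        return 6 if self.channel_mode == "pmsfe6" else 3


@dataclass
class EvalReport:
    """Held-out metrics: accuracy, 4x4 confusion matrix, per-class recall."""

    accuracy: float
    confusion: np.ndarray  # rows = true class, cols = predicted class
    per_class_recall: np.ndarray
    n_test: int
    channel_mode: str
    seed: int

    def confusion_normalized(self) -> np.ndarray:
        """Row-normalized confusion matrix for display."""
        sums = self.confusion.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return self.confusion / sums

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "n_test": self.n_test,
            "channel_mode": self.channel_mode,
            "seed": self.seed,
        }


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TwoBranchClassifier:
    """Parallel-branch MLP over flattened map channels.

    Each branch owns its hidden ReLU stack; branch outputs are concatenated
    and fully connected to the 4 class logits. Zeroing one branch's input
    cannot change the other branch's activations (no shared parameters
    before the head). Argmax ties break toward the lowest class index.
    """

    def __init__(self, spec: ClassifierSpec):
        self.spec = spec
        self._params: dict | None = None
        self._norm: list[tuple[np.ndarray, np.ndarray]] | None = None

    # -- input handling ----------------------------------------------------

    def _branch_inputs(self, maps: np.ndarray) -> list[np.ndarray]:
        maps = np.asarray(maps, dtype=float)
        if maps.ndim != 4:
            raise ValueError("maps must be (n_trials, channels, height, width)")
        need = self.spec.n_channels
        if maps.shape[1] < need:
            raise ValueError(
                f"{self.spec.channel_mode} needs {need} channels, got {maps.shape[1]}"
            )
        n = maps.shape[0]
        if self.spec.n_branches == 2:
            groups = [maps[:, :3], maps[:, 3:6]]
        else:
            groups = [maps[:, :3]]
        return [g.reshape(n, -1) for g in groups]

    def _normalized(self, maps: np.ndarray) -> list[np.ndarray]:
        xs = self._branch_inputs(maps)
        if self._norm is None:
            return xs
        return [(x - mu) / sd for x, (mu, sd) in zip(xs, self._norm)]

    # -- forward / backward -------------------------------------------------

    def _forward(self, xs: list[np.ndarray], params: dict):
        acts = []  # per branch: list of post-ReLU activations
        feats = []
        for b, x in enumerate(xs):
            h = x
            layer_acts = []
            for W, bias in params["branches"][b]:
                h = np.maximum(h @ W + bias, 0.0)
                layer_acts.append(h)
            acts.append(layer_acts)
            feats.append(h)
        concat = np.concatenate(feats, axis=1)
        logits = concat @ params["W_out"] + params["b_out"]
        return logits, concat, acts

    def branch_activations(self, maps: np.ndarray, branch: int) -> list[np.ndarray]:
        """Post-ReLU activations of one branch (for contract inspection)."""
        if self._params is None:
            raise RuntimeError("model is not trained")
        xs = self._normalized(maps)
        _, _, acts = self._forward(xs, self._params)
        return acts[branch]

    def _init_params(self, dims: list[int], rng: np.random.Generator) -> dict:
        hidden = list(self.spec.hidden_sizes)
        branches = []
        for d in dims:
            layers = []
            prev = d
            for h in hidden:
                W = rng.standard_normal((prev, h)) * np.sqrt(2.0 / prev)
                layers.append([W, np.zeros(h)])
                prev = h
            branches.append(layers)
        feat_dim = (hidden[-1] if hidden else dims[0]) * len(dims)
        W_out = rng.standard_normal((feat_dim, N_CLASSES)) * np.sqrt(2.0 / feat_dim)
        return {"branches": branches, "W_out": W_out, "b_out": np.zeros(N_CLASSES)}

    @staticmethod
    def _clone(params: dict) -> dict:
        return {
            "branches": [[[W.copy(), b.copy()] for W, b in layers] for layers in params["branches"]],
            "W_out": params["W_out"].copy(),
            "b_out": params["b_out"].copy(),
        }

    def _loss(self, xs: list[np.ndarray], y0: np.ndarray, params: dict) -> float:
        logits, _, _ = self._forward(xs, params)
        p = _softmax(logits)
        return float(-np.mean(np.log(p[np.arange(len(y0)), y0] + 1e-300)))

    def fit(
        self,
        maps: np.ndarray,
        labels: np.ndarray,
        val_maps: np.ndarray | None = None,
        val_labels: np.ndarray | None = None,
    ) -> dict:
        """Minimize cross-entropy on the training set.

        Tracks per-epoch train and validation loss and restores the
        parameters of the best validation epoch (final epoch when no
        validation set is given). Returns the history dict.
        """
        labels = np.asarray(labels, dtype=int)
        if np.any((labels < 1) | (labels > N_CLASSES)):
            raise ValueError("labels must be workload levels in 1..4")
        y0 = labels - 1
        xs_raw = self._branch_inputs(maps)
        if self.spec.standardize:
            self._norm = []
            for x in xs_raw:
                mu = x.mean(axis=0)
                sd = x.std(axis=0)
                sd[sd < 1e-12] = 1.0
                self._norm.append((mu, sd))
        else:
            self._norm = None
        xs = self._normalized(maps)
        val_xs = None
        if val_maps is not None and len(val_maps):
            val_xs = self._normalized(val_maps)
            val_y0 = np.asarray(val_labels, dtype=int) - 1

        rng = np.random.default_rng(self.spec.seed)
        params = self._init_params([x.shape[1] for x in xs], rng)
        velocity = self._clone(params)
        for layers in velocity["branches"]:
            for layer in layers:
                layer[0][:] = 0.0
                layer[1][:] = 0.0
        velocity["W_out"][:] = 0.0
        velocity["b_out"][:] = 0.0

        n = xs[0].shape[0]
        history: dict = {"train_loss": [], "val_loss": [], "best_epoch": None}
        best_val = np.inf
        best_params = self._clone(params)
        for epoch in range(self.spec.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.spec.batch_size):
                idx = order[start : start + self.spec.batch_size]
                xb = [x[idx] for x in xs]
                yb = y0[idx]
                logits, concat, acts = self._forward(xb, params)
                p = _softmax(logits)
                m = len(idx)
                epoch_loss += -np.sum(np.log(p[np.arange(m), yb] + 1e-300))
                dlogits = p
                dlogits[np.arange(m), yb] -= 1.0
                dlogits /= m
                grads = {
                    "W_out": concat.T @ dlogits,
                    "b_out": dlogits.sum(axis=0),
                    "branches": [],
                }
                dconcat = dlogits @ params["W_out"].T
                offset = 0
                for b, x in enumerate(xb):
                    width = acts[b][-1].shape[1] if acts[b] else x.shape[1]
                    dh = dconcat[:, offset : offset + width]
                    offset += width
                    layer_grads = []
                    layers = params["branches"][b]
                    inputs = [x] + acts[b][:-1]
                    for li in range(len(layers) - 1, -1, -1):
                        dh = dh * (acts[b][li] > 0)
                        layer_grads.append(
                            (inputs[li].T @ dh, dh.sum(axis=0))
                        )
                        if li > 0:
                            dh = dh @ layers[li][0].T
                    grads["branches"].append(layer_grads[::-1])
                # SGD with momentum
                lr, mom = self.spec.lr, self.spec.momentum
                for b, layers in enumerate(params["branches"]):
                    for li, (W, bias) in enumerate(layers):
                        gW, gb = grads["branches"][b][li]
                        vW, vb = velocity["branches"][b][li]
                        vW *= mom
                        vW -= lr * gW
                        vb *= mom
                        vb -= lr * gb
                        W += vW
                        bias += vb
                velocity["W_out"] = mom * velocity["W_out"] - lr * grads["W_out"]
                velocity["b_out"] = mom * velocity["b_out"] - lr * grads["b_out"]
                params["W_out"] += velocity["W_out"]
                params["b_out"] += velocity["b_out"]
            history["train_loss"].append(epoch_loss / n)
            if val_xs is not None:
                vloss = self._loss(val_xs, val_y0, params)
                history["val_loss"].append(vloss)
                if vloss < best_val:
                    best_val = vloss
                    best_params = self._clone(params)
                    history["best_epoch"] = epoch
        if val_xs is not None:
            self._params = best_params
        else:
            self._params = params
            history["best_epoch"] = self.spec.epochs - 1
        return history

    def predict(self, maps: np.ndarray) -> np.ndarray:
        """Predicted workload levels in 1..4; argmax ties -> lowest class."""
        if self._params is None:
            raise RuntimeError("model is not trained")
        xs = self._normalized(maps)
        logits, _, _ = self._forward(xs, self._params)
        return np.argmax(logits, axis=1) + 1

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        import json as _json

        if self._params is None:
            raise RuntimeError("model is not trained")
        arrays = {"W_out": self._params["W_out"], "b_out": self._params["b_out"]}
        for b, layers in enumerate(self._params["branches"]):
            for li, (W, bias) in enumerate(layers):
                arrays[f"branch{b}_W{li}"] = W
                arrays[f"branch{b}_b{li}"] = bias
        if self._norm is not None:
            for b, (mu, sd) in enumerate(self._norm):
                arrays[f"norm{b}_mu"] = mu
                arrays[f"norm{b}_sd"] = sd
        spec_json = _json.dumps(self.spec.__dict__ | {"hidden_sizes": list(self.spec.hidden_sizes)})
        np.savez(path, spec=spec_json, **arrays)

    @classmethod
    def load(cls, path) -> "TwoBranchClassifier":
        import json as _json

        npz = np.load(path)
        raw = _json.loads(str(npz["spec"]))
        raw["hidden_sizes"] = tuple(raw["hidden_sizes"])
        model = cls(ClassifierSpec(**raw))
        branches = []
        for b in range(model.spec.n_branches):
            layers = []
            li = 0
            while f"branch{b}_W{li}" in npz:
                layers.append([npz[f"branch{b}_W{li}"], npz[f"branch{b}_b{li}"]])
                li += 1
            branches.append(layers)
        model._params = {"branches": branches, "W_out": npz["W_out"], "b_out": npz["b_out"]}
        if "norm0_mu" in npz:
            model._norm = [
                (npz[f"norm{b}_mu"], npz[f"norm{b}_sd"]) for b in range(model.spec.n_branches)
            ]
        return model


# ---------------------------------------------------------------------------
# training / evaluation drivers


def _indices_for(trial_ids: np.ndarray, wanted: np.ndarray) -> np.ndarray:
    lookup = {int(t): i for i, t in enumerate(trial_ids)}
    return np.array([lookup[int(t)] for t in wanted], dtype=int)


def train_classifier(
    maps: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    split: SplitPlan | None = None,
    trial_ids: np.ndarray | None = None,
) -> tuple[TwoBranchClassifier, dict]:
    """Train on a split's train part, tracking validation loss per epoch.

    ``maps`` rows align with ``trial_ids`` (defaults to 1..n). Without a
    split the whole input trains the model.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(maps):
        raise ValueError("labels and maps must align")
    if trial_ids is None:
        trial_ids = np.arange(1, len(maps) + 1)
    model = TwoBranchClassifier(spec)
    if split is None:
        history = model.fit(maps, labels)
        return model, history
    tr = _indices_for(trial_ids, split.train_ids)
    va = _indices_for(trial_ids, split.val_ids)
    history = model.fit(
        maps[tr], labels[tr],
        maps[va] if len(va) else None,
        labels[va] if len(va) else None,
    )
    return model, history


def evaluate(
    model,
    maps: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
) -> EvalReport:
    """Accuracy, confusion matrix (rows = true) and per-class recall."""
    labels = np.asarray(labels, dtype=int)
    if len(maps) == 0:
        raise ValueError("test set is empty")
    pred = np.asarray(model.predict(maps), dtype=int)
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for t, p in zip(labels, pred):
        confusion[t - 1, p - 1] += 1
    accuracy = float(np.trace(confusion) / len(labels))
    row_sums = confusion.sum(axis=1)
    recall = np.divide(
        np.diag(confusion), row_sums,
        out=np.zeros(N_CLASSES), where=row_sums > 0,
    )
    mode = getattr(getattr(model, "spec", None), "channel_mode", "unknown")
    return EvalReport(
        accuracy=accuracy,
        confusion=confusion,
        per_class_recall=recall,
        n_test=len(labels),
        channel_mode=mode,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# channel-mode comparison


def apply_trial_gain_jitter(
    sets: Sequence[BandPowerSet],
    sd: float,
    rng: np.random.Generator,
) -> list[BandPowerSet]:
    """Multiply each trial's 192 raw powers by a lognormal gain (sigma=sd).

    Emulates trial-to-trial spectral-range variability: the condition the
    per-trial enhancement is designed to neutralize.
    """
    out = []
    for s in sets:
        g = float(np.exp(sd * rng.standard_normal()))
        out.append(
            BandPowerSet(theta=s.theta * g, alpha=s.alpha * g, beta=s.beta * g,
                         trial_id=s.trial_id)
        )
    return out


def compare_channel_modes(
    maps: np.ndarray,
    labels: np.ndarray,
    manifest: pd.DataFrame,
    spec: ClassifierSpec,
    seeds: Sequence[int],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> pd.DataFrame:
    """Mean accuracy +- sd per channel mode over seeds, and the increased rate.

    Both modes see identical data, splits and seeds. Columns follow the
    comparison-table schema: mode, mean_accuracy_pct, std_accuracy,
    increased_rate_pp (PMSFE minus spectral baseline, percentage points).
    """
    trial_ids = manifest["trial_id"].to_numpy()
    accs: dict[str, list[float]] = {"spectral3": [], "pmsfe6": []}
    for seed in seeds:
        split = make_split(manifest, ratios=ratios, seed=seed)
        te = _indices_for(trial_ids, split.test_ids)
        for mode in ("spectral3", "pmsfe6"):
            mode_spec = replace(spec, channel_mode=mode, seed=seed)
            model, _ = train_classifier(maps, labels, mode_spec, split, trial_ids)
            report = evaluate(model, maps[te], labels[te], seed=seed)
            accs[mode].append(report.accuracy)
    mean = {m: 100.0 * float(np.mean(v)) for m, v in accs.items()}
    std = {m: float(np.std(v)) for m, v in accs.items()}
    increase = mean["pmsfe6"] - mean["spectral3"]
    return pd.DataFrame(
        {
            "mode": ["spectral3", "pmsfe6"],
            "mean_accuracy_pct": [mean["spectral3"], mean["pmsfe6"]],
            "std_accuracy": [std["spectral3"], std["pmsfe6"]],
            "increased_rate_pp": [0.0, increase],
        }
    )


def loso_accuracy_table(
    maps: np.ndarray,
    labels: np.ndarray,
    manifest: pd.DataFrame,
    spec: ClassifierSpec,
) -> pd.DataFrame:
    """Per-subject LOSO accuracy (%) for both channel modes."""
    trial_ids = manifest["trial_id"].to_numpy()
    rows = []
    for split in make_loso_splits(manifest):
        tr = _indices_for(trial_ids, split.train_ids)
        te = _indices_for(trial_ids, split.test_ids)
        row: dict = {"subject": split.test_subject}
        for mode in ("spectral3", "pmsfe6"):
            mode_spec = replace(spec, channel_mode=mode)
            model = TwoBranchClassifier(mode_spec)
            model.fit(maps[tr], labels[tr])
            report = evaluate(model, maps[te], labels[te])
            row[mode + "_accuracy_pct"] = 100.0 * report.accuracy
        row["increased_rate_pp"] = (
            row["pmsfe6_accuracy_pct"] - row["spectral3_accuracy_pct"]
        )
        rows.append(row)
    return pd.DataFrame(rows)
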