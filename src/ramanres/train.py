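"""Training: data splits, the class-weighted loss, the Adam loop, and the
three-strategy weighted ensemble.

The ensemble combines three views of the same spectra — the original rows,
rows with their main peaks intensified, and two half-grid windows
([0, 512) and [128, 640) channels) feeding shallower networks whose
probabilities are averaged — with normalized 8:1:1 weights:

    p = 0.8 * p_original + 0.1 * p_intensify + 0.1 * p_split
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from .augment import IntensifyConfig, intensify_peaks
from .nn.layers import sigmoid
from .nn.optim import Adam
from .preprocess import PreprocessedMatrix, minmax
from .resnet import ModelConfig, ResNet1D, build_model

__all__ = [
    "TrainConfig",
    "EnsembleConfig",
    "EnsembleModel",
    "split_indices",
    "split_dataset",
    "class_weights_inverse_frequency",
    "weighted_loss",
    "train",
    "make_strategy_inputs",
    "train_ensemble",
    "ensemble_predict",
]

_EPS = 1e-7


@dataclass
class TrainConfig:
    """Optimization schedule and data-split policy.

    Defaults follow the reference protocol: Adam at learning rate 1e-4,
    batch size 128, 200 epochs, 80/10/10 train/val/test fractions with
    spectrum-level stratified splitting.  ``selection`` picks the parameter
    snapshot with the best validation accuracy (test-based selection would
    leak); ``split_mode="patient"`` confines whole patients to one
    partition.
    """

    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 200
    class_weighting: str = "inverse_frequency"  # or "none"
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    split_mode: str = "spectrum"  # or "patient"
    selection: str = "best_val_accuracy"  # or "last"
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if min(self.split_fractions) <= 0:
            raise ValueError("split_fractions must be positive")
        if self.split_mode not in ("spectrum", "patient"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")
        if self.selection not in ("best_val_accuracy", "last"):
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.class_weighting not in ("none", "inverse_frequency"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")
        if self.epochs < 0 or self.batch_size < 2:
            raise ValueError("epochs must be >= 0 and batch_size >= 2")


@dataclass
class EnsembleConfig:
    """Member weights (normalized internally) and the two split windows,
    given as half-open channel index ranges on the 1024-point grid."""

    weights: tuple[float, float, float] = (8.0, 1.0, 1.0)
    split_windows: tuple[tuple[int, int], tuple[int, int]] = ((0, 512), (128, 640))

    def normalized_weights(self) -> tuple[float, float, float]:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("ensemble weights must be non-negative with positive sum")
        w = w / w.sum()
        return (float(w[0]), float(w[1]), float(w[2]))

    def validate(self, grid_len: int = 1024) -> None:
        self.normalized_weights()
        for lo, hi in self.split_windows:
            if not (0 <= lo < hi <= grid_len):
                raise ValueError(f"split window [{lo}, {hi}) outside [0, {grid_len})")


def split_indices(
    labels: np.ndarray,
    cfg: TrainConfig,
    patient_ids: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/val/test index partition.

    Spectrum mode stratifies by label; patient mode assigns whole patients
    to a single partition (fractions then hold only approximately).
    """
    cfg.validate()
    labels = np.asarray(labels)
    n = labels.size
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    f_train, f_val, f_test = cfg.split_fractions
    idx = np.arange(n)
    if cfg.split_mode == "patient":
        if patient_ids is None:
            raise ValueError("patient split_mode requires patient ids")
        groups = np.asarray(patient_ids)
        gss = GroupShuffleSplit(n_splits=1, test_size=f_val + f_test, random_state=cfg.seed)
        tr, rest = next(gss.split(idx, labels, groups))
        gss2 = GroupShuffleSplit(
            n_splits=1, test_size=f_test / (f_val + f_test), random_state=cfg.seed + 1
        )
        va_rel, te_rel = next(gss2.split(rest, labels[rest], groups[rest]))
        return idx[tr], idx[rest][va_rel], idx[rest][te_rel]
    tr, rest = train_test_split(
        idx, test_size=f_val + f_test, stratify=labels, random_state=cfg.seed
    )
    va, te = train_test_split(
        rest,
        test_size=f_test / (f_val + f_test),
        stratify=labels[rest],
        random_state=cfg.seed + 1,
    )
    return np.sort(tr), np.sort(va), np.sort(te)


def split_dataset(
    matrix: PreprocessedMatrix, cfg: TrainConfig
) -> tuple[PreprocessedMatrix, PreprocessedMatrix, PreprocessedMatrix]:
    """Partition a labelled matrix into train/val/test matrices."""
    if matrix.labels is None:
        raise ValueError("split_dataset requires labels")
    tr, va, te = split_indices(matrix.labels, cfg, matrix.patient_ids)
    return matrix.subset(tr), matrix.subset(va), matrix.subset(te)


def class_weights_inverse_frequency(y: np.ndarray) -> tuple[float, float]:
    """(w0, w1) with w1 = n / (2 n_pos), w0 = n / (2 n_neg)."""
    y = np.asarray(y)
    n = y.size
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for inverse-frequency weights")
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


def weighted_loss(
    y_true: np.ndarray,
    y_prob: np.ndarray,
    class_weights: Optional[tuple[float, float]] = None,
) -> float:
    """Class-weighted binary cross-entropy, averaged over samples.

    L = -mean( w1 * y * ln(p) + w0 * (1 - y) * ln(1 - p) ), probabilities
    clamped to [1e-7, 1 - 1e-7].
    """
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_prob, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    w0, w1 = class_weights if class_weights is not None else (1.0, 1.0)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(w1 * y * np.log(p) + w0 * (1.0 - y) * np.log(1.0 - p)))


def train(
    model: ResNet1D,
    train_matrix: PreprocessedMatrix,
    val_matrix: PreprocessedMatrix,
    cfg: TrainConfig,
) -> ResNet1D:
    """Mini-batch Adam training of ``model`` in place.

    Records per-epoch train/val loss and accuracy in ``model.history`` and,
    under the default selection policy, restores the parameter snapshot
    with the highest validation accuracy.
    """
    cfg.validate()
    if train_matrix.n == 0:
        raise ValueError("empty training set")
    if train_matrix.labels is None or val_matrix.labels is None:
        raise ValueError("training requires labelled matrices")
    if train_matrix.grid.size != model.config.input_length:
        raise ValueError(
            f"matrix grid {train_matrix.grid.size} != model input {model.config.input_length}"
        )
    x_tr = train_matrix.values
    y_tr = train_matrix.labels.astype(float)
    x_va = val_matrix.values
    y_va = val_matrix.labels.astype(float)
    weights = (
        class_weights_inverse_frequency(y_tr)
        if cfg.class_weighting == "inverse_frequency"
        else (1.0, 1.0)
    )
    w0, w1 = weights
    model.history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    if cfg.epochs == 0:
        return model
    opt = Adam(model.modules(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    best_acc, best_state = -1.0, None
    for _epoch in range(cfg.epochs):
        perm = rng.permutation(train_matrix.n)
        loss_sum, correct, seen = 0.0, 0, 0
        for start in range(0, train_matrix.n, cfg.batch_size):
            sel = perm[start : start + cfg.batch_size]
            if sel.size < 2:  # batch normalization needs >= 2 samples
                continue
            xb, yb = x_tr[sel], y_tr[sel]
            logits = model.forward_logits(xb, training=True, rng=rng)
            p = np.clip(sigmoid(logits.astype(float)), _EPS, 1.0 - _EPS)
            loss_sum += weighted_loss(yb, p, weights) * sel.size
            correct += int(((p >= 0.5).astype(float) == yb).sum())
            seen += sel.size
            dlogits = (w0 * (1.0 - yb) * p - w1 * yb * (1.0 - p)) / sel.size
            model.backward(dlogits)
            opt.step()
        # dropout shifts BN statistics; re-estimate them on clean activations
        if model.config.dropout_rate > 0:
            model.recalibrate_batchnorm(x_tr, batch_size=cfg.batch_size)
        p_va = model.predict_proba(x_va)
        val_acc = float(((p_va >= 0.5).astype(float) == y_va).mean())
        model.history["train_loss"].append(loss_sum / max(seen, 1))
        model.history["train_acc"].append(correct / max(seen, 1))
        model.history["val_loss"].append(weighted_loss(y_va, p_va, weights))
        model.history["val_acc"].append(val_acc)
        if cfg.selection == "best_val_accuracy" and val_acc > best_acc:
            best_acc = val_acc
            best_state = model.copy_state()
    if cfg.selection == "best_val_accuracy" and best_state is not None:
        model.load_state_arrays(best_state)
    return model


STRATEGIES = ("original", "intensify", "split")


def make_strategy_inputs(
    matrix: PreprocessedMatrix,
    strategy: str,
    intensify_cfg: Optional[IntensifyConfig] = None,
    ensemble_cfg: Optional[EnsembleConfig] = None,
) -> list[PreprocessedMatrix]:
    """Materialize one ensemble member's view of the data.

    original -> [matrix]; intensify -> [row-wise peak-intensified matrix];
    split -> one renormalized sub-matrix per configured window.
    """
    if strategy == "original":
        return [matrix]
    if strategy == "intensify":
        cfg = intensify_cfg or IntensifyConfig()
        vals = np.vstack([intensify_peaks(row, cfg) for row in matrix.values]) \
            if matrix.n else matrix.values.copy()
        return [
            PreprocessedMatrix(vals, matrix.grid, list(matrix.sample_ids),
                               matrix.labels, matrix.patient_ids)
        ]
    if strategy == "split":
        ecfg = ensemble_cfg or EnsembleConfig()
        ecfg.validate(matrix.grid.size)
        out = []
        for lo, hi in ecfg.split_windows:
            out.append(
                PreprocessedMatrix(minmax(matrix.values[:, lo:hi]), matrix.grid[lo:hi],
                                   list(matrix.sample_ids), matrix.labels,
                                   matrix.patient_ids)
            )
        return out
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


@dataclass
class EnsembleModel:
    """Trained members of the three strategies plus their mixing weights."""

    original: ResNet1D
    intensify: ResNet1D
    split: list[ResNet1D]
    config: EnsembleConfig = field(default_factory=EnsembleConfig)
    intensify_cfg: IntensifyConfig = field(default_factory=IntensifyConfig)

    def member_probabilities(self, matrix: PreprocessedMatrix) -> dict[str, np.ndarray]:
        """Per-strategy probabilities on ``matrix`` (split = mean of its
        two window models)."""
        if self.original is None or self.intensify is None or len(self.split) == 0:
            raise ValueError("ensemble is missing a member")
        p = {"original": self.original.predict_proba(matrix.values)}
        (im,) = make_strategy_inputs(matrix, "intensify", self.intensify_cfg)
        p["intensify"] = self.intensify.predict_proba(im.values)
        wins = make_strategy_inputs(matrix, "split", ensemble_cfg=self.config)
        p["split"] = np.mean(
            [m.predict_proba(w.values) for m, w in zip(self.split, wins)], axis=0
        )
        return p

    def predict_proba(self, matrix: PreprocessedMatrix) -> np.ndarray:
        return ensemble_predict(self, matrix)

    def save(self, directory: str | Path) -> None:
        """Directory of member archives plus a manifest."""
        import json

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.original.save(d / "original.rnn")
        self.intensify.save(d / "intensify.rnn")
        for i, m in enumerate(self.split):
            m.save(d / f"split{i}.rnn")
        manifest = {
            "weights": list(self.config.weights),
            "split_windows": [list(w) for w in self.config.split_windows],
            "intensify": self.intensify_cfg.__dict__,
            "members": ["original.rnn", "intensify.rnn"]
            + [f"split{i}.rnn" for i in range(len(self.split))],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @staticmethod
    def load(directory: str | Path) -> "EnsembleModel":
        import json

        from .resnet import load_model

        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        return EnsembleModel(
            original=load_model(d / "original.rnn"),
            intensify=load_model(d / "intensify.rnn"),
            split=[load_model(d / m) for m in manifest["members"][2:]],
            config=EnsembleConfig(
                weights=tuple(manifest["weights"]),
                split_windows=tuple(tuple(w) for w in manifest["split_windows"]),
            ),
            intensify_cfg=IntensifyConfig(**manifest["intensify"]),
        )


def train_ensemble(
    matrix: PreprocessedMatrix,
    model_cfg: Optional[ModelConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    ensemble_cfg: Optional[EnsembleConfig] = None,
    intensify_cfg: Optional[IntensifyConfig] = None,
) -> tuple[EnsembleModel, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Train the three strategy members on a shared train/val/test split.

    Returns the ensemble and the (train, val, test) index arrays so the
    caller can evaluate on exactly the held-out spectra.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    ensemble_cfg = ensemble_cfg or EnsembleConfig()
    intensify_cfg = intensify_cfg or IntensifyConfig()
    if matrix.labels is None:
        raise ValueError("train_ensemble requires labels")
    tr, va, te = split_indices(matrix.labels, train_cfg, matrix.patient_ids)

    def fit(inputs: PreprocessedMatrix, cfg: ModelConfig, seed_offset: int) -> ResNet1D:
        mcfg = ModelConfig(**{**cfg.__dict__, "seed": cfg.seed + seed_offset})
        model = build_model(mcfg)
        tcfg = TrainConfig(**{**train_cfg.__dict__, "seed": train_cfg.seed + seed_offset})
        return train(model, inputs.subset(tr), inputs.subset(va), tcfg)

    (orig,) = make_strategy_inputs(matrix, "original")
    (inten,) = make_strategy_inputs(matrix, "intensify", intensify_cfg)
    wins = make_strategy_inputs(matrix, "split", ensemble_cfg=ensemble_cfg)
    members = EnsembleModel(
        original=fit(orig, model_cfg, 0),
        intensify=fit(inten, model_cfg, 1),
        split=[
            fit(w, model_cfg.scaled_to(w.grid.size), 2 + i) for i, w in enumerate(wins)
        ],
        config=ensemble_cfg,
        intensify_cfg=intensify_cfg,
    )
    return members, (tr, va, te)


def ensemble_predict(ensemble: EnsembleModel, matrix: PreprocessedMatrix) -> np.ndarray:
    """Weighted convex combination of member probabilities."""
    w_orig, w_int, w_split = ensemble.config.normalized_weights()
    p = ensemble.member_probabilities(matrix)
    return w_orig * p["original"] + w_int * p["intensify"] + w_split * p["split"]
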