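"""Multi-task sequence CNN: model definition, training, tuning, evaluation.

The architecture is a stack of three units, each convolution -> ReLU ->
batch normalization -> max pooling, followed by a sigmoid-activated fully
connected layer and a sigmoid output unit per task.  A cell model predicts
the six histone marks of one cell type from 1000-bp one-hot DNA; a mark model
predicts cell types from a single mark.  Training minimizes binary cross
entropy with RMSprop (lr 0.001) on minibatches, applies L1+L2 penalties to
the fully connected layer only, and early-stops on validation loss.

Usage follows the model/results idiom::

    model = SequenceCNN(dataset, ModelConfig(n_tasks=6))
    res = model.fit()
    print(res.summary())
    record = res.evaluate("test")
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import _nn
from .dataset import EncodedDataset

# Table of hyper-parameter trials used for random search: paired (L1, L2)
# rows, patience 5000 validation checks, 20 epochs max, minibatch 128,
# crossed with the candidate bin-overlap fractions.
TRIAL_ROWS = [
    (1e-07, 2e-08),
    (2e-07, 4e-08),
    (3e-07, 8e-08),
    (4e-07, 2e-07),
    (5e-07, 4e-07),
    (6e-07, 8e-07),
]
OVERLAP_FRACTIONS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class ModelConfig:
    n_tasks: int
    conv_filters: tuple[int, ...] = (320, 300, 300)
    conv_widths: tuple[int, ...] = (19, 11, 7)
    pool_sizes: tuple[int, ...] = (4, 4, 4)
    fc_units: int = 1000
    l1: float = 0.0
    l2: float = 0.0
    learning_rate: float = 0.001
    batch_size: int = 128
    patience: int = 5000          # validation checks without improvement
    max_epochs: int = 20
    overlap_fraction: float = 0.5
    rng_seed: int = 0
    context_size: int = 1000
    val_check_interval: int | None = None   # minibatches; None = once per epoch
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_tasks < 1 or self.fc_units < 1:
            raise ValueError("all unit counts must be positive")
        if any(f < 1 for f in self.conv_filters + self.conv_widths + self.pool_sizes):
            raise ValueError("all counts must be positive")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("l1 and l2 must be >= 0")

    def flat_length(self) -> int:
        """Flattened feature count entering the fully connected layer."""
        length = self.context_size
        for w, p in zip(self.conv_widths, self.pool_sizes):
            length = length - w + 1
            if length < 1:
                raise ValueError(
                    f"context_size {self.context_size} too small for the "
                    f"receptive field of conv widths {self.conv_widths}"
                )
            length //= p
            if length < 1:
                raise ValueError("pooling collapsed the sequence to zero length")
        return length * self.conv_filters[-1]


def reduced_config(n_tasks: int, **overrides) -> ModelConfig:
    """Desk-scale configuration for toy genomes: 32/16/16 filters.

    Relative to the full-scale defaults the filters are narrower (12 bp in
    the first layer, matching typical TF motif widths), the dense layer is
    small, minibatches are smaller and the learning rate larger (few
    thousand examples mean few updates per epoch), validation is checked
    every 10 minibatches, and a mild L1 penalty on the dense layer curbs
    memorization.
    """
    defaults = dict(conv_filters=(32, 16, 16), conv_widths=(15, 7, 5),
                    fc_units=64, max_epochs=10, batch_size=32,
                    learning_rate=0.02, l1=3e-4, val_check_interval=10)
    defaults.update(overrides)
    return ModelConfig(n_tasks=n_tasks, **defaults)


def fit_with_restarts(
    dataset: EncodedDataset,
    base_config: ModelConfig,
    n_restarts: int = 8,
    seed: int = 0,
    criterion: str = "min_val_auc",
) -> "CNNResults":
    """Train several random restarts and keep the best by validation.

    Random initialization occasionally leaves a small network in a poor
    optimum, typically sacrificing one task; restarts are ranked on the
    validation split only.  ``criterion`` is ``"min_val_auc"`` (maximize the
    weakest task's validation AUC, ties broken by validation loss — the
    model must serve every task) or ``"val_loss"``.  Restart i uses
    rng_seed = seed + 997*i.
    """
    best: tuple[tuple, CNNResults] | None = None
    for i in range(n_restarts):
        cfg = _replace(base_config, base_config.context_size)
        cfg.rng_seed = seed + 997 * i
        res = SequenceCNN(dataset, cfg).fit()
        if criterion == "min_val_auc":
            rec = res.evaluate("val")
            key = (-float(np.nanmin(rec.auc)), res.best_val_loss)
        elif criterion == "val_loss":
            key = (res.best_val_loss,)
        else:
            raise ValueError(f"unknown selection criterion {criterion!r}")
        if best is None or key < best[0]:
            best = (key, res)
    assert best is not None
    return best[1]


@dataclass
class EvaluationRecord:
    """Per-task confusion counts, accuracy and AUC on one data split."""

    task_names: list[str]
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    accuracy: np.ndarray
    auc: np.ndarray
    n: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.auc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"task": self.task_names, "TP": self.tp, "TN": self.tn,
             "FP": self.fp, "FN": self.fn,
             "accuracy": self.accuracy, "auc": self.auc}
        )


# ---------------------------------------------------------------------------
# metrics


def confusion_counts(labels: np.ndarray, probs: np.ndarray, cutoff: float = 0.5):
    labels = np.atleast_2d(labels)
    probs = np.atleast_2d(probs)
    if labels.shape != probs.shape:
        raise ValueError("labels and probs shapes differ")
    if labels.size == 0:
        raise ValueError("empty input")
    pred = probs >= cutoff
    pos = labels > 0.5
    tp = (pred & pos).sum(axis=0)
    tn = (~pred & ~pos).sum(axis=0)
    fp = (pred & ~pos).sum(axis=0)
    fn = (~pred & pos).sum(axis=0)
    return tp, tn, fp, fn


def accuracy(labels: np.ndarray, probs: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """Per-task (TP + TN) / (TP + FN + TN + FP)."""
    tp, tn, fp, fn = confusion_counts(labels, probs, cutoff)
    return (tp + tn) / (tp + tn + fp + fn)


def roc_auc(
    labels: np.ndarray, probs: np.ndarray, return_curves: bool = False
):
    """Per-task AUC via the midrank Mann-Whitney statistic.

    Tasks whose evaluated split has a single class get AUC = NaN with a
    warning.  With ``return_curves`` the per-task ROC points
    (fpr, tpr arrays) are returned alongside.
    """
    labels = np.atleast_2d(labels)
    probs = np.atleast_2d(probs)
    aucs = np.empty(labels.shape[1])
    curves = []
    for t in range(labels.shape[1]):
        y, s = labels[:, t] > 0.5, probs[:, t]
        n_pos, n_neg = int(y.sum()), int((~y).sum())
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"task {t}: single-class split, AUC undefined")
            aucs[t] = np.nan
            curves.append((np.array([0.0, 1.0]), np.array([0.0, 1.0]) * np.nan))
            continue
        ranks = rankdata(s)
        aucs[t] = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        if return_curves:
            order = np.argsort(-s, kind="stable")
            ys = y[order].astype(float)
            thr_change = np.r_[np.diff(s[order]) != 0, True]
            tpr = np.r_[0.0, np.cumsum(ys)[thr_change] / n_pos]
            fpr = np.r_[0.0, np.cumsum(1 - ys)[thr_change] / n_neg]
            curves.append((fpr, tpr))
    return (aucs, curves) if return_curves else aucs


# ---------------------------------------------------------------------------
# model


class SequenceCNN:
    """The multi-task CNN, built from an :class:`EncodedDataset`."""

    def __init__(self, dataset: EncodedDataset | None, config: ModelConfig):
        if dataset is not None:
            if config.n_tasks != dataset.n_tasks:
                raise ValueError("config.n_tasks does not match dataset")
            if dataset.X.shape[1] != config.context_size:
                config = _replace(config, dataset.X.shape[1])
        config.flat_length()  # raises if the receptive field does not fit
        self.dataset = dataset
        self.config = config
        self.fitted = False
        self.history: pd.DataFrame | None = None
        self._rng = np.random.default_rng(config.rng_seed)
        self._build()

    # -- construction ------------------------------------------------------

    def _build(self) -> None:
        cfg = self.config
        dtype = np.dtype(cfg.dtype).type
        rng = self._rng
        layers: list[_nn.Layer] = []
        in_ch = 4
        for k, w, p in zip(cfg.conv_filters, cfg.conv_widths, cfg.pool_sizes):
            layers.append(_nn.Conv1D(w, in_ch, k, rng, dtype=dtype))
            layers.append(_nn.ReLU())
            layers.append(_nn.BatchNorm1D(k, dtype=dtype))
            layers.append(_nn.MaxPool1D(p))
            in_ch = k
        layers.append(_nn.Flatten())
        layers.append(_nn.Dense(cfg.flat_length(), cfg.fc_units, rng,
                                activation="sigmoid", dtype=dtype))
        layers.append(_nn.Dense(cfg.fc_units, cfg.n_tasks, rng, dtype=dtype))
        self.layers = layers
        self._fc_index = len(layers) - 2
        self._dtype = dtype

    def architecture(self) -> list[str]:
        """Layer inventory, one line per layer, matching the configuration."""
        cfg = self.config
        lines = []
        for i, (k, w, p) in enumerate(
            zip(cfg.conv_filters, cfg.conv_widths, cfg.pool_sizes), 1
        ):
            lines.append(f"Conv1D(unit={i}, filters={k}, width={w})")
            lines.append("ReLU()")
            lines.append(f"BatchNorm1D(unit={i}, channels={k})")
            lines.append(f"MaxPool1D(unit={i}, pool={p})")
        lines.append("Flatten()")
        lines.append(f"Dense(units={cfg.fc_units}, activation=sigmoid)")
        lines.append(f"Dense(units={cfg.n_tasks}, activation=sigmoid)  # output")
        return lines

    # -- forward passes ----------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool,
                 nullify: dict[int, float] | None = None) -> np.ndarray:
        h = x.astype(self._dtype, copy=False)
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, train)
            if i == 1 and nullify:  # after the first-layer ReLU
                h = h.copy()
                for k, value in nullify.items():
                    if not (0 <= k < self.config.conv_filters[0]):
                        raise KeyError(f"unknown first-layer filter index {k}")
                    h[:, :, k] = value
        return h  # logits

    def conv1_activations(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Post-ReLU, pre-pooling first-layer activation maps (N, P, K)."""
        self._require_fitted()
        outs = []
        for i in range(0, X.shape[0], batch):
            h = self.layers[0].forward(X[i : i + batch].astype(self._dtype), False)
            outs.append(self.layers[1].forward(h, False))
        return np.concatenate(outs, axis=0)

    def predict_from_acts(self, acts: np.ndarray, batch: int = 256,
                          nullify: dict[int, float] | None = None) -> np.ndarray:
        """Probabilities from given first-layer activation maps (eval mode)."""
        self._require_fitted()
        outs = []
        for i in range(0, acts.shape[0], batch):
            h = acts[i : i + batch].astype(self._dtype)
            if nullify:
                h = h.copy()
                for k, value in nullify.items():
                    h[:, :, k] = value
            for layer in self.layers[2:]:
                h = layer.forward(h, False)
            outs.append(_nn.sigmoid(h))
        return np.concatenate(outs, axis=0)

    def predict(self, X: np.ndarray, batch: int = 256,
                nullify: dict[int, float] | None = None) -> np.ndarray:
        """N x n_tasks probabilities in (0, 1); deterministic (running BN stats)."""
        self._require_fitted()
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != self.config.context_size or X.shape[2] != 4:
            raise ValueError(
                f"expected input of shape (N, {self.config.context_size}, 4), "
                f"got {X.shape}"
            )
        outs = []
        for i in range(0, X.shape[0], batch):
            logits = self._forward(X[i : i + batch], train=False, nullify=nullify)
            outs.append(_nn.sigmoid(logits))
        return np.concatenate(outs, axis=0)

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("model is not fitted; call fit() first")

    # -- training ----------------------------------------------------------

    def loss_on(self, X: np.ndarray, Y: np.ndarray, batch: int = 512,
                include_penalty: bool = True) -> float:
        """Mean BCE (+ FC penalty) in eval mode."""
        total, n = 0.0, 0
        for i in range(0, X.shape[0], batch):
            logits = self._forward(X[i : i + batch], train=False)
            loss, _ = _nn.bce_with_logits(logits, Y[i : i + batch].astype(self._dtype))
            total += loss * logits.size
            n += logits.size
        base = total / n
        if include_penalty:
            pen, _ = _nn.l1l2_penalty(
                self.layers[self._fc_index].params["W"], self.config.l1, self.config.l2
            )
            base += pen
        return base

    def fit(self, verbose: bool = False,
            callback: Callable[[dict], None] | None = None) -> "CNNResults":
        """Train with RMSprop + early stopping; returns a results wrapper.

        The best-validation-loss parameter state is restored at the end.
        """
        if self.dataset is None:
            raise ValueError("model was built without a dataset")
        cfg = self.config
        Xtr, Ytr = self.dataset.subset("train")
        Xva, Yva = self.dataset.subset("val")
        if Xtr.shape[0] == 0 or Xva.shape[0] == 0:
            raise ValueError("empty train or validation partition")
        Ytr = Ytr.astype(self._dtype)
        opt = _nn.RMSprop(self.layers, lr=cfg.learning_rate)
        fc = self.layers[self._fc_index]

        best_val = np.inf
        best_state = None
        stale_checks = 0
        rows = []
        stop = False
        self.fitted = True  # enables eval-mode helpers during training
        n_batches_per_epoch = max(1, int(np.ceil(Xtr.shape[0] / cfg.batch_size)))
        interval = cfg.val_check_interval or n_batches_per_epoch
        step = 0

        for epoch in range(cfg.max_epochs):
            perm = self._rng.permutation(Xtr.shape[0])
            epoch_loss, n_seen = 0.0, 0
            for b in range(0, Xtr.shape[0], cfg.batch_size):
                idx = perm[b : b + cfg.batch_size]
                logits = self._forward(Xtr[idx], train=True)
                loss, grad = _nn.bce_with_logits(logits, Ytr[idx])
                pen, pen_grad = _nn.l1l2_penalty(fc.params["W"], cfg.l1, cfg.l2)
                dy = grad
                for layer in reversed(self.layers):
                    dy = layer.backward(dy)
                fc.grads["W"] = fc.grads["W"] + pen_grad
                opt.step()
                epoch_loss += (loss + pen) * len(idx)
                n_seen += len(idx)
                step += 1
                if step % interval == 0:
                    val_loss = self.loss_on(Xva, Yva)
                    if val_loss < best_val:
                        best_val = val_loss
                        best_state = self._snapshot()
                        stale_checks = 0
                    else:
                        stale_checks += 1
                        if stale_checks >= cfg.patience:
                            stop = True
                            break
            val_loss = self.loss_on(Xva, Yva)
            val_probs = self.predict(Xva)
            val_acc = float(np.mean(accuracy(Yva, val_probs)))
            rows.append({"epoch": epoch, "train_loss": epoch_loss / n_seen,
                         "val_loss": val_loss, "val_accuracy": val_acc})
            if verbose:
                print(f"epoch {epoch}: train {rows[-1]['train_loss']:.4f} "
                      f"val {val_loss:.4f} acc {val_acc:.4f}")
            if callback:
                callback(rows[-1])
            if stop:
                break
        if best_state is not None:
            self._restore(best_state)
        self.history = pd.DataFrame(rows)
        return CNNResults(self, self.history, best_val)

    def _snapshot(self):
        state = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, _nn.BatchNorm1D):
                entry["_rm"] = layer.running_mean.copy()
                entry["_rv"] = layer.running_var.copy()
            state.append(entry)
        return state

    def _restore(self, state) -> None:
        for layer, entry in zip(self.layers, state):
            for k in layer.params:
                layer.params[k][...] = entry[k]
            if isinstance(layer, _nn.BatchNorm1D):
                layer.running_mean[...] = entry["_rm"]
                layer.running_var[...] = entry["_rv"]

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump({"config": asdict(self.config), "fitted": self.fitted},
                      fh, indent=1, sort_keys=True)
        for i, entry in enumerate(self._snapshot()):
            for k, v in entry.items():
                np.save(os.path.join(directory, f"layer{i:02d}_{k}.npy"), v)
        if self.history is not None:
            self.history.to_csv(os.path.join(directory, "history.tsv"),
                                sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | os.PathLike,
             dataset: EncodedDataset | None = None) -> "SequenceCNN":
        with open(os.path.join(directory, "config.json")) as fh:
            blob = json.load(fh)
        cfg_d = blob["config"]
        for key in ("conv_filters", "conv_widths", "pool_sizes"):
            cfg_d[key] = tuple(cfg_d[key])
        model = cls(dataset, ModelConfig(**cfg_d))
        state = []
        for i, layer in enumerate(model.layers):
            entry = {}
            for k in list(layer.params) + (
                ["_rm", "_rv"] if isinstance(layer, _nn.BatchNorm1D) else []
            ):
                entry[k] = np.load(os.path.join(directory, f"layer{i:02d}_{k}.npy"))
            state.append(entry)
        model._restore(state)
        model.fitted = blob["fitted"]
        hist = os.path.join(directory, "history.tsv")
        if os.path.exists(hist):
            model.history = pd.read_csv(hist, sep="\t")
        return model


def _replace(cfg: ModelConfig, context_size: int) -> ModelConfig:
    d = asdict(cfg)
    d["context_size"] = context_size
    for key in ("conv_filters", "conv_widths", "pool_sizes"):
        d[key] = tuple(d[key])
    return ModelConfig(**d)


class CNNResults:
    """Fit results: training history, evaluation, and a summary table."""

    def __init__(self, model: SequenceCNN, history: pd.DataFrame,
                 best_val_loss: float):
        self.model = model
        self.history = history
        self.best_val_loss = best_val_loss

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)

    def evaluate(self, split: str = "test") -> EvaluationRecord:
        X, Y = self.model.dataset.subset(split)
        probs = self.model.predict(X)
        tp, tn, fp, fn = confusion_counts(Y, probs)
        acc = accuracy(Y, probs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aucs = roc_auc(Y, probs)
        return EvaluationRecord(list(self.model.dataset.task_names),
                                tp, tn, fp, fn, acc, aucs, X.shape[0])

    def summary(self) -> str:
        rec = self.evaluate("test")
        cfg = self.model.config
        lines = ["Multi-task sequence CNN fit", "=" * 60]
        lines += self.model.architecture()
        lines.append("-" * 60)
        lines.append(f"epochs run: {len(self.history)}   "
                     f"best val loss: {self.best_val_loss:.5f}")
        lines.append(f"l1={cfg.l1:g} l2={cfg.l2:g} lr={cfg.learning_rate:g} "
                     f"batch={cfg.batch_size} seed={cfg.rng_seed}")
        lines.append("-" * 60)
        lines.append(rec.to_frame().to_string(index=False,
                                              float_format=lambda v: f"{v:.4f}"))
        lines.append(f"mean accuracy {rec.mean_accuracy:.4f}   "
                     f"mean AUC {rec.mean_auc:.4f}   (test n={rec.n})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# hyper-parameter search


def trial_grid() -> list[dict]:
    """The default random-search grid: six (L1, L2) rows x overlap fractions."""
    return [
        {"l1": l1, "l2": l2, "patience": 5000, "max_epochs": 20,
         "batch_size": 128, "overlap_fraction": f}
        for l1, l2 in TRIAL_ROWS
        for f in OVERLAP_FRACTIONS
    ]


def random_search(
    dataset: EncodedDataset | Callable[[float], EncodedDataset],
    grid: Sequence[dict] | None = None,
    n_trials: int = 10,
    seed: int = 0,
    base_config: ModelConfig | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Sample hyper-parameter trials without replacement; pick the best.

    ``dataset`` may be a fixed :class:`EncodedDataset` or a callable mapping
    an overlap fraction to a dataset (needed because the overlap threshold
    changes the labels).  The winner is the configuration with the highest
    mean validation accuracy; the full trial table is returned alongside.
    """
    grid = list(grid if grid is not None else trial_grid())
    if n_trials > len(grid):
        warnings.warn(f"n_trials {n_trials} exceeds grid size {len(grid)}; capped")
        n_trials = len(grid)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(grid), size=n_trials, replace=False)
    rows = []
    best: tuple[float, ModelConfig] | None = None
    for trial_i in chosen:
        trial = grid[trial_i]
        ds = dataset(trial.get("overlap_fraction", 0.5)) if callable(dataset) else dataset
        base = base_config or ModelConfig(n_tasks=ds.n_tasks)
        d = asdict(base)
        for key in ("conv_filters", "conv_widths", "pool_sizes"):
            d[key] = tuple(d[key])
        d.update({k: v for k, v in trial.items() if k in d})
        d["n_tasks"] = ds.n_tasks
        cfg = ModelConfig(**d)
        res = SequenceCNN(ds, cfg).fit()
        val_acc = float(res.history["val_accuracy"].iloc[-1])
        rows.append({**trial, "trial_index": int(trial_i),
                     "val_accuracy": val_acc,
                     "best_val_loss": res.best_val_loss})
        if best is None or val_acc > best[0]:
            best = (val_acc, cfg)
    table = pd.DataFrame(rows)
    assert best is not None
    return best[1], table
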