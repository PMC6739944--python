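"""Model interpretation: filter -> PWM extraction, nullification influence,
and pairwise interaction coefficients.

A trained model's first convolutional layer acts as a bank of motif scanners.
Each filter is turned into a position weight matrix by collecting, from the
test sequences, every window whose activation exceeds a threshold
``(alpha_max - alpha_min) * beta`` — alpha_max/alpha_min being the filter's
extreme activations over all positions of all test sequences — and counting
base frequencies; beta is chosen over a grid to maximize information content.

A filter's importance ("influence" or inference score) is measured by
nullification: its activation map is replaced by its scalar mean activation
and the summed squared change in prediction probability over the test set is
recorded, per task.  Cooperation between two filters is quantified by
regressing the joint-nullification change on the two single-nullification
changes and their product; the product coefficient gamma is the interaction
coefficient (positive = cooperative, negative = antagonistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.lib.stride_tricks import sliding_window_view

from .cnn import SequenceCNN
from .pwm import PwmMotif, information_content


@dataclass
class ExtractionConfig:
    beta_grid: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if any(not (0.0 < b < 1.0) for b in self.beta_grid):
            raise ValueError("beta values must lie in (0, 1)")


@dataclass
class InfluenceRecord:
    """Summed squared prediction change after nullifying one filter."""

    filter_index: int
    task: str                      # task name or "all"
    influence: float
    per_task: dict[str, float]
    n_sequences: int
    mean_per_sequence: float


@dataclass
class InteractionRecord:
    """Interaction coefficient gamma for one filter pair on one task."""

    pair: tuple[int, int]
    task: str
    alpha: float
    beta: float
    gamma: float
    p_value: float
    n_sequences: int
    seed: int
    degenerate: bool = False


def first_layer_activations(model: SequenceCNN, sequences: np.ndarray) -> np.ndarray:
    """Post-ReLU, pre-pooling first-layer outputs, shape (N, P, K)."""
    return model.conv1_activations(sequences)


def activation_threshold(alpha_max: float, alpha_min: float, beta: float) -> float:
    """The extraction threshold (alpha_max - alpha_min) * beta."""
    if not (0.0 < beta < 1.0):
        raise ValueError("beta must lie in (0, 1)")
    if alpha_max < alpha_min:
        raise ValueError("alpha_max must be >= alpha_min")
    return (alpha_max - alpha_min) * beta


def extract_pwm(
    model: SequenceCNN,
    filter_k: int,
    test_sequences: np.ndarray,
    config: ExtractionConfig | None = None,
    activations: np.ndarray | None = None,
    name: str | None = None,
    model_id: str = "model",
) -> PwmMotif | None:
    """Build the PWM for one first-layer filter, or None for a dead filter.

    For each beta in the grid, windows activating above the threshold are
    pooled into a base-count matrix (pseudocount added, rows normalized); the
    beta whose PWM has the highest information content wins.  Filters whose
    best PWM has zero information content are discarded (None).
    """
    if test_sequences.shape[0] == 0:
        raise ValueError("empty test set")
    cfg = config or ExtractionConfig()
    acts = (activations if activations is not None
            else model.conv1_activations(test_sequences))[:, :, filter_k]
    a_max, a_min = float(acts.max()), float(acts.min())
    if a_max <= 0.0:
        return None  # dead filter: no window ever activates
    width = model.config.conv_widths[0]
    # windows[n, p] is the width-w one-hot block scored at position p
    windows = sliding_window_view(test_sequences, width, axis=1).transpose(0, 1, 3, 2)

    best: tuple[float, np.ndarray, float, int] | None = None
    for beta in cfg.beta_grid:
        thr = activation_threshold(a_max, a_min, beta)
        mask = acts > thr
        n_sites = int(mask.sum())
        if n_sites == 0:
            continue
        counts = windows[mask].sum(axis=0) + cfg.pseudocount
        freq = counts / counts.sum(axis=1, keepdims=True)
        ic = information_content(freq)
        if best is None or ic > best[0]:
            best = (ic, freq, beta, n_sites)
    if best is None or best[0] <= 0.0:
        return None
    ic, freq, beta, n_sites = best
    return PwmMotif(
        freq_matrix=freq,
        name=name or f"{model_id}_f{filter_k}",
        n_sites=n_sites,
        beta_used=beta,
        source=(model_id, filter_k),
    )


def extract_all_pwms(
    model: SequenceCNN,
    test_sequences: np.ndarray,
    config: ExtractionConfig | None = None,
    model_id: str = "model",
) -> dict[int, PwmMotif]:
    """PWMs for every live, informative first-layer filter."""
    acts = model.conv1_activations(test_sequences)
    out: dict[int, PwmMotif] = {}
    for k in range(model.config.conv_filters[0]):
        pwm = extract_pwm(model, k, test_sequences, config,
                          activations=acts, model_id=model_id)
        if pwm is not None:
            out[k] = pwm
    return out


# ---------------------------------------------------------------------------
# nullification and influence


def nullification_means(
    model: SequenceCNN,
    filter_set: list[int] | tuple[int, ...],
    test_sequences: np.ndarray,
    activations: np.ndarray | None = None,
) -> dict[int, float]:
    """Per-filter scalar mean activation over all positions of all sequences."""
    acts = (activations if activations is not None
            else model.conv1_activations(test_sequences))
    k_max = model.config.conv_filters[0]
    out = {}
    for k in filter_set:
        if not (0 <= k < k_max):
            raise KeyError(f"unknown first-layer filter index {k}")
        out[k] = float(acts[:, :, k].mean())
    return out


class NullifiedModel:
    """A read-only view of a model with a set of first-layer filters nullified.

    Each named filter's activation map is pinned to its mean activation over
    the reference sequences; the underlying model is untouched.
    """

    def __init__(self, model: SequenceCNN, filter_set, test_sequences: np.ndarray,
                 activations: np.ndarray | None = None):
        self.model = model
        self.values = nullification_means(model, list(filter_set),
                                          test_sequences, activations)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.values:
            return self.model.predict(X)
        return self.model.predict(X, nullify=self.values)


def nullify(model: SequenceCNN, filter_set, test_sequences: np.ndarray,
            activations: np.ndarray | None = None) -> NullifiedModel:
    return NullifiedModel(model, filter_set, test_sequences, activations)


def influence(
    model: SequenceCNN,
    filter_k: int,
    test_sequences: np.ndarray,
    task: str | int = "all",
    task_names: list[str] | None = None,
    activations: np.ndarray | None = None,
    p_pre: np.ndarray | None = None,
) -> InfluenceRecord:
    """Influence of one filter: sum over test sequences of the squared change
    in prediction probability after nullification; per task, with "all" the
    across-task sum (the scalar motif score)."""
    if test_sequences.shape[0] == 0:
        raise ValueError("empty test set")
    names = task_names or (model.dataset.task_names if model.dataset is not None
                           else [str(t) for t in range(model.config.n_tasks)])
    acts = (activations if activations is not None
            else model.conv1_activations(test_sequences))
    if p_pre is None:
        p_pre = model.predict_from_acts(acts)
    values = nullification_means(model, [filter_k], test_sequences, acts)
    p_aft = model.predict_from_acts(acts, nullify=values)
    sq = (p_pre - p_aft) ** 2
    per_task = {name: float(sq[:, t].sum()) for t, name in enumerate(names)}
    if task == "all":
        score = float(sq.sum())
    else:
        t = names.index(task) if isinstance(task, str) else int(task)
        score = float(sq[:, t].sum())
    return InfluenceRecord(
        filter_index=filter_k,
        task=task if isinstance(task, str) else names[task],
        influence=score,
        per_task=per_task,
        n_sequences=test_sequences.shape[0],
        mean_per_sequence=score / test_sequences.shape[0],
    )


def influence_table(
    model: SequenceCNN,
    filters: list[int],
    test_sequences: np.ndarray,
) -> list[InfluenceRecord]:
    """Influence records (task="all") for many filters, sharing one forward pass."""
    acts = model.conv1_activations(test_sequences)
    p_pre = model.predict_from_acts(acts)
    return [
        influence(model, k, test_sequences, "all", activations=acts, p_pre=p_pre)
        for k in filters
    ]


def influence_heatmap_table(
    model: SequenceCNN,
    motifs: dict[int, PwmMotif],
    test_sequences: np.ndarray,
    top_n: int = 100,
) -> pd.DataFrame:
    """Motif x task influence table, rows ranked by max per-task influence."""
    names = (model.dataset.task_names if model.dataset is not None
             else [str(t) for t in range(model.config.n_tasks)])
    records = influence_table(model, sorted(motifs), test_sequences)
    rows = []
    for rec in records:
        row = {"motif": motifs[rec.filter_index].name,
               "filter": rec.filter_index, **rec.per_task}
        rows.append(row)
    tab = pd.DataFrame(rows)
    if tab.empty:
        return tab
    tab["_max"] = tab[names].max(axis=1)
    tab = tab.sort_values(["_max", "filter"], ascending=[False, True],
                          kind="stable").drop(columns="_max")
    return tab.head(top_n).reset_index(drop=True)


def top_motifs(records: list[InfluenceRecord], k: int = 50) -> list[InfluenceRecord]:
    """Top-k records by influence, descending; ties broken by filter index."""
    ranked = sorted(records, key=lambda r: (-r.influence, r.filter_index))
    return ranked[:k]


# ---------------------------------------------------------------------------
# interactions


def interaction(
    model: SequenceCNN,
    filter_i: int | Sequence[int],
    filter_j: int | Sequence[int],
    task: str | int,
    test_sequences: np.ndarray,
    n_sequences: int = 2000,
    seed: int = 0,
    activations: np.ndarray | None = None,
) -> InteractionRecord:
    """Interaction coefficient gamma for a motif pair on one task.

    Each side may be a single first-layer filter or a set of filters (a
    learned motif is often carried redundantly by several filters; nullifying
    the whole set removes the motif's information, nullifying one member
    leaves its duplicates active and dilutes the measured interaction).
    For each sampled sequence x the per-sequence squared change in the task's
    prediction probability is computed under single (dPi, dPj) and joint
    (dPij) nullification; the no-intercept regression
    ``dPij = alpha*dPi + beta*dPj + gamma*(dPi*dPj)`` is fitted by least
    squares and gamma is reported with its two-sided p-value.
    """
    set_i = [filter_i] if isinstance(filter_i, (int, np.integer)) else sorted(filter_i)
    set_j = [filter_j] if isinstance(filter_j, (int, np.integer)) else sorted(filter_j)
    if not set_i or not set_j or set(set_i) & set(set_j):
        raise ValueError("filter sets must be non-empty and disjoint")
    if n_sequences < 10:
        raise ValueError("n_sequences must be >= 10")
    names = (model.dataset.task_names if model.dataset is not None
             else [str(t) for t in range(model.config.n_tasks)])
    t = names.index(task) if isinstance(task, str) else int(task)

    rng = np.random.default_rng(seed)
    n_avail = test_sequences.shape[0]
    idx = rng.choice(n_avail, size=n_sequences, replace=n_sequences > n_avail)
    acts = (activations if activations is not None
            else model.conv1_activations(test_sequences))
    sub = acts[idx]

    values = nullification_means(model, set_i + set_j, test_sequences, acts)
    v_i = {k: values[k] for k in set_i}
    v_j = {k: values[k] for k in set_j}
    p_pre = model.predict_from_acts(sub)[:, t]
    p_i = model.predict_from_acts(sub, nullify=v_i)[:, t]
    p_j = model.predict_from_acts(sub, nullify=v_j)[:, t]
    p_ij = model.predict_from_acts(sub, nullify=values)[:, t]

    d_i = (p_pre - p_i) ** 2
    d_j = (p_pre - p_j) ** 2
    d_ij = (p_pre - p_ij) ** 2

    pair = (tuple(set_i) if len(set_i) > 1 else set_i[0],
            tuple(set_j) if len(set_j) > 1 else set_j[0])
    X = np.column_stack([d_i, d_j, d_i * d_j]).astype(np.float64)
    degenerate = bool(np.any(np.ptp(X, axis=0) == 0.0))
    if degenerate:
        return InteractionRecord(pair, names[t], np.nan, np.nan, np.nan,
                                 np.nan, n_sequences, seed, degenerate=True)
    fit = sm.OLS(d_ij.astype(np.float64), X).fit()
    a, b, g = fit.params
    return InteractionRecord(
        pair=pair, task=names[t],
        alpha=float(a), beta=float(b), gamma=float(g),
        p_value=float(fit.pvalues[2]),
        n_sequences=n_sequences, seed=seed,
    )


def influence_records_to_frame(records: list[InfluenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"filter": r.filter_index, "task": r.task, "score": r.influence,
          "mean_per_sequence": r.mean_per_sequence, "n": r.n_sequences}
         for r in records]
    )


def interaction_records_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"filter_i": r.pair[0], "filter_j": r.pair[1], "task": r.task,
          "alpha": r.alpha, "beta": r.beta, "gamma": r.gamma,
          "p_value": r.p_value, "n": r.n_sequences, "seed": r.seed,
          "degenerate": r.degenerate}
         for r in records]
    )
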