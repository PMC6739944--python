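"""Genome binning, multi-task labeling and one-hot encoding of training data.

The genome is segmented into fixed 200-bp bins; each bin gets one binary label
per task (mark within a cell for a cell model, cell per mark for a mark
model): 1 when the fraction of the bin covered by that task's merged peaks
reaches the overlap threshold.  Bins positive for no task are discarded.  Each
kept bin is widened to a 1000-bp context centred on the bin midpoint and
one-hot encoded (N as 0.25 in every channel).  Examples are split into
train/validation/test at a 2:1:1 ratio under a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peaks import Interval, TrackSet

BIN_SIZE = 200
CONTEXT_SIZE = 1000

_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_CODE[ord("N")] = 4
_CODE[ord("n")] = 4


@dataclass
class LabeledBin:
    chrom: str
    start: int
    end: int
    labels: np.ndarray          # one bit per task
    context: tuple[int, int]    # context interval on the same chromosome


@dataclass
class EncodedDataset:
    """One-hot contexts X, binary labels Y and the 2:1:1 partition."""

    X: np.ndarray               # N x context x 4
    Y: np.ndarray               # N x n_tasks
    task_names: list[str]
    coords: pd.DataFrame        # chrom, start, end of the 200-bp bins
    partition: np.ndarray       # per-example tag in {train, val, test}
    split_seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_examples(self) -> int:
        return self.X.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.Y.shape[1]

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.partition == split
        return self.X[mask], self.Y[mask]

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        np.save(os.path.join(directory, "X.npy"), self.X)
        np.save(os.path.join(directory, "Y.npy"), self.Y)
        self.coords.assign(partition=self.partition).to_csv(
            os.path.join(directory, "coords.tsv"), sep="\t", index=False
        )
        with open(os.path.join(directory, "meta.json"), "w") as fh:
            json.dump(
                {"task_names": self.task_names, "split_seed": self.split_seed,
                 "meta": self.meta},
                fh, indent=1, sort_keys=True,
            )

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "EncodedDataset":
        X = np.load(os.path.join(directory, "X.npy"))
        Y = np.load(os.path.join(directory, "Y.npy"))
        tab = pd.read_csv(os.path.join(directory, "coords.tsv"), sep="\t")
        with open(os.path.join(directory, "meta.json")) as fh:
            meta = json.load(fh)
        return cls(X, Y, meta["task_names"], tab[["chrom", "start", "end"]],
                   tab["partition"].to_numpy(), meta["split_seed"], meta["meta"])


# ---------------------------------------------------------------------------


def bin_genome(
    chrom_sizes: Mapping[str, int], bin_size: int = BIN_SIZE
) -> list[tuple[str, int, int]]:
    """Consecutive non-overlapping bins per chromosome; trailing partial bin dropped."""
    bins = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"non-positive chromosome size for {chrom}")
        for s in range(0, (length // bin_size) * bin_size, bin_size):
            bins.append((chrom, s, s + bin_size))
    return bins


def label_bins(
    bins: Sequence[tuple[str, int, int]],
    task_intervals: Sequence[Sequence[Interval]],
    task_names: Sequence[str],
    overlap_fraction: float = 0.5,
) -> list[LabeledBin]:
    """Per-task binary labels from peak coverage; all-zero bins are dropped.

    Bit t is set when (covered bases of the bin by task t) / bin_size is at
    least ``overlap_fraction`` (inclusive boundary).
    """
    if not (0.0 < overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must be in (0, 1]")
    # per chromosome, per task: sorted disjoint interval arrays for fast coverage
    per_task: list[dict[str, np.ndarray]] = []
    for ivs in task_intervals:
        d: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in ivs:
            d.setdefault(chrom, []).append((s, e))
        per_task.append({c: np.asarray(sorted(v)) for c, v in d.items()})

    out: list[LabeledBin] = []
    for chrom, start, end in bins:
        size = end - start
        labels = np.zeros(len(task_intervals), dtype=np.int8)
        for t, d in enumerate(per_task):
            arr = d.get(chrom)
            if arr is None or arr.size == 0:
                continue
            lo = np.searchsorted(arr[:, 1], start, side="right")
            covered = 0
            for s, e in arr[lo:]:
                if s >= end:
                    break
                covered += min(e, end) - max(s, start)
            if covered / size >= overlap_fraction:
                labels[t] = 1
        if labels.any():
            out.append(LabeledBin(chrom, start, end, labels, (start, end)))
    return out


def extend_bin(
    bin_interval: tuple[str, int, int],
    chrom_len: int,
    context_size: int = CONTEXT_SIZE,
) -> tuple[int, int] | None:
    """Context of ``context_size`` bp centred on the bin midpoint.

    Returns None (bin dropped) when the context would cross a chromosome end.
    """
    _, start, end = bin_interval
    if context_size < end - start:
        raise ValueError("context_size must be >= bin size")
    mid = (start + end) // 2
    half = context_size // 2
    cs, ce = mid - half, mid - half + context_size
    if cs < 0 or ce > chrom_len:
        return None
    return (cs, ce)


def one_hot(seq: str, dtype=np.float32) -> np.ndarray:
    """L x 4 encoding (columns A, C, G, T); N maps to 0.25 per channel."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = np.nonzero(codes < 0)[0]
    if bad.size:
        raise ValueError(f"invalid base {seq[bad[0]]!r} at position {bad[0]}")
    mat = np.zeros((len(seq), 4), dtype=dtype)
    acgt = codes < 4
    mat[np.nonzero(acgt)[0], codes[acgt]] = 1.0
    mat[~acgt] = 0.25
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in np.asarray(mat).argmax(axis=1))


def split_sizes(n: int, ratios: Sequence[int] = (2, 1, 1)) -> tuple[int, ...]:
    """Largest-remainder apportionment of n examples across the ratio parts."""
    total = sum(ratios)
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:rem]:
        sizes[i] += 1
    return tuple(sizes)


def split_dataset(
    X: np.ndarray,
    Y: np.ndarray,
    coords: pd.DataFrame,
    task_names: Sequence[str],
    ratios: Sequence[int] = (2, 1, 1),
    seed: int = 0,
    holdout_chroms: Sequence[str] | None = None,
    meta: dict | None = None,
) -> EncodedDataset:
    """Assign examples to train/val/test.

    Default: random permutation under ``seed`` with largest-remainder 2:1:1
    sizes.  ``holdout_chroms`` switches to a chromosome-holdout mode where the
    listed chromosomes form the test set and the rest are split train/val by
    the first two ratio parts.
    """
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 examples to split 2:1:1")
    partition = np.empty(n, dtype=object)
    if holdout_chroms is not None:
        is_test = coords["chrom"].isin(holdout_chroms).to_numpy()
        partition[is_test] = "test"
        rest = np.nonzero(~is_test)[0]
        rng = np.random.default_rng(seed)
        perm = rng.permutation(rest)
        n_train, n_val = split_sizes(len(rest), ratios[:2])
        partition[perm[:n_train]] = "train"
        partition[perm[n_train:]] = "val"
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_train, n_val, n_test = split_sizes(n, ratios)
        partition[perm[:n_train]] = "train"
        partition[perm[n_train : n_train + n_val]] = "val"
        partition[perm[n_train + n_val :]] = "test"
    return EncodedDataset(X, Y, list(task_names), coords.reset_index(drop=True),
                          partition.astype(str), seed, meta or {})


def build_dataset(
    genome: Mapping[str, str],
    trackset: TrackSet,
    flavour: str,
    fixed: str,
    overlap_fraction: float = 0.5,
    bin_size: int = BIN_SIZE,
    context_size: int = CONTEXT_SIZE,
    seed: int = 0,
    holdout_chroms: Sequence[str] | None = None,
) -> EncodedDataset:
    """End-to-end dataset construction for one model flavour.

    ``genome`` maps chromosome name to sequence (a pyfaidx.Fasta works).
    ``flavour='cell'`` with ``fixed=<cell>`` yields tasks = marks of that
    cell; ``flavour='mark'`` with ``fixed=<mark>`` yields tasks = cells.
    """
    sizes = {c: len(genome[c]) for c in sorted(trackset_chroms(trackset))}
    task_names = trackset.task_names(flavour, fixed)
    if not task_names:
        raise ValueError(f"no tracks for {flavour}={fixed!r}")
    if flavour == "cell":
        task_ivs = [trackset.tracks[(fixed, m)] for m in task_names]
    else:
        task_ivs = [trackset.tracks[(c, fixed)] for c in task_names]

    bins = bin_genome(sizes, bin_size)
    labeled = label_bins(bins, task_ivs, task_names, overlap_fraction)

    rows, X_rows, Y_rows = [], [], []
    for lb in labeled:
        ctx = extend_bin((lb.chrom, lb.start, lb.end), sizes[lb.chrom], context_size)
        if ctx is None:
            continue
        seq = str(genome[lb.chrom][ctx[0] : ctx[1]])
        X_rows.append(one_hot(seq))
        Y_rows.append(lb.labels)
        rows.append((lb.chrom, lb.start, lb.end))
    if not rows:
        raise ValueError("no labeled bins produced; check peaks and thresholds")
    X = np.stack(X_rows)
    Y = np.stack(Y_rows).astype(np.int8)
    coords = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    meta = {"flavour": flavour, "fixed": fixed, "overlap_fraction": overlap_fraction,
            "bin_size": bin_size, "context_size": context_size}
    return split_dataset(X, Y, coords, task_names, seed=seed,
                         holdout_chroms=holdout_chroms, meta=meta)


def trackset_chroms(trackset: TrackSet) -> set[str]:
    return {c for ivs in trackset.tracks.values() for c, _, _ in ivs}
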