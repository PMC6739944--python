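import numpy as np
import pytest

from epimotif.cnn import ModelConfig, SequenceCNN
from epimotif.dataset import one_hot, split_dataset
from epimotif.pwm import PwmMotif

import pandas as pd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sequences(rng, n, length, probs=(0.25, 0.25, 0.25, 0.25)):
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.choice(4, size=length, p=list(probs))]) for _ in range(n)]


def implant(seq: str, instance: str, pos: int) -> str:
    return seq[:pos] + instance + seq[pos + len(instance):]


def sample_instance(pwm: PwmMotif, rng) -> str:
    bases = "ACGT"
    return "".join(bases[rng.choice(4, p=row)] for row in pwm.freq_matrix)


def sharp_pwm(consensus: str, p: float = 0.9, name: str = "toy") -> PwmMotif:
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    freq = np.full((len(consensus), 4), (1 - p) / 3)
    for i, c in enumerate(consensus):
        freq[i, idx[c]] = p
    return PwmMotif(freq, name=name, n_sites=50)


def toy_motif_dataset(rng, n=240, length=100, consensus="ACGTACGTTT", prevalence=0.9):
    """Single-task planted-motif dataset: label 1 iff the motif was implanted."""
    X_rows, y = [], []
    for _ in range(n):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        label = int(rng.random() < 0.5)
        if label and rng.random() < prevalence:
            pos = int(rng.integers(0, length - len(consensus)))
            seq = implant(seq, consensus, pos)
        X_rows.append(one_hot(seq))
        y.append(label)
    X = np.stack(X_rows)
    Y = np.array(y, dtype=np.int8)[:, None]
    coords = pd.DataFrame({"chrom": ["chrT"] * n, "start": range(0, 200 * n, 200),
                           "end": range(200, 200 * (n + 1), 200)})
    return split_dataset(X, Y, coords, ["task0"], seed=0)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small planted-motif model trained for a few epochs; shared by
    interpretation tests (seconds, deterministic)."""
    rng = np.random.default_rng(77)
    ds = toy_motif_dataset(rng, n=300, length=100)
    cfg = ModelConfig(n_tasks=1, conv_filters=(8, 4, 4), conv_widths=(10, 5, 3),
                      pool_sizes=(2, 2, 2), fc_units=16, batch_size=16,
                      learning_rate=0.02, max_epochs=6, context_size=100,
                      rng_seed=5, val_check_interval=5)
    model = SequenceCNN(ds, cfg)
    model.fit()
    return model
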