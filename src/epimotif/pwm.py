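"""Position weight matrix container shared by the interpretation and motif modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on column indices


@dataclass
class PwmMotif:
    """A DNA motif as per-position base probabilities.

    ``freq_matrix`` is width x 4 with columns A, C, G, T; rows sum to 1.
    ``source`` records provenance: ``(model_id, filter_index)`` for a filter-
    derived motif or a merged-cluster id.
    """

    freq_matrix: np.ndarray
    name: str = ""
    n_sites: int = 0
    beta_used: float | None = None
    source: tuple | str | None = None
    info_content: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.freq_matrix = np.asarray(self.freq_matrix, dtype=float)
        if self.freq_matrix.ndim != 2 or self.freq_matrix.shape[1] != 4:
            raise ValueError("freq_matrix must be width x 4")
        if self.freq_matrix.shape[0] < 1:
            raise ValueError("motif width must be >= 1")
        sums = self.freq_matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("freq_matrix rows must sum to 1")
        # tighten row sums so invariants hold exactly within 1e-9
        self.freq_matrix = self.freq_matrix / sums[:, None]
        if self.info_content is None:
            self.info_content = information_content(self.freq_matrix)

    @property
    def width(self) -> int:
        return self.freq_matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq_matrix.argmax(axis=1))

    def reverse_complement(self) -> "PwmMotif":
        rc = self.freq_matrix[::-1, :][:, _COMPLEMENT]
        return PwmMotif(rc, name=self.name + "_rc", n_sites=self.n_sites,
                        beta_used=self.beta_used, source=self.source)


def information_content(freq_matrix: np.ndarray) -> float:
    """Total information content in bits against a uniform background.

    Per column: ``2 + sum_b p_b log2 p_b`` with ``0 log 0 := 0``; a uniform
    column contributes 0 bits, a single-base column 2 bits.
    """
    p = np.asarray(freq_matrix, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return float(np.sum(2.0 + plogp.sum(axis=1)))
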