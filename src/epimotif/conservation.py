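"""Motif-site scanning against a Markov background and conservation analysis.

Motif occurrences are located FIMO-style: each width-w window is scored
``sum_j log2(p_motif(b_j) / p_bg(b_j))`` against the 0-order marginal of the
background, p-values come from a dynamic program over the distribution of the
discretized score under the background, and sites with p at or below the
threshold are reported on both strands.  A 5th-order Markov model fitted to
the scanned sequences serves as the background generator (and its marginal as
the score background).  Per-base conservation (phastCons-like, values in
[0, 1]) is averaged over each motif's sites, and the Pearson correlation
between motif influence scores and motif conservation is tested against the
null of no correlation with a two-tailed p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .pwm import PwmMotif

_CODE = {c: i for i, c in enumerate("ACGT")}
N_BINS = 1000  # score-discretization resolution for the p-value DP


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int64)
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for i, base in enumerate("ACGT"):
        arr[raw == ord(base)] = i
    return arr


@dataclass
class MarkovBackground:
    """Markov chain over ACGT up to a given order with add-one smoothing.

    ``conditionals[m]`` has shape (4**m, 4): P(next | context of length m).
    Contexts containing ambiguous bases fall back to the highest usable
    lower order at generation/evaluation time.
    """

    order: int
    conditionals: list[np.ndarray]
    training_bases: int

    def marginal(self) -> np.ndarray:
        """0-order base composition."""
        return self.conditionals[0][0]

    def sample(self, length: int, rng: np.random.Generator) -> str:
        probs0 = self.marginal()
        out = np.empty(length, dtype=np.int64)
        for i in range(length):
            m = min(i, self.order)
            if m == 0:
                p = probs0
            else:
                ctx = 0
                for b in out[i - m : i]:
                    ctx = ctx * 4 + int(b)
                p = self.conditionals[m][ctx]
            out[i] = rng.choice(4, p=p)
        return "".join("ACGT"[b] for b in out)


def fit_background(sequences: Sequence[str], order: int = 5) -> MarkovBackground:
    """Maximum-likelihood conditionals with add-one smoothing, all orders 0..order."""
    if not sequences or all(len(s) == 0 for s in sequences):
        raise ValueError("empty input sequences")
    total = sum(len(s) for s in sequences)
    if total <= 4 ** order:
        warnings.warn(
            f"only {total} training bases for order {order} "
            f"(4^{order} = {4 ** order} contexts); estimates will lean on smoothing"
        )
    encoded = [_encode(s) for s in sequences]
    conditionals = []
    for m in range(order + 1):
        counts = np.ones((4 ** m, 4))  # add-one smoothing
        for arr in encoded:
            if len(arr) <= m:
                continue
            valid = np.ones(len(arr) - m, dtype=bool)
            ctx = np.zeros(len(arr) - m, dtype=np.int64)
            for j in range(m):
                part = arr[j : j + len(arr) - m]
                valid &= part < 4
                ctx = ctx * 4 + np.where(part < 4, part, 0)
            nxt = arr[m:]
            valid &= nxt < 4
            np.add.at(counts, (ctx[valid], nxt[valid]), 1)
        conditionals.append(counts / counts.sum(axis=1, keepdims=True))
    return MarkovBackground(order, conditionals, total)


# ---------------------------------------------------------------------------
# scanning


@dataclass
class MotifSite:
    chrom: str
    start: int
    end: int
    strand: str
    score: float        # log2 odds vs 0-order background
    p_value: float
    motif: str


@dataclass
class ScoringModel:
    """Discretized log-odds scorer for one PWM against a 0-order background.

    Per-column scores are mapped to integers on a common scale (N_BINS bins
    over the full score range); the null distribution of the integer total
    under the background is the convolution of the per-column distributions,
    and p-values are its survival function.  Scoring and the DP share the
    same discretization, so a brute-force enumeration over all 4^w words
    reproduces the p-values exactly.
    """

    log_odds: np.ndarray          # w x 4 float scores
    int_scores: np.ndarray        # w x 4 nonnegative integers
    sf: np.ndarray                # survival function over integer totals
    offset: int                   # subtracted minimum, for reporting only

    def p_value(self, int_total: int) -> float:
        return float(self.sf[int_total])


def build_scoring_model(
    pwm: PwmMotif,
    background: MarkovBackground,
    pseudo_frac: float = 0.1,
    n_bins: int = N_BINS,
) -> ScoringModel:
    """Log-odds score matrix + exact null distribution of the discretized score."""
    bg = background.marginal()
    p = (pwm.freq_matrix + pseudo_frac * bg[None, :]) / (1.0 + pseudo_frac)
    log_odds = np.log2(p / bg[None, :])
    col_min = log_odds.min(axis=1)
    col_max = log_odds.max(axis=1)
    span = float((col_max - col_min).sum())
    scale = (n_bins - 1) / span if span > 0 else 1.0
    int_scores = np.rint((log_odds - col_min[:, None]) * scale).astype(np.int64)
    max_total = int(int_scores.max(axis=1).sum())
    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    for j in range(pwm.width):
        col = np.zeros(max_total + 1)
        for b in range(4):
            col[int_scores[j, b]] += bg[b]
        dist = np.convolve(dist, col)[: max_total + 1]
    sf = np.cumsum(dist[::-1])[::-1]
    np.clip(sf, 0.0, 1.0, out=sf)
    return ScoringModel(log_odds, int_scores, sf, offset=0)


def scan(
    pwm: PwmMotif,
    sequences: Mapping[str, str],
    background: MarkovBackground,
    p_threshold: float = 1e-5,
    both_strands: bool = True,
) -> list[MotifSite]:
    """Report motif sites with p <= threshold on both strands.

    ``sequences`` maps a chromosome/sequence name to its string; reported
    coordinates are 0-based half-open within that sequence.  Windows
    containing ambiguous bases are skipped.  Overlapping sites on the two
    strands are both reported.
    """
    if background is None:
        raise ValueError("a fitted background is required")
    w = pwm.width
    model = build_scoring_model(pwm, background)
    strands: list[tuple[str, ScoringModel]] = [("+", model)]
    if both_strands:
        strands.append(("-", build_scoring_model(pwm.reverse_complement(), background)))

    sites: list[MotifSite] = []
    for chrom, seq in sequences.items():
        if len(seq) < w:
            continue
        codes = _encode(seq)
        ok = codes < 4
        win_ok = np.ones(len(seq) - w + 1, dtype=bool)
        for j in range(w):
            win_ok &= ok[j : j + len(win_ok)]
        for strand, sm in strands:
            totals = np.zeros(len(win_ok), dtype=np.int64)
            raw = np.zeros(len(win_ok))
            for j in range(w):
                col = codes[j : j + len(win_ok)]
                safe = np.where(col < 4, col, 0)
                totals += sm.int_scores[j, safe]
                raw += sm.log_odds[j, safe]
            pvals = sm.sf[totals]
            hits = np.nonzero(win_ok & (pvals <= p_threshold))[0]
            for pos in hits:
                sites.append(MotifSite(chrom, int(pos), int(pos) + w, strand,
                                       float(raw[pos]), float(pvals[pos]), pwm.name))
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


# ---------------------------------------------------------------------------
# conservation


@dataclass
class ConservationRecord:
    motif: str
    n_sites: int
    mean_conservation: float      # mean per-base phastCons over all sites
    influence: float = np.nan
    n_skipped: int = 0

    @property
    def defined(self) -> bool:
        return self.n_sites > 0 and np.isfinite(self.mean_conservation)


def site_conservation(
    sites: Sequence[MotifSite],
    track: Mapping[str, np.ndarray],
    influence_by_motif: Mapping[str, float] | None = None,
) -> list[ConservationRecord]:
    """Per-motif mean conservation over binding sites.

    Each site's score is the mean of its per-base track values; the motif
    record averages over sites.  Sites not fully covered by the track are
    skipped and counted.  Motifs with zero usable sites are flagged (excluded
    from correlation by ``defined``).
    """
    per_motif: dict[str, list[float]] = {}
    skipped: dict[str, int] = {}
    for s in sites:
        arr = track.get(s.chrom)
        values = None
        if arr is not None and s.end <= len(arr):
            chunk = arr[s.start : s.end]
            if not np.any(np.isnan(chunk)):
                values = float(np.mean(chunk))
        if values is None:
            skipped[s.motif] = skipped.get(s.motif, 0) + 1
        else:
            per_motif.setdefault(s.motif, []).append(values)
    records = []
    motif_names = sorted(set(per_motif) | set(skipped))
    for name in motif_names:
        vals = per_motif.get(name, [])
        records.append(
            ConservationRecord(
                motif=name,
                n_sites=len(vals),
                mean_conservation=float(np.mean(vals)) if vals else np.nan,
                influence=(influence_by_motif or {}).get(name, np.nan),
                n_skipped=skipped.get(name, 0),
            )
        )
    return records


def influence_conservation_correlation(
    records: Sequence[ConservationRecord],
) -> tuple[float, float]:
    """Pearson r between motif influence and conservation, two-tailed p.

    r = cov(I, C) / sqrt(var(I) var(C)); the p-value uses the exact
    t-distribution transform of r under the non-correlation null.
    """
    usable = [r for r in records if r.defined and np.isfinite(r.influence)]
    if len(usable) < 3:
        raise ValueError("need at least 3 records with defined values")
    I = np.array([r.influence for r in usable])
    C = np.array([r.mean_conservation for r in usable])
    if np.ptp(I) == 0 or np.ptp(C) == 0:
        raise ValueError("zero variance in influence or conservation")
    res = stats.pearsonr(I, C)
    return float(res.statistic), float(res.pvalue)
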