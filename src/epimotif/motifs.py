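"""Motif comparison, bidirectional-best-hit merging and model profile clustering.

Learned motifs from different models are often near-duplicates.  Pairs are
compared by sliding one PWM along the other (both orientations, at least
``min_overlap`` aligned columns) and scoring each offset by the mean per-column
Pearson correlation of the base-frequency vectors; significance comes from a
seed-fixed permutation null (target columns shuffled).  Motifs that are each
other's best hit with E-value < 0.1 are joined by an edge; connected
components of that graph become merged motifs (singletons stay model-specific).
The comparator is a functional substitute for Tomtom: same inputs, same
threshold semantics (E < 0.1 to merge, E <= 0.5 for known-motif annotation),
but a column-correlation score with an empirical permutation null instead of
Tomtom's analytic null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .pwm import PwmMotif


@dataclass
class MotifMatch:
    query: str
    target: str
    offset: int            # target column 0 relative to query column 0
    orientation: str       # "+" or "-"
    overlap: int
    score: float           # mean per-column Pearson correlation at best offset
    p_value: float
    e_value: float


@dataclass
class MotifCluster:
    members: list[str]
    merged: PwmMotif
    is_singleton: bool


# ---------------------------------------------------------------------------
# pairwise comparison


def _normalized_columns(freq: np.ndarray) -> np.ndarray:
    """Center and unit-normalize each row's 4-vector; uniform rows -> zeros."""
    c = freq - freq.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    return np.divide(c, norms, out=np.zeros_like(c), where=norms > 1e-12)


def _offsets(w_q: int, w_t: int, min_overlap: int):
    """All offsets with >= min_overlap aligned columns, with index vectors."""
    for off in range(-(w_t - min_overlap), w_q - min_overlap + 1):
        i0, i1 = max(0, off), min(w_q, off + w_t)
        qi = np.arange(i0, i1)
        yield off, qi, qi - off


def _best_over_offsets(C: np.ndarray, min_overlap: int):
    """Best (score, offset, overlap) scanning all offsets of a w_q x w_t
    column-correlation matrix."""
    best = (-np.inf, 0, 0)
    for off, qi, ti in _offsets(C.shape[0], C.shape[1], min_overlap):
        score = float(C[qi, ti].mean())
        if score > best[0]:
            best = (score, off, len(qi))
    return best


def compare_motifs(
    query: PwmMotif,
    target: PwmMotif,
    min_overlap: int = 7,
    n_permutations: int = 1000,
    seed: int = 0,
    n_targets: int = 1,
) -> MotifMatch:
    """Align two PWMs over all offsets and orientations; permutation p-value.

    The null shuffles the target's columns ``n_permutations`` times (the same
    seed gives the same shuffles) and re-scans all offsets/orientations; the
    p-value is the fraction of shuffles whose best score reaches the observed
    one, with the +1 correction.  E = p * n_targets.
    """
    if query.width < min_overlap or target.width < min_overlap:
        raise ValueError(f"both motifs must be at least {min_overlap} columns wide")
    qn = _normalized_columns(query.freq_matrix)
    mats = {
        "+": _normalized_columns(target.freq_matrix),
        "-": _normalized_columns(target.reverse_complement().freq_matrix),
    }
    C = {o: qn @ m.T for o, m in mats.items()}

    best_score, best_off, best_ov, best_orient = -np.inf, 0, 0, "+"
    for orient in ("+", "-"):
        score, off, ov = _best_over_offsets(C[orient], min_overlap)
        if score > best_score:
            best_score, best_off, best_ov, best_orient = score, off, ov, orient

    if n_permutations == 0:  # alignment-only use (e.g. cluster merging)
        return MotifMatch(query.name, target.name, best_off, best_orient,
                          best_ov, best_score, 1.0, float(n_targets))

    # permutation null: shuffling target columns permutes the columns of C
    rng = np.random.default_rng(seed)
    w_t = target.width
    perms = np.stack([rng.permutation(w_t) for _ in range(n_permutations)])
    pairs = [
        (orient, qi, ti)
        for orient in ("+", "-")
        for _, qi, ti in _offsets(query.width, w_t, min_overlap)
    ]
    null_best = np.full(n_permutations, -np.inf)
    for orient, qi, ti in pairs:
        A = C[orient][qi]                      # (n_pairs, w_t)
        idx = perms[:, ti]                     # (n_perm, n_pairs)
        scores = A[np.arange(len(qi))[None, :], idx].mean(axis=1)
        np.maximum(null_best, scores, out=null_best)
    p = (1.0 + np.sum(null_best >= best_score - 1e-12)) / (n_permutations + 1.0)
    return MotifMatch(query.name, target.name, best_off, best_orient,
                      best_ov, best_score, p, p * n_targets)


# ---------------------------------------------------------------------------
# BBH graph and clustering


def _pairwise_matches(
    motifs: Sequence[PwmMotif],
    min_overlap: int,
    n_permutations: int,
    seed: int,
) -> dict[tuple[int, int], MotifMatch]:
    """One match per unordered pair, query = lower index (keeps best-hit
    ranking symmetric and deterministic)."""
    n = len(motifs)
    out = {}
    for a in range(n):
        for b in range(a + 1, n):
            out[(a, b)] = compare_motifs(
                motifs[a], motifs[b], min_overlap, n_permutations,
                seed=seed, n_targets=n - 1,
            )
    return out


def bbh_graph(
    motifs: Sequence[PwmMotif],
    e_threshold: float = 0.1,
    min_overlap: int = 7,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Edges between bidirectional best hits with E below threshold.

    Each motif's best hit is its minimum-E partner (ties broken by larger
    overlap, then name); an edge requires mutual best hits and E < threshold.
    """
    if len(motifs) < 2:
        raise ValueError("need at least two motifs")
    matches = _pairwise_matches(motifs, min_overlap, n_permutations, seed)

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    best_hit: dict[int, int] = {}
    for a in range(len(motifs)):
        candidates = []
        for b in range(len(motifs)):
            if b == a:
                continue
            m = matches[key(a, b)]
            candidates.append((m.e_value, -m.overlap, motifs[b].name, b))
        candidates.sort()
        best_hit[a] = candidates[0][3]

    edges = []
    for a in range(len(motifs)):
        b = best_hit[a]
        if a < b and best_hit[b] == a and matches[(a, b)].e_value < e_threshold:
            edges.append((motifs[a].name, motifs[b].name))
    return edges


def connected_components(
    edges: Sequence[tuple[str, str]],
    motifs: Sequence[PwmMotif],
    min_overlap: int = 7,
) -> list[MotifCluster]:
    """Partition motifs by graph components; unconnected motifs are singletons."""
    g = nx.Graph()
    g.add_nodes_from(m.name for m in motifs)
    g.add_edges_from(edges)
    by_name = {m.name: m for m in motifs}
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        cluster_motifs = [by_name[name] for name in members]
        merged = merge_cluster_pwm(cluster_motifs, min_overlap=min_overlap)
        clusters.append(MotifCluster(members, merged, len(members) == 1))
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def merge_cluster_pwm(
    cluster_motifs: Sequence[PwmMotif],
    min_overlap: int = 7,
    pseudocount: float = 0.5,
    name: str | None = None,
) -> PwmMotif:
    """Merged PWM by aligned site-count pooling.

    Members are aligned to a reference member (the highest information
    content) at their best pairwise offset/orientation and their site counts
    (frequency x n_sites) are summed column-wise over the union of aligned
    columns, then renormalized with a pseudocount.  This replaces de novo
    re-discovery on the pooled binding sites with a closed-form pooling over
    the same information.
    """
    if len(cluster_motifs) == 0:
        raise ValueError("empty cluster")
    if len(cluster_motifs) == 1:
        m = cluster_motifs[0]
        return PwmMotif(m.freq_matrix.copy(), name=name or m.name,
                        n_sites=m.n_sites, source="merged:" + m.name)
    ref = max(cluster_motifs, key=lambda m: (m.info_content, m.name))
    placed = []  # (offset relative to ref column 0, count_matrix)
    for m in cluster_motifs:
        if m is ref:
            placed.append((0, _counts(m)))
            continue
        match = compare_motifs(ref, m, min_overlap=min_overlap, n_permutations=0)
        fm = m if match.orientation == "+" else m.reverse_complement()
        placed.append((match.offset, _counts(fm)))
    lo = min(off for off, _ in placed)
    hi = max(off + c.shape[0] for off, c in placed)
    counts = np.zeros((hi - lo, 4))
    for off, c in placed:
        counts[off - lo : off - lo + c.shape[0]] += c
    counts += pseudocount
    freq = counts / counts.sum(axis=1, keepdims=True)
    total_sites = sum(m.n_sites for m in cluster_motifs)
    return PwmMotif(freq, name=name or "M-" + ref.name, n_sites=total_sites,
                    source="merged:" + "+".join(sorted(m.name for m in cluster_motifs)))


def _counts(m: PwmMotif) -> np.ndarray:
    n = max(m.n_sites, 1)
    return m.freq_matrix * n


def merge_motifs(
    motifs: Sequence[PwmMotif],
    e_threshold: float = 0.1,
    min_overlap: int = 7,
    n_permutations: int = 1000,
    seed: int = 0,
) -> list[MotifCluster]:
    """BBH graph + connected components in one call."""
    edges = bbh_graph(motifs, e_threshold, min_overlap, n_permutations, seed)
    return connected_components(edges, motifs, min_overlap)


# ---------------------------------------------------------------------------
# known-motif annotation


def match_known(
    motifs: Sequence[PwmMotif],
    known_db: Sequence[PwmMotif],
    e_threshold: float = 0.5,
    min_overlap: int = 7,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotate each motif with its best database match at E <= threshold.

    Unmatched motifs are labelled "novel".  E = p * database size.
    """
    rows = []
    for m in motifs:
        best: MotifMatch | None = None
        for known in known_db:
            if known.width < min_overlap:
                continue
            match = compare_motifs(m, known, min_overlap, n_permutations,
                                   seed=seed, n_targets=max(len(known_db), 1))
            if best is None or (match.e_value, -match.overlap) < (best.e_value, -best.overlap):
                best = match
        if best is not None and best.e_value <= e_threshold:
            rows.append({"motif": m.name, "match": best.target,
                         "e_value": best.e_value, "score": best.score,
                         "orientation": best.orientation, "novel": False})
        else:
            rows.append({"motif": m.name, "match": None,
                         "e_value": np.nan if best is None else best.e_value,
                         "score": np.nan if best is None else best.score,
                         "orientation": None, "novel": True})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model profile clustering


def model_profile_clustering(
    presence: pd.DataFrame,
) -> tuple[np.ndarray, str]:
    """Cluster models by their binary motif-presence profiles.

    ``presence`` is models x unique-motifs with 0/1 entries.  Pairwise
    distances are hamming (fraction of differing motifs); the tree is
    average-linkage (UPGMA), returned as a scipy linkage matrix and a Newick
    string whose branch lengths are merge-height differences.
    """
    if presence.shape[0] < 2:
        raise ValueError("need at least two models to cluster")
    dist = pdist(presence.to_numpy(dtype=float), metric="hamming")
    linkage = hierarchy.average(dist)
    tree = hierarchy.to_tree(linkage)
    labels = list(presence.index.astype(str))

    def newick(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = newick(node.left, node.dist)
        right = newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return linkage, newick(tree, tree.dist) + ";"


def sharing_summary(
    clusters: Sequence[MotifCluster],
    motif_models: Mapping[str, str],
) -> pd.DataFrame:
    """Histogram of unique motifs shared by 1..M models.

    ``motif_models`` maps each original motif name to the model that learned
    it; a cluster counts toward the number of distinct models among its
    members.
    """
    n_models_total = len(set(motif_models.values()))
    counts = {k: 0 for k in range(1, n_models_total + 1)}
    for cluster in clusters:
        shared_by = len({motif_models[m] for m in cluster.members})
        counts[shared_by] = counts.get(shared_by, 0) + 1
    return pd.DataFrame(
        {"n_models": list(counts), "n_motifs": [counts[k] for k in counts]}
    )
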