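"""Peak ingestion, quality filtering, replicate consolidation and merging.

Histone ChIP-seq peak calls arrive as scored intervals per (cell type, mark)
track, usually with >= 2 biological replicates.  This module turns the raw
calls into one clean, sorted, disjoint interval set per track:

1. discard low-confidence peaks (-log10 q below threshold) and overlong peaks,
2. drop any peak touching a genome blacklist region,
3. keep only bases covered by at least two replicates (when >= 2 exist),
4. merge to a minimal disjoint set.

All coordinates are 0-based half-open; touching intervals merge (union
semantics).  Filtering precedes the replicate intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

Interval = tuple[str, int, int]


@dataclass
class Peak:
    """A scored genomic interval for one (cell_type, mark) track."""

    chrom: str
    start: int
    end: int
    neglog10_q: float = 0.0
    track: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")
        if self.neglog10_q < 0:
            raise ValueError("neglog10_q must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start

    def interval(self) -> Interval:
        return (self.chrom, self.start, self.end)


@dataclass
class TrackSet:
    """Mapping track -> sorted disjoint intervals over one genome assembly."""

    tracks: dict[tuple[str, str], list[Interval]] = field(default_factory=dict)
    genome_id: str = ""

    def task_names(self, flavour: str, fixed: str) -> list[str]:
        """Task axis for a model: marks of one cell (``flavour='cell'``) or
        cells for one mark (``flavour='mark'``)."""
        if flavour == "cell":
            return sorted({mark for cell, mark in self.tracks if cell == fixed})
        if flavour == "mark":
            return sorted({cell for cell, mark in self.tracks if mark == fixed})
        raise ValueError("flavour must be 'cell' or 'mark'")


def validate_peaks(peaks: Sequence[Peak]) -> None:
    """Raise naming the offending record index for malformed intervals."""
    for i, p in enumerate(peaks):
        if p.end <= p.start:
            raise ValueError(f"record {i}: malformed interval {p.chrom}:{p.start}-{p.end}")


def filter_peaks(
    peaks: Sequence[Peak],
    min_neglog10_q: float = 2.0,
    max_length: int = 10_000,
) -> list[Peak]:
    """Keep peaks with -log10(q) >= threshold and length <= max_length.

    The boundary is inclusive on both: quality exactly at the threshold and
    length exactly ``max_length`` survive; only strictly longer peaks go.
    Input order is preserved.
    """
    validate_peaks(peaks)
    return [p for p in peaks if p.neglog10_q >= min_neglog10_q and p.length <= max_length]


def merge_intervals(intervals: Iterable[Interval | Peak]) -> list[Interval]:
    """Union of intervals as a minimal sorted disjoint set; touching merge."""
    ivs = sorted(
        (p.interval() if isinstance(p, Peak) else (p[0], int(p[1]), int(p[2])))
        for p in intervals
    )
    out: list[Interval] = []
    for chrom, start, end in ivs:
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


def subtract_blacklist(
    peaks: Sequence[Peak],
    blacklist: Iterable[Interval],
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Peak]:
    """Drop any peak sharing >= 1 bp with a blacklist interval (no trimming)."""
    bl = merge_intervals(blacklist)
    if chrom_sizes is not None:
        unknown = {c for c, _, _ in bl} - set(chrom_sizes)
        if unknown:
            warnings.warn(
                f"blacklist chromosomes absent from genome, ignored: {sorted(unknown)}"
            )
            bl = [iv for iv in bl if iv[0] not in unknown]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in bl:
        by_chrom.setdefault(chrom, []).append((s, e))

    import bisect

    kept: list[Peak] = []
    for p in peaks:
        ivs = by_chrom.get(p.chrom)
        if not ivs:
            kept.append(p)
            continue
        starts = [s for s, _ in ivs]
        i = bisect.bisect_right(starts, p.start) - 1
        hit = (i >= 0 and ivs[i][1] > p.start) or (
            i + 1 < len(ivs) and ivs[i + 1][0] < p.end
        )
        if not hit:
            kept.append(p)
    return kept


def replicate_consensus(replicates: Sequence[Sequence[Peak | Interval]]) -> list[Interval]:
    """Bases supported by >= 2 replicates, as maximal intervals.

    With a single replicate its own merged peaks are returned unchanged
    (the "when possible" rule); with zero replicates this is an error.
    """
    if len(replicates) == 0:
        raise ValueError("replicate_consensus requires at least one replicate")
    merged = [merge_intervals(rep) for rep in replicates]
    if len(merged) == 1:
        return merged[0]
    # boundary sweep over per-replicate coverage counts
    events: dict[str, list[tuple[int, int]]] = {}
    for rep in merged:
        for chrom, s, e in rep:
            events.setdefault(chrom, []).append((s, +1))
            events[chrom].append((e, -1))
    out: list[Interval] = []
    for chrom in sorted(events):
        depth = 0
        open_start = None
        for pos, delta in sorted(events[chrom]):
            new_depth = depth + delta
            if depth < 2 <= new_depth:
                open_start = pos
            elif depth >= 2 > new_depth and open_start is not None:
                if pos > open_start:
                    out.append((chrom, open_start, pos))
                open_start = None
            depth = new_depth
    return merge_intervals(out)


def consolidate_track(
    replicate_peaks: Sequence[Sequence[Peak]],
    blacklist: Iterable[Interval] = (),
    min_neglog10_q: float = 2.0,
    max_length: int = 10_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[Interval]:
    """Full per-track pipeline: filter -> blacklist -> consensus -> merge."""
    cleaned = [
        subtract_blacklist(
            filter_peaks(rep, min_neglog10_q, max_length), blacklist, chrom_sizes
        )
        for rep in replicate_peaks
    ]
    return merge_intervals(replicate_consensus(cleaned))


def coverage_of(intervals: Sequence[Interval], chrom: str, start: int, end: int) -> int:
    """Bases of [start, end) on chrom covered by the (disjoint) intervals."""
    covered = 0
    for c, s, e in intervals:
        if c == chrom and s < end and e > start:
            covered += min(e, end) - max(s, start)
    return covered
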