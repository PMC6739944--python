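"""Seed-reproducible toy epigenomes with planted motif grammars.

The generator emulates the *structure* of a multi-cell-type histone-mark
ChIP-seq study — a small genome, per-(cell, mark) peak tracks with two
replicates, a blacklist, a per-base conservation track — with full ground
truth: every peak's label is caused by motif instances implanted in its
sequence, so motif recovery, influence and interaction estimates can be
checked against the planted grammar.

Default grammar (2 cell types x 3 marks over a 2-Mbp genome, five planted
motifs of widths 8-12):

* mark1 is driven by a cell-specific motif (motif 0 in cell A, motif 4 in
  cell B) — single-motif rule;
* mark2 is driven by motif 1 in both cells — shared-motif rule;
* mark3 requires motifs 2 AND 3 together — cooperative pair rule.

Positive peaks carry their rule's motif(s) with probability
``prevalence_positive``; decoy instances of non-rule motifs appear in peaks
at ``prevalence_negative``, and single members of the AND pair are planted in
non-pair peaks at ``single_partner_rate`` so that models must learn the
conjunction rather than either motif alone.  Instances land on a random
strand.  Peak sets include a fraction of low-quality calls (-log10 q < 2),
a couple of overlong calls and calls inside blacklist regions, all of which
the cleaning pipeline must remove.  Conservation is baseline noise elevated
by ``conservation_effect`` at planted sites.

No read-level simulation: peaks are intervals, not alignments.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .dataset import BIN_SIZE, CONTEXT_SIZE, bin_genome, label_bins
from .peaks import Peak, filter_peaks, merge_intervals
from .pwm import PwmMotif

BASES = "ACGT"


@dataclass
class GrammarSpec:
    """Study conditions for one synthetic epigenome."""

    n_cells: int = 2
    n_marks: int = 3
    chrom_length: int = 500_000
    n_chroms: int = 4
    # every load-bearing motif (the cell-A grammar: 0, 1 single; 2, 3 the AND
    # pair) is >= 12 bp: in a 1000-bp two-strand context (~2000 background
    # windows) narrower motifs cannot be detected reliably by any scanner
    motif_widths: tuple[int, ...] = (12, 13, 12, 13, 10)
    consensus_prob: float = 0.95
    peaks_per_track: int = 240
    peak_length_range: tuple[int, int] = (400, 700)
    prevalence_positive: float = 0.95
    prevalence_negative: float = 0.10
    instances_per_rule_motif: int = 2
    single_partner_rate: float = 0.40
    comark_fraction: float = 0.30
    replicates: int = 2
    jitter_sd: float = 30.0
    replicate_drop: float = 0.05
    low_q_fraction: float = 0.05
    n_overlong: int = 2
    blacklist_length: int = 5_000
    blacklist_decoys_per_track: int = 5
    background_probs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    conservation_effect: float = 0.5
    conservation_baseline: tuple[float, float] = (2.0, 8.0)  # Beta(a, b)

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_marks < 1:
            raise ValueError("need at least one cell type and one mark")
        if not (0 <= self.prevalence_negative < self.prevalence_positive <= 1):
            raise ValueError(
                "need prevalence_negative < prevalence_positive in [0, 1] "
                "for the grammar to be learnable"
            )
        if max(self.motif_widths) >= self.peak_length_range[0]:
            raise ValueError("motifs must be narrower than the shortest peak")

    @property
    def cells(self) -> list[str]:
        return [f"cell{chr(ord('A') + i)}" for i in range(self.n_cells)]

    @property
    def marks(self) -> list[str]:
        return [f"mark{i + 1}" for i in range(self.n_marks)]

    def rules(self) -> dict[tuple[str, str], tuple[int, ...]]:
        """Track -> indices of the motifs its peaks must carry (all of them).

        mark1: cell-specific single motif; mark2: motif 1 shared by all
        cells; mark3: the AND pair (2, 3); further marks cycle over the
        remaining motifs.
        """
        n_motifs = len(self.motif_widths)
        rules: dict[tuple[str, str], tuple[int, ...]] = {}
        for ci, cell in enumerate(self.cells):
            for mi, mark in enumerate(self.marks):
                if mi == 0:
                    rules[(cell, mark)] = ((0 if ci == 0 else 4 % n_motifs),)
                elif mi == 1:
                    rules[(cell, mark)] = (1 % n_motifs,)
                elif mi == 2:
                    rules[(cell, mark)] = (2 % n_motifs, 3 % n_motifs)
                else:
                    rules[(cell, mark)] = ((mi + ci) % n_motifs,)
        return rules

    @property
    def and_pair(self) -> tuple[int, int] | None:
        """Motif indices of the cooperative pair, if the grammar has one."""
        if self.n_marks >= 3 and len(self.motif_widths) >= 4:
            return (2, 3)
        return None


@dataclass
class StudyBundle:
    """File layout of one generated study."""

    root: str
    genome_fasta: str
    chrom_sizes: str
    blacklist: str
    peak_beds: dict[str, dict[int, str]] = field(default_factory=dict)
    conservation: str = ""
    truth_motifs: str = ""
    truth_json: str = ""
    manifest: str = ""

    @classmethod
    def paths(cls, root: str | os.PathLike) -> "StudyBundle":
        root = str(root)
        return cls(
            root=root,
            genome_fasta=os.path.join(root, "genome.fa"),
            chrom_sizes=os.path.join(root, "genome.chrom.sizes"),
            blacklist=os.path.join(root, "blacklist.bed"),
            conservation=os.path.join(root, "conservation.wig"),
            truth_motifs=os.path.join(root, "motifs_truth.meme"),
            truth_json=os.path.join(root, "truth.json"),
            manifest=os.path.join(root, "manifest.json"),
        )

    def track_key(self, cell: str, mark: str) -> str:
        return f"{cell}.{mark}"


def make_planted_motifs(spec: GrammarSpec, rng: np.random.Generator) -> list[PwmMotif]:
    """Sharp PWMs (one dominant base per column) with random consensus."""
    motifs = []
    off = (1.0 - spec.consensus_prob) / 3.0
    for i, width in enumerate(spec.motif_widths):
        consensus = rng.integers(0, 4, size=width)
        freq = np.full((width, 4), off)
        freq[np.arange(width), consensus] = spec.consensus_prob
        motifs.append(PwmMotif(freq, name=f"planted{i}", n_sites=100,
                               source="synthetic"))
    return motifs


def _sample_instance(pwm: PwmMotif, rng: np.random.Generator) -> np.ndarray:
    draws = rng.random(pwm.width)
    cum = np.cumsum(pwm.freq_matrix, axis=1)
    return (draws[:, None] > cum).sum(axis=1)


_RC = np.array([3, 2, 1, 0])


def generate_study(
    spec: GrammarSpec,
    seed: int,
    out_dir: str | os.PathLike,
    motifs: Sequence[PwmMotif] | None = None,
) -> StudyBundle:
    """Write a complete study bundle; identical bytes for identical seeds."""
    rng = np.random.default_rng(seed)
    bundle = StudyBundle.paths(out_dir)
    os.makedirs(bundle.root, exist_ok=True)
    os.makedirs(os.path.join(bundle.root, "peaks"), exist_ok=True)

    motifs = list(motifs) if motifs is not None else make_planted_motifs(spec, rng)
    if len(motifs) < len(spec.motif_widths):
        raise ValueError("grammar needs as many motifs as motif_widths entries")
    if max(m.width for m in motifs) >= spec.peak_length_range[0]:
        raise ValueError("motif wider than the narrowest peak")

    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    sizes = {c: spec.chrom_length for c in chroms}
    genome = {
        c: rng.choice(4, size=spec.chrom_length,
                      p=np.asarray(spec.background_probs)).astype(np.int8)
        for c in chroms
    }

    # blacklist: one region per chromosome, away from the edges
    blacklist = []
    for c in chroms:
        start = int(rng.integers(CONTEXT_SIZE,
                                 spec.chrom_length - spec.blacklist_length - CONTEXT_SIZE))
        blacklist.append((c, start, start + spec.blacklist_length))

    # slot allocation keeps peaks of all tracks disjoint; the inter-slot gap
    # isolates each peak's 1000-bp bin contexts from neighbouring peaks so a
    # negative bin's context cannot pick up another track's planted motif
    slot_len = max(spec.peak_length_range[1] + 100, 800)
    stride = slot_len + CONTEXT_SIZE // 2
    margin = CONTEXT_SIZE
    slots = []
    for c in chroms:
        bl = [iv for iv in blacklist if iv[0] == c]
        for s in range(margin, spec.chrom_length - margin - slot_len, stride):
            if any(s < e and s + slot_len > b for _, b, e in bl):
                continue
            slots.append((c, s))
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    rules = spec.rules()

    # peak "jobs" per cell: single-mark peaks plus co-marked (dual) peaks —
    # chromatin marks co-occur at shared loci in vivo, and without co-marked
    # peaks the multi-task labels are one-hot, letting a model predict any
    # mark from the mere absence of the other marks' motifs
    import itertools as _it

    jobs: list[tuple[str, list[str]]] = []
    for cell in spec.cells:
        marks = spec.marks
        pairs = list(_it.combinations(marks, 2))
        n_pair = (int(round(spec.comark_fraction * spec.peaks_per_track / 2))
                  if len(marks) > 1 else 0)
        n_single = spec.peaks_per_track - n_pair * (len(marks) - 1)
        if n_single < 0:
            raise ValueError("comark_fraction too large for peaks_per_track")
        for m in marks:
            jobs += [(cell, [m])] * n_single
        for pr in pairs:
            jobs += [(cell, list(pr))] * n_pair
    if len(jobs) > len(slots):
        raise ValueError(
            f"genome too small: {len(jobs)} peaks requested but only "
            f"{len(slots)} disjoint slots available"
        )

    truth_sites: list[dict] = []
    truth_peaks: list[dict] = []

    def implant(chrom: str, pos: int, motif_i: int, track_key: str,
                causal: bool) -> None:
        inst = _sample_instance(motifs[motif_i], rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            inst = _RC[inst[::-1]]
        genome[chrom][pos : pos + len(inst)] = inst
        truth_sites.append({"chrom": chrom, "start": int(pos),
                            "end": int(pos + len(inst)),
                            "motif": motifs[motif_i].name, "strand": strand,
                            "track": track_key, "causal": causal})

    and_pair = spec.and_pair
    per_track_peaks: dict[str, list[Peak]] = {
        f"{cell}.{mark}": [] for cell, mark in rules
    }
    for slot_i, (cell, job_marks) in enumerate(jobs):
        chrom, slot_start = slots[slot_i]
        plen = int(rng.integers(*spec.peak_length_range, endpoint=True))
        start = slot_start + int(rng.integers(0, slot_len - plen + 1))
        end = start + plen
        center = (start + end) // 2
        junk = rng.random() < spec.low_q_fraction
        q = float(rng.uniform(0.0, 1.9)) if junk else float(2.0 + rng.exponential(8.0))
        rule_union: list[tuple[int, str]] = []  # (motif index, owning track)
        for m in job_marks:
            rule = rules[(cell, m)]
            reps = spec.instances_per_rule_motif if len(rule) == 1 else 1
            for mi in rule:
                rule_union += [(mi, f"{cell}.{m}")] * reps
        has_rule = False
        if not junk and rng.random() < spec.prevalence_positive:
            has_rule = True
            # rule motifs straddle the centre so every bin's 1000-bp context
            # within the peak contains them; single-motif rules implant a
            # homotypic pair of instances (motif sites cluster in vivo)
            gaps = (np.linspace(-30 * (len(rule_union) - 1) / 2,
                                30 * (len(rule_union) - 1) / 2,
                                num=len(rule_union))
                    if len(rule_union) > 1 else [0.0])
            for g, (mi, owner) in zip(gaps, rule_union):
                w = motifs[mi].width
                pos = int(center + g - w // 2 + rng.integers(-5, 6))
                implant(chrom, pos, mi, owner, causal=True)
        if not junk:
            rule_set = {mi for mi, _ in rule_union}
            covers_pair = and_pair is not None and set(and_pair) <= rule_set
            # decoys: non-rule motifs at background prevalence
            for mi in range(len(motifs)):
                if mi in rule_set:
                    continue
                if and_pair and mi in and_pair and not covers_pair:
                    continue  # handled by single_partner_rate below
                if rng.random() < spec.prevalence_negative:
                    w = motifs[mi].width
                    pos = start + int(rng.integers(0, plen - w))
                    implant(chrom, pos, mi, f"{cell}.{job_marks[0]}",
                            causal=False)
            if and_pair and not covers_pair and rng.random() < spec.single_partner_rate:
                mi = int(and_pair[int(rng.integers(0, 2))])
                w = motifs[mi].width
                pos = start + int(rng.integers(0, plen - w))
                implant(chrom, pos, mi, f"{cell}.{job_marks[0]}", causal=False)
        for m in job_marks:
            track_key = f"{cell}.{m}"
            per_track_peaks[track_key].append(Peak(chrom, start, end, q,
                                                   (cell, m)))
            truth_peaks.append({"track": track_key, "chrom": chrom,
                                "start": start, "end": end, "q": q,
                                "marks": list(job_marks),
                                "has_rule_motifs": has_rule, "junk": junk})

    for cell, mark in rules:
        track_peaks = per_track_peaks[f"{cell}.{mark}"]
        # overlong junk calls (length filter fodder)
        for _ in range(spec.n_overlong):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(margin, spec.chrom_length - margin - 12_000))
            track_peaks.append(Peak(chrom, start, start + 12_000,
                                    float(2.0 + rng.exponential(8.0)), (cell, mark)))
        # blacklist decoys (blacklist filter fodder)
        for _ in range(spec.blacklist_decoys_per_track):
            c, bs, be = blacklist[int(rng.integers(0, len(blacklist)))]
            start = int(rng.integers(bs, be - 600))
            track_peaks.append(Peak(c, start, start + 500,
                                    float(2.0 + rng.exponential(8.0)), (cell, mark)))

    # replicate peak sets: replicate 1 as placed, others jittered with dropout
    bundle.peak_beds = {}
    for track_key, track_peaks in per_track_peaks.items():
        bundle.peak_beds[track_key] = {}
        for rep in range(1, spec.replicates + 1):
            reps: list[Peak] = []
            for p in track_peaks:
                if rep > 1:
                    if rng.random() < spec.replicate_drop:
                        continue
                    ds = int(round(rng.normal(0.0, spec.jitter_sd)))
                    de = int(round(rng.normal(0.0, spec.jitter_sd)))
                    s = max(0, p.start + ds)
                    e = min(spec.chrom_length, p.end + de)
                    if e - s < 50:
                        continue
                    reps.append(Peak(p.chrom, s, e, p.neglog10_q, p.track))
                else:
                    reps.append(p)
            path = os.path.join(bundle.root, "peaks", f"{track_key}.rep{rep}.bed")
            eio.write_bed(reps, path)
            bundle.peak_beds[track_key][rep] = path

    # serialize genome and annotation
    base_str = np.array(list(BASES))
    seqs = {c: "".join(base_str[genome[c]]) for c in chroms}
    eio.write_fasta(seqs, bundle.genome_fasta)
    eio.write_chrom_sizes(sizes, bundle.chrom_sizes)
    eio.write_bed(blacklist, bundle.blacklist)
    eio.write_meme(motifs, bundle.truth_motifs,
                   background=spec.background_probs)

    # conservation: baseline noise, elevated at planted sites
    a, b = spec.conservation_baseline
    track = {c: rng.beta(a, b, size=spec.chrom_length) for c in chroms}
    for s in truth_sites:
        arr = track[s["chrom"]]
        arr[s["start"] : s["end"]] = np.minimum(
            1.0, arr[s["start"] : s["end"]] + spec.conservation_effect
        )
    eio.write_wiggle(track, bundle.conservation)

    truth = {"seed": seed, "sites": truth_sites, "peaks": truth_peaks,
             "rules": {f"{c}.{m}": list(r) for (c, m), r in rules.items()},
             "and_pair": list(and_pair) if and_pair else None,
             "motif_names": [m.name for m in motifs]}
    with open(bundle.truth_json, "w") as fh:
        json.dump(truth, fh, sort_keys=True)

    manifest_files = sorted(
        os.path.relpath(os.path.join(dirpath, f), bundle.root)
        for dirpath, _, files in os.walk(bundle.root)
        for f in files
        if f != "manifest.json"
    )
    manifest = {
        "seed": seed,
        "spec": asdict(spec),
        "files": {f: _sha256(os.path.join(bundle.root, f)) for f in manifest_files},
    }
    with open(bundle.manifest, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return bundle


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def truth_table(bundle: StudyBundle) -> dict[str, pd.DataFrame]:
    """Machine-readable ground truth: planted sites and per-bin labels.

    Bin labels are recomputed from the truth peaks (junk and overlong calls
    excluded, quality filter applied) at the default 0.5 overlap fraction;
    each positive bin lists the planted causal sites falling inside its
    1000-bp context.
    """
    with open(bundle.truth_json) as fh:
        truth = json.load(fh)
    sites = pd.DataFrame(truth["sites"])
    peaks_df = pd.DataFrame(truth["peaks"])
    sizes = eio.read_chrom_sizes(bundle.chrom_sizes)

    tracks = sorted(peaks_df["track"].unique())
    task_intervals = []
    for tk in tracks:
        sub = peaks_df[(peaks_df["track"] == tk) & (~peaks_df["junk"])]
        good = filter_peaks(
            [Peak(r.chrom, r.start, r.end, r.q) for r in sub.itertuples()]
        )
        task_intervals.append(merge_intervals(good))
    bins = bin_genome(sizes, BIN_SIZE)
    labeled = label_bins(bins, task_intervals, tracks, overlap_fraction=0.5)

    causal = sites[sites["causal"]]
    rows = []
    for lb in labeled:
        mid = (lb.start + lb.end) // 2
        ctx_s, ctx_e = mid - CONTEXT_SIZE // 2, mid + CONTEXT_SIZE // 2
        inside = causal[(causal["chrom"] == lb.chrom)
                        & (causal["start"] >= ctx_s) & (causal["end"] <= ctx_e)]
        row = {"chrom": lb.chrom, "start": lb.start, "end": lb.end,
               "context_sites": ";".join(sorted(set(inside["motif"])))}
        for t, tk in enumerate(tracks):
            row[tk] = int(lb.labels[t])
        rows.append(row)
    return {"sites": sites, "bins": pd.DataFrame(rows), "tracks": tracks}
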