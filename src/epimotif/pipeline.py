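"""End-to-end convenience layer: study bundle -> cleaned tracks -> dataset ->
trained model -> interpretation, as library calls.

This is what the command-line stages and the reproduction script share; each
step is a thin composition of the per-module functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import io as eio
from .cnn import (CNNResults, ModelConfig, SequenceCNN, fit_with_restarts,
                  reduced_config)
from .dataset import EncodedDataset, build_dataset
from .interpret import extract_all_pwms, influence_table
from .motifs import compare_motifs
from .peaks import TrackSet, consolidate_track
from .pwm import PwmMotif
from .synthetic import StudyBundle


def load_trackset(
    bundle: StudyBundle,
    min_neglog10_q: float = 2.0,
    max_peak_length: int = 10_000,
) -> TrackSet:
    """Read, filter, blacklist-subtract and replicate-consolidate all tracks."""
    blacklist = [p.interval() for p in eio.read_bed(bundle.blacklist)]
    sizes = eio.read_chrom_sizes(bundle.chrom_sizes)
    trackset = TrackSet(genome_id="synthetic")
    for track, reps in bundle.peak_beds.items():
        cell, mark = track.split(".")
        replicate_peaks = [eio.read_bed(reps[r]) for r in sorted(reps)]
        trackset.tracks[(cell, mark)] = consolidate_track(
            replicate_peaks, blacklist, min_neglog10_q, max_peak_length, sizes
        )
    return trackset


def prepare_dataset(
    bundle: StudyBundle,
    flavour: str = "cell",
    fixed: str = "cellA",
    overlap_fraction: float = 0.5,
    seed: int = 0,
) -> EncodedDataset:
    genome = eio.read_fasta(bundle.genome_fasta)
    trackset = load_trackset(bundle)
    return build_dataset(genome, trackset, flavour, fixed,
                         overlap_fraction=overlap_fraction, seed=seed)


def train_model(
    dataset: EncodedDataset,
    config: ModelConfig | None = None,
    n_restarts: int = 8,
    seed: int = 0,
) -> CNNResults:
    """Fit the reduced desk-scale CNN with restart selection on validation."""
    cfg = config or reduced_config(dataset.n_tasks)
    return fit_with_restarts(dataset, cfg, n_restarts=n_restarts, seed=seed)


@dataclass
class MotifRecovery:
    """Extracted filter motifs matched against a reference motif set."""

    pwms: dict[int, PwmMotif]
    matches: dict[str, list[int]] = field(default_factory=dict)  # ref -> filters
    best_e: dict[int, float] = field(default_factory=dict)       # filter -> min E

    def matched_filters(self) -> set[int]:
        return {k for v in self.matches.values() for k in v}

    def unmatched_filters(self, e_annotation: float = 0.5) -> list[int]:
        """Filters whose best E against every reference exceeds the
        annotation threshold (clear non-matches)."""
        return sorted(k for k in self.pwms if self.best_e.get(k, np.inf) > e_annotation)


def match_filters_to_reference(
    model: SequenceCNN,
    test_X: np.ndarray,
    reference: Mapping[str, PwmMotif],
    e_match: float = 0.1,
    n_permutations: int = 1000,
    model_id: str = "model",
) -> MotifRecovery:
    """Extract all filter PWMs and compare each against the reference motifs."""
    pwms = extract_all_pwms(model, test_X, model_id=model_id)
    rec = MotifRecovery(pwms)
    for k, pwm in pwms.items():
        best = np.inf
        for name, ref in reference.items():
            m = compare_motifs(pwm, ref, n_permutations=n_permutations,
                               n_targets=len(reference))
            best = min(best, m.e_value)
            if m.e_value < e_match:
                rec.matches.setdefault(name, []).append(k)
        rec.best_e[k] = float(best)
    return rec


def influence_by_filter_and_task(
    model: SequenceCNN, test_X: np.ndarray
) -> dict[str, dict[int, float]]:
    """task -> filter -> summed squared prediction change (one pass)."""
    names = model.dataset.task_names
    recs = influence_table(model, list(range(model.config.conv_filters[0])), test_X)
    return {t: {r.filter_index: r.per_task[t] for r in recs} for t in names}
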