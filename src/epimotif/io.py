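"""Readers and writers for the plain-text genomics formats the pipeline consumes.

Coordinates are 0-based half-open internally (BED native).  Wiggle input may be
fixedStep, variableStep or bedGraph; wiggle positions are converted from their
native 1-based convention at the boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np

from .peaks import Peak
from .pwm import PwmMotif

# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``<chrom>\\t<length>`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, length = line.split()[:2]
            sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(
    path: str | os.PathLike,
    q_col: int = 8,
    track: tuple[str, str] | None = None,
) -> list[Peak]:
    """Read a BED-like peak file into :class:`~epimotif.peaks.Peak` records.

    Parameters
    ----------
    q_col
        0-based column index of the -log10(q-value) field.  Defaults to 8,
        the ninth column, where narrowPeak/broadPeak carry it.  Files with
        fewer columns get ``neglog10_q = 0``.
    track
        Optional ``(cell_type, mark)`` identifier attached to every record.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: record {i}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(
                    f"{path}: record {i}: malformed interval {chrom}:{start}-{end}"
                )
            q = float(fields[q_col]) if len(fields) > q_col else 0.0
            peaks.append(Peak(chrom, start, end, q, track))
    return peaks


def write_bed(
    intervals: Iterable,
    path: str | os.PathLike,
    extra_cols: Sequence[Sequence] | None = None,
) -> None:
    """Write sorted BED.  ``intervals`` are Peaks or (chrom, start, end) tuples."""
    rows = []
    for i, iv in enumerate(intervals):
        if isinstance(iv, Peak):
            row = [iv.chrom, iv.start, iv.end, f"peak{i}", 0, ".", 0.0, -1, iv.neglog10_q]
        else:
            row = list(iv[:3])
        if extra_cols is not None:
            row += list(extra_cols[i])
        rows.append(row)
    rows.sort(key=lambda r: (r[0], int(r[1]), int(r[2])))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Plain eager FASTA reader (toy scale; use pyfaidx for random access)."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# MEME minimal motif format

_MEME_HEADER = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A {a:.6f} C {c:.6f} G {g:.6f} T {t:.6f}
"""


def write_meme(
    motifs: Sequence[PwmMotif],
    path: str | os.PathLike,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    bg = np.asarray(background, dtype=float)
    with open(path, "w") as fh:
        fh.write(_MEME_HEADER.format(a=bg[0], c=bg[1], g=bg[2], t=bg[3]))
        for m in motifs:
            fh.write(f"\nMOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {m.n_sites} E= 0\n"
            )
            for row in m.freq_matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")


def read_meme(path: str | os.PathLike) -> list[PwmMotif]:
    motifs: list[PwmMotif] = []
    name = None
    rows: list[list[float]] = []
    n_sites = 0
    expect = 0

    def flush():
        if name is not None and rows:
            freq = np.asarray(rows, dtype=float)
            freq /= freq.sum(axis=1, keepdims=True)
            motifs.append(PwmMotif(freq_matrix=freq, name=name, n_sites=n_sites))

    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("MOTIF"):
                flush()
                parts = stripped.split()
                name = parts[1] if len(parts) > 1 else f"motif{len(motifs)}"
                rows, n_sites, expect = [], 0, 0
            elif stripped.startswith("letter-probability matrix"):
                tokens = stripped.replace("=", " = ").split()
                kv = {tokens[i]: tokens[i + 2] for i in range(len(tokens) - 2) if tokens[i + 1] == "="}
                n_sites = int(float(kv.get("nsites", 0)))
                expect = int(kv.get("w", 0))
            elif name is not None and stripped and (expect == 0 or len(rows) < expect):
                try:
                    vals = [float(x) for x in stripped.split()]
                except ValueError:
                    continue
                if len(vals) == 4:
                    rows.append(vals)
    flush()
    return motifs


# ---------------------------------------------------------------------------
# wiggle / bedGraph conservation tracks


def write_wiggle(
    track: Mapping[str, np.ndarray],
    path: str | os.PathLike,
    decimals: int = 3,
) -> None:
    """Write per-base scores as fixedStep (step=1 span=1) wiggle."""
    with open(path, "w") as fh:
        for chrom, values in track.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fmt = f"%.{decimals}f"
            fh.write("\n".join(fmt % v for v in np.asarray(values)))
            fh.write("\n")


def read_wiggle(
    path: str | os.PathLike,
    chrom_sizes: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Read fixedStep/variableStep wiggle or bedGraph into per-base arrays.

    Positions without a value are NaN.  If ``chrom_sizes`` is omitted array
    lengths equal the last covered position per chromosome.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    mode = None  # ("fixed", chrom, next_pos0, step, span) | ("var", chrom, span)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode = ["fixed", kv["chrom"], int(kv["start"]) - 1,
                        int(kv.get("step", 1)), int(kv.get("span", 1))]
            elif line.startswith("variableStep"):
                kv = dict(tok.split("=") for tok in line.split()[1:])
                mode = ["var", kv["chrom"], int(kv.get("span", 1))]
            else:
                fields = line.split()
                if len(fields) == 4:  # bedGraph
                    chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                    per_chrom.setdefault(chrom, []).append((s, e, v))
                elif mode is not None and mode[0] == "fixed":
                    _, chrom, pos, step, span = mode
                    per_chrom.setdefault(chrom, []).append((pos, pos + span, float(fields[0])))
                    mode[2] = pos + step
                elif mode is not None and mode[0] == "var":
                    _, chrom, span = mode
                    pos = int(fields[0]) - 1
                    per_chrom.setdefault(chrom, []).append((pos, pos + span, float(fields[1])))
                else:
                    raise ValueError(f"{path}: data line outside any wiggle block: {line!r}")
    out: dict[str, np.ndarray] = {}
    for chrom, spans in per_chrom.items():
        length = (chrom_sizes or {}).get(chrom, max(e for _, e, _ in spans))
        arr = np.full(length, np.nan)
        for s, e, v in spans:
            arr[s : min(e, length)] = v
        out[chrom] = arr
    return out
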