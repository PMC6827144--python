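"""Sliding-window genome scanning and occupancy tracks.

A trained classifier is slid across each genome record in windows of
the model length (147 or 150 bp).  Every window receives the SVM's
continuous decision score, and each base's occupancy is the mean score
of all windows overlapping it; bases covered by no valid window (ends,
or regions whose every window contains an ambiguous base) carry NaN.
Tracks are written as fixedStep wiggle (1-based) or bedGraph (0-based
half-open) and can be compared to reference occupancy maps by Pearson
correlation over the jointly covered bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator, Sequence, Union

import numpy as np
from scipy import stats

from zcmm.seqio import ACGT, DnaSequence, SequenceSet

logger = logging.getLogger(__name__)


class OccupancyError(ValueError):
    pass


@dataclass(frozen=True)
class Window:
    """One sliding window: 1-based inclusive coordinates on its record."""

    chrom: str
    start: int
    end: int
    bases: str


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-base occupancy over one record; NaN marks uncovered bases."""

    chrom: str
    start: int              # 1-based inclusive coordinate of scores[0]
    scores: np.ndarray
    window: int
    step: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))

    @property
    def end(self) -> int:
        return self.start + len(self.scores) - 1

    def covered_mask(self) -> np.ndarray:
        return np.isfinite(self.scores)


def sliding_windows(
    record: DnaSequence, window: int, step: int = 1
) -> Iterator[Window]:
    """Yield windows of ``window`` bp every ``step`` bp along a record.

    Windows containing non-ACGT bases are skipped (logged once per gap
    run).  On a gap-free record exactly floor((L - W)/step) + 1 windows
    are produced.
    """
    L = len(record)
    if window > L:
        raise OccupancyError(
            f"window ({window} bp) exceeds record {record.id!r} length ({L} bp)"
        )
    if step < 1:
        raise OccupancyError("step must be >= 1")
    in_gap = False
    for start0 in range(0, L - window + 1, step):
        chunk = record.bases[start0 : start0 + window]
        if set(chunk) <= ACGT:
            in_gap = False
            yield Window(record.id, start0 + 1, start0 + window, chunk)
        else:
            if not in_gap:
                logger.info(
                    "skipping windows with ambiguous bases on %r near position %d",
                    record.id,
                    start0 + 1,
                )
            in_gap = True


def count_windows(length: int, window: int, step: int = 1) -> int:
    """Closed-form window count for a gap-free record."""
    if window > length:
        raise OccupancyError("window exceeds record length")
    return (length - window) // step + 1


def occupancy_profile(
    genome: Union[SequenceSet, Sequence[DnaSequence]],
    scorer,
    window: int,
    step: int = 1,
    batch_size: int = 2048,
) -> list[OccupancyProfile]:
    """Score every sliding window and average scores per base.

    ``scorer`` is either a fitted :class:`~zcmm.classify.ZcmmClassifier`
    (its model length must equal ``window``) or any callable mapping a
    list of :class:`DnaSequence` windows to a score vector.
    """
    if hasattr(scorer, "decision_scores"):
        if getattr(scorer, "N", window) != window:
            raise OccupancyError(
                f"classifier model length {scorer.N} != window {window}"
            )
        score_fn: Callable = lambda seqs: scorer.decision_scores(seqs)
    elif callable(scorer):
        score_fn = scorer
    else:
        raise OccupancyError("scorer must be a classifier or a callable")

    profiles = []
    for record in genome:
        L = len(record)
        total = np.zeros(L, dtype=float)
        cover = np.zeros(L, dtype=np.int64)
        batch: list[Window] = []

        def flush(batch: list[Window]) -> None:
            if not batch:
                return
            seqs = [DnaSequence(f"{w.chrom}:{w.start}-{w.end}", w.bases) for w in batch]
            scores = np.asarray(score_fn(seqs), dtype=float)
            for w, sc in zip(batch, scores):
                total[w.start - 1 : w.end] += sc
                cover[w.start - 1 : w.end] += 1

        for w in sliding_windows(record, window, step):
            batch.append(w)
            if len(batch) >= batch_size:
                flush(batch)
                batch = []
        flush(batch)
        with np.errstate(invalid="ignore"):
            per_base = np.where(cover > 0, total / np.maximum(cover, 1), np.nan)
        profiles.append(
            OccupancyProfile(
                chrom=record.id, start=1, scores=per_base, window=window, step=step
            )
        )
    return profiles


def profile_correlation(a: OccupancyProfile, b: OccupancyProfile) -> float:
    """Pearson correlation over the intersection of covered bases."""
    if a.chrom != b.chrom:
        raise OccupancyError("profiles are on different records")
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    if hi < lo:
        raise OccupancyError("profiles do not overlap")
    va = a.scores[lo - a.start : hi - a.start + 1]
    vb = b.scores[lo - b.start : hi - b.start + 1]
    mask = np.isfinite(va) & np.isfinite(vb)
    if mask.sum() < 3:
        raise OccupancyError("fewer than 3 jointly covered bases")
    va, vb = va[mask], vb[mask]
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise OccupancyError("zero variance in one track; correlation undefined")
    return float(stats.pearsonr(va, vb).statistic)


# ---------------------------------------------------------------------------
# track writers/readers (round-trip exact on coordinates and repr-floats)


def _covered_runs(profile: OccupancyProfile) -> Iterator[tuple[int, np.ndarray]]:
    """Yield (1-based start, values) for each maximal covered run."""
    mask = profile.covered_mask()
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            yield profile.start + i, profile.scores[i:j]
            i = j
        else:
            i += 1


def write_wiggle(
    profiles: Sequence[OccupancyProfile], path: Union[str, Path]
) -> None:
    """fixedStep wiggle output (1-based starts, span 1)."""
    with open(path, "w") as fh:
        fh.write('track type=wiggle_0 name="zcmm_occupancy"\n')
        for p in profiles:
            for start, values in _covered_runs(p):
                fh.write(f"fixedStep chrom={p.chrom} start={start} step=1 span=1\n")
                for v in values:
                    fh.write(repr(float(v)) + "\n")


def read_wiggle(path: Union[str, Path]) -> list[OccupancyProfile]:
    """Read fixedStep wiggle written by :func:`write_wiggle`.

    Each record's runs are merged back onto one NaN-padded track
    starting at position 1.
    """
    runs: dict[str, list[tuple[int, list[float]]]] = {}
    chrom = None
    start = step = None
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                if chrom is not None and values:
                    runs.setdefault(chrom, []).append((start, values))
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom, start, step = fields["chrom"], int(fields["start"]), int(fields["step"])
                if step != 1:
                    raise OccupancyError("only step=1 wiggle is supported")
                values = []
            else:
                values.append(float(line))
    if chrom is not None and values:
        runs.setdefault(chrom, []).append((start, values))
    return _runs_to_profiles(runs)


def write_bedgraph(
    profiles: Sequence[OccupancyProfile], path: Union[str, Path]
) -> None:
    """bedGraph output (0-based half-open intervals, one per base)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="zcmm_occupancy"\n')
        for p in profiles:
            for start, values in _covered_runs(p):
                for k, v in enumerate(values):
                    pos1 = start + k  # 1-based
                    fh.write(f"{p.chrom}\t{pos1 - 1}\t{pos1}\t{float(v)!r}\n")


def read_bedgraph(path: Union[str, Path]) -> list[OccupancyProfile]:
    runs: dict[str, list[tuple[int, list[float]]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            chrom, s0, e0, v = line.split("\t")
            s0, e0 = int(s0), int(e0)
            for pos1 in range(s0 + 1, e0 + 1):
                lst = runs.setdefault(chrom, [])
                if lst and lst[-1][0] + len(lst[-1][1]) == pos1:
                    lst[-1][1].append(float(v))
                else:
                    lst.append((pos1, [float(v)]))
    return _runs_to_profiles(runs)


def _runs_to_profiles(
    runs: dict[str, list[tuple[int, list[float]]]]
) -> list[OccupancyProfile]:
    profiles = []
    for chrom, segs in runs.items():
        end = max(s + len(v) - 1 for s, v in segs)
        scores = np.full(end, np.nan)
        for s, v in segs:
            scores[s - 1 : s - 1 + len(v)] = v
        profiles.append(
            OccupancyProfile(chrom=chrom, start=1, scores=scores, window=0, step=1)
        )
    return profiles
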