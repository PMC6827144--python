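"""Synthetic nucleosome/linker datasets and toy genomes.

The generator emulates the two signals the models are built to detect:
a base-composition difference between classes (nucleosomal DNA is
drawn GC-rich, linker DNA GC-poor) and the canonical ~10-bp phased A/T
dinucleotide preference of nucleosome-forming sequences, modeled as a
probability boost of A/T at every 10th position of the positive class.
Negatives are i.i.d. at their own GC content.  A toy genome embeds
positive-class sequences between random spacers and reports the
planted intervals, giving ground truth for the occupancy profiler.

All randomness flows from the single seed in :class:`GeneratorSpec`;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from zcmm.seqio import DnaSequence, Label, SequenceSet

_BASES = np.array(list("ACGT"))


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the two-class sequence generator.

    Defaults define the "strong" condition: a 20-point GC gap between
    classes plus a phased A/T boost of 0.5 — comfortably learnable, the
    regime the end-to-end pipeline is calibrated on.
    """

    n_per_class: int = 500
    length: int = 147
    gc_pos: float = 0.60
    gc_neg: float = 0.40
    periodic_strength: float = 0.5
    period: int = 10
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.length < 1:
            raise GeneratorError("n_per_class and length must be positive")
        for name in ("gc_pos", "gc_neg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.periodic_strength <= 1.0:
            raise GeneratorError("periodic_strength must be in [0, 1]")
        if self.period < 2:
            raise GeneratorError("period must be >= 2")

    @classmethod
    def strong(cls, **overrides) -> "GeneratorSpec":
        """The default, well-separated condition."""
        return cls(**overrides)

    @classmethod
    def null(cls, n_per_class: int = 1000, seed: int = 7, **overrides) -> "GeneratorSpec":
        """Identically distributed classes: no composition gap, no
        periodicity.  Any classifier should score chance accuracy."""
        return cls(
            n_per_class=n_per_class,
            gc_pos=0.5,
            gc_neg=0.5,
            periodic_strength=0.0,
            seed=seed,
            **overrides,
        )


def _class_probs(gc: float) -> np.ndarray:
    """i.i.d. base probabilities (A, C, G, T) at a given GC content."""
    at = 1.0 - gc
    return np.array([at / 2, gc / 2, gc / 2, at / 2])


def positional_probs(spec: GeneratorSpec) -> np.ndarray:
    """4 x L base-probability matrix of the positive class.

    At phased positions (1-based n with (n-1) % period == 0) the A/T
    probability mass is moved toward 1 by the fraction
    ``periodic_strength``; columns stay normalized by construction.
    """
    base = _class_probs(spec.gc_pos)
    probs = np.tile(base[:, None], (1, spec.length))
    s = spec.periodic_strength
    if s > 0:
        phased = np.arange(0, spec.length, spec.period)
        at = base[0] + base[3]
        at_boost = at + s * (1.0 - at)
        gc_left = 1.0 - at_boost
        probs[0, phased] = at_boost / 2
        probs[3, phased] = at_boost / 2
        probs[1, phased] = gc_left / 2
        probs[2, phased] = gc_left / 2
    return probs


def _sample_from_columns(
    probs: np.ndarray, n_seqs: int, rng: np.random.Generator
) -> list[str]:
    """Draw n_seqs strings, position j from the categorical probs[:, j]."""
    L = probs.shape[1]
    cum = np.cumsum(probs, axis=0)  # (4, L)
    u = rng.random((n_seqs, L))
    idx = (u[:, None, :] > cum[None, :, :]).sum(axis=1)  # (n_seqs, L)
    return ["".join(_BASES[row]) for row in idx]


def generate_dataset(spec: GeneratorSpec) -> tuple[SequenceSet, SequenceSet]:
    """Draw one positive (nucleosome-like) and one negative (linker-like)
    sequence set; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    pos_probs = positional_probs(spec)
    neg_probs = np.tile(_class_probs(spec.gc_neg)[:, None], (1, spec.length))
    pos_strs = _sample_from_columns(pos_probs, spec.n_per_class, rng)
    neg_strs = _sample_from_columns(neg_probs, spec.n_per_class, rng)
    pos = SequenceSet(
        tuple(DnaSequence(f"pos_{i + 1}", s) for i, s in enumerate(pos_strs)),
        label=Label.NUCLEOSOME,
    )
    neg = SequenceSet(
        tuple(DnaSequence(f"neg_{i + 1}", s) for i, s in enumerate(neg_strs)),
        label=Label.LINKER,
    )
    return pos, neg


@dataclass(frozen=True)
class PlantedGenome:
    """A toy genome with known nucleosome plants."""

    record: DnaSequence
    truth: tuple[tuple[int, int], ...]  # 1-based inclusive intervals

    def indicator(self) -> np.ndarray:
        """Per-base 0/1 vector marking planted intervals."""
        ind = np.zeros(len(self.record), dtype=float)
        for s, e in self.truth:
            ind[s - 1 : e] = 1.0
        return ind

    def truth_to_bed(self, path: Union[str, Path], name: str = "plant") -> None:
        """Write plant intervals as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for i, (s, e) in enumerate(self.truth, 1):
                fh.write(f"{self.record.id}\t{s - 1}\t{e}\t{name}_{i}\n")


def generate_genome(
    n_plants: int,
    plant_source: SequenceSet,
    spacer_gc: float = 0.40,
    spacer_len_range: tuple[int, int] = (200, 500),
    seed: int = 7,
    chrom: str = "chrSim",
) -> PlantedGenome:
    """Concatenate random spacers and planted positive-class sequences.

    The genome is spacer, plant, spacer, ..., plant, spacer; plants are
    sampled (with replacement) from ``plant_source``, spacers are i.i.d.
    at ``spacer_gc`` with lengths uniform over ``spacer_len_range``.
    Truth intervals (1-based inclusive) never overlap by construction.
    """
    if len(plant_source) == 0:
        raise GeneratorError("plant_source must be non-empty")
    if n_plants < 0:
        raise GeneratorError("n_plants must be >= 0")
    lo, hi = spacer_len_range
    if lo < 1 or hi < lo:
        raise GeneratorError("invalid spacer length range")
    rng = np.random.default_rng(seed)
    spacer_probs = _class_probs(spacer_gc)

    parts: list[str] = []
    truth: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_plants + 1):
        slen = int(rng.integers(lo, hi + 1))
        spacer = "".join(_BASES[rng.choice(4, size=slen, p=spacer_probs)])
        parts.append(spacer)
        pos += slen
        if i < n_plants:
            plant = plant_source[int(rng.integers(0, len(plant_source)))]
            parts.append(plant.bases)
            truth.append((pos + 1, pos + len(plant)))
            pos += len(plant)
    return PlantedGenome(
        record=DnaSequence(chrom, "".join(parts)), truth=tuple(truth)
    )
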