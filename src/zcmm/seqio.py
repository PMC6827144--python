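"""FASTA input/output and the fixed-length sequence-set contract.

The composition models downstream are defined over the four-letter
alphabet {A, C, G, T} and over sets of sequences that all share one
length N (147 or 150 bp in typical nucleosome benchmarks).  This module
enforces both contracts at the boundary so the numerical code never has
to re-check them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ACGT = frozenset("ACGT")
#: IUPAC nucleotide one-letter codes (incl. ambiguity codes) accepted on input.
IUPAC_DNA = frozenset("ACGTURYSWKMBDHVN")


class Label(str, Enum):
    """Class label carried by a sequence set."""

    NUCLEOSOME = "nucleosome"
    LINKER = "linker"
    UNLABELED = "unlabeled"


class SequenceError(ValueError):
    """Raised for malformed or contract-violating sequence input."""


@dataclass(frozen=True)
class DnaSequence:
    """A single DNA sequence.

    Bases are uppercased on construction (soft-masking is irrelevant to
    composition models).  Ambiguity codes are tolerated at this level so
    genome records can be carried around; model-facing code requires the
    strict ACGT alphabet and should check :attr:`is_acgt` (the FASTA
    readers enforce it via their ambiguity policy).
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        norm = self.bases.upper().replace("U", "T")
        if not norm:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(norm) - IUPAC_DNA
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains non-nucleotide characters: {sorted(bad)}"
            )
        object.__setattr__(self, "bases", norm)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_acgt(self) -> bool:
        return set(self.bases) <= ACGT


@dataclass(frozen=True)
class SequenceSet:
    """A non-empty collection of equal-length DNA sequences with a class label.

    ``uniform_length=False`` relaxes the equal-length invariant; this is
    used only for genome records (one per chromosome), which are never
    fed to the fixed-length models directly.
    """

    sequences: tuple[DnaSequence, ...]
    label: Label = Label.UNLABELED
    uniform_length: bool = True

    def __post_init__(self) -> None:
        seqs = tuple(self.sequences)
        if not seqs:
            raise SequenceError("sequence set is empty")
        object.__setattr__(self, "sequences", seqs)
        if self.uniform_length:
            n0 = len(seqs[0])
            for s in seqs:
                if len(s) != n0:
                    raise SequenceError(
                        f"sequence {s.id!r} has length {len(s)}, expected {n0} "
                        f"(set length defined by first record {seqs[0].id!r})"
                    )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[DnaSequence]:
        return iter(self.sequences)

    def __getitem__(self, i):
        return self.sequences[i]

    @property
    def N(self) -> int | None:
        """Common sequence length, or ``None`` for mixed-length sets."""
        if not self.uniform_length:
            return None
        return len(self.sequences[0])


def read_fasta(
    path: Union[str, Path],
    policy: str = "drop",
    label: Label = Label.UNLABELED,
) -> SequenceSet:
    """Read a fixed-length FASTA file into a :class:`SequenceSet`.

    Parameters
    ----------
    path
        FASTA file (multi-record; wrapped or unwrapped lines).
    policy
        What to do with records containing non-ACGT bases:
        ``"drop"`` excludes them with a logged warning, ``"reject"``
        raises.  The models are defined only over A/C/G/T.
    label
        Class label to attach to the set.
    """
    if policy not in ("drop", "reject"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = _parse_records(path)
    kept: list[DnaSequence] = []
    for rec in records:
        if not rec.is_acgt:
            if policy == "reject":
                raise SequenceError(
                    f"record {rec.id!r} in {path} contains ambiguous bases "
                    f"(policy='reject')"
                )
            logger.warning("dropping record %r: ambiguous bases", rec.id)
            continue
        kept.append(rec)
    if not kept:
        raise SequenceError(f"no usable records in {path}")
    return SequenceSet(tuple(kept), label=label)


def read_genome(path: Union[str, Path]) -> SequenceSet:
    """Read a genome FASTA, one record per chromosome/contig.

    Records may contain ambiguity codes (N runs etc.); the sliding-window
    profiler skips windows that contain them.  Lengths may differ.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = _parse_records(path)
    return SequenceSet(tuple(records), label=Label.UNLABELED, uniform_length=False)


def _parse_records(path: Path) -> list[DnaSequence]:
    records: list[DnaSequence] = []
    with open(path) as fh:
        first = fh.read(1)
        if not first:
            raise SequenceError(f"{path} is empty")
        if first != ">":
            raise SequenceError(f"{path} is not FASTA (does not start with '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(DnaSequence(rec.id, str(rec.seq)))
        except SequenceError as e:
            raise SequenceError(f"malformed record {rec.id!r} in {path}: {e}") from e
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return records


def write_fasta(seq_set: SequenceSet, path: Union[str, Path], width: int = 70) -> None:
    """Write a sequence set to FASTA; round-trips ids and bases exactly."""
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seq_set
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
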