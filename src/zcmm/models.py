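"""The three sequence models and their combination.

A DNA sequence of length N maps to a Z-curve: three cumulative
composition tracks

    x_n = (a_n + g_n) - (c_n + t_n)      purine  vs pyrimidine
    y_n = (a_n + c_n) - (g_n + t_n)      amino   vs keto
    z_n = (a_n + t_n) - (g_n + c_n)      weak    vs strong H-bonds

where a_n, c_n, g_n, t_n are the frequencies of each base among
positions 1..n (counts divided by n, so every coordinate lies in
[-1, 1]).  Averaging the cumulative frequencies over a set of m
equal-length sequences and applying the same arithmetic gives the
set-level Z-curve model (ZCM).  A position weight matrix (PWM) of
log-odds M_in = log(q'_in / b_i) captures per-position base preference;
multiplying each mean frequency by the matching PWM entry inside the
Z-curve arithmetic yields the combined ZCMM model

    X_n = (M_nA a_nm + M_nG g_nm) - (M_nC c_nm + M_nT t_nm)
    Y_n = (M_nA a_nm + M_nC c_nm) - (M_nG g_nm + M_nT t_nm)
    Z_n = (M_nA a_nm + M_nT t_nm) - (M_nG g_nm + M_nC c_nm)

which encodes both the horizontal (cumulative) and vertical
(positional) structure of the set.

Conventions fixed here and everywhere downstream: base rows are ordered
A, C, G, T; positions are 1-based in serialized output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
from scipy import stats

from zcmm.seqio import DnaSequence, SequenceSet, SequenceError

#: Fixed base-row ordering for all 4 x N matrices in this package.
BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

ARCHIVE_FORMAT = "zcmm-model"
ARCHIVE_VERSION = 1


class ModelError(ValueError):
    """Raised for invalid model construction or incompatible models."""


# ---------------------------------------------------------------------------
# cumulative frequencies and the Z-curve


@dataclass(frozen=True)
class CumulativeFreqs:
    """Cumulative base frequencies: ``freq[i, n-1]`` is the frequency of
    base ``BASE_ORDER[i]`` among positions 1..n.  Columns sum to 1."""

    freq: np.ndarray  # shape (4, N)

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.ndim != 2 or f.shape[0] != 4 or f.shape[1] < 1:
            raise ModelError(f"cumulative frequencies must be 4 x N, got {f.shape}")
        object.__setattr__(self, "freq", f)

    @property
    def N(self) -> int:
        return self.freq.shape[1]

    @property
    def a(self) -> np.ndarray:
        return self.freq[0]

    @property
    def c(self) -> np.ndarray:
        return self.freq[1]

    @property
    def g(self) -> np.ndarray:
        return self.freq[2]

    @property
    def t(self) -> np.ndarray:
        return self.freq[3]


@dataclass(frozen=True)
class ZCurve:
    """Three coordinate tracks of length N, each in [-1, 1]."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
        if not (self.x.shape == self.y.shape == self.z.shape) or self.x.ndim != 1:
            raise ModelError("x, y, z must be 1-D vectors of equal length")

    @property
    def N(self) -> int:
        return self.x.shape[0]

    @classmethod
    def from_freqs(cls, freqs: CumulativeFreqs) -> "ZCurve":
        a, c, g, t = freqs.a, freqs.c, freqs.g, freqs.t
        return cls(
            x=(a + g) - (c + t),
            y=(a + c) - (g + t),
            z=(a + t) - (g + c),
        )


def cumulative_frequencies(seq: DnaSequence) -> CumulativeFreqs:
    """Per-position cumulative base frequencies of a single sequence."""
    if not seq.is_acgt:
        raise SequenceError(
            f"sequence {seq.id!r} contains non-ACGT bases; models are defined "
            "over the 4-letter alphabet"
        )
    idx = np.fromiter((_BASE_INDEX[b] for b in seq.bases), dtype=np.intp, count=len(seq))
    onehot = np.zeros((4, len(seq)), dtype=float)
    onehot[idx, np.arange(len(seq))] = 1.0
    counts = np.cumsum(onehot, axis=1)
    denom = np.arange(1, len(seq) + 1, dtype=float)
    return CumulativeFreqs(counts / denom)


def zcurve_transform(seq: DnaSequence) -> ZCurve:
    """Map a sequence to its Z-curve (3 x N coordinate matrix)."""
    return ZCurve.from_freqs(cumulative_frequencies(seq))


def inverse_zcurve(curve: ZCurve, id: str = "reconstructed") -> DnaSequence:
    """Recover the unique sequence whose Z-curve equals ``curve``.

    The frequencies invert algebraically:

        a_n = (x_n + y_n + z_n + 1) / 4      g_n = (x_n - y_n - z_n + 1) / 4
        c_n = (-x_n + y_n - z_n + 1) / 4     t_n = (-x_n - y_n + z_n + 1) / 4

    and cumulative counts n * f_n must be integers increasing by a unit
    step in exactly one base per position; otherwise the curve does not
    correspond to any sequence and a :class:`ModelError` is raised.
    """
    x, y, z = curve.x, curve.y, curve.z
    n = np.arange(1, curve.N + 1, dtype=float)
    freqs = np.vstack(
        [
            (x + y + z + 1.0) / 4.0,   # a
            (-x + y - z + 1.0) / 4.0,  # c
            (x - y - z + 1.0) / 4.0,   # g
            (-x - y + z + 1.0) / 4.0,  # t
        ]
    )
    counts = freqs * n  # shape (4, N)
    rounded = np.rint(counts)
    if not np.allclose(counts, rounded, atol=1e-6):
        raise ModelError("curve implies non-integer base counts; not a sequence Z-curve")
    rounded = rounded.astype(np.int64)
    prev = np.zeros(4, dtype=np.int64)
    bases = []
    for j in range(curve.N):
        step = rounded[:, j] - prev
        if step.min() < 0 or step.sum() != 1 or step.max() != 1:
            raise ModelError(
                f"curve position {j + 1} does not correspond to a single-base step"
            )
        bases.append(BASE_ORDER[int(np.argmax(step))])
        prev = rounded[:, j]
    return DnaSequence(id, "".join(bases))


# ---------------------------------------------------------------------------
# set-level models


@dataclass(frozen=True)
class ZcmModel:
    """Set-level Z-curve model: mean cumulative frequencies over m
    sequences and the curve derived from them."""

    mean_freqs: CumulativeFreqs
    curve: ZCurve
    m: int

    @property
    def N(self) -> int:
        return self.mean_freqs.N


def build_zcm(seq_set: SequenceSet) -> ZcmModel:
    """Average the per-sequence cumulative frequencies position-wise and
    derive the set-level Z-curve from the means."""
    if seq_set.N is None:
        raise ModelError("sequence set must have uniform length")
    acc = np.zeros((4, seq_set.N), dtype=float)
    for s in seq_set:
        acc += cumulative_frequencies(s).freq
    mean = CumulativeFreqs(acc / len(seq_set))
    return ZcmModel(mean_freqs=mean, curve=ZCurve.from_freqs(mean), m=len(seq_set))


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix of log-odds ``M[i, n-1] = log(q'_in / b_i)``.

    ``q'_in`` is the pseudocount-smoothed frequency of base i at
    position n, ``b_i`` the background frequency.  Rows follow
    :data:`BASE_ORDER`.
    """

    M: np.ndarray           # (4, N) log-odds
    background: np.ndarray  # (4,) summing to 1
    pseudocount: float
    log_base: str           # "e" or "2"

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if M.ndim != 2 or M.shape[0] != 4:
            raise ModelError(f"PWM must be 4 x N, got {M.shape}")
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ModelError("background must be a 4-vector summing to 1")
        if (bg <= 0).any():
            raise ModelError("background frequencies must be strictly positive")
        if self.log_base not in ("e", "2"):
            raise ModelError(f"log_base must be 'e' or '2', got {self.log_base!r}")
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "background", bg)

    @property
    def N(self) -> int:
        return self.M.shape[1]

    def score_positions(self, seq: DnaSequence) -> np.ndarray:
        """Per-position log-odds of the sequence's bases (length N)."""
        if len(seq) != self.N:
            raise ModelError(f"sequence length {len(seq)} != PWM length {self.N}")
        idx = np.fromiter((_BASE_INDEX[b] for b in seq.bases), dtype=np.intp, count=self.N)
        return self.M[idx, np.arange(self.N)]

    def to_meme(self, path: Union[str, Path], name: str = "zcmm_pwm") -> None:
        """Export the smoothed probability matrix in MEME minimal motif format."""
        base = math.e if self.log_base == "e" else 2.0
        probs = self.background[:, None] * np.power(base, self.M)
        probs = probs / probs.sum(axis=0, keepdims=True)
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write(
                "Background letter frequencies\n"
                + " ".join(
                    f"{b} {f:.6f}" for b, f in zip(BASE_ORDER, self.background)
                )
                + "\n\n"
            )
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {self.N}\n")
            for col in probs.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")


def build_pwm(
    seq_set: SequenceSet,
    background: Union[str, np.ndarray] = "from-set",
    pseudocount: float = 1.0,
    log_base: str = "e",
) -> Pwm:
    """Positional log-odds matrix from a fixed-length sequence set.

    Parameters
    ----------
    background
        ``"from-set"`` pools base frequencies over the whole set,
        ``"uniform"`` uses 0.25 each, or pass an explicit 4-vector
        (order A, C, G, T).
    pseudocount
        Laplace smoothing added per base per column:
        ``q' = (count + a) / (m + 4a)``.  Zero is allowed only when every
        count is positive.
    """
    if seq_set.N is None:
        raise ModelError("sequence set must have uniform length")
    if pseudocount < 0:
        raise ModelError("pseudocount must be non-negative")
    N, m = seq_set.N, len(seq_set)
    counts = np.zeros((4, N), dtype=float)
    for s in seq_set:
        if not s.is_acgt:
            raise SequenceError(f"sequence {s.id!r} contains non-ACGT bases")
        idx = np.fromiter((_BASE_INDEX[b] for b in s.bases), dtype=np.intp, count=N)
        np.add.at(counts, (idx, np.arange(N)), 1.0)
    if pseudocount == 0 and (counts == 0).any():
        raise ModelError(
            "zero counts with pseudocount=0 would give log(0); "
            "use a positive pseudocount"
        )
    q = (counts + pseudocount) / (m + 4.0 * pseudocount)

    if isinstance(background, str):
        if background == "uniform":
            bg = np.full(4, 0.25)
        elif background == "from-set":
            bg = counts.sum(axis=1) / counts.sum()
            if (bg <= 0).any():
                # a base absent from the entire set: fall back to smoothing
                bg = (counts.sum(axis=1) + 1.0) / (counts.sum() + 4.0)
        else:
            raise ModelError(f"unknown background {background!r}")
    else:
        bg = np.asarray(background, dtype=float)

    M = np.log(q / bg[:, None])
    if log_base == "2":
        M = M / math.log(2.0)
    return Pwm(M=M, background=bg, pseudocount=float(pseudocount), log_base=log_base)


@dataclass(frozen=True)
class ZcmmModel:
    """PWM-weighted Z-curve model: three length-N coordinate tracks."""

    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    m: int = 0

    def __post_init__(self) -> None:
        for name in ("X", "Y", "Z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.X.shape == self.Y.shape == self.Z.shape) or self.X.ndim != 1:
            raise ModelError("X, Y, Z must be 1-D vectors of equal length")

    @property
    def N(self) -> int:
        return self.X.shape[0]

    def coords(self) -> np.ndarray:
        """Stacked (3, N) coordinate matrix."""
        return np.vstack([self.X, self.Y, self.Z])


def build_zcmm(zcm: ZcmModel, pwm: Pwm) -> ZcmmModel:
    """Weight the set-level mean frequencies by the PWM inside the
    Z-curve arithmetic.  A unit PWM (all entries 1) reproduces the ZCM
    curve exactly; an all-zero PWM annihilates all coordinates."""
    if zcm.N != pwm.N:
        raise ModelError(f"length mismatch: ZCM N={zcm.N}, PWM N={pwm.N}")
    a, c, g, t = (zcm.mean_freqs.a, zcm.mean_freqs.c,
                  zcm.mean_freqs.g, zcm.mean_freqs.t)
    MA, MC, MG, MT = pwm.M[0], pwm.M[1], pwm.M[2], pwm.M[3]
    wa, wc, wg, wt = MA * a, MC * c, MG * g, MT * t
    return ZcmmModel(
        X=(wa + wg) - (wc + wt),
        Y=(wa + wc) - (wg + wt),
        Z=(wa + wt) - (wg + wc),
        m=zcm.m,
    )


def compare_models(model_a: ZcmmModel, model_b: ZcmmModel) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two coordinate models.

    Compares the position-wise coordinate values of the two models per
    axis and pooled over all three axes.  Returns a dict with keys
    ``"x"``, ``"y"``, ``"z"``, ``"pooled"`` mapping to p-values.
    """
    if model_a.N != model_b.N:
        raise ModelError("models must have equal length")
    if model_a.N < 2:
        raise ModelError("need at least 2 positions for a rank-sum test")
    out = {}
    for key, va, vb in (
        ("x", model_a.X, model_b.X),
        ("y", model_a.Y, model_b.Y),
        ("z", model_a.Z, model_b.Z),
    ):
        out[key] = float(stats.ranksums(va, vb).pvalue)
    pooled_a = np.concatenate([model_a.X, model_a.Y, model_a.Z])
    pooled_b = np.concatenate([model_b.X, model_b.Y, model_b.Z])
    out["pooled"] = float(stats.ranksums(pooled_a, pooled_b).pvalue)
    return out


# ---------------------------------------------------------------------------
# serialization


@dataclass(frozen=True)
class ModelBundle:
    """The three fitted models, serialized together."""

    zcm: ZcmModel
    pwm: Pwm
    zcmm: ZcmmModel

    @property
    def N(self) -> int:
        return self.zcmm.N


def bundle_to_doc(bundle: ModelBundle) -> dict:
    """JSON-serializable dict form of a model bundle."""
    return {
        "format": ARCHIVE_FORMAT,
        "version": ARCHIVE_VERSION,
        "base_order": BASE_ORDER,
        "N": bundle.N,
        "m": bundle.zcm.m,
        "mean_freqs": bundle.zcm.mean_freqs.freq.tolist(),
        "pwm": {
            "M": bundle.pwm.M.tolist(),
            "background": bundle.pwm.background.tolist(),
            "pseudocount": bundle.pwm.pseudocount,
            "log_base": bundle.pwm.log_base,
        },
        "zcmm": {
            "X": bundle.zcmm.X.tolist(),
            "Y": bundle.zcmm.Y.tolist(),
            "Z": bundle.zcmm.Z.tolist(),
        },
    }


def bundle_from_doc(doc: dict) -> ModelBundle:
    """Inverse of :func:`bundle_to_doc`, with format/version checks."""
    if doc.get("format") != ARCHIVE_FORMAT:
        raise ModelError("not a model archive document")
    if doc.get("version") != ARCHIVE_VERSION:
        raise ModelError(
            f"unsupported archive version {doc.get('version')} (expected {ARCHIVE_VERSION})"
        )
    mean = CumulativeFreqs(np.array(doc["mean_freqs"], dtype=float))
    zcm = ZcmModel(mean_freqs=mean, curve=ZCurve.from_freqs(mean), m=int(doc["m"]))
    p = doc["pwm"]
    pwm = Pwm(
        M=np.array(p["M"], dtype=float),
        background=np.array(p["background"], dtype=float),
        pseudocount=float(p["pseudocount"]),
        log_base=p["log_base"],
    )
    zd = doc["zcmm"]
    zcmm = ZcmmModel(
        X=np.array(zd["X"], dtype=float),
        Y=np.array(zd["Y"], dtype=float),
        Z=np.array(zd["Z"], dtype=float),
        m=int(doc["m"]),
    )
    return ModelBundle(zcm=zcm, pwm=pwm, zcmm=zcmm)


def save_model(bundle: ModelBundle, path: Union[str, Path]) -> None:
    """Serialize a model bundle to a single versioned JSON text file.

    Floats are written with full repr precision, so a save/load round
    trip reproduces every numeric field bit-exactly.
    """
    with open(path, "w") as fh:
        json.dump(bundle_to_doc(bundle), fh)


def load_model(path: Union[str, Path]) -> ModelBundle:
    """Load a model bundle saved by :func:`save_model`."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ModelError(f"corrupt model file {path}: {e}") from e
    try:
        return bundle_from_doc(doc)
    except (KeyError, TypeError) as e:
        raise ModelError(f"corrupt model file {path}: {e}") from e


def curve_to_tsv(curve: Union[ZCurve, ZcmmModel], path: Union[str, Path]) -> None:
    """Export a curve as TSV with 1-based positions."""
    if isinstance(curve, ZcmmModel):
        cols = ("X", "Y", "Z")
        vals = (curve.X, curve.Y, curve.Z)
    else:
        cols = ("x", "y", "z")
        vals = (curve.x, curve.y, curve.z)
    with open(path, "w") as fh:
        fh.write("position\t" + "\t".join(cols) + "\n")
        for n in range(len(vals[0])):
            fh.write(
                f"{n + 1}\t" + "\t".join(repr(float(v[n])) for v in vals) + "\n"
            )
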