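"""Classifier features derived from sequences and fitted models.

The primary featurization is the per-position Euclidean distance
between a sequence's own Z-curve and a ZCMM model:

    Ed_n = sqrt((x_n - X_n)^2 + (y_n - Y_n)^2 + (z_n - Z_n)^2)

giving an N-vector per sequence.  Two ablation modes (raw flattened
Z-curve coordinates; per-position PWM log-odds) and a dual-model
variant (distances to both class models) are available for baseline
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from zcmm.models import ModelError, Pwm, ZcmmModel, zcurve_transform
from zcmm.seqio import DnaSequence, SequenceSet


class FeatureMode(str, Enum):
    """How sequences are turned into feature vectors."""

    ZCMM_DISTANCE = "zcmm_distance"            # N distances to the nucleosome model
    ZCMM_DISTANCE_DUAL = "zcmm_distance_dual"  # 2N distances, positive model first
    ZCURVE_RAW = "zcurve_raw"                  # 3N flattened Z-curve coordinates
    PWM_SCORE = "pwm_score"                    # N per-position log-odds


@dataclass(frozen=True)
class DistanceVector:
    """Per-position Euclidean distances of one sequence to a ZCMM model."""

    values: np.ndarray
    sequence_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if (v < 0).any():
            raise ModelError("Euclidean distances cannot be negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FeatureMatrix:
    """Feature rows with optional +1/-1 labels."""

    rows: np.ndarray                 # (M, n_features)
    labels: Optional[np.ndarray]     # (M,) in {+1, -1}, or None
    feature_mode: FeatureMode
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2:
            raise ModelError("feature rows must form a 2-D matrix")
        object.__setattr__(self, "rows", rows)
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=int)
            if labels.shape[0] != rows.shape[0]:
                raise ModelError("label count must equal row count")
            if not set(np.unique(labels)) <= {1, -1}:
                raise ModelError("labels must be +1/-1")
            object.__setattr__(self, "labels", labels)

    @property
    def n_features(self) -> int:
        return self.rows.shape[1]

    def __len__(self) -> int:
        return self.rows.shape[0]


def distance_vector(seq: DnaSequence, model: ZcmmModel) -> DistanceVector:
    """Euclidean distance between the sequence's Z-curve and the model,
    position by position."""
    if len(seq) != model.N:
        raise ModelError(
            f"sequence {seq.id!r} has length {len(seq)}, model expects {model.N}"
        )
    c = zcurve_transform(seq)
    d = np.sqrt(
        (c.x - model.X) ** 2 + (c.y - model.Y) ** 2 + (c.z - model.Z) ** 2
    )
    return DistanceVector(values=d, sequence_id=seq.id)


def featurize(
    seqs: Sequence[DnaSequence],
    mode: FeatureMode = FeatureMode.ZCMM_DISTANCE,
    pos_model: Optional[ZcmmModel] = None,
    neg_model: Optional[ZcmmModel] = None,
    pwm: Optional[Pwm] = None,
) -> np.ndarray:
    """Feature rows for an unlabeled collection of sequences."""
    mode = FeatureMode(mode)
    if mode in (FeatureMode.ZCMM_DISTANCE, FeatureMode.ZCMM_DISTANCE_DUAL):
        if pos_model is None:
            raise ModelError(f"mode {mode.value} requires the positive-class ZCMM model")
        if mode is FeatureMode.ZCMM_DISTANCE_DUAL and neg_model is None:
            raise ModelError("mode zcmm_distance_dual requires both class models")
    if mode is FeatureMode.PWM_SCORE and pwm is None:
        raise ModelError("mode pwm_score requires a PWM")

    rows = []
    for s in seqs:
        if mode is FeatureMode.ZCMM_DISTANCE:
            rows.append(distance_vector(s, pos_model).values)
        elif mode is FeatureMode.ZCMM_DISTANCE_DUAL:
            rows.append(
                np.concatenate(
                    [
                        distance_vector(s, pos_model).values,
                        distance_vector(s, neg_model).values,
                    ]
                )
            )
        elif mode is FeatureMode.ZCURVE_RAW:
            c = zcurve_transform(s)
            rows.append(np.concatenate([c.x, c.y, c.z]))
        else:  # PWM_SCORE
            rows.append(pwm.score_positions(s))
    return np.vstack(rows)


def build_feature_matrix(
    pos: SequenceSet,
    neg: SequenceSet,
    mode: FeatureMode = FeatureMode.ZCMM_DISTANCE,
    pos_model: Optional[ZcmmModel] = None,
    neg_model: Optional[ZcmmModel] = None,
    pwm: Optional[Pwm] = None,
) -> FeatureMatrix:
    """Labeled feature matrix: +1 rows for ``pos``, -1 rows for ``neg``."""
    mode = FeatureMode(mode)
    rows_pos = featurize(list(pos), mode, pos_model, neg_model, pwm)
    rows_neg = featurize(list(neg), mode, pos_model, neg_model, pwm)
    rows = np.vstack([rows_pos, rows_neg])
    labels = np.concatenate(
        [np.ones(len(pos), dtype=int), -np.ones(len(neg), dtype=int)]
    )
    ids = tuple(s.id for s in pos) + tuple(s.id for s in neg)
    return FeatureMatrix(rows=rows, labels=labels, feature_mode=mode, ids=ids)


def to_tsv(fm: FeatureMatrix, path: Union[str, Path]) -> None:
    """Write features as TSV (header = feature indices, optional label column)."""
    with open(path, "w") as fh:
        header = ["id"] + [f"f{i + 1}" for i in range(fm.n_features)]
        if fm.labels is not None:
            header.append("label")
        fh.write("\t".join(header) + "\n")
        for i in range(len(fm)):
            sid = fm.ids[i] if fm.ids else str(i)
            fields = [sid] + [repr(float(v)) for v in fm.rows[i]]
            if fm.labels is not None:
                fields.append(f"{fm.labels[i]:+d}")
            fh.write("\t".join(fields) + "\n")


def to_libsvm(fm: FeatureMatrix, path: Union[str, Path]) -> None:
    """Write features in the sparse libsvm text format (label index:value)."""
    if fm.labels is None:
        raise ModelError("libsvm export requires labels")
    with open(path, "w") as fh:
        for i in range(len(fm)):
            pairs = " ".join(
                f"{j + 1}:{fm.rows[i, j]!r}" for j in range(fm.n_features)
            )
            fh.write(f"{fm.labels[i]:+d} {pairs}\n")
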