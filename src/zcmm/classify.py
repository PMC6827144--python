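"""SVM training, hyperparameter search and stratified cross-validation.

The classifier is an RBF-kernel support vector machine on the distance
features, with two tunable hyperparameters: the kernel width ``gamma``
and the soft-margin ``cost``.  Cross-validation is stratified 10-fold
by default and, crucially, rebuilds the ZCM/PWM/ZCMM models and the
feature scaler inside each fold on the nine training parts only, so no
information from the held-out part leaks into the models it is scored
against.  A ``refit_per_fold=False`` switch builds the models once on
all data for comparison with protocols that do not isolate folds.
"""

from __future__ import annotations

import base64
import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from zcmm.features import FeatureMatrix, FeatureMode, build_feature_matrix, featurize
from zcmm.metrics import ConfusionCounts, MetricsReport, compute_metrics, roc_auc
from zcmm.models import (
    ModelBundle,
    ModelError,
    build_pwm,
    build_zcm,
    build_zcmm,
    bundle_from_doc,
    bundle_to_doc,
)
from zcmm.seqio import DnaSequence, Label, SequenceSet

#: Default hyperparameter grids, the usual coarse libsvm log-2 lattice.
DEFAULT_GAMMA_GRID = (2.0 ** -15, 2.0 ** -11, 2.0 ** -7, 2.0 ** -3, 2.0)
DEFAULT_COST_GRID = (2.0 ** -5, 2.0 ** -1, 2.0 ** 3, 2.0 ** 7, 2.0 ** 11)


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameters and run options."""

    gamma: float = 2.0 ** -7
    cost: float = 8.0
    kernel: str = "rbf"
    scale_features: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise ClassifyError("gamma and cost must be positive")
        if self.kernel != "rbf":
            raise ClassifyError("only the RBF kernel is supported")

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "cost": self.cost,
            "kernel": self.kernel,
            "scale_features": self.scale_features,
            "seed": self.seed,
        }


@dataclass
class CvResult:
    """Per-fold and mean metrics from a cross-validation run."""

    per_fold: list[MetricsReport]
    mean: MetricsReport
    roc_points: list[tuple[np.ndarray, np.ndarray]]  # (scores, labels) per fold
    chosen_config: SvmConfig
    fold_model_hashes: list[str] = field(default_factory=list)

    @property
    def max_auc(self) -> float:
        return max(r.auc for r in self.per_fold if r.auc is not None)


def stratified_folds(labels: Sequence[int], k: int = 10, seed: int = 42) -> np.ndarray:
    """Assign each sample to one of ``k`` stratified folds.

    Deterministic given ``seed``; per-fold class counts differ from
    exact proportionality by less than one sample.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ClassifyError("k must be at least 2")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ClassifyError(
            f"smallest class has {counts.min()} members, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


class TrainedSvm:
    """A fitted scaler+SVM pipeline predicting +1/-1 with a continuous
    decision score."""

    def __init__(self, pipeline: Pipeline, config: SvmConfig):
        self.pipeline = pipeline
        self.config = config

    def predict(self, rows: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.asarray(rows, dtype=float))

    def decision_scores(self, rows: np.ndarray) -> np.ndarray:
        return self.pipeline.decision_function(np.asarray(rows, dtype=float))


def train_svm(features: FeatureMatrix, config: SvmConfig = SvmConfig()) -> TrainedSvm:
    """Fit the RBF SVM on a labeled feature matrix."""
    if features.labels is None:
        raise ClassifyError("training requires labeled features")
    if len(set(features.labels.tolist())) < 2:
        raise ClassifyError("training data contain a single class")
    if not np.isfinite(features.rows).all():
        raise ClassifyError("features contain non-finite values")
    steps = []
    if config.scale_features:
        steps.append(("scale", StandardScaler()))
    steps.append(
        (
            "svm",
            SVC(
                kernel="rbf",
                gamma=config.gamma,
                C=config.cost,
                random_state=config.seed,
            ),
        )
    )
    pipe = Pipeline(steps)
    pipe.fit(features.rows, features.labels)
    return TrainedSvm(pipe, config)


def _fit_fold_models(
    pos_train: SequenceSet,
    neg_train: SequenceSet,
    feature_mode: FeatureMode,
    pseudocount: float,
    background,
    log_base: str,
) -> ModelBundle | tuple[ModelBundle, ModelBundle]:
    zcm_pos = build_zcm(pos_train)
    pwm_pos = build_pwm(pos_train, background=background, pseudocount=pseudocount, log_base=log_base)
    bundle_pos = ModelBundle(zcm_pos, pwm_pos, build_zcmm(zcm_pos, pwm_pos))
    if feature_mode is FeatureMode.ZCMM_DISTANCE_DUAL:
        zcm_neg = build_zcm(neg_train)
        pwm_neg = build_pwm(neg_train, background=background, pseudocount=pseudocount, log_base=log_base)
        bundle_neg = ModelBundle(zcm_neg, pwm_neg, build_zcmm(zcm_neg, pwm_neg))
        return bundle_pos, bundle_neg
    return bundle_pos


def _bundle_hash(bundle: ModelBundle) -> str:
    h = hashlib.sha256()
    h.update(bundle.zcm.mean_freqs.freq.tobytes())
    h.update(bundle.pwm.M.tobytes())
    h.update(bundle.zcmm.X.tobytes())
    h.update(bundle.zcmm.Y.tobytes())
    h.update(bundle.zcmm.Z.tobytes())
    return h.hexdigest()


def cross_validate(
    pos: SequenceSet,
    neg: SequenceSet,
    config: SvmConfig = SvmConfig(),
    k: int = 10,
    seed: int = 42,
    feature_mode: FeatureMode = FeatureMode.ZCMM_DISTANCE,
    pseudocount: float = 1.0,
    background="from-set",
    log_base: str = "e",
    refit_per_fold: bool = True,
    folds: Optional[np.ndarray] = None,
) -> CvResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Within each fold the sequence models and feature scaling are fitted
    on the training parts only, then applied to the held-out part.
    ``folds`` may supply an explicit fold assignment (aligned to the
    concatenation pos-then-neg) to override the seeded stratified split.
    """
    feature_mode = FeatureMode(feature_mode)
    if pos.N != neg.N:
        raise ClassifyError("positive and negative sets must share a length")
    all_seqs: list[DnaSequence] = list(pos) + list(neg)
    y = np.concatenate([np.ones(len(pos), dtype=int), -np.ones(len(neg), dtype=int)])
    if folds is None:
        folds = stratified_folds(y, k=k, seed=seed)
    else:
        folds = np.asarray(folds, dtype=int)
        if folds.shape[0] != len(all_seqs):
            raise ClassifyError("fold assignment length mismatch")
        k = int(folds.max()) + 1

    shared_models = None
    if not refit_per_fold:
        shared_models = _fit_fold_models(
            pos, neg, feature_mode, pseudocount, background, log_base
        )

    per_fold: list[MetricsReport] = []
    roc_points: list[tuple[np.ndarray, np.ndarray]] = []
    hashes: list[str] = []
    for fold in range(k):
        test_mask = folds == fold
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        pos_train = SequenceSet(
            tuple(all_seqs[i] for i in train_idx if y[i] == 1), label=Label.NUCLEOSOME
        )
        neg_train = SequenceSet(
            tuple(all_seqs[i] for i in train_idx if y[i] == -1), label=Label.LINKER
        )
        models = shared_models if shared_models is not None else _fit_fold_models(
            pos_train, neg_train, feature_mode, pseudocount, background, log_base
        )
        if isinstance(models, tuple):
            bundle_pos, bundle_neg = models
        else:
            bundle_pos, bundle_neg = models, None
        hashes.append(_bundle_hash(bundle_pos))

        kwargs = dict(
            mode=feature_mode,
            pos_model=bundle_pos.zcmm,
            neg_model=bundle_neg.zcmm if bundle_neg else None,
            pwm=bundle_pos.pwm,
        )
        X_train = featurize([all_seqs[i] for i in train_idx], **kwargs)
        X_test = featurize([all_seqs[i] for i in test_idx], **kwargs)
        fm_train = FeatureMatrix(X_train, y[train_idx], feature_mode)
        clf = train_svm(fm_train, config)
        y_pred = clf.predict(X_test)
        scores = clf.decision_scores(X_test)
        counts = ConfusionCounts.from_predictions(y[test_idx], y_pred)
        auc, _ = roc_auc(scores, y[test_idx])
        per_fold.append(compute_metrics(counts, auc=auc))
        roc_points.append((scores, y[test_idx]))

    mean = MetricsReport(
        sn=float(np.mean([r.sn for r in per_fold])),
        sp=float(np.mean([r.sp for r in per_fold])),
        acc=float(np.mean([r.acc for r in per_fold])),
        mcc=float(np.mean([r.mcc for r in per_fold])),
        auc=float(np.mean([r.auc for r in per_fold])),
    )
    return CvResult(
        per_fold=per_fold,
        mean=mean,
        roc_points=roc_points,
        chosen_config=config,
        fold_model_hashes=hashes,
    )


def grid_search(
    pos: SequenceSet,
    neg: SequenceSet,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    cost_grid: Sequence[float] = DEFAULT_COST_GRID,
    k: int = 10,
    seed: int = 42,
    **cv_kwargs,
) -> tuple[SvmConfig, CvResult, pd.DataFrame]:
    """Exhaustive (gamma, cost) search maximizing mean CV accuracy.

    Ties break toward smaller cost, then smaller gamma.  Returns the
    winning config, its CV result, and the full grid table.
    """
    if not gamma_grid or not cost_grid:
        raise ClassifyError("hyperparameter grids must be non-empty")
    rows = []
    best: tuple[float, float, float] | None = None  # (-acc, cost, gamma)
    best_result: CvResult | None = None
    best_config: SvmConfig | None = None
    for gamma in gamma_grid:
        for cost in cost_grid:
            config = SvmConfig(gamma=gamma, cost=cost, seed=seed)
            result = cross_validate(pos, neg, config, k=k, seed=seed, **cv_kwargs)
            rows.append(
                {
                    "gamma": gamma,
                    "cost": cost,
                    "acc": result.mean.acc,
                    "sn": result.mean.sn,
                    "sp": result.mean.sp,
                    "mcc": result.mean.mcc,
                    "auc": result.mean.auc,
                }
            )
            key = (-result.mean.acc, cost, gamma)
            if best is None or key < best:
                best, best_result, best_config = key, result, config
    return best_config, best_result, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end classifier (train once, predict/profile later)


class ZcmmClassifier:
    """Sequence models plus trained SVM, the deployable predictor.

    ``fit`` builds the ZCM/PWM/ZCMM models on the full training data and
    trains the SVM on the corresponding features; ``predict`` labels new
    fixed-length sequences and ``decision_scores`` gives the continuous
    score used for ranking and occupancy profiling.
    """

    def __init__(
        self,
        config: SvmConfig = SvmConfig(),
        feature_mode: FeatureMode = FeatureMode.ZCMM_DISTANCE,
        pseudocount: float = 1.0,
        background="from-set",
        log_base: str = "e",
    ):
        self.config = config
        self.feature_mode = FeatureMode(feature_mode)
        self.pseudocount = pseudocount
        self.background = background
        self.log_base = log_base
        self.bundle: ModelBundle | None = None
        self.bundle_neg: ModelBundle | None = None
        self.svm: TrainedSvm | None = None

    @property
    def N(self) -> int:
        if self.bundle is None:
            raise ClassifyError("classifier is not fitted")
        return self.bundle.N

    def fit(self, pos: SequenceSet, neg: SequenceSet) -> "ZcmmClassifier":
        models = _fit_fold_models(
            pos, neg, self.feature_mode, self.pseudocount, self.background, self.log_base
        )
        if isinstance(models, tuple):
            self.bundle, self.bundle_neg = models
        else:
            self.bundle, self.bundle_neg = models, None
        fm = build_feature_matrix(
            pos,
            neg,
            mode=self.feature_mode,
            pos_model=self.bundle.zcmm,
            neg_model=self.bundle_neg.zcmm if self.bundle_neg else None,
            pwm=self.bundle.pwm,
        )
        self.svm = train_svm(fm, self.config)
        return self

    def _features(self, seqs: Sequence[DnaSequence]) -> np.ndarray:
        if self.bundle is None or self.svm is None:
            raise ClassifyError("classifier is not fitted")
        return featurize(
            seqs,
            self.feature_mode,
            pos_model=self.bundle.zcmm,
            neg_model=self.bundle_neg.zcmm if self.bundle_neg else None,
            pwm=self.bundle.pwm,
        )

    def predict(self, seqs: Sequence[DnaSequence]) -> np.ndarray:
        return self.svm.predict(self._features(seqs))

    def decision_scores(self, seqs: Sequence[DnaSequence]) -> np.ndarray:
        return self.svm.decision_scores(self._features(seqs))

    # -- persistence: one text file (JSON; the fitted sklearn pipeline is
    #    embedded as base64 so the archive stays a single text artifact)

    def save(self, path: Union[str, Path]) -> None:
        if self.bundle is None or self.svm is None:
            raise ClassifyError("cannot save an unfitted classifier")
        doc = {
            "format": "zcmm-classifier",
            "version": 1,
            "config": self.config.to_dict(),
            "feature_mode": self.feature_mode.value,
            "pseudocount": self.pseudocount,
            "background": (
                self.background
                if isinstance(self.background, str)
                else list(np.asarray(self.background, dtype=float))
            ),
            "log_base": self.log_base,
            "models": bundle_to_doc(self.bundle),
            "models_neg": (
                bundle_to_doc(self.bundle_neg) if self.bundle_neg is not None else None
            ),
            "svm_pickle_b64": base64.b64encode(pickle.dumps(self.svm.pipeline)).decode(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ZcmmClassifier":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ModelError(f"corrupt classifier file {path}: {e}") from e
        if doc.get("format") != "zcmm-classifier" or doc.get("version") != 1:
            raise ModelError(f"{path} is not a supported classifier archive")
        obj = cls(
            config=SvmConfig(**doc["config"]),
            feature_mode=FeatureMode(doc["feature_mode"]),
            pseudocount=doc["pseudocount"],
            background=doc["background"],
            log_base=doc["log_base"],
        )
        obj.bundle = bundle_from_doc(doc["models"])
        if doc.get("models_neg"):
            obj.bundle_neg = bundle_from_doc(doc["models_neg"])
        pipeline = pickle.loads(base64.b64decode(doc["svm_pickle_b64"]))
        obj.svm = TrainedSvm(pipeline, obj.config)
        return obj
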