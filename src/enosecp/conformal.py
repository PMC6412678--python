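"""Inductive and aggregated conformal classification.

An inductive conformal predictor (ICP) splits the labelled data into a
proper-training part, used to fit an underlying scorer, and a calibration
part, whose nonconformity scores rank any new (object, label) pair.  The
conformal p-value for candidate label c is

    p_c = (#{calibration alpha_j >= alpha_c} + 1) / (n_cal + 1),

with ties counted inclusively.  Under exchangeability, the prediction
region {c : p_c > epsilon} errs with probability at most epsilon.

An aggregated conformal predictor (ACP) repeats the ICP construction K
times on stratified bootstrap resamples — the bootstrap draw (duplicates
retained) trains the scorer, the out-of-bag examples calibrate — and
averages the K per-label p-values.  Averaging trades a little of ICP's
exact calibration for lower variance and typically higher forced-choice
accuracy.

The nonconformity measure is alpha = 1 - estimated class probability
(Platt-calibrated decision values for the RBF-kernel SVM, vote fractions
for the random forest); alternatives can be plugged in through
:class:`FittedScorer`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from enosecp.features import FeatureTable

__all__ = [
    "UnderlyingModelSpec",
    "FittedScorer",
    "ICPModel",
    "ACPModel",
    "PValueVector",
    "fit_underlying",
    "nonconformity",
    "icp_fit",
    "icp_pvalues",
    "acp_fit",
    "acp_pvalues",
    "prediction_region",
    "forced_prediction",
    "confidence_credibility",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UnderlyingModelSpec:
    """Underlying scorer configuration.

    ``svm_rbf`` is an RBF-kernel SVM with penalty C and kernel width gamma
    (defaults C=6000, gamma=0.001, Platt-calibrated probabilities);
    ``random_forest`` uses ``n_trees`` trees (default 500) with vote
    fractions as probabilities.  ``standardize=None`` resolves to z-scoring
    for the SVM (fitted on the training portion only) and no scaling for
    the forest.
    """

    kind: str = "svm_rbf"
    C: float = 6000.0
    gamma: float = 0.001
    n_trees: int = 500
    standardize: bool | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm_rbf", "random_forest"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def effective_standardize(self) -> bool:
        if self.standardize is None:
            return self.kind == "svm_rbf"
        return self.standardize


@dataclass
class FittedScorer:
    """A fitted underlying model exposing probability-like class scores."""

    estimator: object
    label_set: np.ndarray

    def class_probabilities(self, x: np.ndarray) -> np.ndarray:
        """Per-class probability estimates, aligned to ``label_set``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        probs = self.estimator.predict_proba(x)
        # sklearn orders columns by estimator.classes_; align to label_set
        classes = np.asarray(self.estimator.classes_)
        aligned = np.zeros((x.shape[0], self.label_set.size))
        for j, lab in enumerate(self.label_set):
            hit = np.nonzero(classes == lab)[0]
            if hit.size:
                aligned[:, j] = probs[:, hit[0]]
        return aligned


@dataclass
class ICPModel:
    scorer: FittedScorer
    calibration_scores: np.ndarray
    label_set: np.ndarray

    def __post_init__(self) -> None:
        self.calibration_scores = np.asarray(self.calibration_scores, dtype=float)
        if self.calibration_scores.size == 0:
            raise ValueError("calibration_scores must be non-empty")
        if not np.all(np.isfinite(self.calibration_scores)):
            raise ValueError("calibration_scores must be finite")

    @property
    def n_calibration(self) -> int:
        return self.calibration_scores.size


@dataclass
class ACPModel:
    folds: list[ICPModel]
    K: int

    def __post_init__(self) -> None:
        if self.K < 1 or len(self.folds) != self.K:
            raise ValueError("ACP needs K >= 1 fitted folds")
        ref = self.folds[0].label_set
        for fold in self.folds[1:]:
            if not np.array_equal(fold.label_set, ref):
                raise ValueError("all folds must share the same label set")

    @property
    def label_set(self) -> np.ndarray:
        return self.folds[0].label_set


@dataclass
class PValueVector:
    """One conformal p-value per candidate label, each in (0, 1]."""

    labels: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.labels.shape != self.values.shape:
            raise ValueError("labels and values must align")
        if np.any((self.values <= 0) | (self.values > 1)):
            raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return self.values.size

    def p_of(self, label) -> float:
        hit = np.nonzero(self.labels == label)[0]
        if hit.size == 0:
            raise KeyError(f"label {label!r} not in p-value vector")
        return float(self.values[hit[0]])


def fit_underlying(
    train_table: FeatureTable, spec: UnderlyingModelSpec
) -> FittedScorer:
    """Fit the underlying probability scorer on a labelled table."""
    if train_table.labels is None:
        raise ValueError("training table must be labelled")
    labels = np.asarray(train_table.labels)
    label_set = np.unique(labels)
    if label_set.size < 2:
        raise ValueError("training table must contain at least 2 classes")
    if spec.kind == "svm_rbf":
        # Platt-calibrated probabilities on internal cross-validated
        # decision values; cv shrinks on small classes so tiny fixtures fit
        min_count = int(np.bincount(np.searchsorted(label_set, labels)).min())
        if min_count < 2:
            raise ValueError(
                "svm_rbf scorer needs at least 2 training examples per class "
                "for probability calibration"
            )
        model = CalibratedClassifierCV(
            SVC(C=spec.C, gamma=spec.gamma, kernel="rbf", random_state=spec.seed),
            method="sigmoid",
            cv=min(5, min_count),
            ensemble=False,
        )
    else:
        model = RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=spec.seed, n_jobs=1
        )
    if spec.effective_standardize:
        model = Pipeline([("scale", StandardScaler()), ("model", model)])
    model.fit(train_table.values, labels)
    return FittedScorer(estimator=model, label_set=label_set)


def nonconformity(scorer: FittedScorer, obj: np.ndarray, label) -> float:
    """Nonconformity score alpha = 1 - estimated probability of ``label``."""
    hit = np.nonzero(scorer.label_set == label)[0]
    if hit.size == 0:
        raise ValueError(f"unknown label {label!r}")
    probs = scorer.class_probabilities(obj)
    return float(1.0 - probs[0, hit[0]])


def _nonconformity_matrix(scorer: FittedScorer, x: np.ndarray) -> np.ndarray:
    """alpha for every (row, candidate label): 1 - class probability."""
    return 1.0 - scorer.class_probabilities(x)


def _true_label_scores(
    scorer: FittedScorer, x: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    alphas = _nonconformity_matrix(scorer, x)
    col = np.searchsorted(scorer.label_set, labels)
    return alphas[np.arange(labels.size), col]


def _stratified_split(labels: np.ndarray, calib_fraction: float, rng):
    """Indices (train, calib) of a stratified random split."""
    train_idx, calib_idx = [], []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        idx = rng.permutation(idx)
        n_cal = int(round(calib_fraction * idx.size))
        calib_idx.append(idx[:n_cal])
        train_idx.append(idx[n_cal:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(calib_idx))


def icp_fit(
    table: FeatureTable,
    spec: UnderlyingModelSpec,
    calib_fraction: float = 1 / 3,
    seed: int = 0,
) -> ICPModel:
    """Fit an inductive conformal predictor.

    The labelled table is split (stratified) into a proper-training part and
    a calibration part of fraction ``calib_fraction``; the scorer is fitted
    on the former and the calibration nonconformity scores are the alphas of
    the latter under their true labels.
    """
    if table.labels is None:
        raise ValueError("table must be labelled")
    if not 0 < calib_fraction < 1:
        raise ValueError("calib_fraction must be in (0, 1)")
    labels = np.asarray(table.labels)
    rng = np.random.default_rng(seed)
    train_idx, calib_idx = _stratified_split(labels, calib_fraction, rng)
    if calib_idx.size < 1:
        raise ValueError("split leaves no calibration examples")
    if np.unique(labels[train_idx]).size < 2:
        raise ValueError("split leaves fewer than 2 classes for training")
    scorer = fit_underlying(table.subset(train_idx), spec)
    cal_scores = _true_label_scores(
        scorer, table.values[calib_idx], labels[calib_idx]
    )
    return ICPModel(
        scorer=scorer,
        calibration_scores=cal_scores,
        label_set=scorer.label_set,
    )


def _pvalues_from_scores(
    cal_scores: np.ndarray, test_alphas: np.ndarray
) -> np.ndarray:
    """Rank-based p-values with inclusive ties and +1 smoothing.

    ``test_alphas`` has shape [n_objects, n_labels]; returns the same shape.
    """
    counts = (cal_scores[None, None, :] >= test_alphas[:, :, None]).sum(axis=2)
    return (counts + 1) / (cal_scores.size + 1)


def icp_pvalues(model: ICPModel, obj: np.ndarray) -> PValueVector | list:
    """Conformal p-values for every candidate label of one or more objects.

    p_c = (#{alpha_j >= alpha_c} + 1) / (n_cal + 1) with inclusive ties.
    A single object (1-D input) returns one :class:`PValueVector`; a 2-D
    batch returns a list of them.
    """
    obj = np.asarray(obj, dtype=float)
    single = obj.ndim == 1
    x = np.atleast_2d(obj)
    alphas = _nonconformity_matrix(model.scorer, x)
    pvals = _pvalues_from_scores(model.calibration_scores, alphas)
    out = [PValueVector(labels=model.label_set.copy(), values=p) for p in pvals]
    return out[0] if single else out


def _stratified_bootstrap(labels: np.ndarray, rng):
    """Per-class bootstrap draw of the full size; returns (in-bag, OOB)."""
    in_bag = []
    for lab in np.unique(labels):
        idx = np.nonzero(labels == lab)[0]
        in_bag.append(rng.choice(idx, size=idx.size, replace=True))
    in_bag = np.concatenate(in_bag)
    oob = np.setdiff1d(np.arange(labels.size), in_bag)
    return in_bag, oob


def acp_fit(
    table: FeatureTable,
    spec: UnderlyingModelSpec,
    K: int = 5,
    seed: int = 0,
    *,
    max_redraws: int = 20,
) -> ACPModel:
    """Fit an aggregated conformal predictor from K bootstrap ICPs.

    Each fold draws a stratified bootstrap of the full table size with
    replacement (duplicates retained for fitting) and calibrates on the
    out-of-bag examples.  A draw whose training part lacks a class or whose
    out-of-bag set is empty is redrawn up to ``max_redraws`` times.
    """
    if table.labels is None:
        raise ValueError("table must be labelled")
    if K < 1:
        raise ValueError("K must be at least 1")
    labels = np.asarray(table.labels)
    master = np.random.default_rng(seed)
    fold_seeds = master.integers(0, 2**31 - 1, size=K)
    folds = []
    for k in range(K):
        rng = np.random.default_rng(int(fold_seeds[k]))
        for _ in range(max_redraws):
            in_bag, oob = _stratified_bootstrap(labels, rng)
            if oob.size >= 1 and np.unique(labels[in_bag]).size >= 2:
                break
        else:
            raise ValueError(
                f"fold {k}: could not draw a bootstrap with a non-empty "
                f"out-of-bag set in {max_redraws} attempts"
            )
        fold_spec = UnderlyingModelSpec(
            kind=spec.kind,
            C=spec.C,
            gamma=spec.gamma,
            n_trees=spec.n_trees,
            standardize=spec.standardize,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scorer = fit_underlying(table.subset(in_bag), fold_spec)
        cal_scores = _true_label_scores(scorer, table.values[oob], labels[oob])
        folds.append(
            ICPModel(
                scorer=scorer,
                calibration_scores=cal_scores,
                label_set=scorer.label_set,
            )
        )
    return ACPModel(folds=folds, K=K)


def acp_pvalues(model: ACPModel, obj: np.ndarray) -> PValueVector | list:
    """Aggregated p-values: the arithmetic mean of the K fold ICP p-values."""
    obj = np.asarray(obj, dtype=float)
    single = obj.ndim == 1
    x = np.atleast_2d(obj)
    stacked = np.zeros((x.shape[0], model.label_set.size))
    for fold in model.folds:
        alphas = _nonconformity_matrix(fold.scorer, x)
        stacked += _pvalues_from_scores(fold.calibration_scores, alphas)
    stacked /= model.K
    out = [PValueVector(labels=model.label_set.copy(), values=p) for p in stacked]
    return out[0] if single else out


def prediction_region(pvals: PValueVector, epsilon: float) -> list:
    """Labels whose p-value strictly exceeds the significance level."""
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must be in (0, 1)")
    return [lab for lab, p in zip(pvals.labels, pvals.values) if p > epsilon]


def forced_prediction(pvals: PValueVector):
    """The single label with the highest p-value (ties: lowest label index)."""
    if len(pvals) == 0:
        raise ValueError("empty p-value vector")
    best = int(np.argmax(pvals.values))
    ties = np.nonzero(pvals.values == pvals.values[best])[0]
    if ties.size > 1:
        logger.info(
            "forced prediction tie among labels %s; choosing %s",
            pvals.labels[ties].tolist(),
            pvals.labels[best],
        )
    return pvals.labels[best]


def confidence_credibility(pvals: PValueVector) -> tuple[float, float]:
    """(confidence, credibility) of a prediction.

    Credibility is the highest p-value — near zero flags an atypical test
    object.  Confidence is 1 minus the second-highest p-value — high
    confidence means every alternative label conforms poorly.
    """
    if len(pvals) < 2:
        raise ValueError("need at least 2 candidate labels")
    top_two = np.sort(pvals.values)[-2:]
    credibility = float(top_two[1])
    confidence = float(1.0 - top_two[0])
    return confidence, credibility
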