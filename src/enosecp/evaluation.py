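"""Evaluation protocol for conformal e-nose classifiers.

Stratified k-fold cross-validation produces one p-value vector per specimen
(each specimen is a test case exactly once).  From those p-values the module
derives forced-choice accuracy, the calibration (validity) curve of error
rate versus significance level, the efficiency curve of mean prediction-set
size, and summary statistics of the per-prediction confidence and
credibility indicators.  A thin PCA projection supports 2-D visualisation
of the feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from enosecp.conformal import (
    ACPModel,
    PValueVector,
    UnderlyingModelSpec,
    acp_fit,
    acp_pvalues,
    confidence_credibility,
    forced_prediction,
    icp_fit,
    icp_pvalues,
)
from enosecp.features import FeatureTable

__all__ = [
    "CVResult",
    "default_epsilon_grid",
    "cross_validate",
    "accuracy_forced",
    "calibration_curve",
    "efficiency_curve",
    "summarize_indicators",
    "pca_projection",
]

logger = logging.getLogger(__name__)


def default_epsilon_grid() -> np.ndarray:
    """Significance levels 0.01 .. 0.99 in steps of 0.01."""
    return np.round(np.arange(0.01, 1.0, 0.01), 2)


@dataclass
class CVResult:
    """Per-test-sample p-values collected across cross-validation folds."""

    true_labels: np.ndarray
    pvalues: np.ndarray  # [n_samples x n_labels]
    fold_index: np.ndarray
    label_set: np.ndarray
    predictor_id: str

    def __post_init__(self) -> None:
        n = self.true_labels.shape[0]
        if self.pvalues.shape != (n, self.label_set.size):
            raise ValueError("pvalues shape must be [n_samples x n_labels]")
        if self.fold_index.shape[0] != n:
            raise ValueError("fold_index length must match samples")

    @property
    def n_samples(self) -> int:
        return self.true_labels.shape[0]

    def pvalue_vectors(self) -> list[PValueVector]:
        return [
            PValueVector(labels=self.label_set.copy(), values=row)
            for row in self.pvalues
        ]

    def true_label_pvalues(self) -> np.ndarray:
        col = np.searchsorted(self.label_set, self.true_labels)
        return self.pvalues[np.arange(self.n_samples), col]

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.pvalues, columns=[f"p_{lab}" for lab in self.label_set]
        )
        frame.insert(0, "fold", self.fold_index)
        frame.insert(0, "true_label", self.true_labels)
        return frame


def cross_validate(
    table: FeatureTable,
    framework: str,
    spec: UnderlyingModelSpec,
    n_folds: int = 10,
    seed: int = 0,
    *,
    calib_fraction: float = 1 / 3,
    K: int = 5,
) -> CVResult:
    """Stratified k-fold cross-validated conformal p-values.

    For each fold, an ICP (internal train/calibration split) or ACP
    (K bootstrap ICPs) is built on the other folds and queried on the held
    out specimens.  Folds are stratified so per-class counts differ by at
    most one, and the assignment is reproducible from the seed.
    """
    if framework not in ("icp", "acp"):
        raise ValueError(f"unknown framework {framework!r}")
    if table.labels is None:
        raise ValueError("table must be labelled")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    labels = np.asarray(table.labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"every class needs at least {n_folds} samples for {n_folds}-fold CV"
        )
    master = np.random.default_rng(seed)
    skf = StratifiedKFold(
        n_splits=n_folds, shuffle=True, random_state=int(master.integers(2**31 - 1))
    )
    label_set = np.unique(labels)
    pvalues = np.zeros((labels.size, label_set.size))
    fold_index = np.zeros(labels.size, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(table.values, labels)):
        fold_seed = int(master.integers(2**31 - 1))
        train = table.subset(train_idx)
        if framework == "icp":
            model = icp_fit(train, spec, calib_fraction=calib_fraction, seed=fold_seed)
            vecs = icp_pvalues(model, table.values[test_idx])
        else:
            model = acp_fit(train, spec, K=K, seed=fold_seed)
            vecs = acp_pvalues(model, table.values[test_idx])
        for i, vec in zip(test_idx, vecs):
            pvalues[i] = vec.values
            fold_index[i] = fold
        logger.info(
            "fold %d/%d: %d train, %d test", fold + 1, n_folds, train_idx.size,
            test_idx.size,
        )
    return CVResult(
        true_labels=labels.copy(),
        pvalues=pvalues,
        fold_index=fold_index,
        label_set=label_set,
        predictor_id=f"{framework}-{spec.kind}",
    )


def accuracy_forced(result: CVResult) -> dict:
    """Forced-choice accuracy: highest-p-value label versus the truth.

    Returns overall accuracy plus per-fold accuracies and their mean, the
    conventional cross-validation summary.
    """
    if result.n_samples == 0:
        raise ValueError("empty result")
    forced = result.label_set[np.argmax(result.pvalues, axis=1)]
    correct = forced == result.true_labels
    per_fold = []
    for fold in np.unique(result.fold_index):
        mask = result.fold_index == fold
        per_fold.append(float(correct[mask].mean()))
    return {
        "overall": float(correct.mean()),
        "per_fold": per_fold,
        "fold_mean": float(np.mean(per_fold)),
    }


def calibration_curve(
    result: CVResult, epsilon_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Empirical error rate of the prediction region at each significance level.

    An error at level epsilon is a region that excludes the true label,
    i.e. the true label's p-value is <= epsilon.  A valid predictor keeps
    the curve at or below the diagonal.
    """
    if epsilon_grid is None:
        epsilon_grid = default_epsilon_grid()
    p_true = result.true_label_pvalues()
    rows = [
        {"epsilon": float(eps), "error_rate": float(np.mean(p_true <= eps))}
        for eps in epsilon_grid
    ]
    return pd.DataFrame(rows)


def efficiency_curve(
    result: CVResult, epsilon_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Mean prediction-set size at each significance level (smaller = better)."""
    if epsilon_grid is None:
        epsilon_grid = default_epsilon_grid()
    rows = [
        {
            "epsilon": float(eps),
            "mean_set_size": float(np.mean((result.pvalues > eps).sum(axis=1))),
        }
        for eps in epsilon_grid
    ]
    return pd.DataFrame(rows)


def summarize_indicators(result: CVResult) -> pd.DataFrame:
    """Mean and SD of per-sample confidence and credibility."""
    if result.n_samples == 0:
        raise ValueError("empty result")
    conf, cred = [], []
    for vec in result.pvalue_vectors():
        c, r = confidence_credibility(vec)
        conf.append(c)
        cred.append(r)
    if result.n_samples == 1:
        logger.info("single sample: reporting SD = 0 by convention")
    return pd.DataFrame(
        {
            "indicator": ["confidence", "credibility"],
            "mean": [float(np.mean(conf)), float(np.mean(cred))],
            "sd": [float(np.std(conf)), float(np.std(cred))],
        }
    )


def pca_projection(
    table: FeatureTable, n_components: int = 2, *, standardize: bool = False
) -> dict:
    """Mean-centred PCA of the feature table for 2-D visualisation.

    Returns the projected scores, per-component variances, and the fraction
    of total variance each component explains.
    """
    if table.n_rows == 0:
        raise ValueError("empty table")
    if n_components > table.n_features:
        raise ValueError("n_components exceeds feature count")
    x = table.values
    if standardize:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(x)
    return {
        "scores": scores,
        "variance": pca.explained_variance_,
        "variance_fraction": pca.explained_variance_ratio_,
        "labels": table.labels,
    }
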