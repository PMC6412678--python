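"""Shared fixtures: small synthetic tables, fast model specs, and helpers."""

import numpy as np
import pytest

from enosecp.conformal import FittedScorer, UnderlyingModelSpec
from enosecp.synthetic import TimingConfig, make_signatures, simulate_feature_table


@pytest.fixture
def fast_timing():
    """Short, low-rate measurement cycle for cheap signal simulation."""
    return TimingConfig(
        sampling_rate=2.0,
        baseline_duration=4.0,
        reaction_duration=10.0,
        cleaning_duration=6.0,
    )


@pytest.fixture
def small_signatures():
    return make_signatures(3, 4, separation=1.0, seed=11)


@pytest.fixture
def small_table():
    """Well-separated 3-class table, 15 rows per class, 10 features."""
    return simulate_feature_table(3, 15, n_features=10, separation=2.0, seed=5)


@pytest.fixture
def rf_small():
    """Small random forest spec for unit tests where tree count is not at issue."""
    return UnderlyingModelSpec(kind="random_forest", n_trees=50, seed=0)


class _TableScorer:
    """predict_proba stub: object's first coordinate indexes a probability row."""

    def __init__(self, prob_table, classes):
        self.prob_table = np.asarray(prob_table, dtype=float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, x):
        idx = np.asarray(x)[:, 0].astype(int)
        return self.prob_table[idx]


def stub_scorer(prob_table, classes) -> FittedScorer:
    """A FittedScorer whose probabilities are read from a fixed table."""
    return FittedScorer(
        estimator=_TableScorer(prob_table, classes),
        label_set=np.asarray(classes),
    )
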