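"""Conformal machinery: p-values vs brute force, aggregation, regions, indicators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enosecp.conformal import (
    ICPModel,
    PValueVector,
    UnderlyingModelSpec,
    _stratified_bootstrap,
    acp_fit,
    acp_pvalues,
    confidence_credibility,
    fit_underlying,
    forced_prediction,
    icp_fit,
    icp_pvalues,
    nonconformity,
    prediction_region,
)
from enosecp.synthetic import simulate_feature_table

from conftest import stub_scorer


def brute_force_pvalue(cal_scores, alpha):
    """Independent counting oracle for the conformal p-value."""
    count = sum(1 for a in cal_scores if a >= alpha)
    return (count + 1) / (len(cal_scores) + 1)


class TestNonconformity:
    def test_complements_probability(self):
        scorer = stub_scorer([[1.0, 0.0], [0.0, 1.0], [0.813, 0.187]], [0, 1])
        assert nonconformity(scorer, [2.0], 0) == pytest.approx(0.187)
        assert nonconformity(scorer, [0.0], 0) == 0.0
        assert nonconformity(scorer, [1.0], 0) == 1.0

    def test_unknown_label_rejected(self):
        scorer = stub_scorer([[0.5, 0.5]], [0, 1])
        with pytest.raises(ValueError, match="unknown label"):
            nonconformity(scorer, [0.0], 9)


class TestICPPValues:
    def _model(self, cal_scores, prob_table, classes):
        return ICPModel(
            scorer=stub_scorer(prob_table, classes),
            calibration_scores=np.asarray(cal_scores, float),
            label_set=np.asarray(classes),
        )

    def test_hand_counted_example(self):
        # alpha for label 0 is 1 - 0.75 = 0.25; cal scores [0.1, 0.2, 0.3]
        model = self._model([0.1, 0.2, 0.3], [[0.75, 0.25]], [0, 1])
        pv = icp_pvalues(model, np.array([0.0]))
        assert pv.p_of(0) == pytest.approx(2 / 4)

    def test_most_conforming_object_gets_pvalue_one(self):
        model = self._model([0.1, 0.2, 0.3], [[1.0, 0.0]], [0, 1])
        assert icp_pvalues(model, np.array([0.0])).p_of(0) == 1.0

    def test_floor_for_maximally_nonconforming_object(self):
        model = self._model([0.1, 0.2, 0.3], [[1.0, 0.0]], [0, 1])
        # label 1 has probability 0 => alpha = 1 >= all scores... inclusive tie
        assert icp_pvalues(model, np.array([0.0])).p_of(1) == pytest.approx(1 / 4)

    @settings(derandomize=True, max_examples=200)
    @given(
        cal=st.lists(
            st.sampled_from([i / 10 for i in range(11)]), min_size=1, max_size=20
        ),
        alphas=st.tuples(
            st.sampled_from([i / 10 for i in range(11)]),
            st.sampled_from([i / 10 for i in range(11)]),
        ),
    )
    def test_matches_brute_force_with_ties(self, cal, alphas):
        probs = [[1 - alphas[0], 1 - alphas[1]]]
        # normalise is irrelevant: each label's alpha read independently
        model = self._model(cal, probs, [0, 1])
        pv = icp_pvalues(model, np.array([0.0]))
        for lab, alpha in zip([0, 1], alphas):
            # the model sees alpha = 1 - p(label); feed the oracle the same
            # value so exact ties are counted identically
            realized = 1.0 - probs[0][lab]
            assert pv.p_of(lab) == pytest.approx(brute_force_pvalue(cal, realized))


class TestFitting:
    def test_icp_split_counts_are_stratified(self, small_table, rf_small):
        model = icp_fit(small_table, rf_small, calib_fraction=1 / 3, seed=0)
        # 45 rows, one third of each class of 15 -> 15 calibration scores
        assert model.n_calibration == 15
        assert np.all((model.calibration_scores >= 0) & (model.calibration_scores <= 1))

    def test_same_seed_reproduces_scores_and_pvalues(self, small_table, rf_small):
        a = icp_fit(small_table, rf_small, seed=3)
        b = icp_fit(small_table, rf_small, seed=3)
        np.testing.assert_array_equal(a.calibration_scores, b.calibration_scores)
        x = small_table.values[:5]
        pa, pb = icp_pvalues(a, x), icp_pvalues(b, x)
        for va, vb in zip(pa, pb):
            np.testing.assert_array_equal(va.values, vb.values)

    def test_single_class_training_rejected(self, small_table, rf_small):
        one_class = small_table.subset(small_table.labels == 0)
        with pytest.raises(ValueError):
            fit_underlying(one_class, rf_small)

    def test_svm_spec_defaults_match_study_settings(self):
        spec = UnderlyingModelSpec()
        assert spec.kind == "svm_rbf"
        assert (spec.C, spec.gamma, spec.n_trees) == (6000.0, 0.001, 500)

    def test_rf_tree_count_reaches_estimator(self, small_table):
        spec = UnderlyingModelSpec(kind="random_forest", n_trees=500, seed=0)
        scorer = fit_underlying(small_table, spec)
        assert scorer.estimator.n_estimators == 500

    def test_separable_classes_get_confident_scores(self, small_table, rf_small):
        scorer = fit_underlying(small_table, rf_small)
        probs = scorer.class_probabilities(small_table.values)
        pred = scorer.label_set[np.argmax(probs, axis=1)]
        assert np.mean(pred == small_table.labels) > 0.95


class TestACP:
    def test_k_folds_built_and_k1_matches_single_icp(self, small_table, rf_small):
        model = acp_fit(small_table, rf_small, K=5, seed=1)
        assert model.K == 5 and len(model.folds) == 5
        single = acp_fit(small_table, rf_small, K=1, seed=2)
        x = small_table.values[0]
        np.testing.assert_allclose(
            acp_pvalues(single, x).values,
            icp_pvalues(single.folds[0], x).values,
            rtol=0, atol=0,
        )

    def test_aggregation_is_mean_of_fold_pvalues(self, small_table, rf_small):
        model = acp_fit(small_table, rf_small, K=4, seed=5)
        x = small_table.values[:6]
        agg = acp_pvalues(model, x)
        fold_ps = [icp_pvalues(f, x) for f in model.folds]
        for i, vec in enumerate(agg):
            manual = np.mean([fp[i].values for fp in fold_ps], axis=0)
            np.testing.assert_allclose(vec.values, manual, atol=1e-12)

    def test_oob_fraction_approaches_e_inverse(self):
        """Bootstrap leaves ~36.8% of examples out-of-bag for large classes."""
        labels = np.repeat([0, 1], 100)
        rng = np.random.default_rng(0)
        fracs = [
            _stratified_bootstrap(labels, rng)[1].size / labels.size
            for _ in range(60)
        ]
        expected = (1 - 1 / 100) ** 100
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - expected) < 3 * se

    def test_k_zero_rejected(self, small_table, rf_small):
        with pytest.raises(ValueError):
            acp_fit(small_table, rf_small, K=0, seed=0)


class TestRegionsAndIndicators:
    def test_region_keeps_only_labels_above_epsilon(self):
        pv = PValueVector(labels=np.array([1, 2, 3]),
                          values=np.array([0.007, 0.009, 0.813]))
        assert prediction_region(pv, 0.05) == [3]
        assert prediction_region(pv, 0.9) == []
        assert prediction_region(pv, 0.001) == [1, 2, 3]

    def test_epsilon_out_of_range_rejected(self):
        pv = PValueVector(labels=np.array([0, 1]), values=np.array([0.2, 0.4]))
        with pytest.raises(ValueError):
            prediction_region(pv, 0.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        values=st.lists(
            st.floats(min_value=0.001, max_value=1.0), min_size=2, max_size=10
        ),
        e1=st.floats(min_value=0.01, max_value=0.98),
        e2=st.floats(min_value=0.01, max_value=0.98),
    )
    def test_regions_are_nested_in_epsilon(self, values, e1, e2):
        lo, hi = sorted([e1, e2])
        pv = PValueVector(labels=np.arange(len(values)), values=np.array(values))
        assert set(prediction_region(pv, hi)) <= set(prediction_region(pv, lo))

    def test_forced_prediction_argmax_and_tie_break(self):
        pv = PValueVector(labels=np.array([1, 2]), values=np.array([0.5, 0.5]))
        assert forced_prediction(pv) == 1
        pv = PValueVector(labels=np.array([7]), values=np.array([0.2]))
        assert forced_prediction(pv) == 7

    def test_forced_label_is_last_to_leave_region(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0.05, 0.95, size=6)
        pv = PValueVector(labels=np.arange(6), values=values)
        survivors = None
        for eps in np.linspace(0.01, 0.99, 197):
            region = prediction_region(pv, eps)
            if region:
                survivors = region
        assert survivors == [forced_prediction(pv)]

    def test_confidence_credibility_definitions(self):
        pv = PValueVector(labels=np.arange(3), values=np.array([0.1, 0.8, 0.05]))
        conf, cred = confidence_credibility(pv)
        assert conf == pytest.approx(0.9)
        assert cred == pytest.approx(0.8)
        with pytest.raises(ValueError):
            confidence_credibility(
                PValueVector(labels=np.array([0]), values=np.array([0.3]))
            )


def test_icp_validity_on_exchangeable_data():
    """Held-out error rate stays below epsilon plus 3 binomial SE."""
    tab = simulate_feature_table(4, 60, n_features=10, separation=0.3, seed=9)
    train = tab.subset(np.arange(160))
    test = tab.subset(np.arange(160, 240))
    model = icp_fit(
        train, UnderlyingModelSpec(kind="random_forest", n_trees=50, seed=0), seed=0
    )
    vecs = icp_pvalues(model, test.values)
    p_true = np.array([v.p_of(lab) for v, lab in zip(vecs, test.labels)])
    for eps in np.arange(0.05, 1.0, 0.05):
        err = np.mean(p_true <= eps)
        assert err <= eps + 3 * np.sqrt(eps * (1 - eps) / p_true.size)
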