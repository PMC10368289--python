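"""Generative-inference pipeline: prior, training set, forest, importance."""

import numpy as np
import pandas as pd
import pytest

from agedrift.classifier import (LABEL_BIASED, LABEL_UNBIASED,
                                 ClassifierBundle, PriorSpec,
                                 build_training_set, classify,
                                 classify_profiles, draw_training_params,
                                 permutation_importance, train_classifier)
from agedrift.core import ALL, ParameterError
from agedrift.diversity import DEFAULT_Q_GRID, DiversityProfile


def _synthetic_training(n_rows, rng, informative=True, n=100):
    """Labeled 13-feature rows; label = indicator of q0 > threshold when
    informative, otherwise independent of all features."""
    feats = [f"q{q:g}" for q in DEFAULT_Q_GRID]
    X = rng.normal(10.0, 2.0, size=(n_rows, 13))
    X = np.sort(X, axis=1)[:, ::-1]          # profiles decrease in q
    if informative:
        y = X[:, 0] > np.median(X[:, 0])
    else:
        y = rng.random(n_rows) < 0.5
    df = pd.DataFrame(X, columns=feats)
    df["label"] = np.where(y, LABEL_BIASED, LABEL_UNBIASED)
    df["n"] = n
    return df


class TestPrior:
    def test_invalid_priors_rejected(self):
        with pytest.raises(ParameterError):
            PriorSpec(b_sd=0.0)
        with pytest.raises(ParameterError):
            PriorSpec(mu_range=(1e-3, 1e-3))
        with pytest.raises(ParameterError):
            PriorSpec(unbiased_fraction=1.0)

    def test_draws_respect_ranges_and_label_rule(self, rng):
        prior = PriorSpec()
        n_unbiased = 0
        draws = 400
        for _ in range(draws):
            params, label = draw_training_params(prior, rng, N=2000)
            assert 1e-5 <= params.mu <= 1e-3
            assert 0.02 <= params.p_death <= 0.1
            assert params.c_thresh == ALL or params.c_thresh >= 1
            if label == LABEL_UNBIASED:
                assert params.b == 0.0
                n_unbiased += 1
            else:
                assert abs(params.b) >= prior.b_min
        se = np.sqrt(0.25 / draws)
        assert n_unbiased / draws == pytest.approx(0.5, abs=4 * se)

    def test_unbiased_fraction_one_sided(self, rng):
        prior = PriorSpec(unbiased_fraction=0.999)
        labels = {draw_training_params(prior, rng, N=500)[1] for _ in range(50)}
        assert labels == {LABEL_UNBIASED}


class TestTrainingSet:
    def test_construction_shape_and_richness_bound(self, rng):
        df = build_training_set(PriorSpec(), n_examples=100, sample_size=50,
                                N=300, rng=rng)
        assert len(df) == 100
        assert set(df["label"]) <= {LABEL_BIASED, LABEL_UNBIASED}
        q0 = df["q0"].to_numpy()
        assert np.all(q0 == np.round(q0)) and q0.max() <= 50

    def test_rejects_oversized_sample(self, rng):
        with pytest.raises(ParameterError):
            build_training_set(PriorSpec(), 100, sample_size=500, N=300, rng=rng)

    def test_reproducible_with_same_seed(self):
        a = build_training_set(PriorSpec(), 100, 30, N=200,
                               rng=np.random.default_rng(3))
        b = build_training_set(PriorSpec(), 100, 30, N=200,
                               rng=np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)


class TestForest:
    def test_separable_features_reach_high_heldout_accuracy(self, rng):
        df = _synthetic_training(600, rng)
        bundle = train_classifier(df, T=100, rng=rng)
        assert bundle.heldout_accuracy[100] > 0.95

    def test_single_class_training_set_rejected(self, rng):
        df = _synthetic_training(100, rng)
        df["label"] = LABEL_UNBIASED
        with pytest.raises(ParameterError, match="single class"):
            train_classifier(df, T=10, rng=rng)

    def test_single_tree_degenerates_but_predicts(self, rng):
        df = _synthetic_training(200, rng)
        bundle = train_classifier(df, T=1, rng=rng)
        prof = DiversityProfile(DEFAULT_Q_GRID, tuple(np.full(13, 10.0)), 100)
        label, vote = classify(bundle, prof)
        assert label in (LABEL_BIASED, LABEL_UNBIASED)
        assert vote in (0.0, 1.0)

    def test_prediction_is_majority_of_tree_votes(self, rng):
        df = _synthetic_training(300, rng)
        bundle = train_classifier(df, T=49, rng=rng)
        X = np.sort(rng.normal(10, 2, size=(20, 13)), axis=1)[:, ::-1]
        profiles = [DiversityProfile(DEFAULT_Q_GRID, tuple(row), 100) for row in X]
        labels, votes = classify_profiles(bundle, profiles)
        forest = bundle.forests[100]
        per_tree = np.vstack([t.predict(X) for t in forest.estimators_])
        assert np.allclose(votes, per_tree.mean(axis=0))
        assert all((v > 0.5) == (lab == LABEL_BIASED)
                   for v, lab in zip(votes, labels))

    def test_sample_size_mismatch_names_available_sizes(self, rng):
        bundle = train_classifier(_synthetic_training(200, rng), T=10, rng=rng)
        prof = DiversityProfile(DEFAULT_Q_GRID, tuple(np.full(13, 5.0)), 999)
        with pytest.raises(ParameterError, match="100"):
            classify(bundle, prof)

    def test_identical_seeds_give_identical_forests(self, rng):
        df = _synthetic_training(200, rng)
        b1 = train_classifier(df, T=20, rng=np.random.default_rng(5))
        b2 = train_classifier(df, T=20, rng=np.random.default_rng(5))
        X = df[[f"q{q:g}" for q in DEFAULT_Q_GRID]].to_numpy()
        assert np.array_equal(b1.forests[100].predict_proba(X),
                              b2.forests[100].predict_proba(X))

    def test_save_load_roundtrip(self, rng, tmp_path):
        df = _synthetic_training(200, rng)
        bundle = train_classifier(df, T=10, rng=rng)
        bundle.prior = PriorSpec().to_dict()
        bundle.save(tmp_path / "model")
        loaded = ClassifierBundle.load(tmp_path / "model")
        assert loaded.sample_sizes == [100]
        assert loaded.heldout_accuracy == bundle.heldout_accuracy


class TestPermutationImportance:
    def test_uninformative_feature_has_near_zero_importance(self, rng):
        df = _synthetic_training(800, rng)
        # make one feature pure i.i.d. noise, uncorrelated with the label
        df["q3"] = rng.normal(size=len(df))
        bundle = train_classifier(df, T=60, rng=rng)
        imp = permutation_importance(bundle, n_permutations=15, rng=rng)
        noise_row = imp[imp["feature"] == "q3"]["importance"].iloc[0]
        top_row = imp[imp["feature"] == "q0"]["importance"].iloc[0]
        assert abs(noise_row) < 0.02
        assert top_row > 0.05

    def test_shuffling_all_features_falls_to_majority_baseline(self, rng):
        df = _synthetic_training(800, rng)
        bundle = train_classifier(df, T=60, rng=rng)
        X, y = bundle.heldout[100]
        forest = bundle.forests[100]
        accs = []
        for _ in range(20):
            Xs = X.copy()
            for j in range(X.shape[1]):
                rng.shuffle(Xs[:, j])
            accs.append(forest.score(Xs, y))
        baseline = max(np.mean(y), 1 - np.mean(y))
        assert np.mean(accs) == pytest.approx(baseline, abs=0.1)
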