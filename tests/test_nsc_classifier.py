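"""Nearest-shrunken-centroid classifier and the rank-based AUC evaluator."""

import numpy as np
import pandas as pd
import pytest

from sigsubtype.errors import SigsubtypeError, UndefinedStatisticError
from sigsubtype.nsc_classifier import nsc_fit, nsc_predict, roc_auc


def brute_force_nearest_centroid(X_train, y_train, X_test, priors):
    """Standardized nearest-centroid rule, written independently of the model."""
    classes = sorted(set(y_train))
    K = len(classes)
    n, p = X_train.shape
    overall = X_train.mean(axis=0)
    cents, nk = [], []
    for c in classes:
        sub = X_train[np.array(y_train) == c]
        cents.append(sub.mean(axis=0))
        nk.append(len(sub))
    ss = np.zeros(p)
    for c, cent in zip(classes, cents):
        sub = X_train[np.array(y_train) == c]
        ss += ((sub - cent) ** 2).sum(axis=0)
    s = np.sqrt(ss / (n - K))
    s0 = np.median(s)
    preds = []
    for x in X_test:
        scores = [
            (((x - cent) / (s + s0)) ** 2).sum() - 2 * np.log(pi)
            for cent, pi in zip(cents, priors)
        ]
        preds.append(classes[int(np.argmin(scores))])
    return np.array(preds)


def _gaussian_classes(rng, n_per=50, p=20, n_informative=5, shift=4.0):
    X0 = rng.normal(0.0, 1.0, size=(n_per, p))
    X1 = rng.normal(0.0, 1.0, size=(n_per, p))
    X1[:, :n_informative] += shift
    X = np.vstack([X0, X1])
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return X, y


def test_zero_shrinkage_matches_brute_force_nearest_centroid(rng):
    X, y = _gaussian_classes(rng, n_per=30, shift=1.0)
    model = nsc_fit(X, y, delta_grid=[0.0], cv_folds=3, seed=0)
    assert model.delta == 0.0
    assert np.allclose(model.shrunken_centroids, model.class_centroids)
    X_new = rng.normal(0.0, 1.5, size=(40, X.shape[1]))
    preds = nsc_predict(model, X_new)["predicted"].to_numpy()
    expected = brute_force_nearest_centroid(X, y, X_new, model.priors)
    assert (preds == expected).all()


def test_full_shrinkage_degenerates_to_prior_argmax(rng):
    X, y = _gaussian_classes(rng, n_per=20)
    y[:30] = "a"  # unbalance the priors: 30 a vs 10 b
    huge = 1e6
    model = nsc_fit(X, y, delta_grid=[huge], cv_folds=3, seed=0)
    assert np.allclose(model.shrunken_centroids, model.overall_centroid[None, :])
    assert model.n_surviving_features() == 0
    preds = nsc_predict(model, rng.normal(size=(25, X.shape[1])))
    assert (preds["predicted"] == "a").all()  # the majority class


def test_planted_features_selected_and_high_accuracy(rng):
    X, y = _gaussian_classes(rng, n_per=100, p=20, n_informative=5, shift=4.0)
    Xh, yh = _gaussian_classes(rng, n_per=100, p=20, n_informative=5, shift=4.0)
    model = nsc_fit(X, y, cv_folds=10, seed=1)
    preds = nsc_predict(model, Xh)["predicted"].to_numpy()
    assert (preds == yh).mean() >= 0.95
    contrast = np.abs(model.shrunken_centroids - model.overall_centroid[None, :])
    shrunk_null = (contrast[:, 5:] == 0).all(axis=0).sum()
    assert shrunk_null >= 10  # >= 10 of the 15 pure-noise features removed


def test_surviving_features_non_increasing_in_delta(rng):
    X, y = _gaussian_classes(rng, n_per=40)
    model = nsc_fit(X, y, delta_grid=[0.0], cv_folds=3, seed=0)
    counts = [model.n_surviving_features(d) for d in np.linspace(0, 5, 25)]
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_posteriors_sum_to_one_and_match_argmin(rng):
    X, y = _gaussian_classes(rng, n_per=30)
    model = nsc_fit(X, y, cv_folds=3, seed=2)
    preds = nsc_predict(model, rng.normal(size=(20, X.shape[1])))
    posts = preds[[f"posterior_{c}" for c in model.class_labels]].to_numpy()
    assert np.allclose(posts.sum(axis=1), 1.0)
    by_post = np.array(model.class_labels)[np.argmax(posts, axis=1)]
    assert (preds["predicted"].to_numpy() == by_post).all()


def test_centroid_input_predicts_its_own_class(rng):
    X, y = _gaussian_classes(rng, n_per=30)
    model = nsc_fit(X, y, cv_folds=3, seed=0, priors="uniform")
    preds = nsc_predict(model, model.shrunken_centroids)
    assert list(preds["predicted"]) == model.class_labels


def test_equidistant_point_ties_to_first_label_with_half_posteriors(rng):
    X, y = _gaussian_classes(rng, n_per=30)
    model = nsc_fit(X, y, cv_folds=3, seed=0, priors="uniform")
    midpoint = model.shrunken_centroids.mean(axis=0)
    preds = nsc_predict(model, midpoint[None, :])
    assert preds["predicted"].iloc[0] == model.class_labels[0]
    assert preds["posterior_a"].iloc[0] == pytest.approx(0.5, abs=1e-9)


def test_feature_permutation_invariance(rng):
    X, y = _gaussian_classes(rng, n_per=30)
    names = [f"f{i}" for i in range(X.shape[1])]
    model = nsc_fit(pd.DataFrame(X, columns=names), y, cv_folds=3, seed=0)
    X_new = pd.DataFrame(rng.normal(size=(15, X.shape[1])), columns=names)
    base = nsc_predict(model, X_new)["predicted"]
    permuted = X_new[rng.permutation(names)]
    assert (nsc_predict(model, permuted)["predicted"] == base).all()


def test_missing_feature_raises(rng):
    X, y = _gaussian_classes(rng, n_per=20)
    names = [f"f{i}" for i in range(X.shape[1])]
    model = nsc_fit(pd.DataFrame(X, columns=names), y, cv_folds=3, seed=0)
    with pytest.raises(SigsubtypeError, match="f0"):
        nsc_predict(model, pd.DataFrame(np.ones((2, 3)), columns=["f1", "f2", "f3"]))


def test_model_json_round_trip(tmp_path, rng):
    from sigsubtype.nsc_classifier import ShrunkenCentroidModel

    X, y = _gaussian_classes(rng, n_per=25)
    model = nsc_fit(X, y, cv_folds=3, seed=0)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = ShrunkenCentroidModel.from_json(path)
    X_new = rng.normal(size=(10, X.shape[1]))
    assert (
        nsc_predict(loaded, X_new)["predicted"] == nsc_predict(model, X_new)["predicted"]
    ).all()


def test_classifier_transfers_across_simulated_cohorts(small_cohort, small_cs, small_retained, signatures):
    """Train on one simulated cohort, classify an independent one."""
    from sigsubtype.signature_space import build_cs_matrix
    from sigsubtype.synthetic_cohort import SimulationConfig, simulate_cohort

    model = nsc_fit(
        small_cs[small_retained.retained],
        small_cohort.truth["true_subtype"].to_numpy(),
        seed=0,
    )
    external = simulate_cohort(SimulationConfig(n_samples=200, seed=555), signatures=signatures)
    cs_ext = build_cs_matrix(external.spectra, signatures)[small_retained.retained]
    preds = nsc_predict(model, cs_ext)
    agreement = (preds["predicted"].to_numpy() == external.truth["true_subtype"].to_numpy()).mean()
    assert agreement >= 0.9


def test_cross_cohort_auc_robust_to_burden_and_exposure_shifts(small_cohort, small_cs, small_retained, signatures):
    """Posterior AUC >= 0.85 on five shifted external cohorts."""
    from sigsubtype.signature_space import build_cs_matrix
    from sigsubtype.synthetic_cohort import SimulationConfig, simulate_cohort

    model = nsc_fit(
        small_cs[small_retained.retained],
        small_cohort.truth["true_subtype"].to_numpy(),
        seed=0,
    )
    for i, (burden, bump) in enumerate(
        [(100.0, 0.0), (40.0, 0.0), (250.0, 0.0), (80.0, 0.05), (150.0, 0.05)]
    ):
        means = {
            "MUT1": {"SBS2": 0.35 - bump, "SBS13": 0.35, "SBS5": 0.20 + bump, "SBS1": 0.10},
            "MUT2": {"SBS1": 0.30, "SBS6": 0.25 - bump, "SBS15": 0.20, "SBS87": 0.15, "SBS5": 0.10 + bump},
        }
        cfg = SimulationConfig(
            n_samples=80, seed=900 + i, mutation_count_median=burden, exposure_means=means
        )
        cohort = simulate_cohort(cfg, signatures=signatures)
        cs = build_cs_matrix(cohort.spectra, signatures)[small_retained.retained]
        preds = nsc_predict(model, cs)
        truth = (cohort.truth["true_subtype"] == "MUT2").astype(int).to_numpy()
        assert roc_auc(preds["posterior_MUT2"].to_numpy(), truth) >= 0.85


def test_auc_hand_case_and_limits(rng):
    assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert roc_auc([0.0, 0.1, 0.9, 1.0], [0, 0, 1, 1]) == 1.0
    scores = rng.random(4000)
    truth = rng.integers(0, 2, size=4000)
    assert roc_auc(scores, truth) == pytest.approx(0.5, abs=0.05)


def test_auc_matches_sklearn_with_ties(rng):
    from sklearn.metrics import roc_auc_score

    scores = rng.integers(0, 5, size=200).astype(float)  # heavy ties -> midranks
    truth = rng.integers(0, 2, size=200)
    assert roc_auc(scores, truth) == pytest.approx(roc_auc_score(truth, scores), abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(UndefinedStatisticError):
        roc_auc([0.1, 0.2], [1, 1])
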