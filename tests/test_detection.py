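"""Step-1 protocol: balancing, tuning, cross-validation, learning curves,
deployment detection."""

import numpy as np
import pandas as pd
import pytest

from conftest import gaussian_clouds
from hfopipe.detection import (LOG_GRID, balance_binary,
                               crossval_detect, detect, hyperparameter_grid,
                               learning_curve, make_estimator,
                               split_tuning_holdout, train_detector, tune)
from hfopipe.errors import ImbalanceError, SizeError, StratificationError
from hfopipe.features import WindowSpec
from hfopipe.io import Recording
from hfopipe.synth import GeneratorConfig, generate_recording


def _binary_frame(rng, n_pos, n_neg, sep=4.0, scale=1.0):
    return gaussian_clouds(
        rng, {"R": np.array([sep]), "noHFO": np.array([0.0])},
        {"R": n_pos, "noHFO": n_neg}, scale=scale)


def test_grid_definitions():
    assert hyperparameter_grid("lda") == [{}]
    assert len(LOG_GRID) == 13 and LOG_GRID[0] == 1e-3 and LOG_GRID[-1] == 1e3
    assert len(hyperparameter_grid("knn")) == 20
    assert len(hyperparameter_grid("rf")) == 2 * 3 * 3 * 3


def test_balance_binary_counts_and_determinism():
    rng = np.random.default_rng(0)
    table = _binary_frame(rng, 100, 900)
    out = balance_binary(table, seed=3)
    assert len(out) == 200
    assert (out["label"] != "noHFO").sum() == 100
    out2 = balance_binary(table, seed=3)
    pd.testing.assert_frame_equal(out, out2)
    assert not out.equals(balance_binary(table, seed=4))


def test_balance_binary_failure_modes():
    rng = np.random.default_rng(0)
    with pytest.raises(ImbalanceError, match="50 noHFO rows < 100"):
        balance_binary(_binary_frame(rng, 100, 50), seed=0)
    with pytest.raises(ImbalanceError, match="no HFO"):
        balance_binary(_binary_frame(rng, 0, 50), seed=0)


def test_split_tuning_holdout_stratified_arithmetic():
    rng = np.random.default_rng(1)
    table = _binary_frame(rng, 100, 100)
    tuning, dev = split_tuning_holdout(table, 0.30, seed=0)
    assert len(tuning) == 60 and len(dev) == 140
    assert (tuning["label"] != "noHFO").sum() == 30
    assert (dev["label"] != "noHFO").sum() == 70
    # disjoint and exhaustive on the feature rows
    key = "band80_250_line_length"
    union = np.sort(np.concatenate([tuning[key], dev[key]]))
    assert np.array_equal(union, np.sort(table[key].to_numpy()))


def test_split_fraction_zero():
    rng = np.random.default_rng(1)
    table = _binary_frame(rng, 10, 10)
    tuning, dev = split_tuning_holdout(table, 0.0, seed=0)
    assert tuning.empty and len(dev) == len(table)


def test_tune_lda_no_search():
    assert tune("lda", pd.DataFrame(), seed=0)[0] == {}


def test_tune_separable_svm_perfect_auc_and_simplicity_tie():
    rng = np.random.default_rng(2)
    table = _binary_frame(rng, 60, 60, sep=20.0, scale=0.2)
    params, score = tune("svm", table, seed=0)
    assert score == pytest.approx(1.0)
    assert params["C"] == LOG_GRID[0]  # ties resolve to heaviest regularization
    params_knn, score_knn = tune("knn", table, seed=0)
    assert score_knn == pytest.approx(1.0)
    assert params_knn["n_neighbors"] == 20  # smoothest model wins the tie


def test_crossval_separable_all_families():
    rng = np.random.default_rng(3)
    table = _binary_frame(rng, 100, 100, sep=8.0)
    for family in ("lda", "lr", "svm", "knn", "rf"):
        params = {"n_neighbors": 5} if family == "knn" else (
            {"C": 1.0} if family in ("lr", "svm") else
            {"n_estimators": 100, "max_depth": 5, "min_samples_split": 2,
             "min_samples_leaf": 1} if family == "rf" else {})
        m = crossval_detect(table, family, params, seed=0)
        assert m.mean_auc >= 0.99, family
        assert len(m.auc) == 5
    # perfectly separable LDA: sensitivity and specificity 1 at threshold
    m = crossval_detect(_binary_frame(rng, 60, 60, sep=30.0, scale=0.1),
                        "lda", {}, seed=0)
    assert m.mean_sensitivity == 1.0 and m.mean_specificity == 1.0


def test_crossval_null_band_on_permuted_labels():
    rng = np.random.default_rng(4)
    table = _binary_frame(rng, 200, 200, sep=0.0)  # no signal at all
    for family, params in (("lda", {}), ("knn", {"n_neighbors": 20})):
        m = crossval_detect(table, family, params, seed=0)
        assert 0.4 <= m.mean_auc <= 0.6, family


def test_crossval_confusion_consistency():
    rng = np.random.default_rng(5)
    table = _binary_frame(rng, 80, 80, sep=2.0)
    m = crossval_detect(table, "lda", {}, seed=0)
    for cm, sens, spec in zip(m.confusions, m.sensitivity, m.specificity):
        assert cm.sum() == 32  # 160 / 5 folds
        (tn, fp), (fn, tp) = cm
        assert sens == pytest.approx(tp / (tp + fn))
        assert spec == pytest.approx(tn / (tn + fp))
        assert (sens + spec) / 2 == pytest.approx(
            (tp / (tp + fn) + tn / (tn + fp)) / 2)


def test_crossval_single_class_fold_error():
    rng = np.random.default_rng(5)
    with pytest.raises(StratificationError):
        crossval_detect(_binary_frame(rng, 3, 200), "lda", {}, seed=0)


def test_auc_invariant_under_monotone_score_transform():
    """AUC depends only on score ranks: LDA AUC equals the AUC of any strictly
    monotone transform of its decision scores."""
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(6)
    table = _binary_frame(rng, 100, 100, sep=1.5)
    X = table.filter(like="band").to_numpy()
    y = (table["label"] != "noHFO").astype(int).to_numpy()
    model = make_estimator("lda", {}).fit(X, y)
    s = model.predict_proba(X)[:, 1]
    assert roc_auc_score(y, s) == pytest.approx(
        roc_auc_score(y, np.exp(5 * s) + 3), rel=1e-12)


def test_learning_curve_shapes_determinism_and_overfit_direction():
    rng = np.random.default_rng(7)
    table = _binary_frame(rng, 400, 400, sep=1.0)
    lc1 = learning_curve(table, "rf",
                         {"n_estimators": 100, "max_depth": 10,
                          "min_samples_split": 2, "min_samples_leaf": 1},
                         sizes=(100, 200, 400), seed=0)
    lc2 = learning_curve(table, "rf",
                         {"n_estimators": 100, "max_depth": 10,
                          "min_samples_split": 2, "min_samples_leaf": 1},
                         sizes=(100, 200, 400), seed=0)
    assert (lc1["train_auc_mean"] == lc2["train_auc_mean"]).all()
    assert (lc1["val_auc_mean"] == lc2["val_auc_mean"]).all()
    # flexible model on noisy data: train AUC above validation AUC
    assert (lc1["train_auc_mean"] > lc1["val_auc_mean"]).all()
    # well-specified linear model: generalization gap shrinks with n
    lda = learning_curve(table, "lda", {}, sizes=(100, 400), seed=0)
    gap = lda["train_auc_mean"] - lda["val_auc_mean"]
    assert gap.iloc[-1] <= gap.iloc[0] + 0.02
    with pytest.raises(SizeError):
        learning_curve(table, "lda", {}, sizes=(2000,), seed=0)


def test_detect_zero_recording_empty():
    rng = np.random.default_rng(8)
    trained = train_detector(_binary_frame(rng, 200, 600, sep=6.0), "lda",
                             seed=0)
    rec = Recording(np.zeros((1, 2000)), 2000.0, ["z"])
    out = detect(rec, trained)
    assert out.empty


def test_detect_recovers_high_snr_events_and_merges():
    """Deployment path: an LDA detector trained on a high-SNR synthetic
    subject finds >= 90% of annotated events, emitting merged intervals."""
    cfg = GeneratorConfig(duration=120.0, n_channels=2, event_snr=50.0, seed=13)
    rec, anns = generate_recording(cfg)
    from hfopipe.features import extract_features
    table = extract_features(rec, anns, WindowSpec(10))
    trained = train_detector(table, "lda", seed=0)
    out = detect(rec, trained)
    hits = 0
    for ev in anns:
        sub = out[out["channel"] == ev.channel_id]
        hits += bool(((sub["end_s"] > ev.start) & (sub["start_s"] < ev.end)).any())
    assert hits >= 0.90 * len(anns)
    # merged intervals: consecutive positives collapse, so within a channel no
    # two intervals touch
    for _, sub in out.groupby("channel"):
        s = sub.sort_values("start_s")
        assert (s["start_s"].iloc[1:].to_numpy()
                > s["end_s"].iloc[:-1].to_numpy() + 1e-12).all()
        assert ((s["end_s"] - s["start_s"]) >= 0.01 - 1e-12).all()
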