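"""Tri-algorithm selection, consensus, nested CV, bootstrap stability."""

import numpy as np
import pandas as pd
import pytest

from nettox.consensus import (
    FeatureMatrix,
    SelectionResult,
    bootstrap_stability,
    consensus_intersect,
    gbt_importance_select,
    l1_logistic_select,
    nested_cv,
    shadow_feature_select,
)


def make_fm(n=40, p_noise=10, shift=2.0, seed=0, signal_name="SIG"):
    """Balanced two-class matrix with one shifted signal feature."""
    rng = np.random.default_rng(seed)
    cols = [signal_name] + [f"N{i}" for i in range(p_noise)]
    X = pd.DataFrame(rng.normal(size=(n, p_noise + 1)), columns=cols)
    y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
    X.loc[y == 1, signal_name] += shift
    return FeatureMatrix(X, y)


def test_l1_selects_perfect_separator():
    fm = make_fm(shift=4.0, seed=1)
    res = l1_logistic_select(fm, 5, seed=1)
    assert "SIG" in res.selected
    assert res.scores["SIG"] == res.scores.max()


def test_l1_deterministic_and_scores_defined():
    fm = make_fm(seed=2)
    r1 = l1_logistic_select(fm, 5, seed=9)
    r2 = l1_logistic_select(fm, 5, seed=9)
    assert r1.selected == r2.selected
    assert r1.settings["lambda"] == r2.settings["lambda"]
    assert set(r1.scores.index) == set(fm.features)


def test_l1_null_selection_is_sparse():
    """All-noise features: mean selection stays near-empty.

    Frozen from a 100-seed simulation (mean 1.16 selected of 20 features,
    with a heavy upper tail); asserted with a 3-SE margin on these seeds.
    """
    counts = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(40, 20)), columns=[f"F{i}" for i in range(20)])
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        counts.append(len(l1_logistic_select(FeatureMatrix(X, y), 5, seed=seed).selected))
    assert np.mean(counts) <= 2.0


def test_gbt_step_function_feature_dominates():
    rng = np.random.default_rng(3)
    X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("ABCDE"))
    y = (X["C"] > 0).astype(int).to_numpy()
    res = gbt_importance_select(FeatureMatrix(X, y), n_rounds=50, seed=3)
    assert res.scores["C"] == res.scores.max()
    assert "C" in res.selected


def test_gbt_constant_features_give_empty_selection():
    X = pd.DataFrame(np.ones((20, 4)), columns=list("ABCD"))
    y = np.r_[np.ones(10, int), np.zeros(10, int)]
    res = gbt_importance_select(FeatureMatrix(X, y), n_rounds=20, seed=0)
    assert res.selected == set()
    assert (res.scores == 0).all()


def test_gbt_single_class_refused():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
    X.columns = ["a", "b", "c"]
    fm = FeatureMatrix.__new__(FeatureMatrix)  # bypass the class-count check
    fm.X, fm.y = X, np.ones(10, int)
    with pytest.raises(ValueError):
        gbt_importance_select(fm, 10, seed=0)


def test_shadow_confirms_planted_and_partitions_statuses():
    fm = make_fm(n=40, p_noise=15, shift=2.0, seed=4)
    res = shadow_feature_select(fm, max_runs=80, alpha=0.01, seed=4)
    assert "SIG" in res.selected
    assert set(res.settings["rejected"]).isdisjoint(res.selected)
    assert set(res.settings["tentative"]).isdisjoint(res.selected)


def test_shadow_null_confirms_almost_nothing():
    """Pure-noise features: near-zero confirmations.

    The dataset-conditional null is not exactly zero — a noise feature with
    a lucky sample correlation is consistently more important than its
    redrawn shadows. Frozen from a 50-seed simulation (mean 0.76 of 20
    features confirmed); here three fixed seeds stay at <= 1 each.
    """
    y = np.r_[np.ones(20, int), np.zeros(20, int)]
    for s in range(3):
        rng = np.random.default_rng(2000 + s)
        X = pd.DataFrame(rng.normal(size=(40, 12)), columns=[f"F{i}" for i in range(12)])
        res = shadow_feature_select(FeatureMatrix(X, y), max_runs=40, alpha=0.01, seed=5 + s)
        assert len(res.selected) <= 1


def test_shadow_refuses_tiny_samples():
    X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)), columns=list("abc"))
    with pytest.raises(ValueError):
        shadow_feature_select(FeatureMatrix(X, np.array([0, 0, 1, 1])), 20, seed=0)


def test_consensus_intersect_properties():
    r1 = SelectionResult("a", {"x", "y"}, pd.Series(dtype=float))
    r2 = SelectionResult("b", {"y", "z"}, pd.Series(dtype=float))
    r3 = SelectionResult("c", {"y"}, pd.Series(dtype=float))
    assert consensus_intersect([r1, r2, r3]) == {"y"}
    assert consensus_intersect([r1, r1]) == r1.selected
    assert consensus_intersect([r1, SelectionResult("d", set(), pd.Series(dtype=float))]) == set()
    for subset in [consensus_intersect([r1, r2])]:
        assert subset <= r1.selected and subset <= r2.selected
    with pytest.raises(ValueError):
        consensus_intersect([r1])


def test_nested_cv_separable_data_has_auc_one():
    fm = make_fm(n=30, p_noise=4, shift=6.0, seed=6)
    report = nested_cv(fm, outer=5, inner=3, repeats=2, seed=6)
    assert report.aggregate["auc"]["mean"] == pytest.approx(1.0)
    assert (report.records["auc"] == 1.0).all()


def test_nested_cv_records_partition_and_metric_ranges():
    fm = make_fm(n=24, p_noise=6, shift=1.0, seed=7)
    report = nested_cv(fm, outer=4, inner=3, repeats=2, seed=7)
    vals = report.records[["auc", "accuracy", "sensitivity", "specificity"]].to_numpy(float)
    finite = vals[~np.isnan(vals)]
    assert ((finite >= 0) & (finite <= 1)).all()
    assert len(report.records) + report.n_skipped == 2 * 4


def test_nested_cv_deterministic():
    fm = make_fm(seed=8)
    a = nested_cv(fm, 3, 3, 2, seed=11)
    b = nested_cv(fm, 3, 3, 2, seed=11)
    pd.testing.assert_frame_equal(a.records, b.records)


def test_bootstrap_single_iteration_frequencies_binary():
    fm = make_fm(seed=9)
    rep = bootstrap_stability(fm, B=1, seed=9)
    assert set(rep.frequencies.unique()) <= {0.0, 1.0}
    assert rep.n_counted == 1


def test_bootstrap_signal_selected_more_than_noise():
    """Planted predictor beats the median noise-feature frequency (ordering)."""
    wins = 0
    for seed in range(6):
        fm = make_fm(n=30, p_noise=8, shift=2.5, seed=20 + seed)
        rep = bootstrap_stability(fm, B=60, seed=seed)
        noise_median = rep.frequencies.drop("SIG").median()
        wins += rep.frequencies["SIG"] > noise_median
    assert wins >= 5


def test_bootstrap_deterministic():
    fm = make_fm(seed=10)
    a = bootstrap_stability(fm, B=20, seed=13)
    b = bootstrap_stability(fm, B=20, seed=13)
    pd.testing.assert_series_equal(a.frequencies, b.frequencies)
    assert a.aggregate == b.aggregate
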