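"""Tri-algorithm feature selection with consensus, nested CV and bootstrap stability.

Three selectors run on the candidate-gene feature matrix:

* ``l1_logistic_select`` — L1-penalized logistic regression over a
  glmnet-style descending lambda path, lambda chosen by stratified k-fold
  cross-validated binomial deviance (lambda.min convention);
* ``gbt_importance_select`` — gradient-boosted trees with total-gain
  importance, keeping features with nonzero gain;
* ``shadow_feature_select`` — a shadow-feature (Boruta-style) wrapper: each
  iteration appends a permuted copy of every undecided feature, fits a
  random-forest ensemble, scores a "hit" when a real feature beats the best
  shadow, and confirms/rejects features by BH-corrected two-sided binomial
  tests against Binomial(runs, 0.5).

The consensus set is the exact intersection of the selected sets. Honest
generalization estimates come from nested cross-validation (inner CV
re-tunes lambda inside every outer training fold) and stratified bootstrap
resampling with out-of-bag evaluation plus per-gene selection frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._rng import child_seed, substream
from .containers import CASE, ExpressionMatrix
from .diffexpr import bh_adjust

DEFAULT_N_FOLDS = 5
DEFAULT_REPEATS = 100
DEFAULT_BOOTSTRAP_B = 1_000
DEFAULT_MAX_RUNS = 1_000
DEFAULT_ALPHA = 0.01
N_LAMBDA = 60
LAMBDA_MIN_RATIO = 1e-2


@dataclass
class FeatureMatrix:
    """Samples x candidate-gene matrix with binary labels (1 = case)."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if min((self.y == 0).sum(), (self.y == 1).sum()) < 2:
            raise ValueError("need >= 2 samples per class")

    @classmethod
    def from_expression(cls, matrix: ExpressionMatrix, genes) -> "FeatureMatrix":
        genes = [g for g in genes if g in matrix.genes]
        X = matrix.values.loc[genes].T
        y = (matrix.groups.loc[X.index] == CASE).astype(int).to_numpy()
        return cls(X, y)

    @property
    def features(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class SelectionResult:
    algorithm: str
    selected: set[str]
    scores: pd.Series
    settings: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# L1 logistic path


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


def _lambda_path(Xs: np.ndarray, y: np.ndarray, n_lambda: int = N_LAMBDA) -> np.ndarray:
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(Xs.T @ resid).max() / n
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * LAMBDA_MIN_RATIO, n_lambda)


def _fit_l1(Xs: np.ndarray, y: np.ndarray, lam: float, seed: int) -> LogisticRegression:
    n = len(y)
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
        max_iter=2000, tol=1e-6, random_state=seed,
    )
    model.fit(Xs, y)
    return model


def _deviance(model: LogisticRegression, Xs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(model.predict_proba(Xs)[:, 1], 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> tuple[int, list]:
    min_class = min(np.bincount(y, minlength=2))
    if min_class < n_folds:
        warnings.warn(f"reducing folds from {n_folds} to {min_class} (smallest class)")
        n_folds = max(2, int(min_class))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return n_folds, list(skf.split(np.zeros(len(y)), y))


def _cv_lambda(
    X: np.ndarray, y: np.ndarray, n_folds: int, seed: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Choose lambda.min by mean cross-validated binomial deviance."""
    Xs, _, _ = _standardize(X)
    path = _lambda_path(Xs, y)
    n_folds, folds = _stratified_folds(y, n_folds, seed)
    dev = np.zeros((len(folds), len(path)))
    for i, (tr, te) in enumerate(folds):
        Xtr, mu, sd = _standardize(X[tr])
        Xte = (X[te] - mu) / sd
        for j, lam in enumerate(path):
            model = _fit_l1(Xtr, y[tr], lam, seed)
            dev[i, j] = _deviance(model, Xte, y[te])
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))  # argmin takes the first (largest-lambda) minimum
    return float(path[best]), path, mean_dev


def l1_logistic_select(
    fm: FeatureMatrix, n_folds: int = DEFAULT_N_FOLDS, seed: int = 0
) -> SelectionResult:
    """LASSO-style selection: nonzero coefficients at the CV-optimal lambda."""
    X, y = fm.X.to_numpy(float), fm.y
    lam, path, mean_dev = _cv_lambda(X, y, n_folds, child_seed(seed, "l1_cv"))
    Xs, _, sd = _standardize(X)
    model = _fit_l1(Xs, y, lam, child_seed(seed, "l1_fit"))
    coef_orig = model.coef_.ravel() / sd
    scores = pd.Series(np.abs(coef_orig), index=fm.features)
    selected = set(scores.index[scores > 0])
    return SelectionResult(
        algorithm="l1_logistic",
        selected=selected,
        scores=scores,
        settings={"lambda": lam, "log_lambda": float(np.log(lam)), "n_folds": n_folds},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Gradient-boosted trees


def gbt_importance_select(
    fm: FeatureMatrix,
    n_rounds: int = 100,
    rule: str | float = "nonzero",
    seed: int = 0,
    colsample_bytree: float = 0.5,
) -> SelectionResult:
    """Gradient-boosted-tree selection by total-gain importance.

    ``rule="nonzero"`` keeps every feature with positive gain; a float in
    (0, 1) keeps that top fraction of positive-gain features instead.
    Per-tree column subsampling (default 0.5) keeps gain from collapsing
    onto a single feature when a few strongly separating, mutually
    correlated features dominate — the typical small-cohort regime here.
    """
    from xgboost import XGBClassifier

    if n_rounds < 1:
        raise ValueError("need >= 1 boosting round")
    X, y = fm.X.to_numpy(float), fm.y
    if len(np.unique(y)) < 2:
        raise ValueError("single-class input")
    model = XGBClassifier(
        n_estimators=n_rounds, max_depth=2, learning_rate=0.3,
        colsample_bytree=colsample_bytree,
        tree_method="hist", n_jobs=1, random_state=child_seed(seed, "gbt"),
        eval_metric="logloss",
    )
    model.fit(X, y)
    booster = model.get_booster()
    gain = booster.get_score(importance_type="total_gain")
    scores = pd.Series(
        [gain.get(f"f{i}", 0.0) for i in range(len(fm.features))], index=fm.features
    )
    positive = scores[scores > 0].sort_values(ascending=False)
    if rule == "nonzero":
        selected = set(positive.index)
    else:
        frac = float(rule)
        if not 0 < frac <= 1:
            raise ValueError("rule must be 'nonzero' or a fraction in (0, 1]")
        selected = set(positive.index[: max(1, int(np.ceil(frac * len(positive))))]) if len(positive) else set()
    return SelectionResult(
        algorithm="gbt_importance",
        selected=selected,
        scores=scores,
        settings={"n_rounds": n_rounds, "rule": rule},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Shadow-feature (Boruta-style) selection


def shadow_feature_select(
    fm: FeatureMatrix,
    max_runs: int = DEFAULT_MAX_RUNS,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    n_trees: int = 100,
) -> SelectionResult:
    """Shadow-feature wrapper selection around a random-forest ensemble.

    Each iteration appends a permuted shadow copy of every still-active
    feature (at least five shadows), fits a random forest on real + shadow
    columns, and credits a "hit" to every undecided real feature whose
    importance exceeds the maximum shadow importance. After each iteration, two-sided binomial
    tests of the hit counts against Binomial(runs, 1/2) are BH-corrected at
    ``alpha``: upper-tail rejections Confirm, lower-tail rejections Reject.
    Features still undecided at ``max_runs`` are reported as tentative (not
    selected).
    """
    if max_runs < 10:
        raise ValueError("max_runs must be >= 10")
    if len(fm.y) < 5:
        raise ValueError("fewer than 5 samples; ensemble importance unreliable")
    rng = substream(seed, "shadow")
    X = fm.X.to_numpy(float)
    features = fm.features
    p = len(features)
    status = pd.Series("undecided", index=features)
    hits = pd.Series(0, index=features, dtype=int)
    runs = pd.Series(0, index=features, dtype=int)

    for it in range(max_runs):
        undecided = list(status.index[status == "undecided"])
        if not undecided:
            break
        active = list(status.index[status.isin(["undecided", "confirmed"])])
        a_idx = [features.index(f) for f in active]
        # shadow every active feature (and keep >= 5 shadows) so the
        # shadow-max null stays stationary as features are rejected
        s_idx = list(a_idx)
        while len(s_idx) < 5:
            s_idx.append(a_idx[len(s_idx) % len(a_idx)])
        shadows = X[:, s_idx].copy()
        for j in range(shadows.shape[1]):
            shadows[:, j] = rng.permutation(shadows[:, j])
        design = np.hstack([X[:, a_idx], shadows])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            n_jobs=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        forest.fit(design, fm.y)
        imp = forest.feature_importances_
        real_imp = dict(zip(active, imp[: len(active)]))
        shadow_max = imp[len(active):].max() if len(undecided) else 0.0
        for f in undecided:
            runs[f] += 1
            if real_imp[f] > shadow_max:
                hits[f] += 1
        # decision step: two-sided binomial tests with BH correction
        und = list(status.index[status == "undecided"])
        p_hi = np.array([stats.binom.sf(hits[f] - 1, runs[f], 0.5) for f in und])
        p_lo = np.array([stats.binom.cdf(hits[f], runs[f], 0.5) for f in und])
        p_two = np.minimum(1.0, 2 * np.minimum(p_hi, p_lo))
        adj = bh_adjust(p_two)
        for f, a, hi, lo in zip(und, adj, p_hi, p_lo):
            if a < alpha:
                status[f] = "confirmed" if hi < lo else "rejected"

    confirmed = set(status.index[status == "confirmed"])
    tentative = sorted(status.index[status == "undecided"])
    scores = (hits / runs.replace(0, 1)).astype(float)
    return SelectionResult(
        algorithm="shadow_feature",
        selected=confirmed,
        scores=scores,
        settings={
            "max_runs": max_runs,
            "alpha": alpha,
            "tentative": tentative,
            "rejected": sorted(status.index[status == "rejected"]),
            "iterations": int(runs.max()) if p else 0,
        },
        seed=seed,
    )


def consensus_intersect(results: list[SelectionResult]) -> set[str]:
    """Exact intersection of the selected sets from >= 2 algorithms."""
    if len(results) < 2:
        raise ValueError("need at least two selection results")
    out = set(results[0].selected)
    for r in results[1:]:
        out &= r.selected
    return out


# ---------------------------------------------------------------------------
# Nested cross-validation


@dataclass
class CvReport:
    records: pd.DataFrame  # columns: repeat, fold, auc, accuracy, sensitivity, ...
    aggregate: dict
    n_skipped: int
    settings: dict

    def to_json_dict(self) -> dict:
        return {
            "aggregate": self.aggregate,
            "n_skipped": self.n_skipped,
            "settings": self.settings,
            "n_evaluations": int(len(self.records)),
        }


_METRICS = ["auc", "accuracy", "sensitivity", "specificity", "ppv", "npv"]


def _classification_metrics(y_true: np.ndarray, prob: np.ndarray) -> dict:
    pred = (prob >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    def _ratio(a, b):
        return a / b if b > 0 else np.nan
    return {
        "auc": roc_auc_score(y_true, prob) if len(np.unique(y_true)) == 2 else np.nan,
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int = 1000) -> tuple:
    values = values[~np.isnan(values)]
    if len(values) == 0:
        return (np.nan, np.nan)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    return (float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975)))


def nested_cv(
    fm: FeatureMatrix,
    outer: int = DEFAULT_N_FOLDS,
    inner: int = DEFAULT_N_FOLDS,
    repeats: int = DEFAULT_REPEATS,
    seed: int = 0,
) -> CvReport:
    """Repeated nested CV of the L1-logistic classifier.

    The inner loop re-tunes lambda on every outer training split; the refit
    model is scored on the held-out outer fold. Outer test folds containing
    a single class have undefined AUC and are skipped and tallied. 95% CIs
    of the aggregate means are bootstrap percentile intervals over the
    per-evaluation metric values (1,000 resamples).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X, y = fm.X.to_numpy(float), fm.y
    rows = []
    n_skipped = 0
    for rep in range(repeats):
        rep_seed = child_seed(seed, f"ncv_rep{rep}")
        n_outer, folds = _stratified_folds(y, outer, rep_seed)
        for k, (tr, te) in enumerate(folds):
            if len(np.unique(y[te])) < 2:
                n_skipped += 1
                continue
            lam, _, _ = _cv_lambda(X[tr], y[tr], inner, child_seed(rep_seed, f"inner{k}"))
            Xtr, mu, sd = _standardize(X[tr])
            model = _fit_l1(Xtr, y[tr], lam, rep_seed)
            prob = model.predict_proba((X[te] - mu) / sd)[:, 1]
            rows.append({"repeat": rep, "fold": k, **_classification_metrics(y[te], prob)})
    records = pd.DataFrame(rows)
    rng = substream(seed, "ncv_ci")
    aggregate = {}
    for m in _METRICS:
        vals = records[m].to_numpy(float) if len(records) else np.array([np.nan])
        lo, hi = _bootstrap_ci(vals, rng)
        aggregate[m] = {"mean": float(np.nanmean(vals)), "ci95": [lo, hi]}
    return CvReport(
        records=records,
        aggregate=aggregate,
        n_skipped=n_skipped,
        settings={"outer": outer, "inner": inner, "repeats": repeats, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Bootstrap stability


@dataclass
class StabilityReport:
    frequencies: pd.Series  # per-gene selection frequency in [0, 1]
    oob: pd.DataFrame  # per counted iteration: auc, accuracy, ...
    aggregate: dict
    B: int
    n_counted: int
    n_skipped: int
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "frequencies": {k: float(v) for k, v in self.frequencies.items()},
            "aggregate": self.aggregate,
            "B": self.B,
            "n_counted": self.n_counted,
            "n_skipped": self.n_skipped,
        }


def bootstrap_stability(
    fm: FeatureMatrix,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
    n_folds: int = DEFAULT_N_FOLDS,
) -> StabilityReport:
    """Stratified bootstrap with OOB evaluation and selection frequencies.

    Lambda is tuned once by inner CV on the full data; each iteration refits
    the L1 model at that lambda on a within-class bootstrap resample and
    evaluates on the out-of-bag samples. Iterations with an empty OOB set
    are skipped and tallied. frequency(g) = selections(g) / counted
    iterations (LASSO-selection counting).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X, y = fm.X.to_numpy(float), fm.y
    lam, _, _ = _cv_lambda(X, y, n_folds, child_seed(seed, "boot_cv"))
    rng = substream(seed, "bootstrap")
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    counts = pd.Series(0, index=fm.features, dtype=int)
    rows = []
    n_counted = n_skipped = 0
    for b in range(B):
        boot = np.concatenate([
            rng.choice(idx0, size=len(idx0), replace=True),
            rng.choice(idx1, size=len(idx1), replace=True),
        ])
        oob = np.setdiff1d(np.arange(len(y)), np.unique(boot))
        if len(oob) == 0:
            n_skipped += 1
            continue
        Xtr, mu, sd = _standardize(X[boot])
        model = _fit_l1(Xtr, y[boot], lam, child_seed(seed, f"boot{b}"))
        coef = model.coef_.ravel()
        selected = np.flatnonzero(coef != 0)
        counts.iloc[selected] += 1
        n_counted += 1
        prob = model.predict_proba((X[oob] - mu) / sd)[:, 1]
        rows.append(_classification_metrics(y[oob], prob))
    if n_counted == 0:
        raise ValueError("all bootstrap iterations had empty OOB sets")
    oob_df = pd.DataFrame(rows)
    rng_ci = substream(seed, "boot_ci")
    aggregate = {}
    for m in _METRICS:
        vals = oob_df[m].to_numpy(float)
        lo, hi = _bootstrap_ci(vals, rng_ci)
        aggregate[m] = {"mean": float(np.nanmean(vals)), "ci95": [lo, hi]}
    return StabilityReport(
        frequencies=counts / n_counted,
        oob=oob_df,
        aggregate=aggregate,
        B=B,
        n_counted=n_counted,
        n_skipped=n_skipped,
        seed=seed,
    )


def write_frequency_tsv(report: StabilityReport, path) -> None:
    out = pd.DataFrame({
        "symbol": report.frequencies.index,
        "frequency": report.frequencies.values,
    })
    out.sort_values("frequency", ascending=False).to_csv(path, sep="\t", index=False)
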