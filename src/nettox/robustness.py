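"""Two-cohort validation, fold-change sensitivity grid, abundance testing.

A gene is a *core target* when it is rank-sum significant (p < 0.05) in
both the training and the validation cohort with the same direction of
change. The sensitivity grid re-runs the DEG thresholding and three-way
intersection across a ladder of |log2FC| cutoffs (p < 0.05 unadjusted held
fixed) to show how candidate membership depends on the threshold choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, ExpressionMatrix, TargetSet
from .diffexpr import bh_adjust, fit_moderated, threshold_degs
from .targets import intersect3

DEFAULT_THRESHOLDS = (0.25, 0.50, 0.75, 1.00, 1.25, 1.50)
DEFAULT_ALPHA = 0.05


def ranksum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test.

    Exact null distribution (full enumeration) when the combined sample is
    small (<= 12) and tie-free; otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty input")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def validate_core(
    genes,
    train: ExpressionMatrix,
    valid: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    center: str = "median",
) -> pd.DataFrame:
    """Per-gene two-cohort validation verdicts.

    Direction is the sign of the case-minus-control ``center`` difference
    (median by default; mean available). ``is_core`` requires p < alpha in
    both cohorts and matching directions. Genes absent from a cohort are
    reported with NaN p-values, never core.
    """
    if center not in {"median", "mean"}:
        raise ValueError("center must be 'median' or 'mean'")
    agg = np.median if center == "median" else np.mean
    rows = []
    for g in genes:
        row = {"symbol": g}
        for label, em in (("train", train), ("valid", valid)):
            if g not in em.genes:
                row[f"p_{label}"] = np.nan
                row[f"direction_{label}"] = "absent"
                continue
            case = em.case_values.loc[g].to_numpy()
            ctrl = em.control_values.loc[g].to_numpy()
            _, p = ranksum_test(case, ctrl)
            diff = float(agg(case) - agg(ctrl))
            row[f"p_{label}"] = p
            row[f"direction_{label}"] = "up" if diff > 0 else "down"
        row["is_core"] = bool(
            not np.isnan(row.get("p_train", np.nan))
            and not np.isnan(row.get("p_valid", np.nan))
            and row["p_train"] < alpha
            and row["p_valid"] < alpha
            and row["direction_train"] == row["direction_valid"]
            and row["direction_train"] in ("up", "down")
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("symbol")


def sensitivity_grid(
    train: ExpressionMatrix,
    disease: TargetSet,
    chem: TargetSet,
    thresholds=DEFAULT_THRESHOLDS,
    tracked=(),
    p_max: float = DEFAULT_ALPHA,
    use_adjusted: bool = False,
    deg_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Candidate counts and tracked-gene retention across log2FC thresholds.

    The p cutoff stays fixed while the fold-change cutoff varies, so the
    DEG (and hence candidate) sets are nested decreasing in the threshold.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    table = fit_moderated(train) if deg_table is None else deg_table
    rows = []
    for thr in thresholds:
        up, down = threshold_degs(table, thr, p_max, use_adjusted)
        degs = up | down
        cand = intersect3(degs, disease, chem)
        row = {"threshold": thr, "n_deg": len(degs), "n_candidates": len(cand)}
        for g in tracked:
            row[f"retained_{g}"] = g in cand.symbols
        rows.append(row)
    return pd.DataFrame(rows)


def abundance_group_test(table: AbundanceTable, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Per-component rank-sum test with BH correction across the component family."""
    case = table.values[table.groups == "case"]
    ctrl = table.values[table.groups == "control"]
    if len(case) < 3 or len(ctrl) < 3:
        raise ValueError("need >= 3 samples per group")
    rows = []
    for comp in table.values.columns:
        stat, p = ranksum_test(case[comp].to_numpy(), ctrl[comp].to_numpy())
        rows.append({"component": comp, "statistic": stat, "p": p})
    out = pd.DataFrame(rows).set_index("component")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["sig_p"] = out["p"] < alpha
    out["sig_q"] = out["q"] < alpha
    return out
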