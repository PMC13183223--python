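"""Two-group moderated differential expression with BH correction.

The test statistic is the empirical-Bayes moderated t: per-gene pooled
variances s_g^2 (residual df d_g = n1 + n2 - 2) are shrunk toward a common
prior (d0, s0^2) estimated by moment-matching the marginal distribution of
log s_g^2 against its scaled-F form. The posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and t_mod = log2FC / (s~_g * sqrt(1/n1 + 1/n2)) is referred to a t
distribution with d0 + d_g degrees of freedom. This is a deterministic,
closed-form approximation to the moderated statistic of the widely used
limma package.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

DEFAULT_LFC_MIN = 0.5
DEFAULT_P_MAX = 0.05


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from pooled variances with residual df ``df``.

    Under the hierarchical model s_g^2 / s0^2 ~ F(df, d0); matching the mean
    and variance of log s_g^2 gives closed-form estimates (d0 may be +inf
    when the empirical spread is no wider than the chi-square's own).
    """
    s2 = np.asarray(s2, float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need at least two positive variances to estimate the prior")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(evar)
    if np.isinf(d0):
        return np.inf, float(np.exp(e.mean()))
    s0_2 = np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_2)


def fit_moderated(
    matrix: ExpressionMatrix,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t test for every gene (case minus control).

    Parameters
    ----------
    matrix
        Expression matrix with case/control labels.
    prior
        Optional (d0, s0^2) override. ``(0, anything)`` reduces the statistic
        to the classical pooled two-sample t; ``(inf, s0_2)`` fixes the
        denominator at the prior variance.

    Returns
    -------
    DataFrame indexed by symbol with columns ``log2fc, t, df_total, p,
    p_adj, direction, zero_variance``. Genes with identical values in all
    samples are flagged and excluded from prior estimation.
    """
    case = matrix.case_values.to_numpy()
    ctrl = matrix.control_values.to_numpy()
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    df_resid = float(n1 + n2 - 2)

    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    zero_var = np.isclose(
        np.concatenate([case, ctrl], axis=1).var(axis=1), 0.0, atol=1e-30
    )

    if prior is None:
        d0, s0_2 = estimate_variance_prior(s2[~zero_var], df_resid)
    else:
        d0, s0_2 = prior

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.nan)
        t = np.where((se == 0) & (lfc == 0), 0.0, t)
    if np.isnan(t).any():
        warnings.warn("zero-variance genes with d0=0 produce undefined t; p set to NaN")
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "df_total": df_total,
            "p": p,
            "zero_variance": zero_var,
        },
        index=matrix.genes,
    )
    ok = table["p"].notna()
    p_adj = np.full(len(table), np.nan)
    p_adj[ok.to_numpy()] = bh_adjust(table.loc[ok, "p"].to_numpy())
    table["p_adj"] = p_adj
    table.attrs["prior_df"] = d0
    table.attrs["prior_var"] = s0_2
    table.attrs["n_case"], table.attrs["n_ctrl"] = n1, n2
    return annotate_direction(table)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_direction(
    table: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    up, down = threshold_degs(table, lfc_min, p_max, use_adjusted)
    direction = pd.Series("ns", index=table.index)
    direction[list(up)] = "up"
    direction[list(down)] = "down"
    table = table.copy()
    table["direction"] = direction
    return table


def threshold_degs(
    table: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    p_max: float = DEFAULT_P_MAX,
    use_adjusted: bool = False,
) -> tuple[set[str], set[str]]:
    """Strict-inequality DEG classification: |log2FC| > lfc_min and p < p_max."""
    if lfc_min < 0:
        raise ValueError("lfc_min must be non-negative")
    pcol = "p_adj" if use_adjusted else "p"
    sig = table[pcol] < p_max
    up = set(table.index[(table["log2fc"] > lfc_min) & sig])
    down = set(table.index[(table["log2fc"] < -lfc_min) & sig])
    return up, down


def write_deg_tsv(table: pd.DataFrame, path) -> None:
    out = table.reset_index().rename(columns={"index": "symbol", "log2fc": "log2FC"})
    if "symbol" not in out.columns:
        out = out.rename(columns={out.columns[0]: "symbol"})
    out[["symbol", "log2FC", "t", "p", "p_adj", "direction"]].to_csv(
        path, sep="\t", index=False
    )
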