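"""Moderated-t statistic, BH adjustment, and threshold classification."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nettox.diffexpr import (
    annotate_direction,
    bh_adjust,
    estimate_variance_prior,
    fit_moderated,
    threshold_degs,
)
from nettox.syndata import SyntheticConfig, gen_cohorts

from conftest import toy_matrix


def test_identical_values_gene_is_null():
    rng = np.random.default_rng(0)
    case = rng.normal(8, 1, (5, 4))
    ctrl = rng.normal(8, 1, (5, 4))
    case[0] = ctrl[0] = 7.0  # constant everywhere
    em = toy_matrix(case, ctrl)
    table = fit_moderated(em)
    assert table.loc["g0", "log2fc"] == 0.0
    assert table.loc["g0", "t"] == 0.0
    assert table.loc["g0", "p"] == 1.0
    assert table.loc["g0", "zero_variance"]


def test_reduces_to_classical_t_with_zero_prior_df():
    rng = np.random.default_rng(1)
    case = rng.normal(8, 1, (20, 3))
    ctrl = rng.normal(8, 1, (20, 3))
    em = toy_matrix(case, ctrl)
    table = fit_moderated(em, prior=(0.0, 1.0))
    t_ref, p_ref = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
    np.testing.assert_allclose(table["t"], t_ref, rtol=1e-10)
    np.testing.assert_allclose(table["p"], p_ref, rtol=1e-10)


def test_infinite_prior_df_fixes_denominator():
    rng = np.random.default_rng(2)
    case = rng.normal(0, 1, (10, 4))
    ctrl = rng.normal(0, 1, (10, 4))
    em = toy_matrix(case, ctrl)
    s0_2 = 0.7
    table = fit_moderated(em, prior=(np.inf, s0_2))
    lfc = case.mean(axis=1) - ctrl.mean(axis=1)
    expected = lfc / np.sqrt(s0_2 * (1 / 4 + 1 / 4))
    np.testing.assert_allclose(table["t"], expected, rtol=1e-12)


def test_variance_prior_recovery():
    """(d0, s0^2) recovered within 25% at 2,000 genes (frozen tolerance)."""
    for seed in (0, 1, 2):
        cfg = SyntheticConfig(n_genes=2000, var_prior_df=4.0, var_prior_scale=0.05, seed=seed)
        train, _, _ = gen_cohorts(cfg)
        table = fit_moderated(train)
        assert abs(table.attrs["prior_df"] / 4.0 - 1) < 0.25
        assert abs(table.attrs["prior_var"] / 0.05 - 1) < 0.25


def test_bh_adjust_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30), st.randoms())
def test_bh_adjust_permutation_invariant(p, rnd):
    """Adjusted values follow their input p-values under any reordering."""
    adj = bh_adjust(p)
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    adj_perm = bh_adjust([p[i] for i in perm])
    np.testing.assert_allclose([adj[i] for i in perm], adj_perm, atol=1e-12)
    assert np.all(adj >= np.asarray(p) - 1e-12)  # step-up never decreases p


def test_threshold_strictness_and_classification():
    table = pd.DataFrame(
        {
            "log2fc": [0.5, 0.6, -0.9, 0.1],
            "p": [0.001, 0.01, 0.02, 0.5],
            "p_adj": [0.01, 0.05, 0.08, 0.9],
        },
        index=["a", "b", "c", "d"],
    )
    up, down = threshold_degs(table, 0.5, 0.05)
    assert "a" not in up  # boundary log2FC = 0.5 excluded (strict)
    assert up == {"b"} and down == {"c"}
    up_all, down_all = threshold_degs(table, 0.0, 1.0)
    assert up_all | down_all == {"a", "b", "c", "d"}
    with pytest.raises(ValueError):
        threshold_degs(table, -0.1, 0.05)


def test_deg_count_monotone_in_thresholds(small_cohorts):
    train, _, _ = small_cohorts
    table = fit_moderated(train)
    sizes_lfc = []
    for lfc in (0.0, 0.25, 0.5, 1.0):
        up, down = threshold_degs(table, lfc, 0.05)
        sizes_lfc.append(len(up) + len(down))
    assert sizes_lfc == sorted(sizes_lfc, reverse=True)
    sizes_p = []
    for p in (0.2, 0.05, 0.01):
        up, down = threshold_degs(table, 0.5, p)
        sizes_p.append(len(up) + len(down))
    assert sizes_p == sorted(sizes_p, reverse=True)


def test_direction_consistent_with_sign():
    rng = np.random.default_rng(3)
    em = toy_matrix(rng.normal(8, 1, (50, 5)), rng.normal(8, 1, (50, 5)))
    table = annotate_direction(fit_moderated(em), 0.0, 1.0)
    assert ((table["direction"] == "up") == (table["log2fc"] > 0)).all()


R_LIMMA_SCRIPT = """
suppressMessages(library(limma))
x <- read.delim("{expr}", row.names = 1)
design <- cbind(Intercept = 1, Case = {design})
fit <- eBayes(lmFit(x, design))
out <- data.frame(t = fit$t[, "Case"], p = fit$p.value[, "Case"])
out$d0 <- fit$df.prior
out$s0 <- fit$s2.prior
write.csv(out, "{out}")
"""


def test_matches_limma_reference(tmp_path):
    """Independent cross-check against the Bioconductor limma implementation."""
    rng = np.random.default_rng(11)
    n1, n2 = 5, 5
    cfg = SyntheticConfig(
        n_genes=120, n_train_case=n1, n_train_ctrl=n2, frac_de=0.1, db_noise=30, seed=11
    )
    train, _, _ = gen_cohorts(cfg)
    expr = tmp_path / "expr.tsv"
    train.values.to_csv(expr, sep="\t")
    design = "c(" + ",".join(
        "1" if g == "case" else "0" for g in train.groups
    ) + ")"
    out = tmp_path / "limma.csv"
    script = R_LIMMA_SCRIPT.format(expr=expr, design=design, out=out)
    rfile = tmp_path / "run.R"
    rfile.write_text(script)
    subprocess.run(["Rscript", str(rfile)], check=True, capture_output=True)
    ref = pd.read_csv(out, index_col=0)
    table = fit_moderated(train)
    np.testing.assert_allclose(table["t"], ref["t"], rtol=1e-4)
    np.testing.assert_allclose(table["p"], ref["p"], rtol=1e-4)
    assert abs(table.attrs["prior_df"] - ref["d0"].iloc[0]) / ref["d0"].iloc[0] < 0.02
    assert abs(table.attrs["prior_var"] - ref["s0"].iloc[0]) / ref["s0"].iloc[0] < 0.02
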