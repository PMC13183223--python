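"""Generator determinism, planted-structure bookkeeping, and distributional checks."""

import numpy as np
import pandas as pd
import pytest

from nettox.syndata import (
    SyntheticConfig,
    gen_abundance,
    gen_cohorts,
    gen_network,
    gen_target_dbs,
    gene_universe,
)


def test_seed_determinism_all_generators(small_cfg):
    t1, v1, truth1 = gen_cohorts(small_cfg)
    t2, v2, truth2 = gen_cohorts(small_cfg)
    pd.testing.assert_frame_equal(t1.values, t2.values)
    pd.testing.assert_frame_equal(v1.values, v2.values)
    assert truth1.de_genes == truth2.de_genes

    u = gene_universe(small_cfg)
    for a, b in zip(gen_target_dbs(truth1, u, small_cfg), gen_target_dbs(truth2, u, small_cfg)):
        pd.testing.assert_frame_equal(a.entries, b.entries)

    n1 = gen_network(truth1, u, small_cfg)
    n2 = gen_network(truth2, u, small_cfg)
    assert sorted(n1.graph.edges(data="score")) == sorted(n2.graph.edges(data="score"))

    a1 = gen_abundance(small_cfg)
    a2 = gen_abundance(small_cfg)
    pd.testing.assert_frame_equal(a1.values, a2.values)


def test_different_seeds_differ(small_cfg):
    t1, _, _ = gen_cohorts(small_cfg)
    cfg2 = SyntheticConfig(**{**small_cfg.__dict__, "seed": small_cfg.seed + 1})
    t2, _, _ = gen_cohorts(cfg2)
    assert not t1.values.equals(t2.values)


def test_no_signal_case():
    cfg = SyntheticConfig(n_genes=200, frac_de=0.0, seed=1)
    train, valid, truth = gen_cohorts(cfg)
    assert truth.de_genes == {}
    assert truth.target_genes == []
    # group means differ only by sampling noise: no gene shifted by >> noise scale
    diff = train.case_values.mean(axis=1) - train.control_values.mean(axis=1)
    assert np.abs(diff).max() < 2.0


def test_expression_has_no_missing_values(small_cohorts):
    train, valid, _ = small_cohorts
    assert not train.values.isna().any().any()
    assert not valid.values.isna().any().any()


def test_planted_effects_shared_sign_across_cohorts(small_cohorts):
    train, valid, truth = small_cohorts
    for gene, effect in truth.de_genes.items():
        if abs(effect) < 1.0:
            continue
        d_train = train.case_values.loc[gene].mean() - train.control_values.loc[gene].mean()
        d_valid = valid.case_values.loc[gene].mean() - valid.control_values.loc[gene].mean()
        assert np.sign(d_train) == np.sign(effect)
        assert np.sign(d_valid) == np.sign(effect)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(n_genes=0).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(frac_de=1.5).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(n_train_case=1).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(db_noise=10_000, n_genes=100).validate()


def test_degenerate_db_coverage(small_cohorts, small_cfg):
    _, _, truth = small_cohorts
    u = gene_universe(small_cfg)
    cfg = SyntheticConfig(**{**small_cfg.__dict__, "db_coverage": 1.0, "db_noise": 0})
    for db in gen_target_dbs(truth, u, cfg):
        assert db.symbols == set(truth.target_genes)
    cfg0 = SyntheticConfig(**{**small_cfg.__dict__, "db_coverage": 0.0})
    for db in gen_target_dbs(truth, u, cfg0):
        assert db.symbols.isdisjoint(truth.target_genes)


def test_db_coverage_binomial_expectation(small_cohorts, small_cfg):
    """Mean planted count per database matches coverage * n_targets (200 seeds)."""
    _, _, truth = small_cohorts
    u = gene_universe(small_cfg)
    n_targets = len(truth.target_genes)
    coverage = 0.8
    counts = []
    for s in range(200):
        cfg = SyntheticConfig(
            **{**small_cfg.__dict__, "db_coverage": coverage, "seed": s}
        )
        disease, _, _ = gen_target_dbs(truth, u, cfg)
        counts.append(len(disease.symbols & set(truth.target_genes)))
    expected = coverage * n_targets
    se_mean = np.sqrt(n_targets * coverage * (1 - coverage) / 200)
    assert abs(np.mean(counts) - expected) < 3 * se_mean


def test_network_hub_wiring(small_cohorts, small_cfg):
    _, _, truth = small_cohorts
    net = gen_network(truth, gene_universe(small_cfg), small_cfg)
    degrees = dict(net.graph.degree())
    median_deg = np.median(list(degrees.values()))
    for hub in truth.hub_genes:
        assert degrees[hub] >= 3 * median_deg - 1  # hub wiring dominates
    scores = [d["score"] for _, _, d in net.graph.edges(data=True)]
    assert min(scores) > 0.4 and max(scores) <= 1.0


def test_network_errors_with_more_hubs_than_nodes(small_cohorts, small_cfg):
    _, _, truth = small_cohorts
    bad = SyntheticConfig(**{**small_cfg.__dict__, "net_n_nodes": 2})
    with pytest.raises(ValueError):
        gen_network(truth, gene_universe(bad), bad)


def test_abundance_simplex_invariant():
    for seed in range(5):
        tab = gen_abundance(SyntheticConfig(seed=seed))
        np.testing.assert_allclose(tab.values.sum(axis=1), 1.0, atol=1e-12)
        assert (tab.values.to_numpy() >= 0).all()
        assert len(tab.values.columns) == 22


def test_abundance_shift_raises_case_mean():
    cfg = SyntheticConfig(seed=5, abund_effect=5.0)
    tab = gen_abundance(cfg, n_case=30, n_ctrl=30)
    comp = cfg.abund_shift_component
    case_mean = tab.values.loc[tab.groups == "case", comp].mean()
    ctrl_mean = tab.values.loc[tab.groups == "control", comp].mean()
    assert case_mean > ctrl_mean
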