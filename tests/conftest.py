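import numpy as np
import pandas as pd
import pytest

from nettox.containers import CASE, CONTROL, ExpressionMatrix
from nettox.syndata import SyntheticConfig, gen_cohorts, gen_target_dbs, gene_universe


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """Desk-scale study conditions: 9v8 / 6v6 cohorts over 400 genes."""
    return SyntheticConfig(
        n_genes=400,
        frac_de=0.08,
        n_planted_targets=15,
        n_hubs=3,
        db_noise=50,
        net_n_nodes=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohorts(small_cfg):
    return gen_cohorts(small_cfg)


@pytest.fixture(scope="session")
def small_dbs(small_cfg, small_cohorts):
    _, _, truth = small_cohorts
    return gen_target_dbs(truth, gene_universe(small_cfg), small_cfg)


def toy_matrix(case: np.ndarray, ctrl: np.ndarray, genes=None) -> ExpressionMatrix:
    """Build a small two-group expression matrix from per-group arrays."""
    case = np.atleast_2d(case)
    ctrl = np.atleast_2d(ctrl)
    genes = genes or [f"g{i}" for i in range(case.shape[0])]
    samples = [f"c{i}" for i in range(case.shape[1])] + [f"n{i}" for i in range(ctrl.shape[1])]
    values = pd.DataFrame(np.hstack([case, ctrl]), index=genes, columns=samples)
    groups = pd.Series([CASE] * case.shape[1] + [CONTROL] * ctrl.shape[1], index=samples)
    return ExpressionMatrix(values, groups)
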