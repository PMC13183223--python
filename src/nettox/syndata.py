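"""Seeded synthetic cohorts, target databases, networks and abundance tables.

Every generator plants a recoverable ground truth (differential genes,
database targets, network hubs, a shifted composition component) and records
it in :class:`PlantedTruth`, so each downstream analysis stage can be tested
for recovery without any external download.

The expression model is microarray-like: per-gene baselines are Gaussian on
the log2 scale and per-gene variances are drawn from a scaled
inverse-chi-square, which makes the empirical-Bayes variance prior of the
moderated-t stage exactly recoverable. Two cohorts (train/validation) share
the planted effects — same genes, same signed log2 shifts — but redraw
baselines and noise, mirroring an independent-replication design.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import child_seed, substream
from .containers import CASE, CONTROL, AbundanceTable, ExpressionMatrix, TargetSet
from .netrank import InteractionNetwork

#: canonical 22 immune-cell component names (CIBERSORT LM22 panel)
IMMUNE_COMPONENTS = [
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory", "T cells gamma delta",
    "NK cells resting", "NK cells activated",
    "Monocytes", "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle.

    Defaults mimic a small two-cohort clinical array study: a 9 vs 8 training cohort and a
    6 vs 6 validation cohort of log2 array intensities, ~5% of genes
    differential with |log2FC| in 1-2, partially overlapping disease/chemical
    target databases, a scale-free-ish interaction network with planted hubs,
    and 22-component immune compositions with one shifted component.
    """

    n_genes: int = 2000
    n_train_case: int = 9
    n_train_ctrl: int = 8
    n_valid_case: int = 6
    n_valid_ctrl: int = 6
    frac_de: float = 0.05
    effect_range: tuple[float, float] = (1.0, 2.0)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    var_prior_df: float = 4.0
    var_prior_scale: float = 0.05
    n_planted_targets: int = 30
    n_hubs: int = 5
    db_coverage: float = 0.8
    db_noise: int = 150
    net_n_nodes: int = 200
    net_n_edges_per_node: int = 3
    n_components: int = 22
    abund_alpha: float = 2.0
    abund_shift_component: str = "Neutrophils"
    abund_effect: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_train_case", "n_train_ctrl", "n_valid_case", "n_valid_ctrl"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.frac_de < 1.0:
            raise ValueError("frac_de must be in [0, 1)")
        if self.frac_de > 0 and self.frac_de * self.n_genes < 1:
            raise ValueError("frac_de * n_genes must be >= 1")
        if self.effect_range[0] <= 0 or self.effect_range[1] < self.effect_range[0]:
            raise ValueError("effect_range must be positive and ordered")
        if self.var_prior_df <= 0 or self.var_prior_scale <= 0:
            raise ValueError("variance prior parameters must be positive")
        if not 0.0 <= self.db_coverage <= 1.0:
            raise ValueError("db_coverage must be a probability")
        if self.db_noise > self.n_genes:
            raise ValueError("db_noise exceeds universe size")
        if self.n_hubs > self.net_n_nodes:
            raise ValueError("fewer network nodes than hubs")
        if self.abund_alpha <= 0 or self.abund_effect <= 0:
            raise ValueError("abundance concentrations must be positive")


@dataclass
class PlantedTruth:
    """Record of the planted structure for recovery scoring."""

    de_genes: dict[str, float] = field(default_factory=dict)  # symbol -> signed log2 effect
    target_genes: list[str] = field(default_factory=list)
    hub_genes: list[str] = field(default_factory=list)
    composition_shift: tuple[str, float] = ("", 1.0)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["composition_shift"] = tuple(d["composition_shift"])
        return cls(**d)


def gene_universe(config: SyntheticConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def _simulate_cohort(
    rng: np.random.Generator,
    genes: list[str],
    effects: np.ndarray,
    n_case: int,
    n_ctrl: int,
    prefix: str,
    config: SyntheticConfig,
) -> ExpressionMatrix:
    n_genes = len(genes)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, n_genes)
    # scaled inverse-chi-square: df * scale / chi2_df
    sigma2 = (
        config.var_prior_df * config.var_prior_scale
        / rng.chisquare(config.var_prior_df, n_genes)
    )
    n = n_case + n_ctrl
    noise = rng.normal(0.0, 1.0, (n_genes, n)) * np.sqrt(sigma2)[:, None]
    mean = baseline[:, None] + np.outer(effects, np.r_[np.ones(n_case), np.zeros(n_ctrl)])
    samples = [f"{prefix}_case_{i+1}" for i in range(n_case)] + [
        f"{prefix}_ctrl_{i+1}" for i in range(n_ctrl)
    ]
    values = pd.DataFrame(mean + noise, index=pd.Index(genes, name="symbol"), columns=samples)
    groups = pd.Series([CASE] * n_case + [CONTROL] * n_ctrl, index=samples)
    return ExpressionMatrix(values, groups)


def gen_cohorts(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PlantedTruth]:
    """Two independent case/control cohorts over a shared gene universe.

    Planted genes get the same signed log2 shift in cases of both cohorts;
    baselines, per-gene variances and noise are redrawn per cohort.
    """
    config.validate()
    rng = substream(config.seed, "cohorts")
    genes = gene_universe(config)
    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], int)
    lo, hi = config.effect_range
    magnitudes = rng.uniform(lo, hi, n_de)
    signs = rng.choice([-1.0, 1.0], n_de)
    effects = np.zeros(config.n_genes)
    effects[de_idx] = magnitudes * signs

    n_targets = min(config.n_planted_targets, n_de)
    target_idx = rng.choice(de_idx, size=n_targets, replace=False) if n_targets else np.array([], int)
    hub_genes = [genes[i] for i in target_idx[: config.n_hubs]]

    train = _simulate_cohort(
        rng, genes, effects, config.n_train_case, config.n_train_ctrl, "train", config
    )
    valid = _simulate_cohort(
        rng, genes, effects, config.n_valid_case, config.n_valid_ctrl, "valid", config
    )
    truth = PlantedTruth(
        de_genes={genes[i]: float(effects[i]) for i in de_idx},
        target_genes=[genes[i] for i in target_idx],
        hub_genes=hub_genes,
        composition_shift=(config.abund_shift_component, config.abund_effect),
    )
    return train, valid, truth


def _one_db(
    rng: np.random.Generator,
    name: str,
    planted: list[str],
    decoy_pool: list[str],
    config: SyntheticConfig,
    chemical: bool,
) -> TargetSet:
    kept = [g for g in planted if rng.random() < config.db_coverage]
    decoys = list(rng.choice(decoy_pool, size=min(config.db_noise, len(decoy_pool)), replace=False))
    rows = []
    for sym in kept + decoys:
        is_planted = sym in kept
        if chemical:
            source = "ctd" if rng.random() < 0.5 else "pharmmapper"
            p_direct = 0.9 if is_planted else 0.3
            itype = "direct" if rng.random() < p_direct else "indirect"
            score = rng.normal(1.5 if is_planted else 0.0, 1.0)
            rows.append((sym, source, itype, round(float(score), 4), "Homo sapiens"))
        else:
            rows.append((sym, "disease_db", np.nan, np.nan, "Homo sapiens"))
    df = pd.DataFrame(
        rows, columns=["symbol", "source", "interaction_type", "fit_score", "species"]
    )
    return TargetSet(name, df)


def gen_target_dbs(
    truth: PlantedTruth, universe: list[str], config: SyntheticConfig
) -> tuple[TargetSet, TargetSet, TargetSet]:
    """Disease database plus two chemical databases covering the planted targets.

    Each planted target enters each database independently with probability
    ``db_coverage``; ``db_noise`` random non-planted decoys are added.
    Chemical entries carry interaction-type annotation and a pharmacophore
    fit score, with planted genes biased toward "direct" and higher scores.
    """
    missing = set(truth.target_genes) - set(universe)
    if missing:
        raise ValueError(f"planted targets outside universe: {sorted(missing)[:5]}")
    rng = substream(config.seed, "target_dbs")
    decoy_pool = sorted(set(universe) - set(truth.target_genes))
    disease = _one_db(rng, "disease", truth.target_genes, decoy_pool, config, chemical=False)
    chem_a = _one_db(rng, "chemA", truth.target_genes, decoy_pool, config, chemical=True)
    chem_b = _one_db(rng, "chemB", truth.target_genes, decoy_pool, config, chemical=True)
    return disease, chem_a, chem_b


def gen_network(
    truth: PlantedTruth, universe: list[str], config: SyntheticConfig
) -> InteractionNetwork:
    """Preferential-attachment network with planted hubs over-wired.

    Hubs are additionally connected to random nodes until their degree is at
    least 3x the median degree. Edge confidence scores lie above the default
    0.4 threshold, emulating a pre-thresholded interaction export.
    """
    missing = set(truth.hub_genes) - set(universe)
    if missing:
        raise ValueError(f"hub genes outside universe: {sorted(missing)}")
    config.validate()
    rng = substream(config.seed, "network")
    n_nodes = min(config.net_n_nodes, len(universe))
    if n_nodes < len(truth.hub_genes):
        raise ValueError("fewer nodes than hubs")
    must = [g for g in truth.hub_genes + truth.target_genes if g in set(universe)]
    must = list(dict.fromkeys(must))[:n_nodes]
    others = sorted(set(universe) - set(must))
    fill = list(rng.choice(others, size=n_nodes - len(must), replace=False))
    nodes = must + fill
    order = rng.permutation(n_nodes)  # decouple BA insertion order from hub identity
    m = min(config.net_n_edges_per_node, n_nodes - 1)
    ba = nx.barabasi_albert_graph(n_nodes, m, seed=child_seed(config.seed, "ba"))
    g = nx.relabel_nodes(ba, {i: nodes[order[i]] for i in range(n_nodes)})
    degrees = dict(g.degree())
    median_deg = float(np.median(list(degrees.values())))
    max_other = max(d for v, d in degrees.items() if v not in truth.hub_genes) if truth.hub_genes else 0
    # hubs must dominate the natural preferential-attachment tail, not just
    # the median, to be recoverable by centrality ranking
    target_deg = int(np.ceil(max(3 * median_deg, 1.3 * max_other)))
    for hub in truth.hub_genes:
        candidates = [v for v in nodes if v != hub and not g.has_edge(hub, v)]
        rng.shuffle(candidates)
        while g.degree(hub) < target_deg and candidates:
            g.add_edge(hub, candidates.pop())
    for a, b in g.edges:
        g[a][b]["score"] = round(float(rng.uniform(0.41, 1.0)), 3)
    return InteractionNetwork(g, score_min=0.4)


def gen_abundance(
    config: SyntheticConfig,
    n_case: int | None = None,
    n_ctrl: int | None = None,
    effect: float | None = None,
) -> AbundanceTable:
    """Dirichlet compositions with one concentration-shifted component in cases.

    ``effect`` multiplies the shifted component's Dirichlet concentration in
    the case group; ``effect=1`` is the exact null (both groups share one
    Dirichlet).
    """
    config.validate()
    n_case = config.n_train_case if n_case is None else n_case
    n_ctrl = config.n_train_ctrl if n_ctrl is None else n_ctrl
    effect = config.abund_effect if effect is None else effect
    if config.n_components < 2:
        raise ValueError("need at least 2 components")
    if n_case < 3 or n_ctrl < 3:
        raise ValueError("need >= 3 samples per group")
    if effect <= 0:
        raise ValueError("effect must be positive")
    rng = substream(config.seed, "abundance")
    components = (IMMUNE_COMPONENTS * ((config.n_components // 22) + 1))[: config.n_components]
    components = [c if components.count(c) == 1 else f"{c} ({i})" for i, c in enumerate(components)]
    shift = config.abund_shift_component
    if shift not in components:
        shift = components[-1]
    alpha = np.full(config.n_components, config.abund_alpha)
    alpha_case = alpha.copy()
    alpha_case[components.index(shift)] *= effect
    case_rows = rng.dirichlet(alpha_case, n_case)
    ctrl_rows = rng.dirichlet(alpha, n_ctrl)
    samples = [f"case_{i+1}" for i in range(n_case)] + [f"ctrl_{i+1}" for i in range(n_ctrl)]
    values = pd.DataFrame(
        np.vstack([case_rows, ctrl_rows]), index=pd.Index(samples, name="sample"),
        columns=components,
    )
    groups = pd.Series([CASE] * n_case + [CONTROL] * n_ctrl, index=samples)
    return AbundanceTable(values, groups)
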