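"""End-to-end orchestration: configuration, stage sequencing, reporting.

Stages communicate through typed on-disk artifacts (TSV/CSV/JSON), so each
stage is independently runnable and testable from fixtures. A single global
seed fans out to per-stage named substreams; identical (config, seed) pairs
produce identical reports (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consensus, diffexpr, netrank, overlap_stats, robustness, syndata, targets
from ._rng import child_seed
from .containers import AbundanceTable, ExpressionMatrix, TargetSet

log = logging.getLogger("nettox")


@dataclass
class PipelineConfig:
    """All tunables of the triage pipeline, with study defaults.

    Canonical defaults: |log2FC| > 0.5 and p < 0.05
    (unadjusted) for DEGs, top-20% fit scores and direct-interaction
    filtering for chemical targets, 10,000 permutation iterations, top-20
    composite-centrality hubs, 5-fold CV, 100 nested-CV repeats, 1,000
    bootstrap iterations, and 1,000 shadow-feature runs.
    """

    # input paths
    train_expr: str = ""
    train_labels: str = ""
    valid_expr: str = ""
    valid_labels: str = ""
    disease_targets: str = ""
    chem_targets: str = ""
    chem_targets_b: str = ""
    network: str = ""
    abundance: str = ""
    # DEG thresholds
    lfc_min: float = 0.5
    p_max: float = 0.05
    use_adjusted: bool = False
    # context filter
    apply_context_filter: bool = False
    direct_only: bool = True
    fit_top_frac: float = 0.2
    # overlap
    n_perm: int = 10_000
    resample: str = "all"
    # network
    score_min: float = 0.4
    top_k: int = 20
    # ML
    n_folds: int = 5
    repeats: int = 100
    bootstrap_B: int = 1_000
    max_runs: int = 1_000
    alpha: float = 0.01
    gbt_rounds: int = 100
    # sensitivity grid
    grid_thresholds: tuple = robustness.DEFAULT_THRESHOLDS
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["grid_thresholds"] = list(d["grid_thresholds"])
        return d

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "grid_thresholds" in data:
            data["grid_thresholds"] = tuple(data["grid_thresholds"])
        return cls(**data)

    def hash(self) -> str:
        canon = yaml.safe_dump(self.as_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(report: dict, name: str):
    """Context-manager recording stage timing, output or failure."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                report["stages"][name] = {"status": "failed", "error": str(exc), "seconds": dt}
                log.error("stage %s: failed (%s)", name, exc)
                return True  # swallow; downstream stages will see missing inputs
            report["stages"][name].setdefault("status", "ok")
            report["stages"][name]["seconds"] = round(dt, 3)
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    report["stages"].setdefault(name, {})
    return _Ctx()


def _skip(report: dict, name: str, reason: str) -> None:
    report["stages"][name] = {"status": "skipped", "reason": reason}
    log.warning("stage %s: skipped (%s)", name, reason)


def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full triage pipeline and return the run report dict.

    Order: differential expression -> target integration -> overlap
    statistics -> network hub ranking -> consensus ML selection -> two-cohort
    validation / sensitivity grid / abundance testing. A failed stage is
    recorded and its dependents are skipped with a reason.
    """
    report: dict = {
        "config": config.as_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
    }
    outdir = Path(outdir) if outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    train = valid = None
    with _stage(report, "load"):
        train = ExpressionMatrix.read_tsv(config.train_expr, config.train_labels)
        valid = ExpressionMatrix.read_tsv(config.valid_expr, config.valid_labels)
        if len(set(train.genes) & set(valid.genes)) == 0:
            raise ValueError("cohorts share no gene symbols")
        report["stages"]["load"]["n_genes"] = int(len(train.genes))
        report["stages"]["load"]["n_train"] = int(len(train.samples))
        report["stages"]["load"]["n_valid"] = int(len(valid.samples))

    deg_table = None
    deg_symbols: set[str] = set()
    if train is not None:
        with _stage(report, "diffexpr"):
            deg_table = diffexpr.fit_moderated(train)
            up, down = diffexpr.threshold_degs(
                deg_table, config.lfc_min, config.p_max, config.use_adjusted
            )
            deg_symbols = up | down
            report["stages"]["diffexpr"].update(
                n_deg=len(deg_symbols), n_up=len(up), n_down=len(down),
                prior_df=float(deg_table.attrs["prior_df"]),
                prior_var=float(deg_table.attrs["prior_var"]),
            )
            if outdir:
                diffexpr.write_deg_tsv(deg_table, outdir / "deg_table.tsv")
    else:
        _skip(report, "diffexpr", "no expression input")

    disease = chem = None
    candidates = None
    if deg_table is not None and config.disease_targets and config.chem_targets:
        with _stage(report, "targets"):
            disease = targets.standardize(
                pd.read_csv(config.disease_targets), name="disease"
            )
            chem = targets.standardize(pd.read_csv(config.chem_targets), name="chemical")
            if config.apply_context_filter:
                chem = targets.context_filter(
                    chem, [train, valid], config.direct_only, config.fit_top_frac
                )
            candidates = targets.intersect3(deg_symbols, disease, chem)
            report["stages"]["targets"].update(
                n_disease=len(disease), n_chemical=len(chem),
                n_candidates=len(candidates),
                candidates=sorted(candidates.symbols),
                venn=targets.venn_summary(deg_symbols, disease, chem),
            )
    else:
        _skip(report, "targets", "missing DEGs or target lists")

    if candidates is not None and disease is not None and chem is not None:
        with _stage(report, "overlap"):
            background = set(train.genes)
            res = overlap_stats.permute_overlap(
                disease.symbols & background,
                chem.symbols & background,
                deg_symbols & background,
                background,
                n_perm=config.n_perm,
                seed=child_seed(config.seed, "overlap"),
                resample=config.resample,
            )
            d = dataclasses.asdict(res)
            d.pop("null_hist")
            report["stages"]["overlap"].update(d)
            if outdir:
                res.to_json(outdir / "overlap.json")
    else:
        _skip(report, "overlap", "no candidate set")

    if candidates is not None and config.network and len(candidates) > 0:
        with _stage(report, "netrank"):
            net = netrank.InteractionNetwork.read_tsv(config.network, config.score_min)
            sub = net.subgraph(candidates.symbols)
            if sub.graph.number_of_nodes() == 0:
                raise ValueError("no candidate appears in the network")
            table = netrank.rank_table(netrank.centralities(sub))
            top_k = min(config.top_k, len(table))
            hubs = list(table.index[:top_k])
            report["stages"]["netrank"].update(
                n_nodes=int(sub.graph.number_of_nodes()),
                n_edges=int(sub.graph.number_of_edges()),
                top_hubs=hubs,
            )
            if outdir:
                netrank.write_ranked_tsv(table, outdir / "centrality.tsv")
    else:
        _skip(report, "netrank", "no candidates or no network input")

    consensus_set: set[str] = set()
    fm = None
    if candidates is not None and len(candidates) >= 2:
        with _stage(report, "consensus"):
            fm = consensus.FeatureMatrix.from_expression(train, sorted(candidates.symbols))
            sel_l1 = consensus.l1_logistic_select(
                fm, config.n_folds, child_seed(config.seed, "l1")
            )
            sel_gbt = consensus.gbt_importance_select(
                fm, config.gbt_rounds, "nonzero", child_seed(config.seed, "gbt")
            )
            sel_shadow = consensus.shadow_feature_select(
                fm, config.max_runs, config.alpha, child_seed(config.seed, "shadow")
            )
            consensus_set = consensus.consensus_intersect([sel_l1, sel_gbt, sel_shadow])
            report["stages"]["consensus"].update(
                l1_selected=sorted(sel_l1.selected),
                gbt_selected=sorted(sel_gbt.selected),
                shadow_selected=sorted(sel_shadow.selected),
                consensus=sorted(consensus_set),
                log_lambda=sel_l1.settings["log_lambda"],
            )
        with _stage(report, "nested_cv"):
            cv = consensus.nested_cv(
                fm, config.n_folds, config.n_folds, config.repeats,
                child_seed(config.seed, "ncv"),
            )
            report["stages"]["nested_cv"].update(cv.to_json_dict())
        with _stage(report, "bootstrap"):
            stab = consensus.bootstrap_stability(
                fm, config.bootstrap_B, child_seed(config.seed, "boot"), config.n_folds
            )
            report["stages"]["bootstrap"].update(stab.to_json_dict())
            if outdir:
                consensus.write_frequency_tsv(stab, outdir / "stability.tsv")
    else:
        for name in ("consensus", "nested_cv", "bootstrap"):
            _skip(report, name, "fewer than 2 candidate genes")

    if consensus_set and valid is not None:
        with _stage(report, "validate"):
            verdicts = robustness.validate_core(sorted(consensus_set), train, valid)
            report["stages"]["validate"].update(
                core_targets=sorted(verdicts.index[verdicts["is_core"]]),
                table=json.loads(verdicts.to_json(orient="index")),
            )
            if outdir:
                verdicts.to_csv(outdir / "validation.tsv", sep="\t")
    else:
        _skip(report, "validate", "empty consensus set")

    if disease is not None and chem is not None and deg_table is not None:
        with _stage(report, "grid"):
            grid = robustness.sensitivity_grid(
                train, disease, chem, config.grid_thresholds,
                tracked=sorted(consensus_set), deg_table=deg_table,
                p_max=config.p_max,
            )
            report["stages"]["grid"].update(
                table=grid.to_dict(orient="records")
            )
            if outdir:
                grid.to_csv(outdir / "sensitivity_grid.tsv", sep="\t", index=False)
    else:
        _skip(report, "grid", "missing targets stage outputs")

    if config.abundance:
        with _stage(report, "abundance"):
            tab = AbundanceTable.read_tsv(config.abundance)
            res = robustness.abundance_group_test(tab)
            report["stages"]["abundance"].update(
                n_components=int(len(res)),
                sig_p=sorted(res.index[res["sig_p"]]),
                sig_q=sorted(res.index[res["sig_q"]]),
            )
            if outdir:
                res.to_csv(outdir / "abundance_test.tsv", sep="\t")
    else:
        _skip(report, "abundance", "no abundance input")

    report["n_failed"] = sum(
        1 for s in report["stages"].values() if s.get("status") == "failed"
    )
    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, tuple)):
        return sorted(o) if isinstance(o, set) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


# ---------------------------------------------------------------------------
# Fixture bundles


SCALES = {
    # tiny: end-to-end smoke bundle, runs in well under a minute
    "tiny": dict(
        syn=dict(
            n_genes=300, n_train_case=8, n_train_ctrl=8, n_valid_case=5, n_valid_ctrl=5,
            frac_de=0.1, n_planted_targets=12, n_hubs=3, db_noise=40, net_n_nodes=80,
        ),
        cfg=dict(n_perm=500, repeats=5, bootstrap_B=50, max_runs=60, gbt_rounds=50),
    ),
    # study: clinical-scale cohort sizes and scaled list magnitudes
    "study": dict(
        syn=dict(
            n_genes=2000, n_train_case=9, n_train_ctrl=8, n_valid_case=6, n_valid_ctrl=6,
            frac_de=0.05, n_planted_targets=30, n_hubs=5, db_noise=150, net_n_nodes=200,
        ),
        cfg=dict(),
    ),
}


def make_fixture(scale: str, seed: int, outdir: str | Path) -> PipelineConfig:
    """Write a complete synthetic input bundle and its pipeline config."""
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {sorted(SCALES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scale_spec = SCALES[scale]
    syn = syndata.SyntheticConfig(seed=seed, **scale_spec["syn"])
    train, valid, truth = syndata.gen_cohorts(syn)
    disease, chem_a, chem_b = syndata.gen_target_dbs(truth, syndata.gene_universe(syn), syn)
    net = syndata.gen_network(truth, syndata.gene_universe(syn), syn)
    abund = syndata.gen_abundance(syn)

    train.write_tsv(outdir / "expr_train.tsv", outdir / "labels_train.tsv")
    valid.write_tsv(outdir / "expr_valid.tsv", outdir / "labels_valid.tsv")
    disease.write_csv(outdir / "targets_disease.csv")
    chem_a.write_csv(outdir / "targets_chemA.csv")
    chem_b.write_csv(outdir / "targets_chemB.csv")
    net.write_tsv(outdir / "network.tsv")
    abund.write_tsv(outdir / "abundance.tsv")
    truth.to_json(outdir / "truth.json")

    config = PipelineConfig(
        train_expr=str(outdir / "expr_train.tsv"),
        train_labels=str(outdir / "labels_train.tsv"),
        valid_expr=str(outdir / "expr_valid.tsv"),
        valid_labels=str(outdir / "labels_valid.tsv"),
        disease_targets=str(outdir / "targets_disease.csv"),
        chem_targets=str(outdir / "targets_chemA.csv"),
        chem_targets_b=str(outdir / "targets_chemB.csv"),
        network=str(outdir / "network.tsv"),
        abundance=str(outdir / "abundance.tsv"),
        seed=seed,
        **scale_spec["cfg"],
    )
    config.to_yaml(outdir / "config.yaml")
    return config
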