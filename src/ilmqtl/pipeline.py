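"""End-to-end orchestration: simulate/load -> QC -> heritability -> QTL ->
networks -> trait associations, with a machine-readable run report.

The report is deterministic for a fixed configuration (including seeds):
JSON with sorted keys, no timestamps, so identical runs hash identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mapping, networks, preprocess, quantgen, simulate, traits
from .errors import ConfigError, IlmqtlError
from .panel import BinMap, MetabolitePanel, read_bin_map, read_class_table, read_panel


@dataclass
class RunConfig:
    """Flat configuration for :func:`run_pipeline`.

    Either ``sim`` (a :class:`~ilmqtl.simulate.SimConfig`) or ``panel_path``
    must be given.  Defaults mirror the study settings: alpha 0.05, FDR
    level 0.01, 10 imputation repeats, 10 CV folds, the 9-value penalty
    grid.
    """

    sim: simulate.SimConfig | None = None
    panel_path: str | None = None
    bin_map_path: str | None = None
    class_table_path: str | None = None
    traits_path: str | None = None
    control_id: str = simulate.CONTROL_ID
    alpha: float = 0.05
    fdr_level: float = 0.01
    test_variant: str = "anova"
    n_impute_repeats: int = 10
    impute_seed: int = 0
    penalty_grid: tuple = traits.PENALTY_GRID
    cv_folds: int = 10
    cv_seed: int = 0
    heritability_basis: str = "plot"
    outdir: str | None = None

    @classmethod
    def from_mapping(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        sim_doc = doc.pop("sim", None)
        cfg = cls(**doc)
        if sim_doc is not None:
            qtl = [simulate.QtlEffect(**q) if isinstance(q, dict) else simulate.QtlEffect(*q)
                   for q in sim_doc.pop("qtl_effects", [])]
            cfg.sim = simulate.SimConfig(qtl_effects=qtl, **sim_doc)
        return cfg


def _stage(report: dict, name: str, **info) -> None:
    report["stages"].append({"stage": name, **info})


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in fixed order; returns (and optionally writes)
    the run report.  Any stage failure aborts with the stage name."""
    if (config.sim is None) == (config.panel_path is None):
        raise ConfigError("exactly one of sim / panel_path must be set")
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_doc(config), "stages": [], "outputs": {}}

    def emit(name: str, obj, writer) -> None:
        if outdir:
            path = outdir / name
            writer(obj, path)
            report["outputs"][name] = str(path)

    stage = "input"
    try:
        truth = None
        if config.sim is not None:
            panel, truth = simulate.simulate_panel(config.sim)
            bin_map = simulate.simulate_bin_map(config.sim.n_ils, seed=config.sim.seed)
            class_table = simulate.simulate_class_table(panel.metabolites, seed=config.sim.seed)
            emit("truth.csv", truth, lambda t, p: simulate.write_truth(t, p))
        else:
            panel = read_panel(config.panel_path)
            bin_map = read_bin_map(config.bin_map_path) if config.bin_map_path else None
            class_table = (read_class_table(config.class_table_path)
                           if config.class_table_path else None)
        _stage(report, stage, n_rows=panel.values.shape[0],
               n_metabolites=panel.values.shape[1], n_missing=panel.n_missing)

        stage = "filter"
        panel, filt = preprocess.filter_panel(panel)
        _stage(report, stage, removed_lines=filt.removed_lines,
               removed_metabolites=filt.removed_metabolites)

        stage = "impute"
        panel, audit = preprocess.impute_panel(
            panel, n_repeats=config.n_impute_repeats, seed=config.impute_seed)
        _stage(report, stage, n_imputed=len(audit.cells), method=audit.method,
               n_repeats=audit.n_repeats)
        emit("panel_imputed.csv", panel, lambda p, f: p.write_csv(f))

        stage = "variance_components"
        vrep = quantgen.variance_report(panel)
        _stage(report, stage,
               mean_cvg_by_experiment={str(e): float(g["Cvg"].mean())
                                       for e, g in vrep.groupby("experiment")},
               mean_cve_by_experiment={str(e): float(g["Cve"].mean())
                                       for e, g in vrep.groupby("experiment")})
        emit("variance_report.csv", vrep, lambda d, f: d.to_csv(f, index=False))

        experiments = panel.experiments
        herit = None
        if len(experiments) >= 2:
            stage = "heritability"
            herit = quantgen.heritability(panel, basis=config.heritability_basis)
            _stage(report, stage, basis=config.heritability_basis,
                   mean_H2=float(herit["H2"].mean()),
                   min_H2=float(herit["H2"].min()), max_H2=float(herit["H2"].max()))
            emit("heritability.csv", herit, lambda d, f: d.to_csv(f))

        stage = "qtl_tests"
        tests = {e: mapping.per_line_tests(panel, e, config.control_id,
                                           alpha=config.alpha, variant=config.test_variant)
                 for e in experiments}
        _stage(report, stage,
               significant_by_experiment={str(e): int(t["significant"].sum())
                                          for e, t in tests.items()},
               variant=config.test_variant, alpha=config.alpha)

        calls = None
        if len(experiments) >= 2:
            stage = "qtl_calls"
            calls = mapping.call_conserved(tests[experiments[0]], tests[experiments[1]],
                                           alpha=config.alpha)
            rec = {"n_conserved": len(calls), "n_untestable": calls.n_untestable}
            if truth is not None and len(truth.qtl):
                truth_set = set(zip(truth.qtl["il"], truth.qtl["metabolite"]))
                called = set(zip(calls.calls["il"], calls.calls["metabolite"]))
                rec["recall"] = len(truth_set & called) / len(truth_set)
                rec["false_calls"] = len(called - truth_set)
            _stage(report, stage, **rec)
            emit("calls.csv", calls.calls, lambda d, f: d.to_csv(f, index=False))

            if bin_map is not None and class_table is not None and len(calls.calls):
                stage = "qtl_summary"
                summary = mapping.summarize_calls(calls, class_table, bin_map)
                _, gene_range = mapping.genes_per_qtl(calls, bin_map)
                _stage(report, stage, total=summary.total,
                       by_direction=summary.by_direction,
                       by_class=summary.by_class,
                       by_chromosome={str(k): v for k, v in summary.by_chromosome.items()},
                       genes_per_qtl_range=list(gene_range))

            stage = "overlay"
            lfc = preprocess.log2_fold_change(panel, config.control_id)
            e1, e2 = experiments[0], experiments[1]
            l1 = lfc.xs(e1, level="experiment").drop(index=config.control_id)
            l2 = lfc.xs(e2, level="experiment").drop(index=config.control_id)
            sig = {e: tests[e].pivot(index="il", columns="metabolite", values="significant")
                   .loc[l1.index, l1.columns] for e in (e1, e2)}
            score, category = mapping.overlay_matrix(l1, l2, sig[e1], sig[e2])
            cat_counts = category.stack().value_counts().to_dict()
            _stage(report, stage, category_counts={str(k): int(v)
                                                   for k, v in cat_counts.items()})
            emit("overlay_scores.tsv", score, lambda d, f: d.to_csv(f, sep="\t"))
            emit("overlay_categories.tsv", category, lambda d, f: d.to_csv(f, sep="\t"))

        stage = "network"
        nets = {}
        for e in experiments:
            profiles = panel.line_level_means(experiment=e)
            nets[e] = networks.relevance_network(profiles, level=config.fdr_level)
            emit(f"network_exp{e}.csv", nets[e], lambda n, f: n.write_csv(f))
        _stage(report, stage, level=config.fdr_level,
               edges_by_experiment={str(e): len(n) for e, n in nets.items()})

        if config.traits_path:
            stage = "trait_association"
            trait_table = pd.read_csv(config.traits_path, index_col=0)
            profiles = {e: panel.line_level_means(experiment=e) for e in experiments}
            predictors = traits.season_predictors(profiles)
            models = traits.fit_trait_models(
                predictors, trait_table, penalty_grid=config.penalty_grid,
                k=config.cv_folds, seed=config.cv_seed)
            _, edge_df = traits.build_association_network(models)
            _stage(report, stage,
                   traits={t: {"penalty": m.penalty_selected, "r_squared": m.r_squared,
                               "n_nonzero": int((m.coefficients != 0).sum())}
                           for t, m in models.items()})
            emit("trait_edges.csv", edge_df, lambda d, f: d.to_csv(f, index=False))
    except IlmqtlError as err:
        raise IlmqtlError(f"pipeline stage {stage!r} failed: {err}") from err

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        report["outputs"]["report.json"] = str(outdir / "report.json")
    return report


def _config_doc(config: RunConfig) -> dict:
    doc = asdict(config)
    if config.sim is not None:
        doc["sim"]["qtl_effects"] = [
            {"il": q.il, "metabolite": q.metabolite, "delta": q.delta}
            for q in config.sim.effects()
        ]
    return doc


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
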