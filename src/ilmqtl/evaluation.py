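"""Self-contained calibration and recovery studies on synthetic panels.

These routines exercise the package end-to-end under controlled ground
truth: null calibration of the conserved-QTL caller, power against planted
effects, variance-component / heritability recovery, and empirical FDR of
the relevance network.  They are used by the acceptance checks and are
handy for sanity-checking parameter choices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mapping import call_conserved, per_line_tests
from .networks import relevance_network
from .quantgen import anova_mean_squares, heritability, variance_components
from .simulate import QtlEffect, SimConfig, simulate_panel


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible 31-bit child seeds from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def null_conserved_rate(seed: int, n_seeds: int = 30, n_ils: int = 76,
                        n_metabolites: int = 44, alpha: float = 0.05,
                        variant: str = "anova", keep_tables: bool = False) -> dict:
    """Conserved-call rate under the global null (no genotype effects).

    With two independent two-sided tests at level ``alpha`` plus the
    direction-agreement requirement, the analytic rate is alpha^2/2.
    """
    n_calls = n_pairs = 0
    tables = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(n_ils=n_ils, n_metabolites=n_metabolites, sigma_g=0.0,
                        sigma_ge=0.0, sigma_env=0.3, sigma_eps=0.35, seed=s)
        panel, _ = simulate_panel(cfg)
        t1 = per_line_tests(panel, 1, cfg.control_id, alpha=alpha, variant=variant)
        t2 = per_line_tests(panel, 2, cfg.control_id, alpha=alpha, variant=variant)
        res = call_conserved(t1, t2, alpha=alpha)
        n_calls += len(res)
        n_pairs += len(res.pairs)
        if keep_tables:
            tables.append((t1, t2))
    out = {"rate": n_calls / n_pairs, "n_pairs": n_pairs, "n_calls": n_calls,
           "expected": alpha**2 / 2}
    if keep_tables:
        out["tables"] = tables
    return out


def planted_qtl_recall(seed: int, n_seeds: int = 10, n_ils: int = 76,
                       n_metabolites: int = 42, n_qtl: int = 40,
                       effect_in_sd: float = 3.0, sigma_eps: float = 0.35,
                       variant: str = "anova") -> dict:
    """Recall of planted conserved QTL with |delta| = effect_in_sd * sigma_eps."""
    recalls = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        cells = rng.choice(n_ils * n_metabolites, size=n_qtl, replace=False)
        effects = [QtlEffect(int(c // n_metabolites), int(c % n_metabolites),
                             float(rng.choice([-1.0, 1.0])) * effect_in_sd * sigma_eps)
                   for c in cells]
        cfg = SimConfig(n_ils=n_ils, n_metabolites=n_metabolites, sigma_g=0.0,
                        sigma_ge=0.0, sigma_env=0.3, sigma_eps=sigma_eps,
                        qtl_effects=effects, seed=s)
        panel, truth = simulate_panel(cfg)
        t1 = per_line_tests(panel, 1, cfg.control_id, variant=variant)
        t2 = per_line_tests(panel, 2, cfg.control_id, variant=variant)
        res = call_conserved(t1, t2)
        called = set(zip(res.calls["il"], res.calls["metabolite"]))
        truth_set = set(zip(truth.qtl["il"], truth.qtl["metabolite"]))
        recalls.append(len(called & truth_set) / len(truth_set))
    return {"recall": float(np.mean(recalls)), "n_seeds": n_seeds,
            "per_seed": recalls}


def variance_recovery(seed: int, n_seeds: int = 20, n_ils: int = 76,
                      r: int = 4, sigma2_g: float = 2.0,
                      sigma2_e: float = 0.5) -> dict:
    """Recovery of (sigma2_g, sigma2_e) from one-way ANOVA on one experiment.

    sigma2_e = QMe/r is the error variance of a genotype mean, so the
    residual SD is sqrt(sigma2_e * r).
    """
    est_g, est_e = [], []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(n_ils=n_ils, n_metabolites=1, n_replicates=r,
                        n_experiments=1, sigma_g=np.sqrt(sigma2_g), sigma_env=0,
                        sigma_ge=0, sigma_eps=np.sqrt(sigma2_e * r), seed=s)
        panel, _ = simulate_panel(cfg)
        log = panel.to_log2().values
        ms = anova_mean_squares(log.iloc[:, 0],
                                log.index.get_level_values("genotype"))
        s2g, s2e, _ = variance_components(ms.qmg, ms.qme, ms.r)
        est_g.append(s2g)
        est_e.append(s2e)
    return {"sigma2_g": float(np.mean(est_g)), "sigma2_e": float(np.mean(est_e)),
            "truth": (sigma2_g, sigma2_e), "n_seeds": n_seeds}


def heritability_recovery(seed: int, n_seeds: int = 20, n_ils: int = 76,
                          sigma2_G: float = 1.0, sigma2_GE: float = 0.5,
                          sigma2_eps: float = 0.5) -> dict:
    """Mean plot-basis H2-hat; truth = s2G / (s2G + s2GE + s2eps)."""
    h2s = []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(n_ils=n_ils, n_metabolites=1, sigma_g=np.sqrt(sigma2_G),
                        sigma_env=0.3, sigma_ge=np.sqrt(sigma2_GE),
                        sigma_eps=np.sqrt(sigma2_eps), seed=s)
        panel, _ = simulate_panel(cfg)
        h2s.append(float(heritability(panel, basis="plot")["H2"].iloc[0]))
    truth = sigma2_G / (sigma2_G + sigma2_GE + sigma2_eps)
    return {"h2_mean": float(np.mean(h2s)), "truth": truth, "n_seeds": n_seeds}


def network_null_fdr(seed: int, n_seeds: int = 50, n_lines: int = 76,
                     n_features: int = 40, level: float = 0.01) -> dict:
    """Empirical FDR (mean false-discovery proportion) of the edge set
    under a complete independence null: every declared edge is false."""
    fdps = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        prof = pd.DataFrame(rng.standard_normal((n_lines, n_features)),
                            index=[f"L{i}" for i in range(n_lines)],
                            columns=[f"f{j}" for j in range(n_features)])
        net = relevance_network(prof, level=level)
        fdps.append(1.0 if len(net) > 0 else 0.0)
    return {"fdr": float(np.mean(fdps)), "level": level, "n_seeds": n_seeds,
            "n_pairs_per_seed": n_features * (n_features - 1) // 2}
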