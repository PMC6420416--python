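"""Preprocessing: line/metabolite filtering, imputation, fold changes.

The filtering rules mirror standard metabolomics QC for IL panels:

(i)   drop lines for which no metabolite was ever detected;
(ii)  drop metabolites unavailable (at line level) in more than half of the
      lines — a line counts as missing a metabolite only when *all* of its
      replicate cells are missing;
(iii) impute the remaining holes with a random-forest scheme, repeating the
      imputation several times and averaging the runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer

from .errors import DegenerateInputError, MissingDataError
from .panel import MetabolitePanel, replace_below_detection


@dataclass
class FilterReport:
    removed_lines: list = field(default_factory=list)
    removed_metabolites: list = field(default_factory=list)
    mode: str = "per_experiment"

    @property
    def n_removed(self) -> int:
        return len(self.removed_lines) + len(self.removed_metabolites)


def _line_level_missing(values: pd.DataFrame) -> pd.DataFrame:
    """lines x metabolites boolean: all replicate cells of the line missing."""
    return values.isna().groupby(level="genotype", sort=False).all()


def filter_panel(
    panel: MetabolitePanel,
    max_missing_line_fraction: float = 0.5,
    mode: str = "per_experiment",
) -> tuple[MetabolitePanel, FilterReport]:
    """Apply the line and metabolite availability filters.

    Lines with every cell missing are removed; then metabolites that are
    line-level missing in strictly more than ``max_missing_line_fraction``
    of the surviving lines are removed.  With ``mode="per_experiment"`` the
    metabolite rule is evaluated within each experiment and a metabolite
    must survive in every experiment (the per-experiment detected sets are
    intersected); ``mode="concatenated"`` evaluates it on the pooled data.
    The two steps are iterated to a fixed point, so the operation is
    idempotent.
    """
    if mode not in ("per_experiment", "concatenated"):
        raise ValueError(f"unknown filter mode {mode!r}")
    values = panel.values
    report = FilterReport(mode=mode)
    while True:
        changed = False
        # (i) lines in which none of the metabolites were detectable
        all_missing = values.isna().groupby(level="genotype", sort=False).all().all(axis=1)
        dead_lines = list(all_missing.index[all_missing])
        if dead_lines:
            values = values[~values.index.get_level_values("genotype").isin(dead_lines)]
            report.removed_lines.extend(dead_lines)
            changed = True
        if values.empty:
            raise DegenerateInputError("no lines survive filtering")
        # (ii) metabolites unavailable in more than half of the lines
        if mode == "concatenated":
            frac = _line_level_missing(values).mean(axis=0)
            drop = frac > max_missing_line_fraction
        else:
            fracs = []
            for exp in values.index.get_level_values("experiment").unique():
                sub = values.xs(exp, level="experiment")
                fracs.append(_line_level_missing(sub).mean(axis=0))
            drop = pd.concat(fracs, axis=1).max(axis=1) > max_missing_line_fraction
        dead_mets = list(drop.index[drop])
        if dead_mets:
            values = values.drop(columns=dead_mets)
            report.removed_metabolites.extend(dead_mets)
            changed = True
        if values.empty or not len(values.columns):
            raise DegenerateInputError("no metabolites survive filtering")
        if not changed:
            break
    classes = None
    if panel.classes:
        classes = {m: c for m, c in panel.classes.items() if m in values.columns}
    return MetabolitePanel(values.copy(), panel.scale, classes), report


@dataclass
class ImputationAudit:
    """Which cells were imputed, with between-run variability."""

    cells: list[tuple] = field(default_factory=list)  # (genotype, replicate, experiment, metabolite)
    run_variance: dict[tuple, float] = field(default_factory=dict)
    n_repeats: int = 0
    method: str = "forest"


def _forest_impute_once(X: np.ndarray, miss: np.ndarray, rng: np.random.Generator,
                        n_estimators: int, max_iter: int, tol: float,
                        max_depth: int | None) -> np.ndarray:
    """One missForest-style chained run: iterate columns (ascending
    missingness), regressing each on all others with a random forest, until
    the relative change over imputed cells drops below ``tol``."""
    X = X.copy()
    col_means = np.nanmean(X, axis=0)
    for j in range(X.shape[1]):
        X[miss[:, j], j] = col_means[j]
    order = np.argsort(miss.sum(axis=0))
    order = [j for j in order if miss[:, j].any()]
    prev_fill = X[miss].copy()
    prev_change = np.inf
    for _ in range(max_iter):
        for j in order:
            obs = ~miss[:, j]
            others = np.delete(np.arange(X.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                max_features="sqrt",  # missForest's default mtry
                max_depth=max_depth,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[np.ix_(obs, others)], X[obs, j])
            X[miss[:, j], j] = rf.predict(X[np.ix_(miss[:, j], others)])
        cur = X[miss]
        denom = np.sum(cur**2)
        change = np.sum((cur - prev_fill) ** 2) / denom if denom > 0 else 0.0
        if change > prev_change:  # chained updates stopped improving: revert
            X[miss] = prev_fill
            break
        prev_fill = cur.copy()
        prev_change = change
        if change < tol:
            break
    return X


def impute_panel(
    panel: MetabolitePanel,
    n_repeats: int = 10,
    seed: int = 0,
    method: str = "auto",
    n_estimators: int = 15,
    max_depth: int | None = 6,
    max_iter: int = 3,
    tol: float = 1e-3,
    knn_k: int = 5,
) -> tuple[MetabolitePanel, ImputationAudit]:
    """Fill missing cells with the average of ``n_repeats`` imputation runs.

    Imputation operates on log2-transformed values (for a raw panel) so the
    regressions see approximately Gaussian columns; results are mapped back
    to the panel's original scale.  Observed cells are never altered.

    ``method="forest"`` is a missForest-style chained random-forest scheme;
    ``"knn"`` uses k-nearest-neighbour imputation on standardized
    metabolites (Euclidean metric) and is also the automatic fallback for
    panels too small to fit forests (< 4 metabolites or < 10 rows).
    """
    mask = panel.mask
    audit = ImputationAudit(n_repeats=n_repeats)
    if not mask.to_numpy().any():
        audit.method = "none"
        return panel.copy(), audit

    n_obs = (~mask).sum(axis=0)
    thin = n_obs[n_obs < 2]
    if len(thin):
        raise MissingDataError(
            f"metabolite(s) {list(thin.index)} have fewer than 2 observed values"
        )
    if method == "auto":
        method = "knn" if (panel.values.shape[1] < 4 or panel.values.shape[0] < 10) else "forest"
    audit.method = method

    log_scale = panel.scale == "log2"
    work = panel.values if log_scale else np.log2(replace_below_detection(panel.values))
    X = work.to_numpy(dtype=float)
    miss = mask.to_numpy()

    seeds = np.random.SeedSequence(seed).spawn(n_repeats)
    fills = np.empty((n_repeats, int(miss.sum())))
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        if method == "forest":
            filled = _forest_impute_once(X, miss, rng, n_estimators, max_iter, tol, max_depth)
        elif method == "knn":
            mu, sd = np.nanmean(X, axis=0), np.nanstd(X, axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            imp = KNNImputer(n_neighbors=min(knn_k, int(n_obs.min())))
            filled = imp.fit_transform((X - mu) / sd) * sd + mu
        else:
            raise ValueError(f"unknown imputation method {method!r}")
        fills[rep] = filled[miss]

    mean_fill = fills.mean(axis=0)
    out = X.copy()
    out[miss] = mean_fill
    values = pd.DataFrame(out, index=panel.values.index, columns=panel.values.columns)
    if not log_scale:
        values = np.exp2(values)
        values = values.where(mask, panel.values)  # observed cells bit-identical
    rows, cols = np.nonzero(miss)
    idx = panel.values.index
    met = panel.values.columns
    var = fills.var(axis=0)
    for k, (i, j) in enumerate(zip(rows, cols)):
        cell = (*idx[i], met[j])
        audit.cells.append(cell)
        audit.run_variance[cell] = float(var[k])
    return MetabolitePanel(values, panel.scale, panel.classes), audit


def log2_fold_change(panel: MetabolitePanel, control_id: str) -> pd.DataFrame:
    """Per-(genotype, experiment) log2 ratio of genotype mean to control mean.

    Computed on raw-scale values; exact zeros are treated as
    below-detection and replaced by half the metabolite's smallest positive
    value before averaging.
    """
    raw = panel.to_raw()
    if control_id not in raw.genotypes:
        raise MissingDataError(f"control genotype {control_id!r} not in panel")
    vals = replace_below_detection(raw.values)
    means = vals.groupby(level=["genotype", "experiment"], sort=False).mean()
    out = {}
    for exp in raw.experiments:
        ctrl = means.loc[(control_id, exp)]
        zero_ctrl = ctrl[(ctrl == 0) | ctrl.isna()]
        if len(zero_ctrl):
            raise MissingDataError(
                f"control mean is 0/undefined for {list(zero_ctrl.index)} in experiment {exp!r}"
            )
        sub = means.xs(exp, level="experiment")
        out[exp] = np.log2(sub.div(ctrl, axis=1))
    lfc = pd.concat(out, names=["experiment", "genotype"]).swaplevel().sort_index()
    return lfc
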