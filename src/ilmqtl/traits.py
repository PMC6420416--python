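"""Trait-metabolite association by elastic-net regression.

Each phenotypic trait (one value per line) is regressed on the line-level
metabolite profiles of both seasons, concatenated as predictors (one
column per metabolite per season).  The fit minimizes

    (1/2n) * ||y - Xb||^2  +  lambda_ridge * ||b||^2 / 2  +  lambda_lasso * ||b||_1

by cyclic coordinate descent on standardized predictors and response.  The
single "penalty" value of the published grid (0.01, 0.05, 0.1, 0.5, 1,
1.5, 2, 10, 100) is interpreted as the ridge penalty, with the lasso
penalty a fixed fraction of it (default 0.5) — elastic-net tooling of that
era was parameterized by an L2 penalty plus an L1 fraction but reported a
single grid.  The penalty is selected by 10-fold cross-validation with a
seeded fold permutation; the final model is refit on all data and its
in-sample r-squared recorded (the node-size statistic of the association
network).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError

PENALTY_GRID = (0.01, 0.05, 0.1, 0.5, 1.0, 1.5, 2.0, 10.0, 100.0)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize; zero-SD columns are left centered (coef stays 0)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd


@dataclass
class ElasticNetFit:
    coef: np.ndarray
    intercept: float
    objective_path: list[float] = field(default_factory=list)
    n_sweeps: int = 0
    converged: bool = True


def _objective(X, y, beta, lambda_ridge, lambda_lasso) -> float:
    n = len(y)
    resid = y - X @ beta
    return (resid @ resid / (2.0 * n)
            + lambda_ridge * (beta @ beta) / 2.0
            + lambda_lasso * np.abs(beta).sum())


def elastic_net_fit(X, y, lambda_ridge: float, lambda_lasso: float,
                    tol: float = 1e-7, max_sweeps: int = 10_000) -> ElasticNetFit:
    """Cyclic coordinate descent for the elastic net on standardized data.

    Expects column-standardized X (zero-SD columns tolerated, their
    coefficients stay 0).  The objective is tracked per sweep and checked
    to be non-increasing; convergence when the largest coefficient change
    in a sweep is below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ConfigError("non-finite values in regression inputs")
    if lambda_ridge < 0 or lambda_lasso < 0:
        raise ConfigError("penalties must be >= 0")
    n, p = X.shape
    intercept = float(y.mean())
    yc = y - intercept
    beta = np.zeros(p)
    col_sq = (X**2).sum(axis=0) / n  # ~1 for standardized columns, 0 for constant
    resid = yc.copy()
    fit = ElasticNetFit(beta, intercept)
    fit.objective_path.append(_objective(X, yc, beta, lambda_ridge, lambda_lasso))
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            b_old = beta[j]
            rho = (X[:, j] @ resid) / n + col_sq[j] * b_old
            b_new = np.sign(rho) * max(abs(rho) - lambda_lasso, 0.0) / (col_sq[j] + lambda_ridge)
            if b_new != b_old:
                resid -= X[:, j] * (b_new - b_old)
                beta[j] = b_new
                max_delta = max(max_delta, abs(b_new - b_old))
        obj = _objective(X, yc, beta, lambda_ridge, lambda_lasso)
        if obj > fit.objective_path[-1] + 1e-10:
            raise AssertionError("coordinate-descent objective increased")
        fit.objective_path.append(obj)
        if max_delta < tol:
            fit.n_sweeps = sweep + 1
            return fit
    fit.n_sweeps = max_sweeps
    fit.converged = False
    return fit


@dataclass
class TraitAssociation:
    """Cross-validated elastic-net model for one trait."""

    trait: str
    penalty_selected: float
    coefficients: pd.Series  # standardized scale; index = predictor labels
    r_squared: float
    cv_errors: dict[float, float]
    lasso_fraction: float
    cv_folds: int
    seed: int


def cv_select(X: pd.DataFrame, y: pd.Series, penalty_grid=PENALTY_GRID, k: int = 10,
              seed: int = 0, lasso_fraction: float = 0.5,
              trait: str = "trait") -> TraitAssociation:
    """Select the penalty by k-fold CV, refit on all data, record r-squared.

    Folds come from a seeded permutation of the lines.  For each grid
    penalty ``lam``: lambda_ridge = lam, lambda_lasso = lasso_fraction*lam.
    The penalty minimizing mean out-of-fold squared error wins (ties ->
    larger penalty, the more parsimonious model).
    """
    n = len(y)
    if n < k:
        raise DegenerateInputError(f"n={n} lines < k={k} folds; reduce k")
    Xs_full, _, col_sd = standardize(X.to_numpy(dtype=float))
    y_arr = y.to_numpy(dtype=float)
    y_sd = y_arr.std() or 1.0
    ys_full = (y_arr - y_arr.mean()) / y_sd

    X_raw = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    cv_errors = {}
    for lam in penalty_grid:
        errs = []
        for fold in folds:
            test = np.zeros(n, dtype=bool)
            test[fold] = True
            Xtr, mu_tr, sd_tr = standardize(X_raw[~test])
            f = elastic_net_fit(Xtr, ys_full[~test], lam, lasso_fraction * lam)
            # apply the training standardization to the held-out rows
            sd_safe = np.where(sd_tr == 0, 1.0, sd_tr)
            Xte = (X_raw[test] - mu_tr) / sd_safe
            pred = f.intercept + Xte @ f.coef
            errs.append(float(np.mean((ys_full[test] - pred) ** 2)))
        cv_errors[float(lam)] = float(np.mean(errs))
    best = min(sorted(cv_errors, reverse=True), key=lambda lam: cv_errors[lam])
    final = elastic_net_fit(Xs_full, ys_full, best, lasso_fraction * best)
    resid = ys_full - (final.intercept + Xs_full @ final.coef)
    tss = float((ys_full - ys_full.mean()) @ (ys_full - ys_full.mean()))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    r2 = float(np.clip(r2, 0.0, 1.0))
    return TraitAssociation(trait, best, pd.Series(final.coef, index=X.columns),
                            r2, cv_errors, lasso_fraction, k, seed)


def season_predictors(profiles_by_season: dict, mode: str = "columns") -> pd.DataFrame:
    """Concatenate per-season line-level profiles into a predictor table.

    ``mode="columns"`` (default): each metabolite contributes one column
    per season, rows = lines present in every season.  ``mode="rows"``
    stacks seasons as extra observations (the trait value is then repeated
    per season by the caller).
    """
    if mode == "columns":
        blocks = []
        shared = None
        for season, prof in profiles_by_season.items():
            shared = prof.index if shared is None else shared.intersection(prof.index)
        for season, prof in profiles_by_season.items():
            sub = prof.loc[shared].copy()
            sub.columns = [f"{m}@s{season}" for m in prof.columns]
            blocks.append(sub)
        return pd.concat(blocks, axis=1)
    if mode == "rows":
        frames = []
        for season, prof in profiles_by_season.items():
            f = prof.copy()
            f.index = pd.MultiIndex.from_product([[season], f.index], names=["season", "line"])
            frames.append(f)
        return pd.concat(frames, axis=0)
    raise ValueError(f"unknown season concatenation mode {mode!r}")


def fit_trait_models(predictors: pd.DataFrame, traits: pd.DataFrame,
                     penalty_grid=PENALTY_GRID, k: int = 10, seed: int = 0,
                     lasso_fraction: float = 0.5) -> dict[str, TraitAssociation]:
    """Fit one CV-selected elastic net per trait column (shared line index)."""
    shared = predictors.index.intersection(traits.index)
    models = {}
    for trait in traits.columns:
        y = traits.loc[shared, trait].dropna()
        X = predictors.loc[y.index]
        models[trait] = cv_select(X, y, penalty_grid=penalty_grid, k=min(k, len(y)),
                                  seed=seed, lasso_fraction=lasso_fraction, trait=trait)
    return models


def build_association_network(trait_models: dict[str, TraitAssociation]):
    """Bipartite trait <-> predictor network from the fitted models.

    Edges exist only for nonzero coefficients, signed by the coefficient;
    trait nodes carry their model r-squared (the node-size statistic).
    Returns (networkx graph, edge DataFrame).
    """
    import networkx as nx

    g = nx.Graph()
    rows = []
    for trait, model in trait_models.items():
        g.add_node(trait, kind="trait", r_squared=model.r_squared)
        nz = model.coefficients[model.coefficients != 0]
        for pred, coef in nz.items():
            if not g.has_node(pred):
                g.add_node(pred, kind="metabolite")
            sign = "positive" if coef > 0 else "negative"
            g.add_edge(trait, pred, weight=float(coef), sign=sign)
            rows.append({"trait": trait, "predictor": pred,
                         "coefficient": float(coef), "sign": sign,
                         "r_squared": model.r_squared})
    edges = pd.DataFrame(rows, columns=["trait", "predictor", "coefficient",
                                        "sign", "r_squared"])
    return g, edges
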