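"""Variance components, coefficients of variation, broad-sense heritability.

Per experiment, a one-way random-effects ANOVA over genotypes yields the
genotype and error mean squares (QMg, QMe) from which

    sigma2_g = (QMg - QMe) / r        sigma2_e = QMe / r
    Cvg(%)   = 100 * sqrt(sigma2_g) / mc
    Cve(%)   = 100 * sqrt(sigma2_e) / mc

with r the replicate count and mc the trait mean.  Across the two
experiments, a balanced two-way random model (genotype, environment, G-by-E,
residual) is solved by the expected-mean-squares method of moments:

    E[MS_G]  = sigma2_eps + r*sigma2_GE + r*E*sigma2_G
    E[MS_E]  = sigma2_eps + r*sigma2_GE + r*G*sigma2_E
    E[MS_GE] = sigma2_eps + r*sigma2_GE
    E[MS_W]  = sigma2_eps

Negative solutions are truncated at zero (flagged).  Broad-sense
heritability on the default plot basis is

    H2 = sigma2_G / (sigma2_G + sigma2_GE + sigma2_eps)

and on the entry-mean basis sigma2_G / (sigma2_G + sigma2_GE/E +
sigma2_eps/(r*E)).  For unbalanced replicate counts the harmonic-mean r
enters the EMS coefficients (flagged); an iterative REML refinement is
available for unbalanced data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import MissingDataError
from .panel import MetabolitePanel

HERITABILITY_BASES = ("plot", "entry_mean")


@dataclass(frozen=True)
class MeanSquares:
    qmg: float
    qme: float
    r: float  # harmonic mean when unbalanced
    balanced: bool


def anova_mean_squares(values, genotypes) -> MeanSquares:
    """One-way ANOVA mean squares for genotype groups.

    QMg = SS_between/(G-1); QMe = SS_within/sum(n_g - 1).  Every genotype
    needs >= 2 observed replicates.  For unbalanced groups the harmonic
    mean replicate count is reported for use in the EMS formulas.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": np.asarray(genotypes)})
    df = df.dropna()
    counts = df.groupby("g")["y"].count()
    if len(counts) < 2:
        raise MissingDataError("need at least 2 genotypes")
    thin = counts[counts < 2]
    if len(thin):
        raise MissingDataError(f"genotype(s) {list(thin.index)} have fewer than 2 replicates")
    grand = df["y"].mean()
    means = df.groupby("g")["y"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(((df["y"] - means.loc[df["g"]].to_numpy()) ** 2).sum())
    g = len(counts)
    qmg = ss_between / (g - 1)
    qme = ss_within / float((counts - 1).sum())
    balanced = counts.nunique() == 1
    r = float(counts.iloc[0]) if balanced else float(len(counts) / (1.0 / counts).sum())
    return MeanSquares(qmg, qme, r, balanced)


def variance_components(qmg: float, qme: float, r: float) -> tuple[float, float, bool]:
    """(sigma2_g, sigma2_e, truncated) from the printed formulas."""
    if r <= 0:
        raise ValueError("replicate count r must be positive")
    if qmg < 0 or qme < 0:
        raise ValueError("mean squares must be >= 0")
    sigma2_g = (qmg - qme) / r
    truncated = sigma2_g < 0
    return (max(sigma2_g, 0.0), qme / r, truncated)


def cv_coefficients(sigma2_g: float, sigma2_e: float, mc: float) -> tuple[float, float]:
    """Genotypic and environmental coefficients of variation, in percent."""
    if mc == 0:
        raise ValueError("trait mean mc must be nonzero")
    return (100.0 * np.sqrt(sigma2_g) / mc, 100.0 * np.sqrt(sigma2_e) / mc)


def variance_report(panel: MetabolitePanel, experiment=None) -> pd.DataFrame:
    """Per-metabolite QMg/QMe, variance components and Cvg/Cve (percent).

    Computed on raw-scale values (fold changes), per experiment by default;
    pass ``experiment`` to restrict to one, or the report stacks one block
    per experiment.  Rows with a truncated (negative) genotype variance are
    flagged.
    """
    raw = panel.to_raw()
    experiments = [experiment] if experiment is not None else raw.experiments
    blocks = []
    for exp in experiments:
        sub = raw.experiment_view(exp)
        geno = sub.index.get_level_values("genotype")
        rows = []
        for met in sub.columns:
            y = sub[met]
            ok = y.notna()
            ms = anova_mean_squares(y[ok], geno[ok])
            s2g, s2e, trunc = variance_components(ms.qmg, ms.qme, ms.r)
            mc = float(y.mean())
            cvg, cve = cv_coefficients(s2g, s2e, mc)
            rows.append({"experiment": exp, "metabolite": met, "QMg": ms.qmg, "QMe": ms.qme,
                         "r": ms.r, "mc": mc, "sigma2_g": s2g, "sigma2_e": s2e,
                         "Cvg": cvg, "Cve": cve, "truncated": trunc,
                         "balanced": ms.balanced})
        blocks.append(pd.DataFrame(rows))
    return pd.concat(blocks, ignore_index=True)


def _two_way_mean_squares(wide: pd.DataFrame):
    """Mean squares of the balanced two-way layout.

    ``wide``: rows (genotype, replicate, experiment), one column ``y``.
    Returns (ms_g, ms_e, ms_ge, ms_w, G, E, r, balanced).
    """
    y = wide["y"]
    if y.isna().any():
        raise MissingDataError("missing cells present — impute the panel first")
    geno = wide.index.get_level_values("genotype")
    exp = wide.index.get_level_values("experiment")
    G, E = geno.nunique(), exp.nunique()
    counts = wide.groupby([geno, exp])["y"].count()
    if (counts < 2).any():
        raise MissingDataError("every genotype x experiment cell needs >= 2 replicates")
    balanced = counts.nunique() == 1
    r = float(counts.iloc[0]) if balanced else float(len(counts) / (1.0 / counts).sum())

    grand = y.mean()
    m_g = y.groupby(geno).mean()
    m_e = y.groupby(exp).mean()
    m_ge = y.groupby([geno, exp]).mean()
    ms_g = r * E * float(((m_g - grand) ** 2).sum()) / (G - 1)
    ms_e = r * G * float(((m_e - grand) ** 2).sum()) / (E - 1)
    inter = m_ge.copy()
    for (gi, ei), v in m_ge.items():
        inter.loc[(gi, ei)] = v - m_g.loc[gi] - m_e.loc[ei] + grand
    ms_ge = r * float((inter**2).sum()) / ((G - 1) * (E - 1))
    cell_mean = m_ge.loc[list(zip(geno, exp))].to_numpy()
    ss_w = float(((y.to_numpy() - cell_mean) ** 2).sum())
    ms_w = ss_w / float((counts - 1).sum())
    return ms_g, ms_e, ms_ge, ms_w, G, E, r, balanced


def heritability(panel: MetabolitePanel, basis: str = "plot", reml: bool = False) -> pd.DataFrame:
    """Broad-sense heritability per metabolite from a two-experiment panel.

    Operates on log2-transformed values.  Requires a complete panel
    (impute first) with >= 2 genotypes, >= 2 experiments and >= 2
    replicates per cell.  ``basis`` is ``"plot"`` (default) or
    ``"entry_mean"``; the basis label is carried in the output.
    """
    if basis not in HERITABILITY_BASES:
        raise ValueError(f"basis must be one of {HERITABILITY_BASES}")
    log = panel.to_log2()
    if len(log.experiments) < 2:
        raise MissingDataError("heritability needs at least 2 experiments")
    rows = []
    for met in log.metabolites:
        wide = log.values[[met]].rename(columns={met: "y"})
        ms_g, ms_e, ms_ge, ms_w, G, E, r, balanced = _two_way_mean_squares(wide)
        s2_eps = ms_w
        s2_ge = max((ms_ge - ms_w) / r, 0.0)
        s2_G = max((ms_g - ms_ge) / (r * E), 0.0)
        s2_E = max((ms_e - ms_ge) / (r * G), 0.0)
        truncated = (ms_ge < ms_w) or (ms_g < ms_ge) or (ms_e < ms_ge)
        if reml and not balanced:
            s2_G, s2_E, s2_ge, s2_eps = _reml_components(
                wide, x0=(s2_G, s2_E, s2_ge, s2_eps)
            )
            truncated = False
        if basis == "plot":
            denom = s2_G + s2_ge + s2_eps
        else:
            denom = s2_G + s2_ge / E + s2_eps / (r * E)
        h2 = s2_G / denom if denom > 0 else 0.0
        rows.append({"metabolite": met, "sigma2_G": s2_G, "sigma2_E": s2_E,
                     "sigma2_GE": s2_ge, "sigma2_eps": s2_eps, "H2": h2,
                     "basis": basis, "r": r, "balanced": balanced,
                     "truncated": truncated})
    return pd.DataFrame(rows).set_index("metabolite")


def _reml_components(wide: pd.DataFrame, x0) -> tuple[float, float, float, float]:
    """REML for the two-way random model by direct restricted likelihood.

    Intended for modest, possibly unbalanced layouts; optimizes
    log-variances with Nelder-Mead starting from the moment estimates.
    """
    y = wide["y"].to_numpy(dtype=float)
    n = len(y)
    geno = pd.factorize(wide.index.get_level_values("genotype"))[0]
    exp = pd.factorize(wide.index.get_level_values("experiment"))[0]
    cell = pd.factorize(list(zip(geno, exp)))[0]
    Zg = np.eye(geno.max() + 1)[geno]
    Ze = np.eye(exp.max() + 1)[exp]
    Zge = np.eye(cell.max() + 1)[cell]
    X = np.ones((n, 1))

    def neg_restricted_ll(log_s2):
        s2 = np.exp(log_s2)
        V = (s2[0] * Zg @ Zg.T + s2[1] * Ze @ Ze.T + s2[2] * Zge @ Zge.T
             + s2[3] * np.eye(n))
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return np.inf
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        resid = y - X @ beta
        return 0.5 * (logdet + np.log(np.linalg.det(XtViX)) + resid @ Vi @ resid)

    x0 = np.log(np.clip(np.asarray(x0, dtype=float), 1e-6, None))
    res = optimize.minimize(neg_restricted_ll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    return tuple(np.exp(res.x))
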