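"""Synthetic IL-population metabolite panels with known ground truth.

The generator emulates the design of a *S. pennellii* introgression-line
study: ~76 ILs plus the recurrent-parent control (M82), grown with four
replicate plants per genotype in each of two independent experiments
(environments), profiled for a few dozen primary metabolites.

On the log2 scale each observation decomposes additively as

    y[i,j,k,m] = mu[m] + g[i,m] + e[k,m] + ge[i,k,m] + delta[i,m] + eps[i,j,k,m]

with independent zero-mean Gaussian genotype (g), environment (e),
genotype-by-environment (ge) and residual (eps) effects, and planted QTL
shifts ``delta`` applied to chosen (IL, metabolite) pairs.  QTL shifts are
applied identically in both experiments by default, so every planted effect
is a "conserved" QTL by construction.  The control genotype carries no
genotype effect and no QTL.  Panels are exported on the raw scale
(``2**y``), mirroring fold-change tables.

Default variance components (log2 units: sigma_g=0.8, sigma_env=0.3,
sigma_ge=0.55, sigma_eps=0.35) place the genotypic coefficient of variation
near 75%, the environmental one near 25%, and plot-basis heritability around
0.6 — the regime reported for leaf primary metabolites in this population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .panel import BinMap, METABOLITE_CLASSES, MetabolitePanel

CONTROL_ID = "M82"


@dataclass(frozen=True)
class QtlEffect:
    """A planted QTL: signed log2 shift for one (IL, metabolite) pair.

    ``experiments`` restricts the shift to a subset of experiments
    (1-based); ``None`` applies it in every experiment, which makes the
    effect conserved by construction.
    """

    il: int
    metabolite: int
    delta: float
    experiments: tuple[int, ...] | None = None

    @property
    def sign(self) -> int:
        return int(np.sign(self.delta))


@dataclass
class SimConfig:
    """Study design and generative parameters for :func:`simulate_panel`.

    All SDs are on the log2 scale and may be scalars or per-metabolite
    arrays.  ``rho_g`` adds an exchangeable correlation between the genotype
    effects of different metabolites (real metabolite panels are strongly
    inter-correlated; 0 = independent columns).
    """

    n_ils: int = 76
    n_replicates: int = 4
    n_experiments: int = 2
    n_metabolites: int = 42
    mu: float | Sequence[float] = 0.0
    sigma_g: float | Sequence[float] = 0.8
    sigma_env: float | Sequence[float] = 0.3
    sigma_ge: float | Sequence[float] = 0.55
    sigma_eps: float | Sequence[float] = 0.35
    rho_g: float = 0.0
    qtl_effects: Sequence[QtlEffect | tuple] = field(default_factory=list)
    missing_rate: float = 0.0
    missing_mechanism: str = "mcar"  # or "censor" (below-detection)
    seed: int = 0
    control_id: str = CONTROL_ID

    def _sd(self, name: str) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (self.n_metabolites,))
        if not np.all(np.isfinite(arr)):
            raise ConfigError(f"{name} must be finite")
        if (arr < 0).any():
            raise ConfigError(f"{name} must be >= 0")
        return arr

    def validate(self) -> None:
        for n, v in (("n_ils", self.n_ils), ("n_replicates", self.n_replicates),
                     ("n_experiments", self.n_experiments), ("n_metabolites", self.n_metabolites)):
            if int(v) < 1:
                raise ConfigError(f"{n} must be >= 1")
        mu = np.broadcast_to(np.asarray(self.mu, dtype=float), (self.n_metabolites,))
        if not np.all(np.isfinite(mu)):
            raise ConfigError("mu must be finite")
        for name in ("sigma_g", "sigma_env", "sigma_ge", "sigma_eps"):
            self._sd(name)
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.rho_g <= 1.0:
            raise ConfigError("rho_g must be in [0, 1]")
        if self.missing_mechanism not in ("mcar", "censor"):
            raise ConfigError(f"unknown missing mechanism {self.missing_mechanism!r}")
        for q in self.effects():
            if not (0 <= q.il < self.n_ils):
                raise ConfigError(f"QTL il index {q.il} out of range")
            if not (0 <= q.metabolite < self.n_metabolites):
                raise ConfigError(f"QTL metabolite index {q.metabolite} out of range")
            if not np.isfinite(q.delta):
                raise ConfigError("QTL delta must be finite")

    def effects(self) -> list[QtlEffect]:
        out = []
        for q in self.qtl_effects:
            out.append(q if isinstance(q, QtlEffect) else QtlEffect(*q))
        return out

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class TruthRecord:
    """Ground truth of a simulated panel: planted QTL and variance components."""

    qtl: pd.DataFrame  # columns il, metabolite, delta, sign
    variance_components: pd.DataFrame  # per metabolite: mu, sigma2_g, sigma2_env, sigma2_ge, sigma2_eps
    control_id: str = CONTROL_ID

    @property
    def true_qtl(self) -> set[tuple]:
        return {(r.il, r.metabolite, r.sign) for r in self.qtl.itertuples()}


def il_names(n_ils: int) -> list[str]:
    return [f"IL{i + 1:02d}" for i in range(n_ils)]


def metabolite_names(n: int) -> list[str]:
    return [f"met_{m + 1:02d}" for m in range(n)]


def simulate_panel(config: SimConfig) -> tuple[MetabolitePanel, TruthRecord]:
    """Draw one replicate-level panel (raw scale) plus its ground truth.

    Deterministic for a fixed config (including seed).  The control
    genotype has zero genotype and G-by-E effect and never carries a QTL.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_i, r, n_e, n_m = config.n_ils, config.n_replicates, config.n_experiments, config.n_metabolites
    genos = il_names(n_i) + [config.control_id]
    mets = metabolite_names(n_m)
    mu = np.broadcast_to(np.asarray(config.mu, dtype=float), (n_m,))
    s_g, s_env = config._sd("sigma_g"), config._sd("sigma_env")
    s_ge, s_eps = config._sd("sigma_ge"), config._sd("sigma_eps")

    # genotype effects; rho_g shares one factor u[i] across metabolites
    u = rng.standard_normal((n_i, 1))
    v = rng.standard_normal((n_i, n_m))
    g = s_g * (np.sqrt(config.rho_g) * u + np.sqrt(1.0 - config.rho_g) * v)
    g = np.vstack([g, np.zeros((1, n_m))])  # control: g = 0
    e = s_env * rng.standard_normal((n_e, n_m))
    ge = s_ge * rng.standard_normal((n_i, n_e, n_m))
    ge = np.concatenate([ge, np.zeros((1, n_e, n_m))], axis=0)  # control: ge = 0

    delta = np.zeros((n_i + 1, n_e, n_m))
    for q in config.effects():
        exps = range(n_e) if q.experiments is None else [k - 1 for k in q.experiments]
        for k in exps:
            if not 0 <= k < n_e:
                raise ConfigError(f"QTL experiment index {k + 1} out of range")
            delta[q.il, k, q.metabolite] += q.delta

    eps = s_eps * rng.standard_normal((n_i + 1, r, n_e, n_m))
    y = (mu[None, None, None, :] + g[:, None, None, :] + e[None, None, :, :]
         + ge[:, None, :, :] + delta[:, None, :, :] + eps)

    rows = pd.MultiIndex.from_product(
        [genos, range(1, r + 1), range(1, n_e + 1)],
        names=["genotype", "replicate", "experiment"],
    )
    values = pd.DataFrame(np.exp2(y).reshape(-1, n_m), index=rows, columns=mets)

    if config.missing_rate > 0:
        if config.missing_mechanism == "mcar":
            holes = rng.random(values.shape) < config.missing_rate
        else:  # left-censoring: the lowest missing_rate fraction per metabolite
            ranks = values.rank(axis=0, pct=True, method="first").to_numpy()
            holes = ranks <= config.missing_rate
        values = values.mask(holes)

    qtl_rows = [
        {"il": genos[q.il], "metabolite": mets[q.metabolite], "delta": q.delta, "sign": q.sign}
        for q in config.effects()
    ]
    qtl = pd.DataFrame(qtl_rows, columns=["il", "metabolite", "delta", "sign"])
    vc = pd.DataFrame(
        {"mu": mu, "sigma2_g": s_g**2, "sigma2_env": s_env**2,
         "sigma2_ge": s_ge**2, "sigma2_eps": s_eps**2},
        index=pd.Index(mets, name="metabolite"),
    )
    return MetabolitePanel(values, scale="raw"), TruthRecord(qtl, vc, config.control_id)


def truth_table(truth: TruthRecord) -> pd.DataFrame:
    """Planted QTL as a table (il, metabolite, delta, sign), one row per effect."""
    return truth.qtl.copy()


def write_truth(truth: TruthRecord, path: str | Path) -> None:
    truth_table(truth).to_csv(path, index=False)


# ------------------------------------------------------------- companion tables
def simulate_bin_map(n_ils: int = 76, seed: int = 0, control_id: str = CONTROL_ID) -> BinMap:
    """Synthetic IL -> bin assignment covering chromosomes 1..12.

    ILs tile the genome in order; gene counts per introgressed segment are
    drawn uniformly from the published range 98..2185 (mean near 295 is not
    enforced — segments, not bins, carry the count).
    """
    rng = np.random.default_rng(seed)
    ils = il_names(n_ils)
    chroms = 1 + (np.arange(n_ils) * 12) // n_ils
    bins, seen = [], {}
    for c in chroms:
        seen[c] = seen.get(c, 0) + 1
        bins.append(f"{c}-{seen[c]}")
    table = pd.DataFrame(
        {"chromosome": chroms, "bin": bins,
         "gene_count": rng.integers(98, 2186, size=n_ils)},
        index=pd.Index(ils, name="il_id"),
    )
    return BinMap(table)


def simulate_class_table(metabolites: Sequence[str], seed: int = 0) -> dict[str, str]:
    """Assign compound classes in study-like proportions (15:10:7:10)."""
    rng = np.random.default_rng(seed)
    weights = np.array([15, 10, 7, 10], dtype=float)
    classes = rng.choice(METABOLITE_CLASSES, size=len(metabolites), p=weights / weights.sum())
    return dict(zip(metabolites, classes))
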