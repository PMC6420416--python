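"""Conserved metabolite-QTL calling and genome-level summaries.

Each IL is compared with the recurrent-parent control per experiment and
per metabolite; an (IL, metabolite) effect that is significant at the 5%
level in *both* independent experiments with the *same* direction of
change is called a conserved mQTL.  Replication across environments, not a
multiple-testing correction, is the error control: under the global null
the per-pair false-call rate is alpha^2/2 (two independent two-sided tests
at level alpha, times 1/2 for direction agreement).

Test variants
-------------
``"anova"`` (default): contrast of the IL against the control using the
residual mean square pooled over all genotypes in that experiment
(Dunnett-style t without multiplicity adjustment, df = sum(n_g - 1)).
With homoscedastic residuals this is the ANOVA-consistent comparison and
has markedly higher power at small replicate counts than the two-sample
test, while remaining exactly calibrated under the null.
``"student"``: pooled-variance two-sample t-test (IL vs. control only).
``"welch"``: unequal-variance two-sample t-test.

All tests are run on log2-transformed abundances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, MissingDataError
from .panel import BinMap, MetabolitePanel

TEST_VARIANTS = ("anova", "student", "welch")
OVERLAY_CATEGORIES = ("conserved_up", "conserved_down", "inconsistent", "neutral")


def _group_stats(sub: pd.DataFrame):
    """Per-genotype mean / count / within-group SS for one experiment block."""
    geno = sub.index.get_level_values("genotype")
    grp = sub.groupby(geno, sort=False)
    return grp.mean(), grp.count(), grp.agg(lambda s: float(((s - s.mean()) ** 2).sum()))


def per_line_tests(
    panel: MetabolitePanel,
    experiment,
    control_id: str,
    alpha: float = 0.05,
    variant: str = "anova",
) -> pd.DataFrame:
    """Compare every IL against the control for one experiment.

    Returns a table (il, metabolite) -> (p, lfc, significant, untestable).
    ``lfc`` is the log2 ratio of raw genotype mean to raw control mean;
    the p-value comes from the chosen t-test variant on log2 abundances.
    Pairs where either group has < 2 observed replicates are reported as
    untestable (p = NaN), never silently dropped.
    """
    if variant not in TEST_VARIANTS:
        raise ValueError(f"variant must be one of {TEST_VARIANTS}")
    raw = panel.to_raw()
    if control_id not in raw.genotypes:
        raise MissingDataError(f"control genotype {control_id!r} not in panel")
    log = panel.to_log2()
    sub = log.experiment_view(experiment)
    raw_sub = raw.experiment_view(experiment)

    means, counts, ss = _group_stats(sub)
    raw_means = raw_sub.groupby(raw_sub.index.get_level_values("genotype"), sort=False).mean()
    ctrl_mean, ctrl_n, ctrl_ss = means.loc[control_id], counts.loc[control_id], ss.loc[control_id]
    ils = [g for g in means.index if g != control_id]

    # pooled residual MSE over all genotypes (anova variant)
    pooled_ss = ss.sum(axis=0)
    pooled_df = (counts - 1).clip(lower=0).sum(axis=0).astype(float)

    rows = []
    for il in ils:
        m_il, n_il, ss_il = means.loc[il], counts.loc[il], ss.loc[il]
        diff = m_il - ctrl_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(raw_means.loc[il] / raw_means.loc[control_id])
        testable = (n_il >= 2) & (ctrl_n >= 2)
        if variant == "anova":
            df = pooled_df
            mse = pooled_ss / df.replace(0, np.nan)
        elif variant == "student":
            df = (n_il + ctrl_n - 2).astype(float)
            mse = (ss_il + ctrl_ss) / df.replace(0, np.nan)
        else:  # welch
            v_il = ss_il / (n_il - 1).replace(0, np.nan)
            v_c = ctrl_ss / (ctrl_n - 1).replace(0, np.nan)
            se2 = v_il / n_il + v_c / ctrl_n
            df = se2**2 / ((v_il / n_il) ** 2 / (n_il - 1) + (v_c / ctrl_n) ** 2 / (ctrl_n - 1))
        if variant == "welch":
            tstat = diff / np.sqrt(se2)
        else:
            tstat = diff / np.sqrt(mse * (1.0 / n_il + 1.0 / ctrl_n))
        p = pd.Series(
            2.0 * stats.t.sf(np.abs(tstat.to_numpy(dtype=float)), df.to_numpy(dtype=float)),
            index=tstat.index,
        )
        p[~testable] = np.nan
        for met in sub.columns:
            rows.append({
                "il": il, "metabolite": met, "p": float(p[met]), "lfc": float(lfc[met]),
                "significant": bool(p[met] <= alpha) if np.isfinite(p[met]) else False,
                "untestable": not bool(testable[met]),
            })
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["experiment"] = experiment
    out.attrs["variant"] = variant
    return out


@dataclass
class ConservedCalls:
    """Result of the two-experiment replication rule."""

    calls: pd.DataFrame  # conserved calls only
    pairs: pd.DataFrame  # every shared (il, metabolite) pair with both tests
    n_untestable: int
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.calls)


def call_conserved(tests_exp1: pd.DataFrame, tests_exp2: pd.DataFrame,
                   alpha: float = 0.05) -> ConservedCalls:
    """Apply the replication rule: significant in both experiments, same sign.

    A pair is conserved iff p1 <= alpha, p2 <= alpha and
    sign(lfc1) = sign(lfc2) != 0.  Untestable pairs (either experiment)
    are excluded from calling and counted.
    """
    merged = tests_exp1.merge(
        tests_exp2, on=["il", "metabolite"], suffixes=("_exp1", "_exp2"), how="inner"
    )
    if merged.empty:
        raise DegenerateInputError("the two experiments share no (il, metabolite) pairs")
    untestable = merged["untestable_exp1"] | merged["untestable_exp2"]
    s1 = np.sign(merged["lfc_exp1"])
    s2 = np.sign(merged["lfc_exp2"])
    conserved = (
        ~untestable
        & (merged["p_exp1"] <= alpha)
        & (merged["p_exp2"] <= alpha)
        & (s1 == s2)
        & (s1 != 0)
    )
    merged["conserved"] = conserved
    merged["direction"] = np.where(s1 > 0, "positive", "negative")
    merged.loc[~conserved, "direction"] = ""
    cols = ["il", "metabolite", "p_exp1", "p_exp2", "lfc_exp1", "lfc_exp2",
            "direction", "conserved"]
    calls = merged.loc[conserved, cols].reset_index(drop=True)
    return ConservedCalls(calls, merged[cols + ["untestable_exp1", "untestable_exp2"]],
                          int(untestable.sum()), alpha)


@dataclass
class CallSummary:
    total: int
    by_direction: dict
    by_class: dict
    by_chromosome: dict
    per_il: dict

    def consistent(self) -> bool:
        return (sum(self.by_direction.values()) == self.total
                and sum(self.by_class.values()) == self.total
                and sum(self.by_chromosome.values()) == self.total
                and sum(self.per_il.values()) == self.total)


def summarize_calls(calls: ConservedCalls | pd.DataFrame, class_table: dict[str, str],
                    bin_map: BinMap) -> CallSummary:
    """Count conserved calls by direction, compound class, chromosome and IL."""
    df = calls.calls if isinstance(calls, ConservedCalls) else calls
    unclassified = sorted(set(df["metabolite"]) - set(class_table))
    if unclassified:
        raise MissingDataError(f"metabolites without a class: {unclassified}")
    unmapped = sorted({il for il in df["il"].unique() if il not in bin_map})
    if unmapped:
        raise MissingDataError(f"ILs without a bin-map entry: {unmapped}")
    by_dir = df["direction"].value_counts().to_dict()
    by_class = df["metabolite"].map(class_table).value_counts().to_dict()
    by_chrom = df["il"].map(lambda il: bin_map.chromosome(il)).value_counts().to_dict()
    per_il = df["il"].value_counts().to_dict()
    return CallSummary(len(df), by_dir, by_class, {int(k): v for k, v in by_chrom.items()}, per_il)


def genes_per_qtl(calls: ConservedCalls | pd.DataFrame,
                  bin_map: BinMap) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Annotated-gene count of each called IL's segment, with the (min, max) range."""
    df = (calls.calls if isinstance(calls, ConservedCalls) else calls).copy()
    missing = sorted({il for il in df["il"].unique() if il not in bin_map})
    if missing:
        raise MissingDataError(f"no gene_count for ILs: {missing}")
    df["gene_count"] = df["il"].map(lambda il: bin_map.gene_count(il))
    if df.empty:
        return df, (0, 0)
    return df, (int(df["gene_count"].min()), int(df["gene_count"].max()))


def overlay_matrix(lfc_exp1: pd.DataFrame, lfc_exp2: pd.DataFrame,
                   sig_exp1: pd.DataFrame, sig_exp2: pd.DataFrame
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive overlay of the two experiments' fold-change matrices.

    Returns (score, category): score = lfc1 + lfc2; category is
    ``conserved_up``/``conserved_down`` where both experiments are
    significant with a common sign, ``inconsistent`` where both are
    significant with opposite signs, else ``neutral``.
    """
    for other in (lfc_exp2, sig_exp1, sig_exp2):
        if other.shape != lfc_exp1.shape:
            raise ValueError("overlay inputs must share one shape")
        if not (other.index.equals(lfc_exp1.index) and other.columns.equals(lfc_exp1.columns)):
            raise ValueError("overlay inputs must share index and columns")
    score = lfc_exp1 + lfc_exp2
    s1, s2 = np.sign(lfc_exp1), np.sign(lfc_exp2)
    both = sig_exp1.astype(bool) & sig_exp2.astype(bool)
    category = pd.DataFrame("neutral", index=lfc_exp1.index, columns=lfc_exp1.columns)
    category = category.mask(both & (s1 == s2) & (s1 > 0), "conserved_up")
    category = category.mask(both & (s1 == s2) & (s1 < 0), "conserved_down")
    category = category.mask(both & (s1 == -s2) & (s1 != 0), "inconsistent")
    return score, category


def cross_tissue_overlap(calls_by_tissue: dict[str, ConservedCalls | pd.DataFrame]
                         ) -> pd.DataFrame:
    """(IL, metabolite) pairs called in >= 2 tissues, with per-tissue direction.

    Flags direction reversals between tissues (e.g. a metabolite lowered in
    leaves but raised in fruits of the same IL).
    """
    frames = []
    for tissue, calls in calls_by_tissue.items():
        df = calls.calls if isinstance(calls, ConservedCalls) else calls
        frames.append(df[["il", "metabolite", "direction"]].assign(tissue=tissue))
    if not frames:
        return pd.DataFrame(columns=["il", "metabolite", "n_tissues", "directions", "reversal"])
    stacked = pd.concat(frames, ignore_index=True)
    rows = []
    for (il, met), grp in stacked.groupby(["il", "metabolite"]):
        if len(grp) < 2:
            continue
        directions = dict(zip(grp["tissue"], grp["direction"]))
        rows.append({"il": il, "metabolite": met, "n_tissues": len(grp),
                     "directions": directions,
                     "reversal": len(set(directions.values())) > 1})
    return pd.DataFrame(rows, columns=["il", "metabolite", "n_tissues", "directions", "reversal"])


def plot_overlay(score: pd.DataFrame, category: pd.DataFrame, path=None):
    """Render the overlay heat map (red = conserved up, blue = down,
    purple = inconsistent); returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lim = float(np.nanmax(np.abs(score.to_numpy()))) or 1.0
    fig, ax = plt.subplots(figsize=(max(4, score.shape[1] * 0.2),
                                    max(4, score.shape[0] * 0.12)))
    ax.imshow(score.to_numpy(), cmap="bwr", vmin=-lim, vmax=lim, aspect="auto")
    inconsistent = (category == "inconsistent").to_numpy()
    ys, xs = np.nonzero(inconsistent)
    ax.scatter(xs, ys, s=6, c="purple", marker="s")
    ax.set_xlabel("metabolite")
    ax.set_ylabel("introgression line")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
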