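"""Replicate-level metabolite panels and the tabular formats around them.

A :class:`MetabolitePanel` holds relative metabolite abundances for an
introgression-line (IL) population: one row per (genotype, replicate,
experiment) plant, one column per metabolite.  Values are fold changes
relative to the recurrent-parent control (or raw relative abundances);
missing cells are NaN and exposed through :attr:`MetabolitePanel.mask`.

The on-disk layout is a wide CSV/TSV with three leading key columns
``genotype,replicate,experiment`` followed by one numeric column per
metabolite.  Empty cells and the tokens ``NA``/``NaN`` (case-insensitive)
denote missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, MissingDataError, PanelFormatError

KEY_COLUMNS = ("genotype", "replicate", "experiment")

#: tokens (lower-cased) accepted as missing-value markers in panel files
NA_TOKENS = frozenset({"", "na", "nan"})

METABOLITE_CLASSES = ("amino_acid", "sugar", "organic_acid", "other")


def _normalize_metabolite(name: str) -> str:
    """Case-insensitive, whitespace-normalized metabolite key."""
    return " ".join(str(name).split()).lower()


@dataclass
class MetabolitePanel:
    """Abundance tensor keyed by (genotype, replicate, experiment, metabolite).

    Parameters
    ----------
    values
        DataFrame with a 3-level row MultiIndex ``(genotype, replicate,
        experiment)`` and one float column per metabolite.  NaN marks a
        missing cell.
    scale
        ``"raw"`` for fold changes / relative abundances (values >= 0) or
        ``"log2"`` for log2-transformed values.
    classes
        Optional mapping metabolite -> compound class
        (one of ``amino_acid``, ``sugar``, ``organic_acid``, ``other``).
    """

    values: pd.DataFrame
    scale: str = "raw"
    classes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values.index, pd.MultiIndex) or self.values.index.nlevels != 3:
            raise PanelFormatError(
                "panel rows must be indexed by (genotype, replicate, experiment)"
            )
        self.values.index = self.values.index.set_names(list(KEY_COLUMNS))
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise PanelFormatError(f"duplicate (genotype, replicate, experiment) keys: {dups}")
        if self.scale not in ("raw", "log2"):
            raise PanelFormatError(f"unknown scale {self.scale!r}")
        if self.scale == "raw":
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy() < 0).any():
                    raise PanelFormatError("raw-scale abundances must be >= 0")

    # ------------------------------------------------------------------ views
    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicator, congruent with ``values`` (True = missing)."""
        return self.values.isna()

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genotypes(self) -> list:
        return list(self.values.index.get_level_values("genotype").unique())

    @property
    def experiments(self) -> list:
        return list(self.values.index.get_level_values("experiment").unique())

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "MetabolitePanel":
        return MetabolitePanel(self.values.copy(), self.scale, dict(self.classes or {}) or None)

    def experiment_view(self, experiment) -> pd.DataFrame:
        """Rows of one experiment, indexed by (genotype, replicate)."""
        sub = self.values.xs(experiment, level="experiment")
        if sub.empty:
            raise MissingDataError(f"experiment {experiment!r} not present in panel")
        return sub

    # --------------------------------------------------------------- transforms
    def to_log2(self, zero_policy: str = "half_min") -> "MetabolitePanel":
        """Log2-transform a raw-scale panel.

        Exact zeros (below-detection readings) cannot be log-transformed;
        with ``zero_policy="half_min"`` they are replaced by half the
        smallest positive observed value of that metabolite before taking
        logs, with ``"error"`` they raise.
        """
        if self.scale == "log2":
            return self
        vals = replace_below_detection(self.values, policy=zero_policy)
        return MetabolitePanel(np.log2(vals), "log2", self.classes)

    def to_raw(self) -> "MetabolitePanel":
        if self.scale == "raw":
            return self
        return MetabolitePanel(np.exp2(self.values), "raw", self.classes)

    def line_level_means(self, experiment=None, log_scale: bool = True) -> pd.DataFrame:
        """Per-genotype mean profiles (lines x metabolites).

        Replicates are averaged; on ``log_scale`` the mean is taken on
        log2-transformed values (the scale used for network inference).
        """
        base = self.to_log2() if log_scale else self
        vals = base.values
        if experiment is not None:
            vals = base.experiment_view(experiment)
            return vals.groupby(level="genotype", sort=False).mean()
        return vals.groupby(level="genotype", sort=False).mean()

    # ------------------------------------------------------------------- io
    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        out = self.values.reset_index()
        out.to_csv(path, sep=sep, index=False, na_rep="NA")


def replace_below_detection(values: pd.DataFrame, policy: str = "half_min") -> pd.DataFrame:
    """Replace exact-zero (below-detection) abundances.

    ``half_min`` substitutes half the smallest positive observed value of
    the metabolite — the conventional surrogate for a censored reading.
    """
    if policy == "error":
        if (values.to_numpy() == 0).any():
            bad = [c for c in values.columns if (values[c] == 0).any()]
            raise MissingDataError(f"zero abundance in metabolites {bad}; cannot log-transform")
        return values
    if policy != "half_min":
        raise ValueError(f"unknown zero policy {policy!r}")
    out = values.copy()
    for col in out.columns:
        col_vals = out[col]
        zero = col_vals == 0
        if zero.any():
            positive = col_vals[col_vals > 0]
            if positive.empty:
                raise MissingDataError(f"metabolite {col!r} has no positive values")
            out.loc[zero, col] = positive.min() / 2.0
    return out


# ---------------------------------------------------------------------- readers
def read_panel(path: str | Path, sep: str | None = None, scale: str = "raw") -> MetabolitePanel:
    """Read a wide replicate-level panel (fold changes vs. the control).

    Raises :class:`PanelFormatError` on duplicate (genotype, replicate,
    experiment) keys or non-numeric cells that are not NA tokens.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_keys = [k for k in KEY_COLUMNS if k not in raw.columns]
    if missing_keys:
        raise PanelFormatError(f"panel file lacks key column(s) {missing_keys}")
    met_cols = [c for c in raw.columns if c not in KEY_COLUMNS]
    if not met_cols:
        raise PanelFormatError("panel file has no metabolite columns")

    data = {}
    for col in met_cols:
        cleaned = raw[col].str.strip()
        is_na = cleaned.str.lower().isin(NA_TOKENS)
        numeric = pd.to_numeric(cleaned.where(~is_na), errors="coerce")
        bad = (~is_na) & numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelFormatError(
                f"non-numeric cell {raw[col].iloc[row]!r} in column {col!r}, data row {row}"
            )
        data[col] = numeric
    keys = raw[list(KEY_COLUMNS)].copy()
    for k in ("replicate", "experiment"):  # numeric keys read back as ints
        numeric = pd.to_numeric(keys[k], errors="coerce")
        if numeric.notna().all():
            keys[k] = numeric.astype(int)
    values = pd.DataFrame(data)
    values.index = pd.MultiIndex.from_frame(keys)
    return MetabolitePanel(values, scale=scale)


@dataclass(frozen=True)
class BinMap:
    """IL -> (chromosome, bin label, annotated-gene count) lookup.

    Bins are the shorter intervals delimited by overlaps between adjacent
    ILs' introgressions; the gene count is the number of annotated genes in
    the IL's introgressed segment.
    """

    table: pd.DataFrame = field()

    def __post_init__(self) -> None:
        t = self.table
        for col in ("chromosome", "bin", "gene_count"):
            if col not in t.columns:
                raise PanelFormatError(f"bin map lacks column {col!r}")
        if t.index.has_duplicates:
            raise PanelFormatError("an IL maps to more than one bin-map row")
        chrom = t["chromosome"].astype(int)
        if ((chrom < 1) | (chrom > 12)).any():
            raise PanelFormatError("chromosome must be in 1..12")
        if (t["gene_count"].astype(int) <= 0).any():
            raise PanelFormatError("gene_count must be > 0")

    def chromosome(self, il) -> int:
        return int(self.table.loc[il, "chromosome"])

    def gene_count(self, il) -> int:
        return int(self.table.loc[il, "gene_count"])

    def __contains__(self, il) -> bool:
        return il in self.table.index

    def write_csv(self, path: str | Path) -> None:
        self.table.rename_axis("il_id").reset_index().to_csv(path, index=False)


def read_bin_map(path: str | Path) -> BinMap:
    t = pd.read_csv(path)
    if "il_id" not in t.columns:
        raise PanelFormatError("bin map file lacks 'il_id' column")
    return BinMap(t.set_index("il_id"))


def read_class_table(path: str | Path) -> dict[str, str]:
    """Read a metabolite -> compound-class table (CSV: metabolite,class)."""
    t = pd.read_csv(path)
    for col in ("metabolite", "class"):
        if col not in t.columns:
            raise PanelFormatError(f"class table lacks column {col!r}")
    bad = set(t["class"]) - set(METABOLITE_CLASSES)
    if bad:
        raise PanelFormatError(f"unknown metabolite classes {sorted(bad)}")
    return dict(zip(t["metabolite"], t["class"]))


def harmonize_metabolites(*panels: MetabolitePanel) -> tuple[MetabolitePanel, ...]:
    """Restrict panels to their shared metabolites.

    Names are matched case-insensitively after whitespace normalization
    (two experiments typically detect overlapping but unequal metabolite
    sets; analysis proceeds on the intersection).
    """
    keymaps = []
    for p in panels:
        keymaps.append({_normalize_metabolite(m): m for m in p.metabolites})
    shared = set(keymaps[0])
    for km in keymaps[1:]:
        shared &= set(km)
    if not shared:
        raise DegenerateInputError("panels share no metabolites after name harmonization")
    # preserve the first panel's ordering
    ordered = [k for k in (_normalize_metabolite(m) for m in panels[0].metabolites) if k in shared]
    out = []
    for p, km in zip(panels, keymaps):
        cols = [km[k] for k in ordered]
        sub = p.values[cols].copy()
        sub.columns = [keymaps[0][k] for k in ordered]  # canonical names from panel 1
        out.append(MetabolitePanel(sub, p.scale, p.classes))
    return tuple(out)
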