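"""Metabolite relevance networks: pairwise Pearson correlation + FDR.

Edges connect feature pairs whose Pearson correlation across lines is
significant after Benjamini-Hochberg correction at the chosen level
(default q <= 0.01).  Correlations are computed on line-level mean
profiles (replicates averaged on the log2 scale); with residual
missingness, pairwise-complete observations are used (minimum 3).
Cross-tissue networks concatenate the per-tissue profiles of the shared
lines and flag intra- versus inter-tissue edges; BH is applied jointly
over all tested pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError

MIN_PAIRWISE = 3


def pearson_matrix(profiles: pd.DataFrame, min_pairwise: int = MIN_PAIRWISE
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric correlation and two-sided p-value matrices.

    ``profiles``: lines x features.  p-values use the t distribution with
    n-2 degrees of freedom on the pairwise-complete sample size.
    Zero-variance features are excluded with a warning; pairs with fewer
    than ``min_pairwise`` complete observations get NaN.
    """
    if len(profiles) < MIN_PAIRWISE:
        raise DegenerateInputError("need at least 3 lines for correlation")
    X = profiles.to_numpy(dtype=float)
    keep = []
    for j, col in enumerate(profiles.columns):
        v = X[:, j]
        v = v[np.isfinite(v)]
        if len(v) >= 2 and np.nanstd(v) > 0:
            keep.append(j)
        else:
            warnings.warn(f"feature {col!r} has zero variance; excluded from network")
    cols = profiles.columns[keep]
    X = X[:, keep]
    p_feat = len(keep)
    finite = np.isfinite(X)

    if finite.all():
        n = np.full((p_feat, p_feat), X.shape[0], dtype=float)
        r = np.corrcoef(X, rowvar=False)
    else:
        r = np.full((p_feat, p_feat), np.nan)
        n = np.zeros((p_feat, p_feat))
        np.fill_diagonal(r, 1.0)
        for a in range(p_feat):
            for b in range(a + 1, p_feat):
                ok = finite[:, a] & finite[:, b]
                n[a, b] = n[b, a] = ok.sum()
                if ok.sum() >= min_pairwise:
                    xa, xb = X[ok, a], X[ok, b]
                    if xa.std() > 0 and xb.std() > 0:
                        r[a, b] = r[b, a] = float(np.corrcoef(xa, xb)[0, 1])
        np.fill_diagonal(n, X.shape[0])

    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(np.isnan(r) | (n < min_pairwise), np.nan, p)
    np.fill_diagonal(p, 0.0)
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return rdf, pdf


@dataclass
class RelevanceNetwork:
    """FDR-thresholded correlation network.

    ``edges`` columns: node_a, node_b (canonical a < b order), r, p, q and
    — for cross-tissue networks — tissue/season tags plus an
    ``intra_tissue`` flag.
    """

    nodes: pd.DataFrame  # index = node label; optional tissue/season columns
    edges: pd.DataFrame
    level: float = 0.01

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node, row in self.nodes.iterrows():
            g.add_node(node, **row.dropna().to_dict())
        for row in self.edges.itertuples():
            g.add_edge(row.node_a, row.node_b, r=row.r, p=row.p, q=row.q)
        return g

    def write_csv(self, path) -> None:
        self.edges.to_csv(path, index=False)

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def fdr_threshold_edges(r: pd.DataFrame, p: pd.DataFrame, level: float = 0.01,
                        node_meta: pd.DataFrame | None = None) -> RelevanceNetwork:
    """Benjamini-Hochberg step-up over the upper triangle; keep q <= level."""
    features = list(r.columns)
    iu = np.triu_indices(len(features), k=1)
    pvals = p.to_numpy()[iu]
    rvals = r.to_numpy()[iu]
    ok = np.isfinite(pvals)
    q = np.full_like(pvals, np.nan)
    if ok.any():
        _, q_ok, _, _ = multipletests(pvals[ok], alpha=level, method="fdr_bh")
        q[ok] = q_ok
    keep = ok & (q <= level)
    rows = []
    for a_i, b_i, rv, pv, qv in zip(iu[0][keep], iu[1][keep], rvals[keep],
                                    pvals[keep], q[keep]):
        rows.append({"node_a": features[a_i], "node_b": features[b_i],
                     "r": float(rv), "p": float(pv), "q": float(qv)})
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "r", "p", "q"])
    if node_meta is None:
        node_meta = pd.DataFrame(index=pd.Index(features, name="node"))
    if not edges.empty and "tissue" in node_meta.columns:
        edges["tissue_a"] = edges["node_a"].map(node_meta["tissue"])
        edges["tissue_b"] = edges["node_b"].map(node_meta["tissue"])
        edges["intra_tissue"] = edges["tissue_a"] == edges["tissue_b"]
    return RelevanceNetwork(node_meta, edges, level)


def relevance_network(profiles: pd.DataFrame, level: float = 0.01) -> RelevanceNetwork:
    """Single-panel relevance network (lines x metabolites profiles)."""
    r, p = pearson_matrix(profiles)
    return fdr_threshold_edges(r, p, level=level)


def cross_tissue_network(profiles_by_tissue: dict, level: float = 0.01,
                         fdr_scope: str = "global") -> RelevanceNetwork:
    """Joint network over several tissues (and/or seasons).

    ``profiles_by_tissue`` maps a tissue label (e.g. ``"leaf"`` or
    ``("leaf", 1)`` for tissue+season) to a lines x metabolites profile
    table.  Lines are intersected across tissues; node labels are
    ``"<tissue>:<metabolite>"``.  ``fdr_scope="global"`` applies BH once
    over all tested pairs (default); ``"per_pair"`` corrects each
    tissue-pair block separately.
    """
    if not profiles_by_tissue:
        raise DegenerateInputError("no tissue panels given")
    shared = None
    for prof in profiles_by_tissue.values():
        shared = prof.index if shared is None else shared.intersection(prof.index)
    if shared is None or len(shared) < MIN_PAIRWISE:
        raise DegenerateInputError("fewer than 3 lines shared across tissues")
    blocks, meta_rows = [], []
    for key, prof in profiles_by_tissue.items():
        tissue = key if isinstance(key, str) else ":".join(str(k) for k in key)
        sub = prof.loc[shared].copy()
        sub.columns = [f"{tissue}:{m}" for m in prof.columns]
        blocks.append(sub)
        for m in prof.columns:
            meta_rows.append({"node": f"{tissue}:{m}", "tissue": tissue, "metabolite": m})
    joint = pd.concat(blocks, axis=1)
    meta = pd.DataFrame(meta_rows).set_index("node")
    r, p = pearson_matrix(joint)
    meta = meta.loc[r.columns]
    if fdr_scope == "global":
        return fdr_threshold_edges(r, p, level=level, node_meta=meta)
    if fdr_scope != "per_pair":
        raise ValueError(f"unknown fdr scope {fdr_scope!r}")
    # per tissue-pair BH: threshold each block separately, then concatenate
    tissues = meta["tissue"].unique()
    all_edges = []
    for i, ta in enumerate(tissues):
        for tb in tissues[i:]:
            nodes = list(meta.index[meta["tissue"].isin({ta, tb})])
            sub_net = fdr_threshold_edges(r.loc[nodes, nodes], p.loc[nodes, nodes],
                                          level=level, node_meta=meta.loc[nodes])
            e = sub_net.edges
            if ta != tb and not e.empty:
                e = e[e["tissue_a"] != e["tissue_b"]]
            elif ta == tb and not e.empty:
                e = e[e["tissue_a"] == e["tissue_b"]]
            all_edges.append(e)
    edges = (pd.concat(all_edges, ignore_index=True).drop_duplicates(["node_a", "node_b"])
             if all_edges else pd.DataFrame())
    return RelevanceNetwork(meta, edges, level)
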