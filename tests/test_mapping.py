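"""Conserved-QTL calling: calibration, decision rule, summaries, overlay."""

import numpy as np
import pandas as pd
import pytest

from ilmqtl.errors import DegenerateInputError, MissingDataError
from ilmqtl.mapping import (call_conserved, cross_tissue_overlap, genes_per_qtl,
                            overlay_matrix, per_line_tests, summarize_calls)
from ilmqtl.panel import BinMap
from ilmqtl.simulate import (QtlEffect, SimConfig, simulate_bin_map,
                             simulate_class_table, simulate_panel)

from conftest import make_panel


def _tests_frame(rows):
    """(il, met, p1, p2, lfc1, lfc2) -> two per-experiment test tables."""
    t1, t2 = [], []
    for il, met, p1, p2, l1, l2 in rows:
        t1.append({"il": il, "metabolite": met, "p": p1, "lfc": l1,
                   "significant": p1 <= 0.05, "untestable": False})
        t2.append({"il": il, "metabolite": met, "p": p2, "lfc": l2,
                   "significant": p2 <= 0.05, "untestable": False})
    return pd.DataFrame(t1), pd.DataFrame(t2)


class TestPerLineTests:
    def test_identical_groups_not_significant_zero_lfc(self):
        panel = make_panel(
            {("M82", i, 1): [2.0 + 0.1 * i] for i in range(1, 5)}
            | {("IL01", i, 1): [2.0 + 0.1 * i] for i in range(1, 5)},
            ["metA"],
        )
        t = per_line_tests(panel, 1, "M82", variant="student")
        row = t.iloc[0]
        assert row["lfc"] == pytest.approx(0.0)
        assert row["p"] > 0.9
        assert not row["significant"]

    def test_clear_separation_significant_with_lfc_two(self):
        rng = np.random.default_rng(0)
        panel = make_panel(
            {("M82", i, 1): [1.0 * (1 + 1e-3 * rng.standard_normal())]
             for i in range(1, 5)}
            | {("IL01", i, 1): [4.0 * (1 + 1e-3 * rng.standard_normal())]
               for i in range(1, 5)},
            ["metA"],
        )
        for variant in ("anova", "student", "welch"):
            row = per_line_tests(panel, 1, "M82", variant=variant).iloc[0]
            assert row["significant"]
            assert row["lfc"] == pytest.approx(2.0, abs=0.01)

    @pytest.mark.parametrize("variant", ["anova", "student"])
    def test_null_false_positive_rate_near_alpha(self, variant):
        """No QTL, sigma_g=sigma_ge=0: significant fraction ~ alpha."""
        hits = total = 0
        for seed in range(6):
            cfg = SimConfig(n_ils=40, n_metabolites=40, sigma_g=0, sigma_ge=0,
                            sigma_env=0.3, sigma_eps=0.3, n_experiments=1,
                            seed=seed)
            panel, _ = simulate_panel(cfg)
            t = per_line_tests(panel, 1, "M82", variant=variant)
            hits += int(t["significant"].sum())
            total += len(t)
        rate = hits / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * se

    def test_small_groups_reported_untestable(self):
        panel = make_panel(
            {("M82", 1, 1): [1.0], ("M82", 2, 1): [1.1],
             ("IL01", 1, 1): [2.0]},  # single replicate -> untestable
            ["metA"],
        )
        t = per_line_tests(panel, 1, "M82")
        assert t.iloc[0]["untestable"]
        assert np.isnan(t.iloc[0]["p"])

    def test_control_absent_raises(self, tiny_panel):
        with pytest.raises(MissingDataError):
            per_line_tests(tiny_panel, 1, "missing_control")


class TestCallConserved:
    def test_rule_application(self):
        t1, t2 = _tests_frame([
            ("IL01", "m1", 0.01, 0.03, +1.2, +0.8),   # conserved positive
            ("IL01", "m2", 0.01, 0.20, +1.0, +1.0),   # exp2 not significant
            ("IL02", "m1", 0.01, 0.01, +1.0, -1.0),   # direction conflict
            ("IL02", "m2", 0.04, 0.04, -0.5, -0.2),   # conserved negative
        ])
        res = call_conserved(t1, t2)
        assert len(res) == 2
        got = {(r.il, r.metabolite): r.direction for r in res.calls.itertuples()}
        assert got == {("IL01", "m1"): "positive", ("IL02", "m2"): "negative"}

    def test_boundary_p_inclusive(self):
        t1, t2 = _tests_frame([("IL01", "m1", 0.05, 0.05, 1.0, 1.0)])
        assert len(call_conserved(t1, t2)) == 1

    def test_zero_lfc_never_called(self):
        t1, t2 = _tests_frame([("IL01", "m1", 0.001, 0.001, 0.0, 0.0)])
        assert len(call_conserved(t1, t2)) == 0

    def test_untestable_pairs_counted_not_called(self):
        t1, t2 = _tests_frame([("IL01", "m1", 0.01, 0.01, 1.0, 1.0)])
        t1.loc[0, "untestable"] = True
        t1.loc[0, "p"] = np.nan
        res = call_conserved(t1, t2)
        assert len(res) == 0 and res.n_untestable == 1

    def test_no_shared_metabolites_raises(self):
        t1, t2 = _tests_frame([("IL01", "m1", 0.01, 0.01, 1.0, 1.0)])
        t2["metabolite"] = "other"
        with pytest.raises(DegenerateInputError):
            call_conserved(t1, t2)

    def test_planted_qtl_recovered_and_reconciled(self, small_sim):
        """All strong planted effects called; totals reconcile with truth."""
        cfg, panel, truth = small_sim
        t1 = per_line_tests(panel, 1, cfg.control_id)
        t2 = per_line_tests(panel, 2, cfg.control_id)
        res = call_conserved(t1, t2)
        called = set(zip(res.calls["il"], res.calls["metabolite"]))
        truth_set = set(zip(truth.qtl["il"], truth.qtl["metabolite"]))
        assert truth_set <= called
        signs = dict(zip(zip(res.calls["il"], res.calls["metabolite"]),
                         res.calls["direction"]))
        assert signs[("IL01", "met_01")] == "positive"
        assert signs[("IL04", "met_03")] == "negative"
        # reconciliation: total = recovered truth + false positives
        assert len(res) == len(truth_set & called) + len(called - truth_set)


class TestSummaries:
    def setup_method(self):
        self.bin_map = simulate_bin_map(10, seed=0)
        self.calls = pd.DataFrame([
            {"il": "IL01", "metabolite": "m1", "direction": "positive"},
            {"il": "IL01", "metabolite": "m2", "direction": "negative"},
            {"il": "IL09", "metabolite": "m1", "direction": "negative"},
        ])
        self.classes = {"m1": "sugar", "m2": "amino_acid"}

    def test_counts_consistent_across_groupings(self):
        s = summarize_calls(self.calls, self.classes, self.bin_map)
        assert s.total == 3
        assert s.consistent()
        assert s.by_class == {"sugar": 2, "amino_acid": 1}
        assert s.by_direction == {"negative": 2, "positive": 1}

    def test_empty_calls_give_zero_summary(self):
        empty = self.calls.iloc[:0]
        s = summarize_calls(empty, self.classes, self.bin_map)
        assert s.total == 0 and s.consistent()

    def test_unclassified_metabolite_listed(self):
        with pytest.raises(MissingDataError, match="m2"):
            summarize_calls(self.calls, {"m1": "sugar"}, self.bin_map)

    def test_unmapped_il_listed(self):
        small_map = BinMap(self.bin_map.table.drop(index="IL09"))
        with pytest.raises(MissingDataError, match="IL09"):
            summarize_calls(self.calls, self.classes, small_map)

    def test_genes_per_qtl_range(self):
        table = pd.DataFrame(
            {"chromosome": [1, 2], "bin": ["1-1", "2-1"], "gene_count": [100, 2000]},
            index=pd.Index(["IL01", "IL09"], name="il_id"),
        )
        df, rng = genes_per_qtl(self.calls, BinMap(table))
        assert rng == (100, 2000)
        assert list(df["gene_count"]) == [100, 100, 2000]

        one = self.calls.iloc[:1]
        table295 = pd.DataFrame(
            {"chromosome": [1], "bin": ["1-1"], "gene_count": [295]},
            index=pd.Index(["IL01"], name="il_id"),
        )
        _, rng1 = genes_per_qtl(one, BinMap(table295))
        assert rng1 == (295, 295)


class TestOverlay:
    def _mats(self, l1, l2, s1, s2):
        idx = pd.Index(["IL01"], name="il")
        cols = ["m1"]
        mk = lambda v: pd.DataFrame([[v]], index=idx, columns=cols)
        return mk(l1), mk(l2), mk(s1), mk(s2)

    @pytest.mark.parametrize("l1,l2,s1,s2,score,cat", [
        (+2.0, +1.5, True, True, 3.5, "conserved_up"),
        (-2.0, -1.5, True, True, -3.5, "conserved_down"),
        (+2.0, -2.0, True, True, 0.0, "inconsistent"),
        (+2.0, +1.5, False, True, 3.5, "neutral"),
        (+9.0, -9.0, False, False, 0.0, "neutral"),
    ])
    def test_categories_and_scores(self, l1, l2, s1, s2, score, cat):
        sc, ct = overlay_matrix(*self._mats(l1, l2, s1, s2))
        assert sc.iloc[0, 0] == pytest.approx(score)
        assert ct.iloc[0, 0] == cat

    def test_categories_partition_matrix(self, small_sim):
        cfg, panel, _ = small_sim
        from ilmqtl.preprocess import log2_fold_change
        lfc = log2_fold_change(panel, cfg.control_id)
        l1 = lfc.xs(1, level="experiment").drop(index=cfg.control_id)
        l2 = lfc.xs(2, level="experiment").drop(index=cfg.control_id)
        t = {e: per_line_tests(panel, e, cfg.control_id)
             .pivot(index="il", columns="metabolite", values="significant")
             .loc[l1.index, l1.columns] for e in (1, 2)}
        score, cat = overlay_matrix(l1, l2, t[1], t[2])
        counts = cat.stack().value_counts()
        assert counts.sum() == score.size

    def test_shape_mismatch_rejected(self):
        a, b, s1, s2 = self._mats(1.0, 1.0, True, True)
        with pytest.raises(ValueError):
            overlay_matrix(a, b.T, s1, s2)

    def test_heat_map_rendering(self, tmp_path):
        from ilmqtl.mapping import plot_overlay
        a, b, s1, s2 = self._mats(2.0, -1.0, True, True)
        score, cat = overlay_matrix(a, b, s1, s2)
        out = tmp_path / "overlay.png"
        fig = plot_overlay(score, cat, path=out)
        assert out.exists() and out.stat().st_size > 0
        import matplotlib.pyplot as plt
        plt.close(fig)


class TestCrossTissue:
    def test_disjoint_calls_empty(self):
        leaf = pd.DataFrame([{"il": "IL01", "metabolite": "thr", "direction": "negative"}])
        fruit = pd.DataFrame([{"il": "IL02", "metabolite": "gaba", "direction": "positive"}])
        assert cross_tissue_overlap({"leaf": leaf, "fruit": fruit}).empty

    def test_identical_calls_all_matched(self):
        calls = pd.DataFrame([
            {"il": "IL01", "metabolite": "thr", "direction": "negative"},
            {"il": "IL02", "metabolite": "suc", "direction": "positive"},
        ])
        out = cross_tissue_overlap({"leaf": calls, "seed": calls.copy()})
        assert len(out) == 2
        assert not out["reversal"].any()

    def test_direction_reversal_flagged(self):
        leaf = pd.DataFrame([{"il": "IL05", "metabolite": "gaba", "direction": "negative"}])
        fruit = pd.DataFrame([{"il": "IL05", "metabolite": "gaba", "direction": "positive"}])
        out = cross_tissue_overlap({"leaf": leaf, "fruit": fruit})
        assert len(out) == 1
        assert bool(out.iloc[0]["reversal"])
        assert out.iloc[0]["directions"] == {"leaf": "negative", "fruit": "positive"}
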