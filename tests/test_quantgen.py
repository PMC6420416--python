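"""Variance components, Cvg/Cve and heritability estimators."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ilmqtl.errors import MissingDataError
from ilmqtl.quantgen import (anova_mean_squares, cv_coefficients, heritability,
                             variance_components, variance_report)
from ilmqtl.simulate import SimConfig, simulate_panel


class TestAnovaMeanSquares:
    def test_hand_anova_on_four_numbers(self):
        # groups {0,0} and {2,2}: means 0 and 2, grand mean 1
        # SS_between = 2*(0-1)^2 + 2*(2-1)^2 = 4 -> QMg = 4/(2-1) = 4
        ms = anova_mean_squares([0, 0, 2, 2], ["a", "a", "b", "b"])
        assert ms.qmg == pytest.approx(4.0)
        assert ms.qme == pytest.approx(0.0)
        assert ms.r == 2

    def test_all_identical_gives_zero_mean_squares(self):
        ms = anova_mean_squares([5.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert ms.qmg == 0.0 and ms.qme == 0.0

    def test_two_group_f_equals_squared_t(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)
            ms = anova_mean_squares(np.r_[a, b], ["a"] * 5 + ["b"] * 5)
            t = stats.ttest_ind(a, b).statistic
            assert ms.qmg / ms.qme == pytest.approx(t**2, rel=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1, 4) for m in (0, 1, 2, 0.5)]
        ms = anova_mean_squares(np.concatenate(groups),
                                np.repeat(list("abcd"), 4))
        f = stats.f_oneway(*groups).statistic
        assert ms.qmg / ms.qme == pytest.approx(f, rel=1e-10)

    def test_single_replicate_group_rejected(self):
        with pytest.raises(MissingDataError):
            anova_mean_squares([1, 2, 3], ["a", "a", "b"])


class TestVarianceComponents:
    def test_printed_formula(self):
        s2g, s2e, trunc = variance_components(10.0, 2.0, 4)
        assert s2g == pytest.approx(2.0)
        assert s2e == pytest.approx(0.5)
        assert not trunc

    def test_equal_mean_squares_give_zero_genetic_variance(self):
        s2g, _, trunc = variance_components(3.0, 3.0, 2)
        assert s2g == 0.0 and not trunc

    def test_negative_estimate_truncated_and_flagged(self):
        s2g, s2e, trunc = variance_components(1.0, 3.0, 2)
        assert s2g == 0.0 and trunc
        assert s2e == pytest.approx(1.5)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            variance_components(1.0, 1.0, 0)


class TestCvCoefficients:
    def test_printed_formula(self):
        cvg, _ = cv_coefficients(4.0, 1.0, 10.0)
        assert cvg == pytest.approx(20.0)

    def test_formula_on_qm_example(self):
        # QMg=10, QMe=2, r=4 -> sigma2_g=2; mc=10 -> Cvg = 100*sqrt(2)/10
        s2g, s2e, _ = variance_components(10.0, 2.0, 4)
        cvg, cve = cv_coefficients(s2g, s2e, 10.0)
        assert cvg == pytest.approx(100 * np.sqrt(2) / 10)
        assert cve == pytest.approx(100 * np.sqrt(0.5) / 10)

    def test_zero_genetic_variance_gives_zero_cvg(self):
        assert cv_coefficients(0.0, 1.0, 5.0)[0] == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_coefficients(1.0, 1.0, 0.0)


class TestRecovery:
    def test_variance_component_recovery_on_simulated_panels(self):
        """sigma2_g=2, sigma2_e=0.5, r=4, 76 genotypes: mean estimates
        within 15% of truth over 20 seeds (log2 scale, one experiment).

        sigma2_e = QMe/r is the error variance of a genotype mean, so a
        true value of 0.5 at r=4 corresponds to residual variance 2.
        """
        est_g, est_e = [], []
        for seed in range(20):
            cfg = SimConfig(n_ils=76, n_metabolites=1, n_replicates=4,
                            n_experiments=1, sigma_g=np.sqrt(2.0), sigma_env=0,
                            sigma_ge=0, sigma_eps=np.sqrt(2.0), seed=seed)
            panel, _ = simulate_panel(cfg)
            log = panel.to_log2().values
            ms = anova_mean_squares(log["met_01"],
                                    log.index.get_level_values("genotype"))
            s2g, s2e, _ = variance_components(ms.qmg, ms.qme, ms.r)
            est_g.append(s2g)
            est_e.append(s2e)
        assert np.mean(est_g) == pytest.approx(2.0, rel=0.15)
        assert np.mean(est_e) == pytest.approx(0.5, rel=0.15)

    def test_expected_genotype_mean_square(self):
        """E[QMg] = sigma2_eps + r*sigma2_g, checked over many seeds."""
        r, s2g, s2e = 4, 0.64, 0.09
        qmgs = []
        for seed in range(30):
            cfg = SimConfig(n_ils=40, n_metabolites=20, n_replicates=r,
                            n_experiments=1, sigma_g=np.sqrt(s2g), sigma_env=0,
                            sigma_ge=0, sigma_eps=np.sqrt(s2e), seed=100 + seed)
            panel, _ = simulate_panel(cfg)
            log = panel.to_log2().values
            geno = log.index.get_level_values("genotype")
            for met in log.columns:
                qmgs.append(anova_mean_squares(log[met], geno).qmg)
        assert np.mean(qmgs) == pytest.approx(s2e + r * s2g, rel=0.03)

    def test_estimator_consistency_across_replicate_counts(self):
        """sigma2_g-hat targets sigma_g^2 and r*sigma2_e-hat targets the
        residual variance at every r in {4, 16, 64} (within 3 MC SEs)."""
        for r in (4, 16, 64):
            est_g, est_resid = [], []
            for seed in range(10):
                cfg = SimConfig(n_ils=20, n_metabolites=10, n_replicates=r,
                                n_experiments=1, sigma_g=0.5, sigma_env=0,
                                sigma_ge=0, sigma_eps=0.3, seed=seed)
                panel, _ = simulate_panel(cfg)
                log = panel.to_log2().values
                geno = log.index.get_level_values("genotype")
                for met in log.columns:
                    ms = anova_mean_squares(log[met], geno)
                    s2g, s2e, _ = variance_components(ms.qmg, ms.qme, ms.r)
                    est_g.append(s2g)
                    est_resid.append(r * s2e)
            assert np.mean(est_g) == pytest.approx(0.25, abs=0.03)
            assert np.mean(est_resid) == pytest.approx(0.09, abs=0.01)


class TestHeritability:
    def test_null_genotype_variance_gives_near_zero_h2(self):
        h2s = []
        for seed in range(10):
            cfg = SimConfig(n_ils=76, n_metabolites=1, sigma_g=0.0,
                            sigma_env=0.3, sigma_ge=np.sqrt(0.5),
                            sigma_eps=np.sqrt(0.5), seed=seed)
            panel, _ = simulate_panel(cfg)
            h2s.append(heritability(panel)["H2"].iloc[0])
        assert np.mean(h2s) < 0.05

    def test_h2_recovery_at_one_half(self):
        """sigma2_G=1, sigma2_GE=0.5, sigma2_eps=0.5 -> plot-basis H2 = 0.5."""
        h2s = []
        for seed in range(20):
            cfg = SimConfig(n_ils=76, n_metabolites=1, sigma_g=1.0,
                            sigma_env=0.3, sigma_ge=np.sqrt(0.5),
                            sigma_eps=np.sqrt(0.5), seed=seed)
            panel, _ = simulate_panel(cfg)
            h2s.append(heritability(panel, basis="plot")["H2"].iloc[0])
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.05)

    def test_h2_affine_invariance_and_bounds(self):
        cfg = SimConfig(n_ils=12, n_metabolites=4, seed=7)
        panel, _ = simulate_panel(cfg)
        log = panel.to_log2()
        h_base = heritability(log)
        shifted = log.copy()
        shifted.values = shifted.values * 3.0 + 5.0
        h_shift = heritability(shifted)
        np.testing.assert_allclose(h_base["H2"], h_shift["H2"], rtol=1e-10)
        assert ((h_base["H2"] >= 0) & (h_base["H2"] <= 1)).all()

    def test_entry_mean_basis_not_below_plot_basis(self):
        cfg = SimConfig(n_ils=15, n_metabolites=5, seed=8)
        panel, _ = simulate_panel(cfg)
        plot = heritability(panel, basis="plot")["H2"]
        entry = heritability(panel, basis="entry_mean")["H2"]
        assert (entry >= plot - 1e-12).all()

    def test_missing_cells_direct_user_to_impute(self):
        cfg = SimConfig(n_ils=8, n_metabolites=3, missing_rate=0.2, seed=1)
        panel, _ = simulate_panel(cfg)
        with pytest.raises(MissingDataError, match="impute"):
            heritability(panel)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
    def test_matches_lme4_reml_on_balanced_data(self, tmp_path):
        """On balanced data the moment estimator equals REML (lme4)."""
        cfg = SimConfig(n_ils=8, n_metabolites=1, n_replicates=3, sigma_g=1.0,
                        sigma_env=0.4, sigma_ge=0.6, sigma_eps=0.5, seed=3)
        panel, _ = simulate_panel(cfg)
        log = panel.to_log2().values.reset_index()
        log.columns = ["genotype", "replicate", "experiment", "y"]
        data = tmp_path / "d.csv"
        out = tmp_path / "vc.csv"
        log.to_csv(data, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{data}")
            m <- lmer(y ~ 1 + (1|genotype) + (1|experiment) +
                      (1|genotype:experiment), data=d, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            write.csv(vc[, c("grp", "vcov")], "{out}", row.names=FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out).set_index("grp")["vcov"]
        ours = heritability(panel).iloc[0]
        assert ours["sigma2_G"] == pytest.approx(ref["genotype"], rel=1e-3)
        assert ours["sigma2_GE"] == pytest.approx(ref["genotype:experiment"], rel=1e-3)
        assert ours["sigma2_eps"] == pytest.approx(ref["Residual"], rel=1e-3)


def test_variance_report_columns_and_cv_ranges():
    cfg = SimConfig(n_ils=20, n_metabolites=6, seed=5)
    panel, _ = simulate_panel(cfg)
    rep = variance_report(panel)
    assert set(rep["experiment"]) == {1, 2}
    assert (rep["Cvg"] >= 0).all() and (rep["Cve"] >= 0).all()
    assert len(rep) == 12
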