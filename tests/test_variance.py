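"""Genotype F-test, variance components (REML/EMS) and heritability."""

import numpy as np
import pandas as pd
import pytest

import rhizotype as rz
from rhizotype.variance import VarianceComponents


def _components(s2g, s2b, s2e, r=3, method="EMS"):
    return VarianceComponents(s2g, s2b, s2e, r, method)


class TestHeritabilityFormula:
    def test_no_residual_gives_one(self):
        assert rz.broad_sense_heritability(_components(1.0, 0.0, 0.0)).H2 == 1.0

    def test_direct_arithmetic(self):
        # H2 = 2 / (2 + 3/3) = 2/3
        h = rz.broad_sense_heritability(_components(2.0, 0.5, 3.0, r=3))
        assert h.H2 == pytest.approx(2.0 / 3.0)

    def test_zero_over_zero_is_missing(self):
        assert np.isnan(rz.broad_sense_heritability(_components(0.0, 1.0, 0.0)).H2)

    @pytest.mark.parametrize("r", [2, 3, 5])
    def test_monotone_in_components(self, r):
        s2e = 3.0
        h2s = [
            rz.broad_sense_heritability(_components(g, 0.0, s2e, r)).H2
            for g in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a < b for a, b in zip(h2s, h2s[1:]))
        h2e = [
            rz.broad_sense_heritability(_components(1.0, 0.0, e, r)).H2
            for e in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(h2e, h2e[1:]))

    def test_negative_components_rejected(self):
        with pytest.raises(ValueError):
            _components(-0.1, 0.0, 1.0)


class TestGenotypeAnova:
    def test_identical_genotypes_give_zero_f(self):
        df = pd.DataFrame(
            {
                "genotype": ["A", "A", "B", "B"] * 2,
                "block": ["B1"] * 4 + ["B2"] * 4,
                "plant": [1, 2] * 4,
                "culled": False,
                "y": [1.0, 2.0, 1.0, 2.0, 3.0, 4.0, 3.0, 4.0],
            }
        )
        res = rz.fit_genotype_anova(df, "y")
        assert res.F_statistic == pytest.approx(0.0, abs=1e-10)

    def test_constant_trait_degenerate(self):
        df = pd.DataFrame(
            {"genotype": ["A", "A", "B", "B"], "block": ["B1", "B2"] * 2,
             "plant": 1, "culled": False, "y": 5.0}
        )
        res = rz.fit_genotype_anova(df, "y")
        assert np.isnan(res.p_value)

    def test_degrees_of_freedom(self, small_trial):
        res = rz.fit_genotype_anova(small_trial, "y")
        N, G, B = len(small_trial), 8, 3
        assert res.df_numerator == G - 1
        assert res.df_denominator == N - G - B + 1

    def test_matches_statsmodels_anova(self, small_trial):
        """Independent oracle: statsmodels OLS + anova_lm on the additive
        fixed-effects model reproduces F and p."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        fit = smf.ols("y ~ C(genotype) + C(block)", small_trial).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        res = rz.fit_genotype_anova(small_trial, "y")
        assert res.F_statistic == pytest.approx(table.loc["C(genotype)", "F"], rel=1e-9)
        assert res.p_value == pytest.approx(table.loc["C(genotype)", "PR(>F)"], rel=1e-9)
        assert res.df_denominator == int(table.loc["Residual", "df"])

    def test_unbalanced_data_still_matches_statsmodels(self, small_trial):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        culled, _ = rz.apply_culling(small_trial, 1.5, seed=9)
        fit = smf.ols("y ~ C(genotype) + C(block)", culled).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        res = rz.fit_genotype_anova(culled, "y")
        assert res.F_statistic == pytest.approx(table.loc["C(genotype)", "F"], rel=1e-9)

    def test_power_at_high_heritability(self):
        """Strong genotype signal (H2 = 0.8) is detected essentially always
        at the study design size."""
        s2e = rz.sigma2_e_for_h2(0.8, 1.0, 3, 5)
        hits = 0
        for i in range(50):
            cfg = rz.SimulationConfig(
                46, 3, 5, ["y"], [0.0], [1.0], [0.3], [s2e], seed=40_000 + i
            )
            hits += rz.fit_genotype_anova(rz.simulate_trial(cfg), "y").p_value < 0.05
        assert hits >= 50 * 0.99


class TestVarianceComponents:
    def test_reml_matches_mixedlm_oracle_unbalanced(self):
        """Independent REML oracle: statsmodels MixedLM with genotype and
        block variance components on unbalanced plot means."""
        import statsmodels.formula.api as smf

        cfg = rz.SimulationConfig(
            12, 3, 4, ["y"], [5.0], [2.0], [1.0], [1.5], culling_rate=1.5, seed=77
        )
        table, _ = rz.apply_culling(rz.simulate_trial(cfg), 1.5, cfg)
        # drop one whole plot for genuine missing-cell unbalance
        table = table.loc[~((table.genotype == "G001") & (table.block == "B1"))]
        mine = rz.estimate_variance_components(table, "y", method="REML")

        pm = rz.plot_means(table, "y").assign(one=1)
        oracle = smf.mixedlm(
            "y ~ 1", pm, groups="one",
            vc_formula={"genotype": "0 + C(genotype)", "block": "0 + C(block)"},
        ).fit(reml=True)
        assert mine.sigma2_g == pytest.approx(float(oracle.vcomp[1]), rel=1e-3)
        assert mine.sigma2_b == pytest.approx(float(oracle.vcomp[0]), rel=1e-3, abs=1e-6)
        assert mine.sigma2_e == pytest.approx(float(oracle.scale), rel=1e-3)

    def test_ems_truncates_negative_genotype_variance(self):
        # genotype means closer together than residual noise -> negative EMS
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6):
            for j in range(3):
                for p in range(4):
                    rows.append(
                        {"genotype": f"G{i}", "block": f"B{j}", "plant": p,
                         "culled": False,
                         # identical genotype centers, large noise
                         "y": rng.normal(0.0, 5.0)}
                    )
        df = pd.DataFrame(rows)
        results = [
            rz.estimate_variance_components(df.assign(y=rng.permutation(df.y)), "y", "EMS")
            for _ in range(10)
        ]
        assert any(r.truncated for r in results)
        assert all(r.sigma2_g >= 0 for r in results)

    def test_null_truth_gives_near_zero_estimates(self):
        ests = []
        for i in range(30):
            cfg = rz.SimulationConfig(
                20, 3, 4, ["y"], [0.0], [0.0], [0.5], [1.0], seed=90_000 + i
            )
            ests.append(
                rz.estimate_variance_components(rz.simulate_trial(cfg), "y", "REML").sigma2_g
            )
        assert np.median(ests) == pytest.approx(0.0, abs=0.01)
        assert np.mean(ests) < 0.05

    def test_recovery_of_configured_genotype_variance(self):
        """sigma2_g = 2, sigma2_e = 3 at the 46x3x5 design: the mean REML
        estimate over replicate simulations recovers the truth within 10%."""
        ests = []
        for i in range(100):
            cfg = rz.SimulationConfig(
                46, 3, 5, ["y"], [0.0], [2.0], [0.5], [3.0], seed=91_000 + i
            )
            ests.append(
                rz.estimate_variance_components(rz.simulate_trial(cfg), "y").sigma2_g
            )
        assert np.mean(ests) == pytest.approx(2.0, rel=0.10)

    def test_plant_scale_option(self, small_trial):
        vc = rz.estimate_variance_components(small_trial, "y", scale="plants")
        assert vc.scale == "plants"
        # plant-level residual is ~n_plants times the plot-mean residual
        vc_pm = rz.estimate_variance_components(small_trial, "y", scale="plot_means")
        assert vc.sigma2_e > vc_pm.sigma2_e

    def test_unbalanced_ems_warns(self, small_trial):
        culled, _ = rz.apply_culling(small_trial, 1.5, seed=4)
        with pytest.warns(UserWarning, match="harmonic"):
            rz.estimate_variance_components(culled, "y", method="EMS", scale="plants")

    def test_invalid_method_rejected(self, small_trial):
        with pytest.raises(ValueError, match="method"):
            rz.estimate_variance_components(small_trial, "y", method="ANOVA")


def test_heritability_table_columns(small_trial):
    out = rz.heritability_table(small_trial, ["y"])
    assert set(out.columns) >= {
        "trait", "F", "df_num", "df_den", "p_value",
        "sigma2_g", "sigma2_b", "sigma2_e", "r", "H2", "method", "truncated",
    }
    assert out.loc[0, "r"] == 3
    # stored H2 reproduces the formula from stored components exactly
    row = out.iloc[0]
    assert row["H2"] == pytest.approx(
        row["sigma2_g"] / (row["sigma2_g"] + row["sigma2_e"] / row["r"])
    )
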