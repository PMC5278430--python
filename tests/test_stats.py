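"""Repeated-measures battery: oracles against pingouin/statsmodels and
design-structure checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from echowing import (
    between_anova,
    fit_rm,
    sphericity,
    tukey_kramer,
    within_anova,
)
from echowing.stats import RMFit, _orthonormal_contrasts
from echowing.synthetic import default_rm_means, gen_rm_dataset
from echowing.types import RMDataset


@pytest.fixture(scope="module")
def dataset():
    return gen_rm_dataset(seed=3)


class TestFitRM:
    def test_study_design_dimensions(self, dataset):
        fit = fit_rm(dataset, "preparation")
        assert fit.n_subjects == 54  # 9 preparations x 6 sets
        assert fit.n_levels == 9
        assert fit.n_bands == 8
        assert len(fit.subjects) == 54

    def test_cell_means_match_groupby_oracle(self, dataset):
        fit = fit_rm(dataset, "preparation")
        oracle = dataset.data.groupby(["preparation", "fc_hz"])["alpha"].mean()
        for lev in fit.levels:
            for fc in fit.bands_hz:
                assert fit.cell_means.loc[lev, fc] == pytest.approx(
                    oracle[(lev, fc)], abs=1e-12
                )

    def test_unbalanced_design_identified(self, dataset):
        broken = dataset.data.copy()
        broken.loc[broken.index[0], "fc_hz"] = 12_345.0
        with pytest.raises(ValueError):
            fit_rm(RMDataset(broken), "preparation")


class TestBetweenAnova:
    def test_preparation_dfs(self, dataset):
        res = between_anova(fit_rm(dataset, "preparation"))
        assert (res.df1, res.df2) == (8, 45)

    def test_group_dfs(self, dataset):
        res = between_anova(fit_rm(dataset, "group"))
        assert (res.df1, res.df2) == (2, 51)

    def test_matches_scipy_f_oneway(self, dataset):
        fit = fit_rm(dataset, "group")
        res = between_anova(fit)
        groups = [
            fit.subjects.loc[fit.subjects["level"] == lev, "marginal_mean"]
            for lev in fit.levels
        ]
        F, p = sps.f_oneway(*groups)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-8)

    def test_null_p_values_uniform(self):
        """Equal generating means: between-ANOVA p is U(0,1) over seeds."""
        means = default_rm_means()
        means["mean_alpha"] = 0.4
        ps = []
        for seed in range(200):
            ds = gen_rm_dataset(means, seed=seed)
            ps.append(between_anova(fit_rm(ds, "preparation")).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestSphericity:
    def test_compound_symmetric_covariance_is_spherical(self, dataset):
        fit = fit_rm(dataset, "preparation")
        k = fit.n_bands
        fit.pooled_cov = 0.02 * np.eye(k) + 0.01 * np.ones((k, k))
        chi2, p, eps = sphericity(fit)
        assert eps == pytest.approx(1.0, abs=1e-12)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_epsilon_lower_bound(self):
        for seed in range(20):
            ds = gen_rm_dataset(seed=seed)
            _, _, eps = sphericity(fit_rm(ds, "preparation"))
            assert 1.0 / 7.0 <= eps <= 1.0

    def test_single_group_matches_pingouin(self):
        """chi2 and GG epsilon agree with pingouin to 1e-8 when there is a
        single between-level (pingouin pools across all subjects)."""
        pg = pytest.importorskip("pingouin")
        means = default_rm_means().query("preparation == 'A_io_F'")
        ds = gen_rm_dataset(means, seed=5, n_sets=8)
        fit = fit_rm(ds, "preparation")
        chi2, _, eps = sphericity(fit)
        df = ds.data.rename(columns={"set_id": "subject"})
        sph = pg.sphericity(df, dv="alpha", within="fc_hz", subject="subject")
        eps_pg = pg.epsilon(
            df, dv="alpha", within="fc_hz", subject="subject", correction="gg"
        )
        assert chi2 == pytest.approx(float(sph.chi2), abs=1e-8)
        assert eps == pytest.approx(float(eps_pg), abs=1e-10)


class TestWithinAnova:
    def test_preparation_design_dfs(self, dataset):
        res = within_anova(fit_rm(dataset, "preparation"), correction="none")
        assert (res[0].df1, res[0].df2) == (7, 315)    # band main effect
        assert (res[1].df1, res[1].df2) == (56, 315)   # interaction

    def test_group_design_dfs(self, dataset):
        res = within_anova(fit_rm(dataset, "group"), correction="none")
        assert (res[0].df1, res[0].df2) == (7, 357)
        assert (res[1].df1, res[1].df2) == (14, 357)

    def test_f_statistics_match_pingouin_mixed_anova(self, dataset):
        pg = pytest.importorskip("pingouin")
        fit = fit_rm(dataset, "preparation")
        mine = [between_anova(fit).F] + [r.F for r in within_anova(fit, "none")]
        df = dataset.data.rename(columns={"set_id": "subject"})
        mx = pg.mixed_anova(
            data=df, dv="alpha", within="fc_hz", between="preparation",
            subject="subject",
        )
        np.testing.assert_allclose(mine, mx["F"].to_numpy(), rtol=1e-8)

    def test_gg_correction_deflates_dfs(self, dataset):
        fit = fit_rm(dataset, "preparation")
        res = within_anova(fit, correction="greenhouse_geisser")
        assert all(0 < r.epsilon <= 1 for r in res)
        # corrected p computed from epsilon-scaled dfs
        r = res[0]
        assert r.p == pytest.approx(
            float(sps.f.sf(r.F, r.epsilon * r.df1, r.epsilon * r.df2)), rel=1e-12
        )

    def test_no_interaction_null_p_uniform(self):
        """Generative model with parallel curves: interaction p is uniform."""
        means = default_rm_means()
        base = means.groupby("fc_hz")["mean_alpha"].transform("mean")
        offset = means.groupby("preparation")["mean_alpha"].transform("mean")
        means["mean_alpha"] = base + (offset - offset.mean())  # additive only
        ps = []
        for seed in range(200):
            ds = gen_rm_dataset(means, seed=seed)
            ps.append(within_anova(fit_rm(ds, "preparation"), "none")[1].p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestTukeyKramer:
    def test_identical_levels_give_q_zero_p_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.4, 0.05, size=(6, 8))
        rows = []
        for lev in ("A", "B"):
            for s in range(6):
                for j, fc in enumerate(np.linspace(20e3, 100e3, 8)):
                    rows.append(
                        {"preparation": lev, "group": "g", "set_id": f"{lev}{s}",
                         "fc_hz": fc, "alpha": vals[s, j]}
                    )
        ds = RMDataset(pd.DataFrame(rows))
        out = tukey_kramer(ds, "preparation")
        assert out["q"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_two_level_case_equals_pooled_t_test(self):
        """With two groups the studentized-range p equals the two-sided
        pooled-variance t-test p."""
        means = default_rm_means().query("group != 'chalcosiine'")
        ds = gen_rm_dataset(means, seed=7)
        out = tukey_kramer(ds, "group")
        fit = fit_rm(ds, "group")
        a = fit.subjects.loc[fit.subjects["level"] == fit.levels[0], "marginal_mean"]
        b = fit.subjects.loc[fit.subjects["level"] == fit.levels[1], "marginal_mean"]
        t = sps.ttest_ind(a, b, equal_var=True)
        assert out["p"].iloc[0] == pytest.approx(t.pvalue, rel=1e-8)

    def test_matches_statsmodels_tukeyhsd(self, dataset):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        fit = fit_rm(dataset, "group")
        mine = tukey_kramer(dataset, "group")
        res = sm.pairwise_tukeyhsd(
            fit.subjects["marginal_mean"], fit.subjects["level"]
        )
        np.testing.assert_allclose(
            mine["p"].to_numpy(), res.pvalues, atol=1e-6
        )

    def test_per_band_comparison_uses_band_values(self, dataset):
        out_overall = tukey_kramer(dataset, "group")
        out_25k = tukey_kramer(dataset, "group", at_band=25_000.0)
        assert set(out_25k.columns) == set(out_overall.columns)
        assert not np.allclose(out_25k["q"], out_overall["q"])
        with pytest.raises(ValueError):
            tukey_kramer(dataset, "group", at_band=12_345.0)


def test_orthonormal_contrasts_properties():
    C = _orthonormal_contrasts(8)
    np.testing.assert_allclose(C @ C.T, np.eye(7), atol=1e-12)
    np.testing.assert_allclose(C @ np.ones(8), 0.0, atol=1e-12)
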