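import numpy as np
import pytest
import scipy.stats as st
import statsmodels.api as sm

import tastecourse as tc
from tastecourse.diffexp import dispersion_from_counts
from tastecourse.simulate import ArchetypeSpec


def null_counts(n_genes, phi, seed):
    flat = ArchetypeSpec("flat", (0.0,) * 7, 1.0)
    cfg = tc.SimConfig(n_genes=n_genes, archetypes=(flat,), dispersion=phi,
                       planted_category=None, n_decoy_categories=0, seed=seed)
    a, b, _, _ = tc.generate_dataset(cfg)
    return a, b


class TestFitNbGlm:
    def test_intercept_only_poisson_mean_is_arithmetic_mean(self):
        y = np.array([3.0, 7.0, 5.0, 9.0])
        fit = tc.fit_nb_glm(y, np.ones((4, 1)), dispersion=0.0)
        np.testing.assert_allclose(fit.fitted, y.mean(), rtol=1e-6)

    @pytest.mark.parametrize("phi", [0.05, 0.5, 2.0])
    def test_intercept_only_nb_mean_is_arithmetic_mean(self, phi):
        # the NB score equation with a free intercept is solved by the mean
        y = np.array([3.0, 7.0, 5.0, 9.0, 0.0, 12.0])
        fit = tc.fit_nb_glm(y, np.ones((6, 1)), dispersion=phi)
        np.testing.assert_allclose(fit.fitted, y.mean(), rtol=1e-6)

    def test_saturated_poisson_fit_reproduces_observations(self):
        y = np.array([2.0, 8.0, 5.0])
        X = np.eye(3)
        fit = tc.fit_nb_glm(y, X, dispersion=0.0)
        np.testing.assert_allclose(fit.fitted, y, rtol=1e-5)
        assert fit.deviance == pytest.approx(0.0, abs=1e-8)

    def test_loglik_equals_direct_pmf_summation(self, seven_stage_design):
        rng = np.random.default_rng(0)
        phi = 0.3
        mu = np.exp(rng.normal(4, 0.5, 14))
        y = rng.negative_binomial(1 / phi, (1 / phi) / (1 / phi + mu)).astype(float)
        fit = tc.fit_nb_glm(y, seven_stage_design.X_full,
                            seven_stage_design.offsets, dispersion=phi)
        r = 1 / phi
        direct = st.nbinom.logpmf(y, r, r / (r + fit.fitted)).sum()
        assert fit.loglik == pytest.approx(direct, abs=1e-9)

    @pytest.mark.parametrize("phi", [0.0, 0.3])
    def test_agrees_with_statsmodels_glm(self, seven_stage_design, phi):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.normal(4, 0.5, 14))
        y = rng.poisson(mu).astype(float)
        fam = (sm.families.Poisson() if phi == 0.0
               else sm.families.NegativeBinomial(alpha=phi))
        ours = tc.fit_nb_glm(y, seven_stage_design.X_full,
                             seven_stage_design.offsets, dispersion=phi)
        ref = sm.GLM(y, seven_stage_design.X_full,
                     offset=seven_stage_design.offsets, family=fam).fit()
        np.testing.assert_allclose(ours.coef, ref.params, atol=1e-4)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(tc.InputError):
            tc.fit_nb_glm(np.ones(3), np.ones((3, 1)), dispersion=-1.0)


class TestLrt:
    def test_flat_counts_give_zero_statistic(self, seven_stage_design):
        y = np.full(14, 50.0)
        full = tc.fit_nb_glm(y, seven_stage_design.X_full,
                             seven_stage_design.offsets, dispersion=0.1)
        red = tc.fit_nb_glm(y, seven_stage_design.X_reduced,
                            seven_stage_design.offsets, dispersion=0.1)
        lr, df, p = tc.lrt_stage(full, red)
        assert df == 6
        assert lr == pytest.approx(0.0, abs=1e-4)
        assert p > 0.99

    def test_non_nested_designs_rejected(self):
        rng = np.random.default_rng(2)
        y = rng.poisson(20, 6).astype(float)
        X1 = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        X2 = np.column_stack([np.ones(6), [0, 1, 0, 1, 0, 1]])
        f1 = tc.fit_nb_glm(y, X1, dispersion=0.0)
        f2 = tc.fit_nb_glm(y, X2, dispersion=0.0)
        with pytest.raises(tc.InputError):
            tc.lrt_stage(f1, f2)

    def test_statistic_invariant_to_observation_order(self, seven_stage_design):
        rng = np.random.default_rng(3)
        y = rng.poisson(30, 14).astype(float)
        X, off = seven_stage_design.X_full, seven_stage_design.offsets
        Xr = seven_stage_design.X_reduced
        lr0, _, _ = tc.lrt_stage(tc.fit_nb_glm(y, X, off, 0.1),
                                 tc.fit_nb_glm(y, Xr, off, 0.1))
        perm = rng.permutation(14)
        lr1, _, _ = tc.lrt_stage(tc.fit_nb_glm(y[perm], X[perm], off[perm], 0.1),
                                 tc.fit_nb_glm(y[perm], Xr[perm], off[perm], 0.1))
        assert lr0 == pytest.approx(lr1, abs=1e-6)

    def test_pvalues_approximately_uniform_under_null(self):
        a, b = null_counts(2000, 0.1, seed=11)
        res = tc.de_test(a, b, dispersion=0.1)
        ks = st.kstest(res.table["p_value"], "uniform")
        assert ks.pvalue > 0.01


class TestDispersion:
    def test_poisson_truth_gives_near_zero_genewise(self):
        a, b = null_counts(2000, 0.0, seed=12)
        phi, _ = tc.estimate_dispersion(a, b, mode="genewise")
        assert np.median(phi) < 0.02

    def test_common_mode_recovers_truth_within_ten_percent(self):
        a, b = null_counts(2000, 0.1, seed=13)
        _, info = tc.estimate_dispersion(a, b, mode="common")
        assert abs(info["common"] - 0.1) / 0.1 < 0.10

    def test_shrunk_lies_between_genewise_and_common(self):
        a, b = null_counts(300, 0.1, seed=14)
        phi_g, _ = tc.estimate_dispersion(a, b, mode="genewise")
        _, info = tc.estimate_dispersion(a, b, mode="common")
        phi_s, _ = tc.estimate_dispersion(a, b, mode="shrunk")
        # shrinkage contracts the genewise spread around the common value
        spread_g = np.abs(np.log(phi_g + 1e-6) - np.log(info["common"]))
        spread_s = np.abs(np.log(phi_s + 1e-6) - np.log(info["common"]))
        assert np.median(spread_s) < np.median(spread_g)

    def test_all_zero_gene_flagged_with_zero_dispersion(self):
        a, b = null_counts(20, 0.1, seed=15)
        a.values.iloc[0] = 0.0
        b.values.iloc[0] = 0.0
        phi, info = tc.estimate_dispersion(a, b, mode="genewise")
        assert phi[0] == 0.0
        assert info["n_all_zero"] == 1

    def test_degenerate_design_without_residual_df_rejected(self):
        rng = np.random.default_rng(4)
        Y = rng.poisson(20, (5, 3)).astype(float)
        design = tc.DesignSpec(stages=["d2", "d4", "d6"], X_full=np.eye(3),
                               X_reduced=np.eye(3)[:, :1],
                               offsets=np.zeros(3))
        with pytest.raises(tc.InputError):
            dispersion_from_counts(Y, design)


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(tc.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_vectors(self):
        assert tc.bh_adjust([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(tc.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=100)
        adj = tc.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj <= 1.0).all()

    def test_invalid_pvalues_rejected(self):
        for bad in ([1.2], [-0.1], [np.nan]):
            with pytest.raises(tc.InputError):
                tc.bh_adjust(bad)


class TestDeTest:
    def test_table_schema_and_df(self):
        a, b = null_counts(50, 0.1, seed=16)
        res = tc.de_test(a, b)
        assert (res.table["df"] == 6).all()
        assert res.table["p_value"].between(0, 1).all()
        assert {"lr_stat", "fdr", "dispersion"} <= set(res.table.columns)
        assert res.table.filter(like="log2_effect").shape[1] == 6

    def test_refuses_rpkm_input(self, default_dataset):
        a, b, _, _ = default_dataset
        with pytest.raises(tc.InputError):
            tc.de_test(tc.compute_rpkm(a), tc.compute_rpkm(b))

    def test_power_increases_with_effect_size(self):
        def power(span, seed):
            arch = ArchetypeSpec(
                "late_rise", (0, 0, 0, 0, 0.9 * span, 0.95 * span, span), 1.0)
            cfg = tc.SimConfig(n_genes=400, archetypes=(arch,), dispersion=0.1,
                               planted_category=None, n_decoy_categories=0,
                               seed=seed)
            a, b, _, _ = tc.generate_dataset(cfg)
            return (tc.de_test(a, b).table["fdr"] <= 0.05).mean()

        assert power(2.0, 21) > power(1.0, 21)
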