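"""Mixed models, BH correction, restricted PERMANOVA, Tukey HSD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mycoforage.inference import (
    LMMSpec,
    bh_adjust,
    bray_curtis,
    fit_lmm,
    hellinger,
    permanova_restricted,
    test_genus_intercepts as genus_intercept_tests,
    tukey_hsd,
)


class TestHellinger:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((1 / 9, 4 / 9, 4 / 9), (1 / 3, 2 / 3, 2 / 3)),
            ((0.0, 1.0), (0.0, 1.0)),
            ((0.25,), (0.5,)),
        ],
    )
    def test_square_root_values(self, row, expected):
        np.testing.assert_allclose(hellinger(row), expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hellinger([-0.1, 0.5])


def nested_labels(n_sites, caf_per_site, obs_per_caf=1):
    sites, cafs = [], []
    for s in range(n_sites):
        for c in range(caf_per_site):
            sites += [f"S{s}"] * obs_per_caf
            cafs += [f"S{s}C{c}"] * obs_per_caf
    return np.array(sites), np.array(cafs)


class TestFitLMM:
    def test_constant_response_degenerate(self):
        sites, cafs = nested_labels(3, 2)
        spec = LMMSpec.build(np.full(6, 4.2), random={"site": sites, "cafeteria": cafs})
        fit = fit_lmm(spec)
        assert fit.beta[0] == pytest.approx(4.2)
        assert all(v == 0.0 for v in fit.vcomp.values())
        assert fit.singular

    def test_zero_group_variance_matches_ols(self):
        # group means engineered to be identical: REML puts the group
        # variance at the 0 boundary and GLS collapses to OLS exactly
        y = np.tile([1.0, 3.0], 6)  # every group mean = 2
        groups = np.repeat([f"g{i}" for i in range(6)], 2)
        fit = fit_lmm(LMMSpec.build(y, random={"group": groups}))
        assert fit.singular
        assert fit.beta[0] == pytest.approx(y.mean())
        ols_se = y.std(ddof=1) / np.sqrt(len(y))
        assert fit.intercept_test()["se"] == pytest.approx(ols_se, rel=1e-4)

    def test_matches_statsmodels_reml(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(1)
        sites, cafs = nested_labels(10, 5)
        site_eff = dict(zip(np.unique(sites), rng.normal(0, 1, 10)))
        y = 2 + np.array([site_eff[s] for s in sites]) + rng.normal(0, 1, 50)
        fit = fit_lmm(LMMSpec.build(y, random={"site": sites}))
        df = pd.DataFrame({"y": y, "site": sites})
        sm_fit = smf.mixedlm(
            "y ~ 1", df, groups=np.ones(50), vc_formula={"site": "0 + C(site)"}
        ).fit(reml=True)
        assert fit.beta[0] == pytest.approx(sm_fit.fe_params.iloc[0], abs=1e-5)
        assert fit.intercept_test()["se"] == pytest.approx(sm_fit.bse_fe.iloc[0], rel=1e-3)
        assert fit.vcomp["site"] == pytest.approx(sm_fit.vcomp[0], rel=1e-2, abs=1e-4)

    def test_satterthwaite_df_balanced_between_design(self):
        # with dominant between-site variance, the intercept test has
        # ~(n_sites - 1) denominator df
        rng = np.random.default_rng(2)
        sites, cafs = nested_labels(8, 4)
        site_eff = dict(zip(np.unique(sites), rng.normal(0, 3, 8)))
        y = np.array([site_eff[s] for s in sites]) + rng.normal(0, 0.3, len(sites))
        fit = fit_lmm(LMMSpec.build(y, random={"site": sites}))
        assert fit.intercept_test()["df"] == pytest.approx(7, abs=0.5)

    def test_intercept_recovery_simulation(self):
        # 20 sites x 5 cafeterias, true intercept 2: the estimate should sit
        # within 3 SE of truth in >= 95% of seeded replicates
        hits = 0
        n_rep = 100
        sites, cafs = nested_labels(20, 5)
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            site_eff = dict(zip(np.unique(sites), rng.normal(0, 1, 20)))
            caf_eff = dict(zip(np.unique(cafs), rng.normal(0, 0.5, 100)))
            y = (
                2.0
                + np.array([site_eff[s] for s in sites])
                + np.array([caf_eff[c] for c in cafs])
                + rng.normal(0, 1, 100)
            )
            fit = fit_lmm(LMMSpec.build(y, random={"site": sites, "cafeteria": cafs}))
            t = fit.intercept_test()
            hits += abs(t["estimate"] - 2.0) <= 3 * t["se"]
        assert hits >= 95

    def test_shuffled_sites_give_no_site_variance(self):
        # no true site effect: the site component should be ~0 relative to
        # residual variance (median over seeds)
        ratios = []
        sites, cafs = nested_labels(10, 5)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 1, 50)
            fit = fit_lmm(LMMSpec.build(y, random={"site": rng.permutation(sites)}))
            ratios.append(fit.vcomp["site"] / max(fit.vcomp["residual"], 1e-12))
        assert np.median(ratios) < 0.05

    def test_non_identifiable_design_raises(self):
        y = np.arange(4.0)
        factor = ["a", "a", "a", "a"]  # single level: dummy column absent
        spec = LMMSpec.build(y, factor=factor, random={"g": ["x", "x", "y", "y"]})
        # single-level factor yields intercept-only design; make collinear one
        X = spec.fixed.copy()
        X["dup"] = X["(Intercept)"]
        spec.fixed = X
        with pytest.raises(ValueError):
            fit_lmm(spec)


class TestGenusIntercepts:
    def _records(self, genus_values, n_caf=12):
        rows = []
        for genus, vals in genus_values.items():
            for i in range(n_caf):
                rows.append(
                    {
                        "genus": genus,
                        "ratio_type": "bags_vs_roots",
                        "site": f"S{i // 4}",
                        "cafeteria": f"S{i // 4}C{i % 4}",
                        "log_ratio": vals[i],
                    }
                )
        return pd.DataFrame(rows)

    def test_all_zero_ratios_give_zero_estimate_p_one(self):
        lr = self._records({"G": np.zeros(12)})
        out = genus_intercept_tests(lr)
        assert out["estimate"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_bh_contract_over_12_genera(self):
        rng = np.random.default_rng(3)
        lr = self._records({f"G{i:02d}": rng.normal(0, 1, 12) for i in range(12)})
        out = genus_intercept_tests(lr)
        assert len(out) == 12
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        ordered = out.sort_values("p")
        assert ordered["p_adj"].is_monotonic_increasing

    def test_power_for_threefold_enrichment(self):
        # true mean ln 3 at low noise over 20 cafeterias in 5 sites:
        # BH-adjusted p <= 0.05 in >= 90% of replicates
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = {
                "Enriched": np.log(3) + rng.normal(0, 0.3, 20),
                "Null1": rng.normal(0, 0.3, 20),
                "Null2": rng.normal(0, 0.3, 20),
            }
            out = genus_intercept_tests(self._records(vals, n_caf=20))
            row = out[out["genus"] == "Enriched"].iloc[0]
            detected += row["p_adj"] <= 0.05
        assert detected >= 18

    def test_too_few_records_skipped(self):
        lr = self._records({"G": np.zeros(12)}).iloc[:1]
        assert genus_intercept_tests(lr).empty


class TestBHAdjust:
    def test_step_up_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_and_is_monotone(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 15)
        mine = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(mine, ref, atol=1e-12)
        assert (mine >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(mine[order]) >= -1e-12).all()


class TestPermanova:
    def test_two_blocks_exhaustive_enumeration(self):
        # two blocks of two samples admit 4 restricted permutations; because
        # a global swap of the two group labels reproduces the same partition
        # (and hence the same F), exactly 2 of the 4 labelings attain the
        # maximal observed F, so p converges to 2/4 = 1/2
        y = np.array([0.0, 1.0, 0.1, 1.1])
        D = np.abs(y[:, None] - y[None, :])
        groups = np.array(["a", "b", "a", "b"])
        blocks = np.array([1, 1, 2, 2])
        res = permanova_restricted(D, groups, blocks, n_perm=4000, seed=0)
        assert res.p_value == pytest.approx(0.5, abs=0.03)

    def test_three_blocks_identity_uniquely_maximal(self):
        # with three blocks, 2 of the 8 restricted labelings (identity and
        # the global swap) attain the maximum: p converges to 2/8 = 1/4
        y = np.array([0.0, 1.0, 0.1, 1.1, 0.2, 1.2])
        D = np.abs(y[:, None] - y[None, :])
        groups = np.array(["a", "b", "a", "b", "a", "b"])
        blocks = np.array([1, 1, 2, 2, 3, 3])
        res = permanova_restricted(D, groups, blocks, n_perm=4000, seed=0)
        assert res.p_value == pytest.approx(0.25, abs=0.03)

    def test_univariate_euclidean_equals_anova_f(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 30)
        g = np.repeat(["a", "b", "c"], 10)
        D = np.abs(y[:, None] - y[None, :])
        res = permanova_restricted(D, g, np.arange(30) % 10, n_perm=9, seed=0)
        f_ref = stats.f_oneway(y[g == "a"], y[g == "b"], y[g == "c"]).statistic
        assert res.pseudo_f == pytest.approx(f_ref, abs=1e-8)

    def test_matches_skbio_pseudo_f(self):
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        rng = np.random.default_rng(5)
        data = rng.gamma(1.0, 1.0, size=(12, 4))
        rel = data / data.sum(axis=1, keepdims=True)
        D = bray_curtis(rel)
        g = np.repeat(["x", "y", "z"], 4)
        res = permanova_restricted(D, g, np.arange(12) % 4, n_perm=9, seed=0)
        sk = sk_permanova(DistanceMatrix(D), g.tolist(), permutations=0)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], abs=1e-8)

    def test_single_group_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            permanova_restricted(D, ["a"] * 4, [1, 1, 2, 2])

    def test_all_singleton_blocks_rejected(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            permanova_restricted(D, ["a", "b", "a", "b"], [1, 2, 3, 4])

    def test_asymmetric_matrix_rejected(self):
        D = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError):
            permanova_restricted(D, ["a", "b", "a", "b"], [1, 1, 2, 2])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        data = rng.gamma(1.0, 1.0, size=(16, 5))
        D = bray_curtis(data / data.sum(axis=1, keepdims=True))
        g = np.tile(["a", "b"], 8)
        blocks = np.repeat(np.arange(8), 2)
        r1 = permanova_restricted(D, g, blocks, n_perm=99, seed=7)
        r2 = permanova_restricted(D, g, blocks, n_perm=99, seed=7)
        assert r1.p_value == r2.p_value


def q_range_mc_oracle(q_obs, k, df, n_draws=100_000, seed=0):
    """Monte-Carlo P(studentized range >= q_obs) for k means and df error df."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_draws, k))
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    q = (z.max(axis=1) - z.min(axis=1)) / s
    return float(np.mean(q >= q_obs))


class TestTukey:
    def _fit(self, y, levels, blocks):
        return fit_lmm(LMMSpec.build(y, factor=levels, random={"caf": blocks}))

    def test_two_levels_reduce_to_pairwise_t(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, 40) + np.repeat([0.0, 0.5], 20)
        levels = np.repeat(["a", "b"], 20)
        blocks = np.tile(np.arange(10), 4)
        fit = self._fit(y, levels, blocks)
        tk = tukey_hsd(fit)
        pairwise = fit.contrast_test(np.array([0.0, 1.0]))
        assert tk["p_adj"].iloc[0] == pytest.approx(pairwise["p"], abs=1e-9)

    def test_identical_level_means_give_p_one(self):
        y = np.tile([1.0, 2.0, 1.0, 2.0, 1.0, 2.0], 4)
        levels = np.tile(np.repeat(["a", "b", "c"], 2), 4)
        blocks = np.repeat(np.arange(4), 6)
        tk = tukey_hsd(self._fit(y, levels, blocks))
        assert (tk["p_adj"] > 0.9999).all()

    def test_three_group_p_matches_monte_carlo(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 30) + np.repeat([0.0, 0.8, 0.2], 10)
        levels = np.repeat(["a", "b", "c"], 10)
        fit = fit_lmm(LMMSpec.build(y, factor=levels, random={}))
        tk = tukey_hsd(fit)
        for _, row in tk.iterrows():
            q_obs = abs(row["estimate"]) / row["se"] * np.sqrt(2)
            mc = q_range_mc_oracle(q_obs, k=3, df=row["df"])
            assert row["p_adj"] == pytest.approx(mc, abs=0.01)

    def test_single_level_rejected(self):
        y = np.arange(6.0)
        fit = fit_lmm(LMMSpec.build(y, random={"g": ["a", "b", "c"] * 2}))
        with pytest.raises(ValueError):
            tukey_hsd(fit)


class TestExplorationTypeCalibration:
    def test_f_test_p_uniform_under_null(self):
        # genus effects exist but are independent of exploration type:
        # the exploration-type F-test p-value should be ~Uniform(0,1)
        n_sim = 300
        genera = [f"G{i}" for i in range(8)]
        etype = dict(zip(genera, np.repeat(["c", "s", "mdf", "mds"], 2)))
        sites, cafs = nested_labels(5, 2)
        pvals = []
        for seed in range(n_sim):
            rng = np.random.default_rng(10_000 + seed)
            rows = []
            g_eff = dict(zip(genera, rng.normal(0, 0.8, len(genera))))
            c_eff = dict(zip(np.unique(cafs), rng.normal(0, 0.3, len(np.unique(cafs)))))
            for g in genera:
                for s, c in zip(sites, cafs):
                    rows.append(
                        {
                            "y": g_eff[g] + c_eff[c] + rng.normal(0, 0.5),
                            "etype": etype[g],
                            "genus": g,
                            "site": s,
                            "caf": c,
                        }
                    )
            df = pd.DataFrame(rows)
            fit = fit_lmm(
                LMMSpec.build(
                    df["y"].to_numpy(),
                    factor=df["etype"].to_numpy(),
                    random={
                        "genus": df["genus"].to_numpy(),
                        "site": df["site"].to_numpy(),
                        "caf": df["caf"].to_numpy(),
                    },
                )
            )
            pvals.append(fit.factor_ftest()["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
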