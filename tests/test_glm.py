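import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from nbsconn import (
    apply_permutation,
    build_design,
    contrast_t,
    fit_edges,
    group_contrast,
    omnibus_F,
    permute_design,
)
from nbsconn.glm import DesignError, DesignMatrix


def small_cohort(n_per_group=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("HC", "MDD", "MDD_ANX"):
        for k in range(n_per_group):
            rows.append({
                "subject_id": f"{g}{k}", "group": g,
                "age": float(rng.uniform(20, 60)),
                "sex": rng.choice(["female", "male"]),
                "site": rng.choice(["site1", "site2"]),
                "stai_trait": float(rng.normal(40, 10)),
            })
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_group_design_columns(self):
        d = build_design(small_cohort(), covariates=("age", "sex", "site"))
        # intercept + 2 group dummies + age + sex + site
        assert d.p == 6
        assert [d.column_names[k] for k in d.effect_columns] == \
            ["group_MDD", "group_MDD_ANX"]

    def test_continuous_effect_single_column(self):
        d = build_design(small_cohort(), effect="continuous:stai_trait")
        assert d.q == 1
        assert d.column_names[d.effect_columns[0]] == "stai_trait"
        # centered
        assert d.X[:, d.effect_columns[0]].mean() == pytest.approx(0, abs=1e-10)

    def test_duplicated_covariate_rank_error(self):
        with pytest.raises(DesignError, match="rank deficient"):
            build_design(small_cohort(), covariates=("age", "age"))

    def test_contrast_vectors(self):
        d = build_design(small_cohort())
        c = group_contrast(d, "MDD", "HC")
        assert c[d.column_names.index("group_MDD")] == 1
        assert np.sum(c != 0) == 1
        c2 = group_contrast(d, "MDD_ANX", "MDD")
        assert c2[d.column_names.index("group_MDD_ANX")] == 1
        assert c2[d.column_names.index("group_MDD")] == -1


class TestFitEdges:
    def test_hand_computed_normal_equations(self):
        # 4 subjects, intercept + slope; closed-form OLS
        X = np.column_stack([np.ones(4), [0.0, 1, 2, 3]])
        d = DesignMatrix(X, ("intercept", "x"), np.array([1]))
        y = np.array([1.0, 2.0, 2.0, 4.0])
        fit = fit_edges(y[:, None], d)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coef[:, 0] == pytest.approx(beta)
        assert fit.rss[0] == pytest.approx(np.sum((y - X @ beta) ** 2))

    def test_group_constant_response_zero_residual(self):
        cohort = small_cohort()
        d = build_design(cohort, covariates=())
        y = cohort["group"].map({"HC": 1.0, "MDD": 2.0, "MDD_ANX": 5.0}).to_numpy()
        fit = fit_edges(y[:, None], d)
        assert fit.rss[0] == pytest.approx(0, abs=1e-18)

    def test_nonfinite_rejected_with_columns(self):
        d = build_design(small_cohort(), covariates=())
        Y = np.ones((30, 3))
        Y[4, 2] = np.nan
        with pytest.raises(DesignError, match=r"\[2\]"):
            fit_edges(Y, d)


class TestStatistics:
    def test_omnibus_matches_statsmodels_ancova(self):
        """Edge-wise F equals the textbook ANCOVA F from statsmodels."""
        cohort = small_cohort(12, seed=1)
        d = build_design(cohort)
        rng = np.random.default_rng(2)
        y = rng.normal(size=len(cohort)) + \
            cohort["group"].map({"HC": 0, "MDD": 0.5, "MDD_ANX": 1.0}).to_numpy()
        fit = fit_edges(y[:, None], d)
        F = omnibus_F(fit, d).values[0]
        ols = sm.OLS(y, d.X).fit()
        R = np.zeros((2, d.p))
        R[0, d.effect_columns[0]] = 1
        R[1, d.effect_columns[1]] = 1
        assert F == pytest.approx(float(ols.f_test(R).fvalue), abs=1e-8)

    def test_identical_groups_give_zero_F(self):
        cohort = small_cohort()
        d = build_design(cohort, covariates=())
        y = np.ones(len(cohort)) * 3.0
        fit = fit_edges(y[:, None], d)
        stats = omnibus_F(fit, d)
        assert stats.values[0] == 0.0
        assert stats.flags[0]  # zero-variance edge flagged

    def test_two_group_F_equals_t_squared(self):
        cohort = small_cohort().query("group != 'MDD_ANX'").reset_index(drop=True)
        cohort = cohort.copy()
        # build a 2-level design manually: drop the empty level column
        rng = np.random.default_rng(3)
        y = rng.normal(size=len(cohort))
        X = np.column_stack([np.ones(len(cohort)),
                             (cohort["group"] == "MDD").astype(float)])
        d = DesignMatrix(X, ("intercept", "group_MDD"), np.array([1]))
        fit = fit_edges(y[:, None], d)
        F = omnibus_F(fit, d).values[0]
        t = contrast_t(fit, d, np.array([0.0, 1.0])).values[0]
        assert F == pytest.approx(t**2, rel=1e-10)

    def test_contrast_t_matches_statsmodels(self):
        cohort = small_cohort(15, seed=4)
        d = build_design(cohort)
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(cohort))
        fit = fit_edges(y[:, None], d)
        c = group_contrast(d, "MDD", "HC")
        t = contrast_t(fit, d, c).values[0]
        ols = sm.OLS(y, d.X).fit()
        assert t == pytest.approx(
            float(np.asarray(ols.t_test(c).tvalue).squeeze()), abs=1e-8)

    def test_contrast_antisymmetry(self):
        cohort = small_cohort(8, seed=6)
        d = build_design(cohort)
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(len(cohort), 5))
        fit = fit_edges(Y, d)
        c = group_contrast(d, "MDD_ANX", "HC")
        assert np.allclose(contrast_t(fit, d, -c).values,
                           -contrast_t(fit, d, c).values)

    def test_zero_contrast_gives_zero_everywhere(self):
        cohort = small_cohort(8)
        d = build_design(cohort)
        Y = np.random.default_rng(8).normal(size=(len(cohort), 4))
        fit = fit_edges(Y, d)
        stats = contrast_t(fit, d, np.zeros(d.p))
        assert np.all(stats.values == 0)
        assert np.all(stats.flags)


class TestPermutation:
    def test_identity_reproduces_observed(self):
        cohort = small_cohort(10, seed=9)
        d = build_design(cohort)
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(len(cohort), 6))
        fit = fit_edges(Y, d)
        observed_F = omnibus_F(fit, d).values
        for scheme in ("label", "freedman_lane"):
            real = permute_design(d, scheme, rng=0)
            identity = real.__class__(order=np.arange(d.n), scheme=scheme)
            Yp, dp = apply_permutation(Y, d, identity)
            Fp = omnibus_F(fit_edges(Yp, dp), dp).values
            assert np.allclose(Fp, observed_F, atol=1e-10), scheme

    def test_fixed_seed_reproducible(self):
        d = build_design(small_cohort())
        a = permute_design(d, "label", rng=42).order
        b = permute_design(d, "label", rng=42).order
        assert np.array_equal(a, b)

    def test_unknown_scheme_rejected(self):
        d = build_design(small_cohort())
        with pytest.raises(DesignError, match="unknown permutation scheme"):
            permute_design(d, "bootstrap")

    @pytest.mark.parametrize("scheme", ["label", "freedman_lane"])
    def test_null_p_values_uniform_single_edge(self, scheme):
        """Permutation p at a noise edge is uniform under the null."""
        from nbsconn.nbs import _PermEngine

        n, n_perm, n_rep = 30, 99, 300
        master = np.random.default_rng(314)
        pvals = []
        for _ in range(n_rep):
            cohort = small_cohort(10, seed=int(master.integers(2**31)))
            d = build_design(cohort, covariates=("age",))
            y = master.normal(size=(len(cohort), 1))
            obs = omnibus_F(fit_edges(y, d), d).values[0]
            eng = _PermEngine(y, d, scheme)
            null = [eng.f_stats(master.permutation(len(cohort)))[0]
                    for _ in range(n_perm)]
            pvals.append((1 + sum(f >= obs for f in null)) / (1 + n_perm))
        pvals = np.array(pvals)
        assert abs(pvals.mean() - 0.5) < 0.05
        rate = np.mean(pvals <= 0.10)
        # binomial 3-sigma band around 0.10
        assert rate < 0.10 + 3 * np.sqrt(0.1 * 0.9 / n_rep)
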