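import numpy as np
import pandas as pd
import pytest

from elevdiv.env_rda import (
    collapse_om_block,
    hierarchical_partition,
    rda,
    rda_over_bootstrap,
    select_predictors,
    vif,
)


def _frame(arr, cols):
    return pd.DataFrame(arr, columns=cols)


class TestVif:
    def test_orthogonal_columns_unity(self):
        # +-1 contrast columns: mutually orthogonal and orthogonal to the
        # intercept, so nothing inflates
        a = np.tile([1.0, -1.0], 6)
        b = np.repeat([1.0, -1.0], 6)
        x = _frame(np.column_stack([a, b, a * b]), list("abc"))
        out = vif(x)
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(0)
        a = rng.random(20)
        x = _frame(np.column_stack([a, a, rng.random(20)]), list("abc"))
        out = vif(x)
        assert np.isinf(out["a"]) and np.isinf(out["b"])
        assert np.isfinite(out["c"])

    def test_matches_direct_ols_definition(self):
        rng = np.random.default_rng(1)
        x = rng.random((30, 3))
        x[:, 2] = 0.7 * x[:, 0] + 0.3 * rng.random(30)
        frame = _frame(x, list("abc"))
        ours = vif(frame)
        import statsmodels.api as sm

        for j, col in enumerate(frame.columns):
            others = sm.add_constant(np.delete(x, j, axis=1))
            r2 = sm.OLS(x[:, j], others).fit().rsquared
            assert ours[col] == pytest.approx(1 / (1 - r2))


class TestOmCollapse:
    def test_identical_columns_share_one(self):
        rng = np.random.default_rng(2)
        a = rng.random(20)
        frame = _frame(np.column_stack([a, a, a, a]), ["SOM", "TOC", "TON", "WC"])
        out = collapse_om_block(frame, block=("SOM", "TOC", "TON", "WC"))
        assert out.variance_share == pytest.approx(1.0)

    def test_sign_convention_follows_som(self, sim_default):
        _, _, env, _ = sim_default
        out = collapse_om_block(env)
        assert np.corrcoef(out.scores, env.frame["SOM"])[0, 1] > 0
        assert out.variance_share > 0.9

    def test_scores_invariant_to_column_order(self, sim_default):
        _, _, env, _ = sim_default
        a = collapse_om_block(env, block=("SOM", "TOC", "TON", "WC"))
        b = collapse_om_block(env, block=("WC", "TON", "TOC", "SOM"))
        np.testing.assert_allclose(a.scores.to_numpy(), b.scores.to_numpy(), atol=1e-10)

    def test_zero_variance_column_rejected(self):
        frame = _frame(np.ones((10, 4)), ["SOM", "TOC", "TON", "WC"])
        frame["SOM"] = np.arange(10.0)
        with pytest.raises(ValueError, match="zero-variance"):
            collapse_om_block(frame, block=("SOM", "TOC", "TON", "WC"))


class TestRda:
    def test_linear_response_full_fit(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.random((12, 2)), list("ab"))
        Y = np.column_stack([2 * X["a"], X["a"] - X["b"], 0.5 * X["b"]])
        fit = rda(Y, X)
        assert fit.r_squared == pytest.approx(1.0)

    def test_orthogonal_predictors_zero_fit(self):
        n = 8
        Y = np.column_stack([np.tile([1.0, -1.0], n // 2)])
        X = _frame(np.repeat([1.0, -1.0], n // 2)[:, None], ["a"])
        fit = rda(Y, X)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)
        assert fit.adj_r_squared <= 0

    def test_matches_per_column_ols_projection(self):
        rng = np.random.default_rng(4)
        X = _frame(rng.random((5, 2)), list("ab"))
        Y = rng.random((5, 3))
        fit = rda(Y, X)
        import statsmodels.api as sm

        Xs = (X - X.mean()) / X.std()
        Xi = sm.add_constant(Xs.to_numpy())
        Yc = Y - Y.mean(axis=0)
        ss_fit = sum(sm.OLS(Yc[:, k], Xi).fit().ess for k in range(3))
        ss_tot = float((Yc**2).sum())
        assert fit.r_squared == pytest.approx(ss_fit / ss_tot)
        n, m = 5, 2
        assert fit.adj_r_squared == pytest.approx(
            1 - (1 - fit.r_squared) * (n - 1) / (n - m - 1)
        )

    def test_rank_deficient_design_named(self):
        rng = np.random.default_rng(5)
        a = rng.random(10)
        X = _frame(np.column_stack([a, a]), list("ab"))
        with pytest.raises(ValueError, match="collinear"):
            rda(rng.random((10, 2)), X)


class TestSelection:
    def test_single_generating_predictor_selected(self):
        rng = np.random.default_rng(6)
        X = _frame(rng.standard_normal((30, 1)), ["b"])
        Y = np.outer(X["b"], [1.0, -0.5, 2.0]) + 0.05 * rng.standard_normal((30, 3))
        res = select_predictors(Y, X, n_perm=199, seed=0)
        assert res.selected == ["b"]
        assert sum(step["step"] == "forward" for step in res.path) == 1

    def test_ceiling_blocks_overshooting_candidate(self):
        """A dominant predictor diluted by pure-noise candidates can push a
        one-variable model past the all-candidate adjusted R2; the double
        stopping rule then ends the forward phase without adding it."""
        rng = np.random.default_rng(60)
        X = _frame(rng.standard_normal((20, 5)), list("abcde"))
        Y = np.outer(X["b"], [1.0, -0.5, 2.0]) + 0.02 * rng.standard_normal((20, 3))
        res = select_predictors(Y, X, n_perm=199, seed=0)
        assert any(s.get("reason") == "adjusted-R2 ceiling" for s in res.path) or res.selected == ["b"]

    def test_duplicate_candidate_kept_once(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(25)
        X = _frame(np.column_stack([a, a]), ["x", "x_copy"])
        Y = np.outer(a, [1.0, 0.5]) + 0.1 * rng.standard_normal((25, 2))
        res = select_predictors(Y, X, n_perm=199, seed=1)
        assert len(res.selected) == 1

    def test_pure_noise_rarely_selects(self):
        """Family-level false-selection rate stays near the nominal alpha."""
        rng = np.random.default_rng(8)
        hits = 0
        runs = 200
        for i in range(runs):
            X = _frame(rng.standard_normal((20, 4)), list("abcd"))
            Y = rng.standard_normal((20, 5))
            res = select_predictors(Y, X, alpha=0.05, n_perm=99, seed=i)
            if res.selected:
                hits += 1
        assert hits <= 0.12 * runs

    def test_column_order_invariance(self):
        rng = np.random.default_rng(9)
        X = _frame(rng.standard_normal((30, 3)), list("abc"))
        Y = np.outer(X["a"] + 0.5 * X["c"], [1.0, 2.0]) + 0.1 * rng.standard_normal((30, 2))
        r1 = select_predictors(Y, X, n_perm=199, seed=3)
        r2 = select_predictors(Y, X[["c", "b", "a"]], n_perm=199, seed=3)
        assert set(r1.selected) == set(r2.selected)


class TestHierarchicalPartition:
    def test_orthogonal_predictors_individual_equals_unique(self):
        n = 16
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        X = _frame(np.column_stack([a, b]), list("ab"))
        rng = np.random.default_rng(10)
        Y = np.outer(a, [1.0]) + np.outer(b, [0.5]) + 0.1 * rng.standard_normal((n, 1))
        out = hierarchical_partition(Y, X, adjusted=False)
        np.testing.assert_allclose(out["individual"], out["unique"], atol=1e-10)

    def test_two_predictor_closed_form(self):
        rng = np.random.default_rng(11)
        X = _frame(rng.standard_normal((25, 2)), list("ab"))
        Y = np.outer(X["a"] + 0.7 * X["b"], [1.0, -1.0]) + 0.3 * rng.standard_normal((25, 2))
        out = hierarchical_partition(Y, X)

        def adj(cols):
            if not cols:
                return 0.0
            f = rda(Y, X[cols])
            return f.adj_r_squared

        expected_a = 0.5 * (adj(["a"]) + adj(["a", "b"]) - adj(["b"]))
        assert out.loc["a", "individual"] == pytest.approx(expected_a, abs=1e-12)
        assert out.loc["a", "unique"] == pytest.approx(adj(["a", "b"]) - adj(["b"]), abs=1e-12)

    def test_individual_sums_to_full_model(self):
        rng = np.random.default_rng(12)
        X = _frame(rng.standard_normal((30, 5)), list("abcde"))
        Y = rng.standard_normal((30, 8)) + X[["a", "b"]].sum(axis=1).to_numpy()[:, None]
        out = hierarchical_partition(Y, X)
        assert out["individual"].sum() == pytest.approx(out.attrs["full_adj_r2"], abs=1e-9)

    def test_suppressor_unique_exceeds_individual(self):
        """Negative shared variance: the suppressed predictor's unique
        contribution exceeds its order-averaged individual contribution."""
        rng = np.random.default_rng(13)
        n = 60
        x1 = rng.standard_normal(n)
        x2 = -0.9 * x1 + 0.45 * rng.standard_normal(n)
        y = x1 + x2 + 0.1 * rng.standard_normal(n)
        X = _frame(np.column_stack([x1, x2]), ["x1", "x2"])
        out = hierarchical_partition(y[:, None], X)
        assert (out["unique"] > out["individual"]).all()
        # negative shared variance is exactly what makes that possible
        shared = out["individual"].sum() - out["unique"].sum()
        assert shared < 0

    def test_guard_against_combinatorial_blowup(self):
        X = _frame(np.random.default_rng(14).random((12, 9)), list("abcdefghi"))
        with pytest.raises(ValueError, match="8"):
            hierarchical_partition(np.random.default_rng(15).random((12, 2)), X)


class TestBootstrapRda:
    def test_identical_datasets_single_set(self):
        rng = np.random.default_rng(16)
        X = _frame(rng.standard_normal((30, 3)), list("abc"))
        Y = np.outer(X["a"], [1.0, 0.5]) + 0.05 * rng.standard_normal((30, 2))
        summary, records = rda_over_bootstrap([(Y, X)] * 6, n_perm=99, seed=0)
        assert len(summary) == 1
        assert summary.loc[0, "frequency"] == 6
        assert summary["frequency"].sum() == len(records) == 6

    def test_driving_pair_dominates_selection(self, sim_default):
        """When composition is driven by the elevation gradient and the
        OM latent tracks it, selected sets should be dominated by
        OM_pc1/elevation."""
        from elevdiv.bootstrap import draw_combinations
        from elevdiv.core_data import hellinger, to_relative
        from elevdiv.env_rda import build_design

        table, meta, env, _ = sim_default
        hel = hellinger(to_relative(table))
        design = build_design(env, meta.frame)
        combos = draw_combinations(meta, 30, seed=2)
        datasets = [
            (hel.loc[list(c.sample_ids)], design.loc[list(c.sample_ids)]) for c in combos
        ]
        summary, _ = rda_over_bootstrap(datasets, n_perm=99, seed=3)
        # OM_pc1 and elevation are near-collinear proxies of the same latent
        # gradient, so recovering either (often both) counts as a hit
        driver = summary["selected_set"].str.contains("OM_pc1|elevation")
        assert summary.loc[driver, "frequency"].sum() > 0.5 * summary["frequency"].sum()
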