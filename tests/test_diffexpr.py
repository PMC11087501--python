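"""Design construction, moderated fits, BH, residualization, hidden factors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sexdimorph import (
    DesignSpec,
    ExprMatrix,
    adjust_bh,
    build_design,
    estimate_hidden_factors,
    fit_moderated,
    residualize,
    screen_covariates,
)
from sexdimorph.diffexpr import ModerationParams, posterior_variance


def _meta(n_per_cell=6, regions=("a",), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for region in regions:
        for sex in ("F", "M"):
            for dx in ("CTL", "SZ"):
                for i in range(n_per_cell):
                    rows.append(
                        {
                            "sample_id": f"{sex}{dx}{i}_{region}",
                            "donor_id": f"{sex}{dx}{i}",
                            "sex": sex,
                            "diagnosis": dx,
                            "region": region,
                            "age": rng.uniform(17, 80),
                            "qc1": rng.normal(),
                            "qc2": rng.normal(),
                        }
                    )
    return pd.DataFrame(rows).set_index("sample_id")


def _expr(meta, g=50, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(5, 1, (g, len(meta)))
    return ExprMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(g)], columns=meta.index),
        kind="logCPM",
    )


class TestBuildDesign:
    def test_sex_model_column_count(self):
        meta = _meta()
        pcs = np.random.default_rng(123).normal(size=(len(meta), 3))
        meta[["snpPC1", "snpPC2", "snpPC3"]] = pcs
        factors = pd.DataFrame(
            np.random.default_rng(1).normal(size=(len(meta), 2)),
            index=meta.index,
            columns=["SV1", "SV2"],
        )
        spec = DesignSpec(model="sex", covariates=["qc1", "qc2", "snpPC1", "snpPC2", "snpPC3"])
        design, contrast = build_design(meta, spec, factors)
        # 1 intercept + sex + diagnosis + age + 2 qc + 3 snpPC + 2 SV = 11
        assert design.shape[1] == 11
        assert contrast == ["sex_M"]

    def test_region_interaction_coding(self):
        meta = _meta(regions=("a", "b", "c"))
        spec = DesignSpec(model="sex_x_region")
        design, contrast = build_design(meta, spec)
        assert contrast == ["sex_M:region_b", "sex_M:region_c"]
        # product columns are sex_M * region dummy
        assert np.array_equal(
            design["sex_M:region_b"], design["sex_M"] * design["region_b"]
        )

    def test_diagnosis_by_sex_rejects_mixed_input(self):
        meta = _meta()
        with pytest.raises(ValueError, match="single-sex"):
            build_design(meta, DesignSpec(model="diagnosis_by_sex"))

    def test_rank_deficiency_lists_aliased_columns(self):
        meta = _meta()
        meta["dup_age"] = meta["age"]
        with pytest.raises(ValueError, match="aliased"):
            build_design(meta, DesignSpec(model="sex", covariates=["dup_age"]))

    def test_null_designs_exclude_their_targets(self):
        meta = _meta()
        d5, _ = build_design(meta, DesignSpec(model="null_with_diagnosis"))
        assert "sex_M" not in d5.columns and "diagnosis_SZ" in d5.columns
        d6, _ = build_design(meta, DesignSpec(model="null_minimal"))
        assert "sex_M" not in d6.columns and "diagnosis_SZ" not in d6.columns


def brute_force_wls_t(y, X, w, cidx):
    """Independent WLS t via the sqrt-weight transform and lstsq."""
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], y * sw
    beta, res, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    cov = np.linalg.inv(Xw.T @ Xw) * s2
    return beta[cidx] / np.sqrt(cov[cidx, cidx]), df


class TestModeratedFit:
    def setup_method(self):
        self.meta = _meta(n_per_cell=8, seed=3)
        self.expr = _expr(self.meta, g=80, seed=3)
        self.spec = DesignSpec(model="sex", covariates=["qc1"])
        self.design, self.contrast = build_design(self.meta, self.spec)

    def test_d0_zero_equals_ordinary_wls(self, rng):
        w = pd.DataFrame(
            rng.uniform(0.5, 2.0, self.expr.values.shape),
            index=self.expr.genes,
            columns=self.expr.samples,
        )
        from sexdimorph.quantnorm import WeightMatrix

        res = fit_moderated(self.expr, WeightMatrix(w), self.design, self.contrast, d0=0)
        X = self.design.to_numpy()
        cidx = list(self.design.columns).index("sex_M")
        for g in [0, 7, 42]:
            t_ref, df = brute_force_wls_t(
                self.expr.values.iloc[g].to_numpy(), X, w.iloc[g].to_numpy(), cidx
            )
            assert np.isclose(res.table["t"].iloc[g], t_ref, rtol=1e-10)
            p_ref = 2 * stats.t.sf(abs(t_ref), df)
            assert np.isclose(res.table["P.Value"].iloc[g], p_ref, rtol=1e-10)

    def test_unweighted_moderation_off_equals_ols_oracle(self):
        res = fit_moderated(self.expr, None, self.design, self.contrast, d0=0)
        X = self.design.to_numpy()
        cidx = list(self.design.columns).index("sex_M")
        ones = np.ones(X.shape[0])
        for g in range(0, 80, 13):
            t_ref, _ = brute_force_wls_t(
                self.expr.values.iloc[g].to_numpy(), X, ones, cidx
            )
            assert np.isclose(res.table["t"].iloc[g], t_ref, rtol=1e-10)

    def test_d0_infinite_collapses_to_prior_variance(self):
        res = fit_moderated(self.expr, None, self.design, self.contrast, d0=np.inf)
        prior = res.moderation
        s2 = np.full(5, 2.0)
        assert np.allclose(
            posterior_variance(s2, 10, prior), prior.s0_squared
        )

    def test_posterior_variance_closed_form(self):
        # d0=4, s0^2=1, d=4, s^2=2 -> (4*1 + 4*2)/8 = 1.5
        prior = ModerationParams(s0_squared=1.0, d0=4.0)
        assert posterior_variance(np.array([2.0]), 4, prior)[0] == pytest.approx(1.5)

    def test_fdr_dominates_p(self):
        res = fit_moderated(self.expr, None, self.design, self.contrast)
        t = res.table
        assert (t["adj.P.Val"] >= t["P.Value"] - 1e-15).all()
        ordered = t.sort_values("P.Value")
        assert (np.diff(ordered["adj.P.Val"]) >= -1e-15).all()

    def test_bad_weights_rejected(self):
        from sexdimorph.quantnorm import WeightMatrix

        w = pd.DataFrame(
            np.ones(self.expr.values.shape), index=self.expr.genes, columns=self.expr.samples
        )
        w.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="weights"):
            fit_moderated(self.expr, WeightMatrix(w), self.design, self.contrast)

    def test_cluster_robust_interaction_fit_runs(self):
        meta = _meta(n_per_cell=8, regions=("a", "b"), seed=4)
        expr = _expr(meta, g=40, seed=4)
        design, contrast = build_design(meta, DesignSpec(model="sex_x_region"))
        res = fit_moderated(expr, None, design, contrast, clusters=meta["donor_id"])
        assert res.table["P.Value"].between(0, 1).all()
        assert res.moderation is None  # robust path skips moderation


class TestAdjustBH:
    def bh_oracle(self, p):
        """Step-up definition: p(i)*m/i, cumulative min from the largest rank."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_hand_example(self):
        q = adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_degenerate_cases(self):
        assert np.allclose(adjust_bh(np.ones(5)), 1.0)
        assert adjust_bh(np.array([0.3]))[0] == pytest.approx(0.3)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_step_up_definition(self, p):
        assert np.allclose(adjust_bh(np.array(p)).to_numpy(), self.bh_oracle(p))

    def test_nan_propagates_with_warning(self):
        with pytest.warns(UserWarning, match="NaN"):
            q = adjust_bh(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])


class TestResidualize:
    def test_intercept_only_null_z_scores(self):
        meta = _meta()
        expr = _expr(meta)
        null = pd.DataFrame({"Intercept": np.ones(len(meta))}, index=meta.index)
        out, flagged = residualize(expr, null)
        assert not flagged
        vals = out.values.to_numpy()
        assert np.allclose(vals.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(vals.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_residuals_orthogonal_to_null_covariates(self):
        meta = _meta()
        expr = _expr(meta)
        null, _ = build_design(meta, DesignSpec(model="null_minimal", covariates=["qc1"]))
        out, _ = residualize(expr, null)
        for col in ("age", "qc1"):
            v = meta[col].to_numpy(dtype=float)
            vc = v - v.mean()
            r = out.values.to_numpy() @ vc / (
                np.linalg.norm(out.values.to_numpy(), axis=1) * np.linalg.norm(vc)
            )
            assert np.abs(r).max() < 1e-10

    def test_sex_signal_survives_sexless_null(self):
        """A planted sex effect stays separable after removing the null design."""
        meta = _meta(n_per_cell=15, seed=9)
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 1, (20, len(meta)))
        vals[0, (meta["sex"] == "M").to_numpy()] += 2.0
        expr = ExprMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(20)], columns=meta.index),
            kind="logCPM",
        )
        null, _ = build_design(meta, DesignSpec(model="null_with_diagnosis"))
        out, _ = residualize(expr, null)
        male = out.values.loc["g0", meta.index[meta["sex"] == "M"]]
        female = out.values.loc["g0", meta.index[meta["sex"] == "F"]]
        _, p = stats.ttest_ind(male, female)
        assert p < 0.01

    def test_zero_variance_gene_flagged(self):
        meta = _meta()
        expr = _expr(meta)
        expr.values.iloc[3] = 7.0  # constant gene
        null = pd.DataFrame({"Intercept": np.ones(len(meta))}, index=meta.index)
        out, flagged = residualize(expr, null)
        assert flagged == ["g3"]
        assert "g3" not in out.values.index


class TestScreenCovariates:
    def test_pc1_clone_selected_noise_mostly_not(self):
        meta = _meta(n_per_cell=12, seed=2)
        rng = np.random.default_rng(2)
        factor = rng.normal(size=len(meta))
        vals = rng.normal(0, 0.3, (60, len(meta))) + np.outer(rng.normal(size=60), factor)
        expr = ExprMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(60)], columns=meta.index),
            kind="logCPM",
        )
        meta["pc_clone"] = factor
        meta["noise"] = rng.normal(size=len(meta))
        selected = screen_covariates(expr, meta, candidates=["pc_clone", "noise"])
        assert "pc_clone" in selected

    def test_duplicate_covariate_dropped_before_testing(self):
        meta = _meta()
        meta["qc1_copy"] = meta["qc1"]
        expr = _expr(meta)
        selected = screen_covariates(expr, meta, candidates=["qc1", "qc1_copy", "qc2"])
        assert "qc1_copy" not in selected

    def test_constant_covariate_warned_and_excluded(self):
        meta = _meta()
        meta["flat"] = 1.0
        expr = _expr(meta)
        with pytest.warns(UserWarning, match="constant"):
            selected = screen_covariates(expr, meta, candidates=["flat", "qc1"])
        assert "flat" not in selected

    def test_null_covariates_rarely_selected(self):
        """20 pure-noise candidates selected with probability <= 0.05 per sim."""
        hits = 0
        trials = 10
        for seed in range(trials):
            meta = _meta(n_per_cell=10, seed=seed)
            rng = np.random.default_rng(100 + seed)
            expr = _expr(meta, g=40, seed=seed)
            cands = []
            for i in range(20):
                meta[f"n{i}"] = rng.normal(size=len(meta))
                cands.append(f"n{i}")
            hits += len(screen_covariates(expr, meta, candidates=cands))
        assert hits / (20 * trials) <= 0.05


class TestHiddenFactors:
    def test_planted_batch_recovered(self):
        meta = _meta(n_per_cell=15, seed=6)
        rng = np.random.default_rng(6)
        batch = rng.normal(size=len(meta))
        loadings = rng.normal(scale=1.0, size=100)
        vals = rng.normal(0, 0.5, (100, len(meta))) + np.outer(loadings, batch)
        expr = ExprMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(100)], columns=meta.index),
            kind="logCPM",
        )
        null, _ = build_design(meta, DesignSpec(model="null_with_diagnosis"))
        sv = estimate_hidden_factors(expr, null, k="auto", seed=1)
        assert sv.shape[1] >= 1
        r = np.corrcoef(sv["SV1"], batch)[0, 1]
        assert abs(r) > 0.9

    def test_pure_noise_auto_k_mostly_zero(self):
        zeros = 0
        for seed in range(10):
            meta = _meta(n_per_cell=8, seed=seed)
            expr = _expr(meta, g=60, seed=200 + seed)
            null, _ = build_design(meta, DesignSpec(model="null_minimal"))
            sv = estimate_hidden_factors(expr, null, k="auto", seed=seed)
            zeros += sv.shape[1] == 0
        assert zeros >= 9

    def test_k_zero_is_noop(self):
        meta = _meta()
        expr = _expr(meta)
        null, _ = build_design(meta, DesignSpec(model="null_minimal"))
        sv = estimate_hidden_factors(expr, null, k=0)
        assert sv.shape == (len(meta), 0)
        spec = DesignSpec(model="sex")
        d_with, _ = build_design(meta, spec, sv)
        d_without, _ = build_design(meta, spec, None)
        pd.testing.assert_frame_equal(d_with, d_without)

    def test_k_exceeding_residual_df_rejected(self):
        meta = _meta(n_per_cell=2)
        expr = _expr(meta, g=30)
        null, _ = build_design(meta, DesignSpec(model="null_minimal"))
        with pytest.raises(ValueError, match="residual"):
            estimate_hidden_factors(expr, null, k=len(meta))
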