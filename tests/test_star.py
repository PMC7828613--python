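import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from hapstar.graphs import AdjacencyGraph, load_area_fixture
from hapstar.star import (
    DesignMatrices,
    McmcConfig,
    ModelSpec,
    PosteriorDraws,
    assemble_design,
    compute_dic,
    fit_star,
    gibbs_probit,
    icar_precision,
    summarize_posterior,
)


def fixed_only_design(y, X, names):
    return DesignMatrices(y=y, X=X, fixed_names=names, spline=None,
                          penalty=None, mother_index=None, n_mothers=0,
                          area_index=None, icar=None, ages=np.zeros(len(y)))


FIXED_SPEC = ModelSpec(spatial_structured=False, spatial_unstructured=False)


class TestIcarPrecision:
    def test_path3_matrix(self):
        g = AdjacencyGraph.from_edges(3, [(0, 1), (1, 2)])
        Q = icar_precision(g).matrix
        np.testing.assert_array_equal(
            Q, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_symmetric_zero_row_sums(self, lattice36):
        Q = icar_precision(lattice36).matrix
        np.testing.assert_array_equal(Q, Q.T)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_nigeria_rank_is_36(self):
        Q = icar_precision(load_area_fixture("nigeria37")).matrix
        assert np.linalg.matrix_rank(Q) == 36

    def test_disconnected_rejected(self):
        g = AdjacencyGraph.from_edges(4, [(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="disconnected"):
            icar_precision(g)


class TestAssembleDesign:
    def test_no_missingness_keeps_all_rows(self, small_cohort, lattice36):
        spec = ModelSpec(fixed_terms=("fuel",))
        d = assemble_design(small_cohort.births, spec, lattice36,
                            "stillbirth")
        assert d.audit["n_kept"] == len(small_cohort.births)
        assert d.audit["n_dropped"] == 0
        assert d.fixed_names == ["intercept", "fuel_unclean"]

    def test_lbw_complete_case_fraction(self, small_cohort, lattice36):
        """~94% missing birth weight leaves ~6% of births in the design."""
        spec = ModelSpec(fixed_terms=("fuel",))
        d = assemble_design(small_cohort.births, spec, lattice36, "lbw")
        kept_frac = d.audit["n_kept"] / d.audit["n_total"]
        assert kept_frac == pytest.approx(0.061, abs=0.02)

    def test_wealth_with_fuel_warns(self, small_cohort, lattice36):
        spec = ModelSpec(fixed_terms=("fuel", "wealth"))
        with pytest.warns(UserWarning, match="collinear"):
            d = assemble_design(small_cohort.births, spec, lattice36,
                                "stillbirth")
        assert any("collinear" in w for w in d.audit["warnings"])

    def test_absent_level_is_an_error(self, lattice36):
        df = pd.DataFrame({
            "outcome_stillbirth": [0.0, 1.0, 0.0, 1.0],
            "fuel_unclean": [1, 0, 1, 0],
            "mother_id": [0, 0, 1, 1],
            "area_id": [0, 0, 1, 1],
            "education": pd.Categorical(
                ["none", "none", "primary", "primary"],
                categories=["none", "primary", "secondary", "higher"]),
        })
        spec = ModelSpec(fixed_terms=("fuel", "education"),
                         spatial_structured=False,
                         spatial_unstructured=False)
        with pytest.raises(ValueError, match="absent"):
            assemble_design(df, spec, None, "stillbirth")

    def test_incidence_structure(self, small_cohort, lattice36):
        spec = ModelSpec(fixed_terms=("fuel",), mother_effect=True,
                         smooth_age=True)
        d = assemble_design(small_cohort.births, spec, lattice36,
                            "stillbirth")
        assert d.mother_index.max() + 1 == d.n_mothers
        assert d.spline.basis_matrix.shape == (d.n_obs, d.spline.n_basis)
        np.testing.assert_allclose(d.spline.basis_matrix.sum(axis=1), 1.0,
                                   atol=1e-10)


class TestGibbs:
    def test_all_ones_outcome_forces_positive_intercept(self):
        y = np.ones(50)
        X = np.ones((50, 1))
        d = fixed_only_design(y, X, ["intercept"])
        draws = gibbs_probit(d, FIXED_SPEC,
                             McmcConfig(n_iter=400, burn_in=100, thin=1,
                                        seed=0))
        assert draws.fixed[:, 0].mean() > 0

    def test_stored_draw_count(self):
        y = np.r_[np.ones(30), np.zeros(30)]
        d = fixed_only_design(y, np.ones((60, 1)), ["intercept"])
        mc = McmcConfig(n_iter=500, burn_in=100, thin=7, seed=1)
        draws = gibbs_probit(d, FIXED_SPEC, mc)
        assert draws.n_stored == (500 - 100) // 7 == mc.n_stored

    def test_matches_probit_mle_oracle(self):
        """Flat-prior posterior means agree with an independent Newton
        maximum-likelihood probit fit within 3 posterior sd."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.uniform(size=n) < norm.cdf(-1.0 + 0.5 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        mle = sm.Probit(y, X).fit(disp=0, method="newton")
        d = fixed_only_design(y, X, ["intercept", "fuel"])
        draws = gibbs_probit(d, FIXED_SPEC,
                             McmcConfig(n_iter=2500, burn_in=500, thin=1,
                                        seed=3))
        pm, psd = draws.fixed.mean(axis=0), draws.fixed.std(axis=0)
        assert np.all(np.abs(pm - mle.params) < 3 * psd)

    def test_reproducible_bit_identical(self, small_cohort, lattice36):
        spec = ModelSpec(fixed_terms=("fuel",), mother_effect=True,
                         smooth_age=True)
        d = assemble_design(small_cohort.births, spec, lattice36,
                            "stillbirth")
        mc = McmcConfig(n_iter=200, burn_in=50, thin=2, seed=11)
        a = gibbs_probit(d, spec, mc)
        b = gibbs_probit(d, spec, mc)
        np.testing.assert_array_equal(a.fixed, b.fixed)
        np.testing.assert_array_equal(a.deviance, b.deviance)
        np.testing.assert_array_equal(a.structured, b.structured)

    def test_identifiability_invariants_every_stored_draw(self, small_cohort,
                                                          lattice36):
        spec = ModelSpec(fixed_terms=("fuel",), mother_effect=True,
                         smooth_age=True)
        d = assemble_design(small_cohort.births, spec, lattice36,
                            "stillbirth")
        draws = gibbs_probit(d, spec,
                             McmcConfig(n_iter=300, burn_in=100, thin=1,
                                        seed=5))
        assert draws.spline_centre_abs.max() <= 1e-8
        assert draws.structured_sum_abs.max() <= 1e-8
        assert np.abs(draws.structured.sum(axis=1)).max() <= 1e-8
        assert draws.divergence_flags == []
        assert all(v.min() > 0 for v in draws.variances.values())


class TestDic:
    def _short_fit(self):
        rng = np.random.default_rng(2)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.uniform(size=n) < norm.cdf(-0.5 + 0.4 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        d = fixed_only_design(y, X, ["intercept", "fuel"])
        draws = gibbs_probit(d, FIXED_SPEC,
                             McmcConfig(n_iter=600, burn_in=100, thin=1,
                                        seed=4))
        return draws, d

    def test_dic_identity(self):
        draws, d = self._short_fit()
        dic, p_d, dbar = compute_dic(draws, d)
        assert dic - dbar - p_d == 0.0

    def test_identical_draws_give_zero_pd(self):
        draws, d = self._short_fit()
        const = draws.fixed.mean(axis=0)
        draws.fixed = np.tile(const, (50, 1))
        from hapstar.star import _deviance
        dev = _deviance(d.y, d.X @ const)
        draws.deviance = np.full(50, dev)
        dic, p_d, dbar = compute_dic(draws, d)
        assert p_d == pytest.approx(0.0, abs=1e-9)
        assert dic == pytest.approx(dbar)

    def test_pd_approximates_parameter_count(self):
        """Near-flat-prior probit with 2 coefficients: pD ~ 2, the
        effective parameter count of an approximately Gaussian posterior."""
        sm_seed = 1
        rng = np.random.default_rng(11)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.uniform(size=n) < norm.cdf(-1.0 + 0.5 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        d = fixed_only_design(y, X, ["intercept", "fuel"])
        draws = gibbs_probit(d, FIXED_SPEC,
                             McmcConfig(n_iter=4000, burn_in=1000, thin=1,
                                        seed=sm_seed))
        _, p_d, _ = compute_dic(draws, d)
        assert p_d == pytest.approx(2.0, rel=0.10)


class TestSummaries:
    def _const_draws(self, c=1.5, n_areas=4):
        S = 20
        return PosteriorDraws(
            fixed=np.full((S, 1), c), fixed_names=["intercept"],
            spline_coef=None, spline=None, mother_mean=None,
            mother_draws=None,
            structured=np.full((S, n_areas), 0.25),
            unstructured=np.full((S, n_areas), -0.1),
            variances={}, deviance=np.full(S, 10.0),
            spline_centre_abs=None, structured_sum_abs=None,
            divergence_flags=[],
            mcmc=McmcConfig(n_iter=40, burn_in=20, thin=1, seed=0))

    def test_constant_draws_collapse_cri(self):
        res = summarize_posterior(self._const_draws())
        row = res.params[res.params.name == "intercept"].iloc[0]
        assert (row["mean"], row.ci_low, row.ci_high) == (1.5, 1.5, 1.5)

    def test_total_spatial_is_structured_plus_unstructured(self):
        res = summarize_posterior(self._const_draws())
        np.testing.assert_allclose(
            res.spatial["total"],
            res.spatial["structured"] + res.spatial["unstructured"])

    def test_smooth_bands_nest(self, small_cohort, lattice36):
        spec = ModelSpec(fixed_terms=("fuel",), smooth_age=True,
                         spatial_structured=False,
                         spatial_unstructured=False)
        res, draws, design = fit_star(
            small_cohort.births, spec, lattice36, "stillbirth",
            McmcConfig(n_iter=300, burn_in=100, thin=2, seed=8))
        s = res.smooth
        assert np.all(s["lo95"] <= s["lo80"])
        assert np.all(s["lo80"] <= s["mean"])
        assert np.all(s["mean"] <= s["hi80"])
        assert np.all(s["hi80"] <= s["hi95"])

    def test_empty_age_grid_omits_smooth(self):
        res = summarize_posterior(self._const_draws(), age_grid=[])
        assert res.smooth is None
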