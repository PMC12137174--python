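"""Small-area model: structure assembly, likelihood, fitting, draws."""

import numpy as np
import pytest
import scipy.sparse as sp

from countyhale.observations import IndicatorObservations
from countyhale.sae_indicators import (
    FitConfig,
    _JointObjective,
    aggregate_expectation,
    build_effect_structure,
    draw_posterior,
    fit_indicator_model,
)
from countyhale.strata import AgeGrid, StrataCoords
from countyhale.synthetic_data import (
    ObservationDesign,
    SyntheticConfig,
    make_geography,
    simulate_indicator_observations,
    simulate_population,
    simulate_truth,
)
from tests.conftest import SMALL_AGES


class TestAggregateExpectation:
    def test_singleton_identity(self):
        assert aggregate_expectation([0.37], [123.0]) == pytest.approx(0.37)

    def test_hand_weighted_mean(self):
        assert aggregate_expectation(
            [0.2, 0.1], [1000.0, 3000.0]
        ) == pytest.approx(0.125)

    def test_convex_combination_bound(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, 6)
            w = rng.uniform(0.1, 5, 6)
            val = aggregate_expectation(p, w)
            assert p.min() - 1e-12 <= val <= p.max() + 1e-12

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            aggregate_expectation([0.5, 0.5], [0.0, 0.0])


class TestBuildEffectStructure:
    def test_icar_block_two_counties_one_edge(self):
        g = make_geography(2, 1, seed=0)
        strata = StrataCoords(
            counties=g.county_ids, races=("black", "white"),
            age_grid=AgeGrid(SMALL_AGES), years=(2009, 2010),
        )
        st = build_effect_structure(g, strata)
        county = next(b for b in st.blocks if b.name == "county")
        np.testing.assert_allclose(
            county.Q.toarray(), [[1, -1], [-1, 1]]
        )

    def test_rw1_block_three_years(self):
        g = make_geography(2, 1, seed=0)
        strata = StrataCoords(
            counties=g.county_ids, races=("black",),
            age_grid=AgeGrid(SMALL_AGES), years=(2009, 2010, 2011),
        )
        st = build_effect_structure(g, strata)
        year = next(b for b in st.blocks if b.name == "year")
        np.testing.assert_allclose(
            year.Q.toarray(), [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]
        )

    def test_all_blocks_row_sum_to_zero(self, small_geography, small_config):
        strata = small_config.strata_for(small_geography)
        st = build_effect_structure(small_geography, strata)
        for b in st.blocks:
            np.testing.assert_allclose(
                np.asarray(b.Q.sum(axis=1)).ravel(), 0.0, atol=1e-12
            )

    def test_unknown_county_rejected(self, small_geography, small_config):
        strata = StrataCoords(
            counties=("nowhere",), races=small_config.races,
            age_grid=small_config.age_grid, years=small_config.years,
        )
        with pytest.raises(ValueError, match="absent"):
            build_effect_structure(small_geography, strata)


def _manual_obs(strata, sets, weights, n, k, indicator="toy"):
    rows, cols, data = [], [], []
    for r, (ss, ww) in enumerate(zip(sets, weights)):
        for s, w in zip(ss, ww):
            rows.append(r)
            cols.append(s)
            data.append(w)
    M = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(sets), strata.n_strata)
    ).tocsr()
    return IndicatorObservations(
        indicator=indicator, strata=strata,
        n=np.asarray(n), k=np.asarray(k), membership=M,
    )


class TestLikelihood:
    def test_aggregated_likelihood_matches_direct_formula(self, rng):
        g = make_geography(3, 1, seed=0)
        strata = StrataCoords(
            counties=g.county_ids, races=("white",),
            age_grid=AgeGrid((0.0,)), years=(2009,),
        )
        st = build_effect_structure(g, strata, include_age_trend=False)
        obs = _manual_obs(
            strata, [[0, 1, 2], [1]], [[100.0, 300.0, 600.0], [1.0]],
            n=[50, 80], k=[20, 30],
        )
        joint = _JointObjective(obs, st)
        theta = rng.normal(0, 0.3, st.n_params)
        from scipy.special import expit

        p = expit(st.A @ theta)
        pbar0 = aggregate_expectation(p[[0, 1, 2]], [100, 300, 600])
        pbar1 = p[1]
        expected = (
            20 * np.log(pbar0) + 30 * np.log(1 - pbar0)
            + 30 * np.log(pbar1) + 50 * np.log(1 - pbar1)
        )
        Q = st.prior_precision(np.zeros(len(st.blocks)))
        got = joint.value(theta, Q) + 0.5 * theta @ Q @ theta
        assert got == pytest.approx(expected, rel=1e-12)

    def test_equal_weight_aggregation_equals_plain_average(self, rng):
        # an aggregated observation with equal weights uses the plain
        # average of its member prevalences
        g = make_geography(4, 1, seed=0)
        strata = StrataCoords(
            counties=g.county_ids, races=("white",),
            age_grid=AgeGrid((0.0,)), years=(2009,),
        )
        st = build_effect_structure(g, strata, include_age_trend=False)
        obs_any = _manual_obs(
            strata, [[0, 1, 2, 3]], [[7.0, 7.0, 7.0, 7.0]], n=[40], k=[10]
        )
        obs_unit = _manual_obs(
            strata, [[0, 1, 2, 3]], [[1.0, 1.0, 1.0, 1.0]], n=[40], k=[10]
        )
        theta = rng.normal(0, 0.5, st.n_params)
        Q = st.prior_precision(np.zeros(len(st.blocks)))
        assert _JointObjective(obs_any, st).value(
            theta, Q
        ) == pytest.approx(_JointObjective(obs_unit, st).value(theta, Q))


class TestFitIndicatorModel:
    def test_zero_variance_limit_recovers_pooled_proportion(self):
        # with precisions pinned huge and an intercept-only design every
        # stratum estimate collapses to the pooled k/n
        g = make_geography(4, 2, seed=0)
        strata = StrataCoords(
            counties=g.county_ids, races=("white",),
            age_grid=AgeGrid((0.0,)), years=(2009, 2010),
        )
        st = build_effect_structure(g, strata, include_age_trend=False)
        rng = np.random.default_rng(0)
        n = np.full(strata.n_strata, 500)
        p_true = 0.3
        k = rng.binomial(n, p_true)
        obs = _manual_obs(
            strata, [[i] for i in range(strata.n_strata)],
            [[1.0]] * strata.n_strata, n=n, k=k,
        )
        fit = fit_indicator_model(
            obs, st, fixed_log_tau=np.full(len(st.blocks), 12.0)
        )
        pooled = k.sum() / n.sum()
        from scipy.special import expit

        est = expit(st.A @ fit.theta)
        np.testing.assert_allclose(est, pooled, rtol=1e-3)

    def test_singleton_large_n_approaches_empirical(self, rng):
        cfg = SyntheticConfig(
            n_counties=9, n_states=3, n_races=2, n_causes=2,
            years=(2009, 2010), age_starts=(0.0, 45.0, 85.0),
        )
        g = make_geography(9, 3, seed=1)
        truth = simulate_truth(g, cfg, seed=21)
        pop = simulate_population(g, cfg, seed=21)
        obs = simulate_indicator_observations(
            truth, pop,
            ObservationDesign(n_per_obs=50_000, aggregate_fraction=0.0),
            seed=3,
        )["asthma"]
        strata = cfg.strata_for(g)
        st = build_effect_structure(g, strata, truth.covariates)
        fit = fit_indicator_model(obs, st)
        from scipy.special import expit

        est = expit(st.A @ fit.theta)
        emp = np.zeros(strata.n_strata)
        M = obs.row_normalized().tocsc()
        phat = obs.k / obs.n
        # every stratum has exactly one singleton observation here
        for j in range(strata.n_strata):
            sl = slice(M.indptr[j], M.indptr[j + 1])
            emp[j] = phat[M.indices[sl][0]] if sl.stop > sl.start else np.nan
        assert float(np.abs(est - emp).mean()) < 0.005

    def test_separable_data_warns(self):
        g = make_geography(2, 1, seed=0)
        strata = StrataCoords(
            counties=g.county_ids, races=("white",),
            age_grid=AgeGrid((0.0,)), years=(2009,),
        )
        st = build_effect_structure(g, strata, include_age_trend=False)
        obs = _manual_obs(
            strata, [[0], [1]], [[1.0], [1.0]], n=[10, 10], k=[0, 0]
        )
        with pytest.warns(UserWarning, match="separable"):
            fit_indicator_model(
                obs, st, fixed_log_tau=np.full(len(st.blocks), 4.0)
            )


@pytest.fixture(scope="module")
def fitted(small_geography, small_config, small_truth, small_population):
    obs = simulate_indicator_observations(
        small_truth, small_population,
        ObservationDesign(n_per_obs=1000, aggregate_fraction=0.25),
        seed=4,
    )["activity_limit"]
    strata = small_config.strata_for(small_geography)
    st = build_effect_structure(
        small_geography, strata, small_truth.covariates
    )
    fit = fit_indicator_model(obs, st)
    return fit, st


class TestDrawPosterior:
    def test_draw_count_and_range(self, fitted):
        fit, st = fitted
        cube = draw_posterior(fit, st, n_draws=1000, seed=5)
        assert cube.sizes["draw"] == 1000
        assert float(cube.min()) >= 0 and float(cube.max()) <= 1

    def test_draw_mean_near_mode_prediction(self, fitted):
        from scipy.special import expit

        fit, st = fitted
        cube = draw_posterior(fit, st, n_draws=1000, seed=6)
        mode_pred = st.strata.from_flat(expit(st.A @ fit.theta))
        dmean = cube.mean("draw")
        mc_se = cube.std("draw") / np.sqrt(1000)
        # second-order (Jensen) bias is tiny; 3 MC standard errors plus a
        # small curvature allowance covers it
        gap = np.abs(dmean - mode_pred)
        assert float((gap <= 3 * mc_se + 5e-4).mean()) > 0.99

    def test_deterministic_per_seed(self, fitted):
        fit, st = fitted
        a = draw_posterior(fit, st, n_draws=20, seed=7)
        b = draw_posterior(fit, st, n_draws=20, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_non_positive_definite_curvature_names_block(self, fitted):
        import dataclasses

        fit, st = fitted
        bad = fit.neg_hessian.copy()
        block = st.blocks[1]  # year block
        i = block.offset
        bad[i, i] = -1.0
        broken = dataclasses.replace(fit, neg_hessian=bad)
        with pytest.raises(ValueError, match="year"):
            draw_posterior(broken, st, n_draws=5, seed=8)


class TestAggregationConsistency:
    def test_state_level_agreement(self):
        # fitting on state-aggregated observations recovers the same
        # population-weighted state prevalences as fitting disaggregated
        cfg = SyntheticConfig(
            n_counties=12, n_states=3, n_races=2, n_causes=2,
            years=(2009, 2010), age_starts=(0.0, 45.0, 85.0),
        )
        g = make_geography(12, 3, seed=2)
        truth = simulate_truth(g, cfg, seed=31)
        pop = simulate_population(g, cfg, seed=31)
        strata = cfg.strata_for(g)
        cubes = {}
        for frac in (0.0, 1.0):
            obs = simulate_indicator_observations(
                truth, pop,
                ObservationDesign(n_per_obs=20_000, aggregate_fraction=frac),
                seed=8,
            )["activity_limit"]
            st = build_effect_structure(g, strata, truth.covariates)
            fit = fit_indicator_model(obs, st)
            cubes[frac] = draw_posterior(fit, st, n_draws=400, seed=9)
        codes = g.state_codes
        w = pop.values
        diffs = []
        for frac, cube in cubes.items():
            est = cube.mean("draw").values
            num = np.zeros((len(g.states),) + est.shape[2:])
            den = np.zeros_like(num)
            np.add.at(num, codes, (w * est).sum(axis=1))
            np.add.at(den, codes, w.sum(axis=1))
            cubes[frac] = num / den
        gap = np.abs(cubes[0.0] - cubes[1.0])
        assert float(gap.max()) < 0.015
        assert float(gap.mean()) < 0.005


class TestEducationAxis:
    def test_education_marginalized_out(self):
        cfg = SyntheticConfig(
            n_counties=4, n_states=2, n_races=2, n_causes=2,
            years=(2009, 2010), age_starts=(0.0, 45.0, 85.0),
            n_education=3,
        )
        g = make_geography(4, 2, seed=3)
        truth = simulate_truth(g, cfg, seed=41)
        pop = simulate_population(g, cfg, seed=41)
        obs = simulate_indicator_observations(
            truth, pop, ObservationDesign(n_per_obs=2000), seed=5
        )["asthma"]
        strata_edu = cfg.strata_for(g, education=True)
        assert "education" in strata_edu.dims
        st = build_effect_structure(g, strata_edu, truth.covariates)
        assert "education" in st.block_names
        fit = fit_indicator_model(obs, st)
        cube = draw_posterior(fit, st, n_draws=30, seed=6)
        # draws feed downstream stages without an education axis
        assert "education" not in cube.dims
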