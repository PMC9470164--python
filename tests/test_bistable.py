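"""Steady states, bistable ranges, stochastic corral ensembles."""

from dataclasses import replace

import numpy as np
import pytest

from memkin import (
    CompetitionModel,
    ReactionSimConfig,
    bistable_range,
    find_steady_states,
    geometry_sensing_scan,
    run_corral_ensemble,
    simulate_reaction,
)

K_WT = (0.001, 0.02, 0.3)
K_LIN_MATCHED = (0.001, 0.22, 0.0)    # same mean activity over [0, 1]


def sign_scan_roots(model, n=10_000):
    """Dense sign-change scan of g on [0, 1] (independent oracle)."""
    x = np.linspace(0.0, 1.0, n)
    g = model.g(x)
    roots = []
    for i in np.nonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]:
        roots.append(0.5 * (x[i] + x[i + 1]))
    for edge in (0.0, 1.0):
        if abs(model.g(edge)) < 1e-12:
            roots.append(edge)
    return sorted(roots)


class TestFindSteadyStates:
    def test_phosphatase_off_unique_stable_one(self):
        m = CompetitionModel(k_coeffs=K_WT, phosphatase_coeffs=(0.0, 0.0))
        states = find_steady_states(m)
        assert states == [(1.0, "stable")]

    def test_matched_linear_rates_degenerate_continuum(self):
        m = CompetitionModel(k_coeffs=(0.0, 0.3, 0.0),
                             phosphatase_coeffs=(0.0, 0.3))
        with pytest.raises(ValueError, match="degenerate"):
            find_steady_states(m)

    def test_bistable_parameter_set_three_roots(self):
        m = CompetitionModel(k_coeffs=K_WT, phosphatase_coeffs=(0.02, 0.1))
        states = find_steady_states(m)
        kinds = [k for _, k in states]
        assert kinds.count("stable") == 2 and kinds.count("unstable") == 1
        oracle = sign_scan_roots(m)
        np.testing.assert_allclose([x for x, _ in states], oracle,
                                   atol=2e-4)

    def test_agrees_with_sign_scan_on_random_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            m = CompetitionModel(
                k_coeffs=tuple(rng.uniform(0, 0.3, 3)),
                phosphatase_coeffs=tuple(rng.uniform(0, 0.3, 2)))
            states = find_steady_states(m)
            oracle = sign_scan_roots(m)
            interior = [x for x, _ in states if 1e-4 < x < 1 - 1e-4]
            oracle_int = [x for x in oracle if 1e-4 < x < 1 - 1e-4]
            assert len(interior) == len(oracle_int)
            np.testing.assert_allclose(interior, oracle_int, atol=2e-4)


class TestBistableRange:
    def test_second_order_contains_matched_linear(self):
        mwt = CompetitionModel(k_coeffs=K_WT,
                               phosphatase_coeffs=(0.0, 0.1))
        mlin = CompetitionModel(k_coeffs=K_LIN_MATCHED,
                                phosphatase_coeffs=(0.0, 0.1))
        lo_w, hi_w = bistable_range(mwt, "p0", 0.0, 1.0, n_scan=200)
        lo_l, hi_l = bistable_range(mlin, "p0", 0.0, 1.0, n_scan=200)
        assert np.isfinite(lo_w) and hi_w - lo_w > 0.01
        # the linear-feedback kinase has no deterministic bistable range
        # here (degree < 3 dynamics): strictly contained, possibly empty
        assert np.isnan(lo_l)

    def test_no_activity_empty_interval(self):
        m = CompetitionModel(k_coeffs=(0.0, 0.0, 0.0),
                             phosphatase_coeffs=(0.0, 0.1))
        lo, hi = bistable_range(m, "p0", 0.01, 1.0, n_scan=50)
        assert np.isnan(lo) and np.isnan(hi)

    def test_edges_bracket_saddle_node(self):
        m = CompetitionModel(k_coeffs=K_WT, phosphatase_coeffs=(0.0, 0.1))
        lo, hi = bistable_range(m, "p0", 0.0, 1.0, n_scan=200)
        eps = 1e-4
        inside = replace(m, phosphatase_coeffs=(hi - eps, 0.1))
        outside = replace(m, phosphatase_coeffs=(hi + eps, 0.1))
        n_in = sum(k == "stable" for _, k in find_steady_states(inside))
        n_out = sum(k == "stable" for _, k in find_steady_states(outside))
        assert n_in >= 2 and n_out < 2


@pytest.fixture(scope="module")
def small_corral_model():
    return CompetitionModel(k_coeffs=K_WT, phosphatase_coeffs=(0.0, 0.0),
                            corral_area=1.0, S_total=5000.0,
                            kinase_kon=0.02, kinase_solution_conc=10.0)


class TestCorralEnsembles:
    def test_zero_arrival_frozen_at_x0(self):
        m = CompetitionModel(k_coeffs=K_WT, phosphatase_coeffs=(0.0, 0.0),
                             corral_area=1.0, S_total=5000.0,
                             kinase_kon=0.0, x0=0.2)
        res = run_corral_ensemble(m, 5, seed=0, t_end=100.0)
        assert np.allclose(res.trajectories.x, 0.2, atol=1e-9)

    def test_trajectories_bounded_and_reproducible(self, small_corral_model):
        r1 = run_corral_ensemble(small_corral_model, 10, seed=4,
                                 t_end=400.0)
        r2 = run_corral_ensemble(small_corral_model, 10, seed=4,
                                 t_end=400.0)
        assert r1.trajectories.x.between(0.0, 1.0).all()
        np.testing.assert_array_equal(r1.trajectories.x, r2.trajectories.x)

    def test_large_area_collapses_onto_ode(self):
        # high-copy, large-corral ensemble mean matches the deterministic
        # trace in sup-norm
        m = CompetitionModel(k_coeffs=K_WT, phosphatase_coeffs=(0.0, 0.0),
                             corral_area=25.0, S_total=5000.0,
                             kinase_kon=0.2, kinase_solution_conc=50.0)
        det = simulate_reaction(m.to_reaction_config(0, 900.0, 2.0),
                                "deterministic")
        res = run_corral_ensemble(m, 60, seed=1, t_end=900.0, dt_record=2.0)
        mean_x = res.trajectories.groupby("t").x.mean().to_numpy()
        assert np.max(np.abs(mean_x - det.x)) < 0.03

    def test_dimerizing_kinase_more_heterogeneous_than_matched_linear(
            self, small_corral_model):
        # matching the weaker linear-feedback kinase requires more copies
        # (higher solution concentration), which suppresses its noise
        m_lin = replace(small_corral_model, k_coeffs=(0.0005, 0.08, 0.0),
                        kinase_solution_conc=40.0)
        r_wt = run_corral_ensemble(small_corral_model, 60, seed=7,
                                   t_end=2000.0, dt_record=5.0)
        r_lin = run_corral_ensemble(m_lin, 60, seed=7, t_end=2000.0,
                                    dt_record=5.0)
        assert r_wt.half_time_cv > 1.3 * r_lin.half_time_cv

    def test_completion_time_cv_decreases_with_area(self,
                                                    small_corral_model):
        big = replace(small_corral_model, corral_area=25.0)
        r_small = run_corral_ensemble(small_corral_model, 60, seed=2,
                                      t_end=2000.0, dt_record=5.0)
        r_big = run_corral_ensemble(big, 60, seed=2, t_end=2000.0,
                                    dt_record=5.0)
        assert r_small.half_time_cv > r_big.half_time_cv


class TestGeometrySensing:
    def test_outcome_fraction_declines_toward_deterministic(self):
        # phosphatase-favored model just outside the bistable range:
        # small corrals can stochastically flip to the product state
        m = CompetitionModel(k_coeffs=(0.01, 0.2, 3.0),
                             phosphatase_coeffs=(0.42, 1.0),
                             corral_area=1.0, S_total=5000.0,
                             kinase_kon=0.02, kinase_solution_conc=10.0)
        det = simulate_reaction(m.to_reaction_config(0, 600.0),
                                "deterministic")
        assert det.x[-1] < 0.5                      # deterministic outcome
        df = geometry_sensing_scan(m, [0.5, 2.0, 10.0], n_corrals=60,
                                   seed=3, t_end=600.0)
        assert df.fraction_product.iloc[0] > df.fraction_product.iloc[-1]
        assert df.fraction_product.iloc[-1] <= 0.05

    def test_granularity_guard(self):
        m = CompetitionModel(k_coeffs=K_WT, S_total=5000.0)
        with pytest.raises(ValueError, match="lipid"):
            geometry_sensing_scan(m, [0.001, 1.0], n_corrals=2, seed=0)

    def test_areas_must_increase(self):
        m = CompetitionModel(k_coeffs=K_WT, S_total=5000.0)
        with pytest.raises(ValueError, match="increasing"):
            geometry_sensing_scan(m, [1.0, 1.0], n_corrals=2, seed=0)
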