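"""Synthetic-data generator: statistical structure and invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from memkin import (
    ReactionSimConfig,
    SimConfig,
    simulate_brightness,
    simulate_isotherm,
    simulate_reaction,
    simulate_tracks,
)
from memkin.synthgen import hill


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        dict(frame_interval=0.0),
        dict(arrival_rate=-1.0),
        dict(dwell_taus=(0.0,), dwell_fractions=(1.0,)),
        dict(dwell_fractions=(0.6, 0.5), dwell_taus=(1.0, 2.0)),
        dict(maturation_prob=1.5),
        dict(bleach_tau=0.0),
        dict(diff_coeffs=()),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)

    def test_undersampling_warns(self):
        cfg = SimConfig(frame_interval=0.2, dwell_taus=(0.5,))
        assert any("undersampling" in w for w in cfg.validate())
        with pytest.warns(UserWarning, match="undersampling"):
            simulate_tracks(SimConfig(frame_interval=0.2, dwell_taus=(0.5,),
                                      arrival_rate=0.001, n_frames=20))


class TestSimulateTracks:
    def test_fixed_seed_bit_identical(self, base_sim_config):
        t1, g1 = simulate_tracks(base_sim_config)
        t2, g2 = simulate_tracks(base_sim_config)
        pd.testing.assert_frame_equal(t1, t2)
        assert g1["true_dwell"] == g2["true_dwell"]

    def test_zero_arrival_rate_empty_table(self):
        tracks, truth = simulate_tracks(SimConfig(arrival_rate=0.0))
        assert len(tracks) == 0 and truth["n_tracks"] == 0

    def test_mixture_mean_dwell_matches_closed_form(self):
        # 0.7 * 0.5 + 0.3 * 2.0 = 0.95 s, bleaching off; the generator's
        # frame discretization conditions on >= 1 observed frame, so the
        # closed-form target uses the per-component conditional mean
        # E[k dt | k >= 1] = dt / (1 - exp(-dt/tau)) mixed by the
        # probability each component is observed at all.
        dt = 0.05
        cfg = SimConfig(seed=11, frame_interval=dt, n_frames=3000,
                        field_size=(40.0, 40.0), arrival_rate=0.015,
                        dwell_taus=(0.5, 2.0), dwell_fractions=(0.7, 0.3),
                        bleach_tau=math.inf, maturation_prob=1.0)
        _, truth = simulate_tracks(cfg)
        arr = np.asarray(truth["arrival_time"])
        nfr = np.asarray(truth["n_frames_observed"])
        ok = (arr < cfg.n_frames * dt - 30.0) & (nfr > 0)   # no end-truncation
        sample_mean = float(np.mean(nfr[ok]) * dt)

        def cond_mean(tau):
            return dt / (1.0 - math.exp(-dt / tau))

        def p_obs(tau):                     # P(at least one frame sampled)
            return (tau / dt) * (1.0 - math.exp(-dt / tau))

        w = np.array([0.7 * p_obs(0.5), 0.3 * p_obs(2.0)])
        expected = float(
            (w @ [cond_mean(0.5), cond_mean(2.0)]) / w.sum())
        assert expected == pytest.approx(0.95, rel=0.06)    # sanity on oracle
        assert sample_mean == pytest.approx(expected, abs=0.03)

    def test_table1_condition_dwell_and_diffusion(self):
        # dilute-label conditions: tau 0.453 s with 26.7 s bleaching gives
        # an observed time constant 1/(1/0.453 + 1/26.7) = 0.4455 s
        dt = 0.05
        cfg = SimConfig(seed=5, frame_interval=dt, n_frames=3000,
                        arrival_rate=0.012, dwell_taus=(0.453,),
                        diff_coeffs=(0.148,), bleach_tau=26.7,
                        localization_sigma=0.0, maturation_prob=1.0)
        tracks, truth = simulate_tracks(cfg)
        arr = np.asarray(truth["arrival_time"])
        nfr = np.asarray(truth["n_frames_observed"])
        ok = (arr < cfg.n_frames * dt - 20.0) & (nfr > 0)
        tau_obs = 1.0 / (1.0 / 0.453 + 1.0 / 26.7)
        expected = dt / (1.0 - math.exp(-dt / tau_obs))
        assert float(np.mean(nfr[ok]) * dt) == pytest.approx(expected,
                                                             abs=0.02)
        # steps: mean r^2 / (4 dt) estimates D (no localization noise here)
        g = tracks.groupby("TRACK_ID")
        r2 = []
        for _, tr in g:
            r2.extend(np.diff(tr["POSITION_X"]) ** 2
                      + np.diff(tr["POSITION_Y"]) ** 2)
        assert np.mean(r2) / (4 * dt) == pytest.approx(0.148, rel=0.03)

    def test_dwell_survival_matches_generating_mixture(self):
        # KS distance between observed dwells (half-frame corrected) and
        # the generating mixture CDF stays below 0.02
        dt = 0.05
        cfg = SimConfig(seed=2, frame_interval=dt, n_frames=10_000,
                        arrival_rate=0.018, dwell_taus=(3.0, 9.0),
                        dwell_fractions=(0.6, 0.4), bleach_tau=math.inf,
                        maturation_prob=1.0, field_size=(30.0, 30.0))
        _, truth = simulate_tracks(cfg)
        arr = np.asarray(truth["arrival_time"])
        nfr = np.asarray(truth["n_frames_observed"])
        ok = (arr < cfg.n_frames * dt - 90.0) & (nfr > 0)
        dwells = nfr[ok] * dt - dt / 2.0
        assert dwells.size > 5000

        def cdf(t):
            return (0.6 * (1 - np.exp(-np.asarray(t) / 3.0))
                    + 0.4 * (1 - np.exp(-np.asarray(t) / 9.0)))

        ks = stats.kstest(dwells, cdf).statistic
        assert ks < 0.02

    def test_msd_per_frame_includes_localization_noise(self):
        dt = 0.05
        sigma = 0.03
        cfg = SimConfig(seed=9, frame_interval=dt, n_frames=2000,
                        arrival_rate=0.01, dwell_taus=(1.0,),
                        diff_coeffs=(0.1,), bleach_tau=math.inf,
                        localization_sigma=sigma, maturation_prob=1.0)
        tracks, _ = simulate_tracks(cfg)
        r2 = []
        for _, tr in tracks.groupby("TRACK_ID"):
            r2.extend(np.diff(tr["POSITION_X"]) ** 2
                      + np.diff(tr["POSITION_Y"]) ** 2)
        expected = 4 * 0.1 * dt + 4 * sigma ** 2
        assert np.mean(r2) == pytest.approx(expected, rel=0.03)


class TestSimulateBrightness:
    def test_fully_mature_noiseless_dimers_start_at_2x(self):
        cfg = SimConfig(seed=0, maturation_prob=1.0,
                        monomer_intensity_sd=0.0, n_frames=5)
        traces, _ = simulate_brightness(cfg, "dimer", 200,
                                        observe_bleaching=False)
        assert np.allclose(traces[:, 0], 2 * cfg.monomer_intensity_mean)

    def test_maturation_conditional_two_visible_fraction(self):
        # p^2 / (1 - (1-p)^2) = 0.6667 at p = 0.8
        cfg = SimConfig(seed=1, maturation_prob=0.8, n_frames=3)
        _, truth = simulate_brightness(cfg, "dimer", 100_000,
                                       observe_bleaching=False)
        nm = truth.n_mature.to_numpy()
        frac = (nm == 2).sum() / (nm >= 1).sum()
        assert frac == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_two_visible_survival_is_squared_exponential(self):
        # among initially two-visible dimers, both alive at t with
        # probability exp(-2 t / tau_bleach)
        cfg = SimConfig(seed=3, maturation_prob=1.0, bleach_tau=5.0,
                        n_frames=200, monomer_intensity_sd=0.0)
        traces, truth = simulate_brightness(cfg, "dimer", 20_000,
                                            observe_bleaching=True)
        t_check = 2.0
        i_check = int(t_check / cfg.frame_interval)
        both_alive = traces[:, i_check] > 1.5 * cfg.monomer_intensity_mean
        assert both_alive.mean() == pytest.approx(
            math.exp(-2 * t_check / 5.0), abs=0.01)

    def test_arrival_window_staggers_starts(self):
        cfg = SimConfig(seed=4, n_frames=100)
        traces, truth = simulate_brightness(cfg, "dimer", 500,
                                            arrival_window=3.0)
        assert np.isnan(traces[truth.arrival_time > 0.5, 0]).all()


class TestSimulateIsotherm:
    def test_half_saturation_identity(self):
        df = simulate_isotherm(100.0, 52.0, 2.0, [52.0], noise_cv=0.0)
        assert df.density.iloc[0] == pytest.approx(50.0)

    def test_saturation_limit(self):
        df = simulate_isotherm(100.0, 52.0, 1.0, [52e6], noise_cv=0.0)
        assert df.density.iloc[0] == pytest.approx(100.0, rel=1e-4)

    def test_hill_ratio_at_kd_and_half_kd(self):
        df = simulate_isotherm(100.0, 52.0, 2.0, [52.0, 26.0], noise_cv=0.0)
        assert df.density.iloc[0] / df.density.iloc[1] == pytest.approx(2.5)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_isotherm(100.0, -1.0, 2.0, [1.0])


class TestSimulateReaction:
    def test_constant_rate_closed_form(self):
        # k(x) = k0, no phosphatase: x(t) = 1 - exp(-k0 t)
        cfg = ReactionSimConfig(k_coeffs=(0.01, 0.0, 0.0),
                                phosphatase_coeffs=(0.0, 0.0), t_end=400.0)
        tr = simulate_reaction(cfg, "deterministic")
        assert np.allclose(tr.x, 1.0 - np.exp(-0.01 * tr.t), atol=1e-6)

    def test_no_phosphatase_monotone_to_one(self):
        cfg = ReactionSimConfig(k_coeffs=(0.005, 0.02, 0.1), t_end=2000.0)
        tr = simulate_reaction(cfg, "deterministic")
        assert np.all(np.diff(tr.x) >= -1e-12)
        assert tr.x[-1] == pytest.approx(1.0, abs=1e-4)

    def test_stochastic_granularity_guard(self):
        cfg = ReactionSimConfig(S0=50.0, corral_area=1.0)
        with pytest.raises(ValueError, match="100"):
            simulate_reaction(cfg, "stochastic")

    def test_stochastic_trace_bounded_and_reproducible(self):
        cfg = ReactionSimConfig(seed=7, S0=2000.0, corral_area=1.0,
                                t_end=300.0)
        tr1 = simulate_reaction(cfg, "stochastic")
        tr2 = simulate_reaction(cfg, "stochastic")
        assert np.array_equal(tr1.x, tr2.x)
        assert tr1.x.min() >= 0.0 and tr1.x.max() <= 1.0

    def test_small_corral_has_larger_halftime_variance(self):
        # ensemble comparison at two corral sizes, fixed seeds
        from memkin.feedback import half_time
        hts = {}
        for area in (1.0, 25.0):
            h = []
            for s in range(30):
                cfg = ReactionSimConfig(
                    seed=s, S0=2000.0, corral_area=area,
                    k_coeffs=(0.001, 0.02, 0.3), t_end=1500.0,
                    dt_record=5.0)
                tr = simulate_reaction(cfg, "stochastic")
                h.append(half_time(tr.t, tr.x))
            hts[area] = np.var(h)
        assert hts[1.0] > hts[25.0]

    def test_hill_function_basic(self):
        assert hill(52.0, 100.0, 52.0, 2.0) == pytest.approx(50.0)
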