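"""Generator-level checks: determinism, model consistency, frequencies."""

import numpy as np
import pytest

from termcycle.rendseq import compute_delta_S
from termcycle.simulate import (
    RendSimConfig,
    TraceSimConfig,
    simulate_bounded_walk,
    simulate_cohort,
    simulate_lifetimes,
    simulate_rendseq,
    simulate_slide_stick,
    simulate_trace,
)


class TestTraceSim:
    def test_seed_reproducibility(self):
        cfg = TraceSimConfig(seed=5, n_frames=120)
        tr1, gt1 = simulate_trace(cfg)
        tr2, gt2 = simulate_trace(cfg)
        np.testing.assert_array_equal(tr1.I_rnap, tr2.I_rnap)
        np.testing.assert_array_equal(gt1.z, gt2.z)
        assert gt1.lam == gt2.lam

    @pytest.mark.parametrize(
        "field,value",
        [
            ("p_retain", 1.3),
            ("p_antisense", -0.1),
            ("frame_interval", 0.0),
            ("noise_sd", -1.0),
            ("z_P", 2400.0),  # violates z_P < z_T
            ("I_P", float("nan")),
        ],
    )
    def test_invalid_config_rejected(self, field, value):
        cfg = TraceSimConfig(**{field: value})
        with pytest.raises(ValueError):
            simulate_trace(cfg)

    def test_elongation_follows_exponential_decay(self, noiseless_trace):
        """Noiseless elongation frames sit exactly on I_P e^-lt + I_mn."""
        cfg, trace, truth = noiseless_trace
        el = truth.states == "elongating"
        expected = (
            cfg.I_P * np.exp(-truth.lam * (trace.time[el] - truth.t_start)) + cfg.I_mn
        )
        np.testing.assert_allclose(trace.I_rnap[el], expected, rtol=1e-12)

    def test_residuals_are_exactly_the_injected_noise(self):
        """I_rnap minus the truth-channel mean reproduces the noise draw."""
        cfg = TraceSimConfig(seed=3, noise_sd=15.0, n_frames=200)
        trace, truth = simulate_trace(cfg)
        resid = trace.I_rnap - truth.mean_rnap
        assert abs(np.std(resid) - cfg.noise_sd) < 2.0
        # and with the noise turned off the residuals vanish identically
        trace0, truth0 = simulate_trace(
            TraceSimConfig(seed=3, noise_sd=0.0, n_frames=200)
        )
        np.testing.assert_array_equal(trace0.I_rnap, truth0.mean_rnap)

    def test_post_termination_intensity_constant_without_motion(self, noiseless_trace):
        """No noise, no sliding, full retention: flat post-termination record."""
        cfg, trace, truth = noiseless_trace
        post = (truth.states == "sliding") | (truth.states == "stuck")
        assert post.sum() > 10
        vals = trace.I_rnap[post]
        np.testing.assert_allclose(vals, vals[0], rtol=1e-12)
        # constant at the termination value of the decay
        I_T = cfg.I_P * np.exp(-truth.lam * (truth.t_T - truth.t_start)) + cfg.I_mn
        np.testing.assert_allclose(vals[0], I_T, rtol=1e-9)

    def test_antisense_reuses_the_molecules_rate(self):
        """The mirrored antisense profile carries the same lambda."""
        cfg = TraceSimConfig(
            seed=17,
            noise_sd=0.0,
            D_slide=0.0,
            p_retain=1.0,
            p_antisense=1.0,
            k_RNAP=0.0,
            k_PB=0.0,
            secondary_delay_mean=20.0,
            antisense_start_sd=0.0,
        )
        trace, truth = simulate_trace(cfg)
        assert truth.antisense
        asel = truth.states == "antisense"
        assert asel.sum() >= 10
        t = trace.time[asel]
        # mirrored segment: I(t) = I_P exp(-lam*(t_end - t)) + I_mn
        depth = (cfg.z_T - truth.z[asel]) * 0 + (truth.z[asel] - cfg.z_P)
        expected = cfg.I_P * np.exp(-(truth.lam / truth.r) * depth) + cfg.I_mn
        np.testing.assert_allclose(trace.I_rnap[asel], expected, rtol=1e-9)
        # log-slope of the rise equals +lambda exactly in the noiseless limit
        slope = np.polyfit(t, np.log(trace.I_rnap[asel] - cfg.I_mn), 1)[0]
        np.testing.assert_allclose(slope, truth.lam, rtol=1e-6)

    def test_retention_frequency_matches_config(self):
        cfg = TraceSimConfig(seed=11, n_frames=30, p_retain=0.87)
        _, truths = simulate_cohort(cfg, 500)
        frac = np.mean([gt.retained for gt in truths])
        se = np.sqrt(0.87 * 0.13 / 500)
        assert abs(frac - 0.87) <= 3 * se

    def test_antisense_frequency_matches_config(self):
        cfg = TraceSimConfig(seed=13, n_frames=30, p_retain=1.0, p_antisense=0.25)
        _, truths = simulate_cohort(cfg, 500)
        frac = np.mean([gt.antisense for gt in truths])
        se = np.sqrt(0.25 * 0.75 / 500)
        assert abs(frac - 0.25) <= 3 * se

    def test_probe_channel_tracks_sense_transcript(self, noiseless_trace):
        cfg, trace, truth = noiseless_trace
        on = trace.probe_present
        t_on = trace.time[on]
        assert t_on[0] >= truth.t_start + cfg.hybridization_lag
        assert t_on[-1] < truth.t_T
        assert np.all(trace.I_probe[on] > trace.I_probe[~on].max())

    def test_down_orientation_mirrors_intensity(self):
        up = TraceSimConfig(seed=21, noise_sd=0.0, lambda_cv=0.0, r_cv=0.0,
                            k_RNAP=0.0, k_PB=0.0, p_retain=1.0, p_antisense=0.0,
                            p_sense_reinit=0.0, D_slide=0.0)
        down = TraceSimConfig(**{**up.__dict__, "tether_orientation": "down"})
        tr_u, gt_u = simulate_trace(up)
        tr_d, gt_d = simulate_trace(down)
        el_u = gt_u.states == "elongating"
        el_d = gt_d.states == "elongating"
        # up decays toward the terminator, down rises toward it
        assert tr_u.I_rnap[el_u][-1] < tr_u.I_rnap[el_u][0]
        assert tr_d.I_rnap[el_d][-1] > tr_d.I_rnap[el_d][0]
        # peak intensity matches at the respective tether-proximal ends
        # (to within one frame of decay, since frames quantize t_T)
        np.testing.assert_allclose(tr_u.I_rnap[el_u][0], tr_d.I_rnap[el_d][-1],
                                   rtol=0.03)


class TestBoundedWalk:
    def test_zero_diffusion_is_constant(self):
        z = simulate_bounded_walk(0.0, 100.0, 1.0, 50, seed=1)
        np.testing.assert_array_equal(z, z[0])

    def test_free_limit_matches_2Dt(self):
        """L >> sqrt(2Dn dt): time-averaged MSD at lag tau ~ 2 D tau."""
        D, dt = 1.0e4, 1.0
        z = simulate_bounded_walk(D, 1e12, dt, 50_000, seed=2, z0=5e11)
        for k in (1, 5):
            d = z[k:] - z[:-k]
            msd = np.mean(d * d)
            # ~n/k independent displacements of variance 2Dk dt
            se = np.sqrt(2.0 / (d.size / k)) * 2 * D * k * dt
            assert abs(msd - 2 * D * k * dt) <= 4 * se

    def test_long_run_msd_plateau_is_L2_over_6(self):
        """Stationary uniform positions give MSD -> L^2/6 at long lags."""
        D, L, dt = 3.5e4, 500.0, 1.0
        z = simulate_bounded_walk(D, L, dt, 40_000, seed=3)
        lag = 200
        d = z[lag:] - z[:-lag]
        msd = np.mean(d * d)
        assert abs(msd - L**2 / 6) <= 0.2 * L**2 / 6

    def test_walk_stays_in_bounds(self):
        z = simulate_bounded_walk(3.5e4, 2500.0, 2.0, 5000, seed=4)
        assert z.min() >= 0 and z.max() <= 2500.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            simulate_bounded_walk(-1.0, 100.0, 1.0, 10)
        with pytest.raises(ValueError):
            simulate_bounded_walk(1.0, 100.0, 0.0, 10)


class TestSlideStick:
    def test_stuck_frames_do_not_move(self):
        z, sliding = simulate_slide_stick(3.5e4, 2000, seed=5)
        stuck_steps = np.diff(z)[~sliding[1:]]
        np.testing.assert_array_equal(stuck_steps, 0.0)

    def test_reproducible(self):
        z1, s1 = simulate_slide_stick(1e4, 500, seed=6)
        z2, s2 = simulate_slide_stick(1e4, 500, seed=6)
        np.testing.assert_array_equal(z1, z2)
        np.testing.assert_array_equal(s1, s2)


class TestLifetimes:
    def test_uncensored_mean_converges(self):
        durations, censored = simulate_lifetimes(1 / 500, 0.0, 1e9, 20_000, seed=7)
        assert not censored.any()
        assert abs(durations.mean() - 500) < 3 * 500 / np.sqrt(20_000)

    def test_censoring_binds_at_t_censor(self):
        durations, censored = simulate_lifetimes(1 / 1140, 1 / 600, 2000, 500, seed=8)
        assert censored.any() and (~censored).any()
        np.testing.assert_array_equal(durations[censored], 2000.0)
        assert durations[~censored].max() < 2000.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_lifetimes(1.0, 0.0, 0.0, 10)
        with pytest.raises(ValueError):
            simulate_lifetimes(0.0, 0.0, 100.0, 10)


class TestRendSim:
    def test_zero_background_single_spike(self):
        cfg = RendSimConfig(
            genome_length=1000,
            terminators=[(500, "+")],
            background_rate=0.0,
            term_peak_height=8,
            fraction_terminators_with_antisense=0.0,
            seed=1,
        )
        tracks, truth = simulate_rendseq(cfg)
        k, delta, pos = compute_delta_S(tracks, 500, "+")
        assert (k, delta, pos) == (8, 3.0, 500)
        assert tracks.five_minus.sum() == 0

    def test_no_antisense_fraction_plants_nothing(self):
        cfg = RendSimConfig(
            genome_length=5000,
            terminators=[(1000, "+"), (3000, "-")],
            background_rate=0.0,
            fraction_terminators_with_antisense=0.0,
            seed=2,
        )
        tracks, truth = simulate_rendseq(cfg)
        assert not truth["has_antisense"].any()
        assert tracks.five_plus.sum() == 0 and tracks.five_minus.sum() == 0

    def test_fixed_offsets_oriented_by_strand(self):
        cfg = RendSimConfig(
            genome_length=10_000,
            terminators=[(2000, "+"), (7000, "-")],
            background_rate=0.0,
            antisense_offset_dist=("fixed", 100),
            fraction_terminators_with_antisense=1.0,
            antisense_peak_height=16,
            seed=3,
        )
        tracks, truth = simulate_rendseq(cfg)
        # '+' terminator: antisense 5' peak on '-' strand 100 nt downstream
        assert tracks.five_minus[2100] == 16
        # '-' terminator: downstream means decreasing coordinate
        assert tracks.five_plus[6900] == 16

    def test_reproducible(self):
        cfg = RendSimConfig(
            genome_length=2000, terminators=[(800, "+")], seed=9
        )
        t1, _ = simulate_rendseq(cfg)
        t2, _ = simulate_rendseq(cfg)
        np.testing.assert_array_equal(t1.three_plus, t2.three_plus)
        np.testing.assert_array_equal(t1.five_minus, t2.five_minus)
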