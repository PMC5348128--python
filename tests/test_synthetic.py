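"""Generator correctness: Brownian statistics, rendering photometry,
photobleaching, WLC mechanics and flow images, all against closed forms
or the emitted ground truth."""

import numpy as np
import pytest

from kymoquant.config import ExperimentConfig, OpticsConfig
from kymoquant.synthetic import (GroundTruth, make_static_cluster_truth,
                                 render_kymograph, sample_cluster_sizes,
                                 simulate_compaction_experiment,
                                 simulate_flow_image, simulate_force_distance,
                                 simulate_trajectory)
from kymoquant.wlc import wlc_extension, wlc_force


class TestTrajectory:
    def test_zero_diffusion_gives_constant_position(self):
        cfg = ExperimentConfig(diffusion_constant_true=0.0)
        x = simulate_trajectory(cfg, 16.0, 5.0, seed=0, x0=3.0)
        assert np.all(x == 3.0)

    def test_step_variance_matches_brownian_closed_form(self):
        # var of increments = 2 D dt, checked at 1e4 steps within 5%
        cfg = ExperimentConfig(diffusion_constant_true=0.16)
        dt = 0.02
        x = simulate_trajectory(cfg, 1e6, 1e4 * dt, seed=1, dt=dt, x0=5e5)
        v = np.diff(x).var()
        assert v == pytest.approx(2 * 0.16 * dt, rel=0.05)

    def test_reflecting_boundaries_keep_path_inside(self):
        cfg = ExperimentConfig(diffusion_constant_true=5.0)
        x = simulate_trajectory(cfg, 0.5, 20.0, seed=2, x0=0.49)
        assert np.all((x >= 0) & (x <= 0.5))

    def test_msd_slope_matches_2d_at_long_traces(self):
        cfg = ExperimentConfig(diffusion_constant_true=0.16)
        dt = 0.02
        x = simulate_trajectory(cfg, 1e6, 1e5 * dt, seed=3, dt=dt, x0=5e5)
        lag = 5
        d = x[lag:] - x[:-lag]
        assert np.mean(d * d) == pytest.approx(2 * 0.16 * lag * dt, rel=0.05)

    def test_reproducible_given_seed(self):
        cfg = ExperimentConfig()
        a = simulate_trajectory(cfg, 16.0, 2.0, seed=9)
        b = simulate_trajectory(cfg, 16.0, 2.0, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_invalid_inputs_rejected(self):
        cfg = ExperimentConfig()
        with pytest.raises(ValueError):
            simulate_trajectory(cfg, 16.0, -1.0, seed=0)
        with pytest.raises(ValueError):
            simulate_trajectory(cfg, 0.0, 1.0, seed=0)
        with pytest.raises(ValueError):
            ExperimentConfig(diffusion_constant_true=-0.1)


class TestCompactionScenario:
    def test_conversion_probability_zero_keeps_all_diffusive(self):
        cfg = ExperimentConfig(n_tetramers=20, cluster_conversion_probability=0.0,
                               extra_phase_time=1.0, seed=4)
        truth, _ = simulate_compaction_experiment(cfg)
        assert np.all(truth.cluster_of == -1)

    def test_conversion_probability_one_clusters_everyone(self):
        cfg = ExperimentConfig(n_tetramers=150, cluster_conversion_probability=1.0,
                               extra_phase_time=1.0, seed=5)
        truth, sep = simulate_compaction_experiment(cfg)
        assert np.all(truth.cluster_of >= 0)
        # cluster members are pinned after the hold starts
        hold_line = int(np.ceil(truth.phase_times["hold_start"] / 0.02)) + 1
        for cid, anchor in truth.cluster_positions.items():
            members = np.flatnonzero(truth.cluster_of == cid)
            frac = truth.positions[members, hold_line] / sep[hold_line]
            later = truth.positions[members, -1] / sep[-1]
            np.testing.assert_allclose(later, frac, atol=1e-9)

    def test_positions_always_within_bead_separation(self):
        cfg = ExperimentConfig(n_tetramers=30, seed=6, extra_phase_time=1.0)
        truth, sep = simulate_compaction_experiment(cfg)
        assert np.all(truth.positions >= 0)
        assert np.all(truth.positions <= sep[None, :] + 1e-9)

    def test_cluster_size_distribution_matches_configuration(self, rng):
        sizes = sample_cluster_sizes(rng, 4000)
        assert sizes.min() >= 20 and sizes.max() <= 160
        assert sizes.mean() == pytest.approx(67.0, rel=0.03)

    def test_ground_truth_json_round_trip(self):
        cfg = ExperimentConfig(n_tetramers=5, seed=7, extra_phase_time=0.5)
        truth, _ = simulate_compaction_experiment(cfg)
        back = GroundTruth.from_json(truth.to_json())
        np.testing.assert_allclose(back.positions, truth.positions)
        np.testing.assert_array_equal(back.cluster_of, truth.cluster_of)


class TestRenderer:
    def test_no_fluorophores_no_background_gives_zero_image(self):
        optics = OpticsConfig(background_rate=0.0)
        truth = GroundTruth(times=np.arange(50) * 0.02,
                            positions=np.empty((0, 50)),
                            separation=np.full(50, 4.0),
                            cluster_of=np.empty(0, dtype=int))
        kymo = render_kymograph(truth, optics, seed=0)
        assert kymo.counts.shape == (50, int(np.ceil(4.0 / 0.075)))
        assert np.all(kymo.counts == 0)

    def test_single_fluorophore_amplitude_is_calibration_value(self):
        # mean fitted amplitude over many noisy lines ~ 1.5 photons
        from kymoquant.photometry import fit_profile
        optics = OpticsConfig(bleach_rate_at_reference=0.0, background_rate=0.0)
        n = 4000
        truth = GroundTruth(times=np.arange(n) * 0.02,
                            positions=np.full((1, n), 2.0),
                            separation=np.full(n, 4.0),
                            cluster_of=np.array([-1]), fluors_per_tetramer=1)
        kymo = render_kymograph(truth, optics, seed=11)
        prof = kymo.counts.mean(axis=0)
        fit = fit_profile(prof, kymo.pixel_centers_um)
        assert fit.amplitude == pytest.approx(1.5, rel=0.05)

    def test_photon_conservation_in_expectation(self):
        # mean rendered counts over seeds equals the analytic signal field
        optics = OpticsConfig(bleach_rate_at_reference=0.0, background_rate=0.3)
        truth = make_static_cluster_truth([10], tether_length=4.0, duration=1.0,
                                          optics=optics, seed=0)
        n_lines = truth.times.size
        n_pixels = int(np.ceil(4.0 / 0.075))
        xc = (np.arange(n_pixels) + 0.5) * 0.075
        anchor = truth.positions[0, 0]
        per_line = 10 * 4 * 1.5 * np.exp(-0.5 * ((xc - anchor) / 0.1) ** 2).sum()
        expected = n_lines * (per_line + 0.3 * n_pixels)
        sums = [render_kymograph(truth, optics, seed=s).counts.sum()
                for s in range(30)]
        assert np.mean(sums) == pytest.approx(expected, rel=0.01)

    def test_bleaching_survival_follows_exponential(self):
        k = 0.2
        optics = OpticsConfig(bleach_rate_at_reference=k)
        n = 301
        truth = make_static_cluster_truth([200], tether_length=4.0, duration=6.0,
                                          optics=optics, seed=1)
        render_kymograph(truth, optics, seed=1)
        bt = np.asarray(truth.bleach_times).ravel()
        t = 3.0
        surv = np.mean(bt > t)
        p = np.exp(-k * t)
        sem = np.sqrt(p * (1 - p) / bt.size)
        assert abs(surv - p) < 4 * sem

    def test_integrated_intensity_decays_at_the_bleach_rate(self):
        from scipy.optimize import curve_fit
        k = 0.05
        optics = OpticsConfig(bleach_rate_at_reference=k, background_rate=0.0)
        truth = make_static_cluster_truth([300], tether_length=4.0, duration=40.0,
                                          optics=optics, seed=2)
        kymo = render_kymograph(truth, optics, seed=2)
        trace = kymo.total_intensity()
        popt, _ = curve_fit(lambda t, i0, kk: i0 * np.exp(-kk * t),
                            kymo.times, trace, p0=[trace[0], 0.01])
        assert popt[1] == pytest.approx(k, rel=0.1)

    def test_rendering_deterministic_given_seed(self):
        optics = OpticsConfig()
        truth = make_static_cluster_truth([30], duration=1.0, optics=optics, seed=3)
        truth2 = make_static_cluster_truth([30], duration=1.0, optics=optics, seed=3)
        a = render_kymograph(truth, optics, seed=4)
        b = render_kymograph(truth2, optics, seed=4)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestForceDistance:
    def test_no_sequestration_equals_free_curve(self, experiment):
        a = simulate_force_distance(experiment, 0.0, 0, force_noise_sd=0.0)
        b = simulate_force_distance(experiment, 0.0, 0, force_noise_sd=0.0)
        np.testing.assert_allclose(a.samples, b.samples)
        assert a.label == "free"

    def test_free_lambda_dna_near_16um_at_5pn(self, experiment):
        ext = wlc_extension(5.0, experiment.contour_length, experiment.persistence_length)
        assert abs(ext - 16.0) < 1.0

    def test_wlc_force_increasing_in_extension(self):
        x = np.linspace(1.0, 16.0, 200)
        f = wlc_force(x, 16.4, 50.0)
        assert np.all(np.diff(f) > 0)

    def test_compacted_force_strictly_above_free(self, experiment):
        free = simulate_force_distance(experiment, 0.0, 0, force_noise_sd=0.0)
        comp = simulate_force_distance(experiment, 1.0, 3, force_noise_sd=0.0)
        f_free = wlc_force(comp.distance, experiment.contour_length, 50.0)
        assert np.all(comp.force > f_free)

    def test_excess_sequestration_rejected(self, experiment):
        with pytest.raises(ValueError):
            simulate_force_distance(experiment, 20.0, 0)


class TestFlowImage:
    def test_empty_segments_give_background_only(self, optics):
        img, truth = simulate_flow_image(2, [], optics, seed=0)
        assert truth["dye_positions_um"].shape == (0, 2)
        # Poisson background only: mean close to background rate
        assert img.mean() == pytest.approx(optics.background_rate, rel=0.1)

    def test_planted_density_matches_footprint(self, optics):
        seg = ((0.5, 1.0), (4.5, 1.0))
        _, truth = simulate_flow_image(2, [seg], optics, footprint_nm=3.6,
                                       image_size_um=(5.0, 2.0), seed=1)
        assert truth["n_tetramers_per_segment"][0] == round(4000 / 3.6)

    def test_out_of_bounds_segment_rejected(self, optics):
        with pytest.raises(ValueError):
            simulate_flow_image(2, [((0.0, 0.0), (99.0, 0.0))], optics,
                                image_size_um=(5.0, 2.0), seed=0)
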