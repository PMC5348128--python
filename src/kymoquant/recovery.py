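"""Ground-truth recovery experiments on the synthetic generator.

Each function generates data at the study's stated conditions, runs the
corresponding estimator exactly as it would run on real data, and returns
the recovered quantity together with the problem size.  They serve as the
package's benchmark suite: if an estimator is biased, it shows up here.
"""

from __future__ import annotations

import numpy as np

from .compaction import (FootprintInputs, flow_boxes_along_segment,
                         footprint_from_box, footprint_from_compaction,
                         length_at_force)
from .config import ExperimentConfig, OpticsConfig
from .diffusion import fit_diffusion, msd
from .photometry import (Calibration, bleach_step_amplitudes,
                         calibrate_single_fluorophore, estimate_bleach_rate,
                         fit_power_exponent, measure_clusters)
from .synthetic import (make_cascade_truth, make_static_cluster_truth,
                        render_kymograph, sample_cluster_sizes,
                        simulate_flow_image, simulate_force_distance,
                        simulate_trajectory)

__all__ = [
    "recover_step_calibration",
    "recover_cluster_mean",
    "recover_diffusion_constant",
    "recover_compaction_footprint",
    "recover_flow_footprint",
    "recover_bleach_rate",
    "recover_power_exponent",
]

# calibration cascades: rate chosen so a 4-fluorophore cascade completes
# within a ~1200-line trace (step size is independent of the rate)
CASCADE_BLEACH_RATE = 0.1  # 1/s


def recover_step_calibration(n_kymographs: int = 10, seed: int = 0) -> dict:
    """Photobleaching-step calibration on immobile 4-fluorophore emitters.

    Renders ``n_kymographs`` Poisson-noised bleach cascades at the nominal
    single-fluorophore yield, detects steps and averages their amplitudes.
    """
    rng = np.random.default_rng(seed)
    optics = OpticsConfig(bleach_rate_at_reference=CASCADE_BLEACH_RATE)
    steps = []
    for _ in range(n_kymographs):
        truth = make_cascade_truth(optics=optics)
        kymo = render_kymograph(truth, optics, seed=rng)
        steps.extend(bleach_step_amplitudes(kymo))
    cal = calibrate_single_fluorophore(steps)
    return {"photons_per_fluor": cal.photons_per_fluor,
            "photons_per_tetramer": cal.photons_per_tetramer,
            "n_steps": cal.n_steps_used}


def recover_cluster_mean(n_clusters: int = 50, seed: int = 0,
                         clusters_per_kymo: int = 5) -> dict:
    """Bleaching-corrected cluster stoichiometry on synthetic static clusters.

    True sizes are drawn from the configured distribution (mean 67, range
    20–160 tetramers); each cluster is measured by Gaussian-amplitude
    photometry with the I_total-ratio bleaching correction.
    """
    rng = np.random.default_rng(seed)
    exp = ExperimentConfig()
    optics = OpticsConfig()
    cal = Calibration(photons_per_fluor=optics.photons_per_fluor_per_line,
                      labels_per_tetramer=exp.fluors_per_tetramer)
    est, true = [], []
    while len(est) < n_clusters:
        sizes = sample_cluster_sizes(rng, clusters_per_kymo,
                                     exp.cluster_size_mean, exp.cluster_size_range)
        truth = make_static_cluster_truth(sizes, tether_length=exp.extended_separation,
                                          duration=6.0, optics=optics,
                                          fluors_per_tetramer=exp.fluors_per_tetramer,
                                          seed=rng)
        kymo = render_kymograph(truth, optics, seed=rng)
        found = measure_clusters(kymo, row=0, cal=cal)
        est.extend(e.tetramers for e in found)
        true.extend(sizes.tolist())
    return {"mean_tetramers": float(np.mean(est)),
            "true_mean_tetramers": float(np.mean(true)),
            "configured_mean": exp.cluster_size_mean,
            "n_clusters": len(est)}


def recover_diffusion_constant(n_trajectories: int = 8, seed: int = 0,
                               duration: float = 12.0,
                               d_true: float = 0.16) -> dict:
    """MSD diffusion-constant recovery on simulated sliding trajectories."""
    rng = np.random.default_rng(seed)
    cfg = ExperimentConfig(diffusion_constant_true=d_true)
    optics = OpticsConfig()
    ds = []
    for _ in range(n_trajectories):
        x = simulate_trajectory(cfg, cfg.extended_separation, duration,
                                seed=rng, dt=optics.line_period)
        curve = msd(x, dt=optics.line_period, max_lag=12)
        d, _, flag = fit_diffusion(curve)
        if flag == "ok":
            ds.append(d)
    return {"D_mean": float(np.mean(ds)), "D_sd": float(np.std(ds)),
            "D_true": d_true, "n": len(ds)}


def recover_compaction_footprint(seed: int = 0, planted_footprint_nm: float = 2.7,
                                 n_molecules: int = 3) -> dict:
    """Force–distance footprint recovery.

    Each molecule carries clusters of the configured size distribution;
    every bound tetramer sequesters twice the planted per-domain footprint
    of contour length, plus one persistence-length loop allowance per
    cluster.  Lengths are read at 25 pN and the compaction formula applied.
    """
    rng = np.random.default_rng(seed)
    exp = ExperimentConfig()
    fps = []
    for _ in range(n_molecules):
        n_cl = int(rng.integers(2, 5))
        sizes = sample_cluster_sizes(rng, n_cl, exp.cluster_size_mean,
                                     exp.cluster_size_range)
        n_tet = int(sizes.sum())
        seq_um = 2.0 * planted_footprint_nm * n_tet * 1e-3
        free = simulate_force_distance(exp, 0.0, 0, seed=rng)
        comp = simulate_force_distance(exp, seq_um, n_cl, seed=rng)
        inp = FootprintInputs(length_free=length_at_force(free),
                              length_bound=length_at_force(comp),
                              n_clusters=n_cl, n_tetramers_total=n_tet,
                              persistence_length=exp.persistence_length)
        f, ok = footprint_from_compaction(inp)
        if ok:
            fps.append(f)
    return {"footprint_nm": float(np.mean(fps)), "sd_nm": float(np.std(fps)),
            "planted_nm": planted_footprint_nm, "n_molecules": len(fps)}


def recover_flow_footprint(seed: int = 0, planted_footprint_nm: float = 3.6,
                           min_boxes: int = 13) -> dict:
    """Flow-box footprint recovery on synthetic bridged-DNA images."""
    rng = np.random.default_rng(seed)
    optics = OpticsConfig()
    seg = ((0.5, 1.2), (5.5, 1.2))
    fps = []
    while len(fps) < min_boxes:
        img, _ = simulate_flow_image(2, [seg], optics,
                                     footprint_nm=planted_footprint_nm,
                                     image_size_um=(6.0, 3.2), seed=rng)
        for b in flow_boxes_along_segment(img, optics, seg):
            _, fp, ok = footprint_from_box(b)
            if ok:
                fps.append(fp)
    return {"footprint_nm": float(np.mean(fps)), "sd_nm": float(np.std(fps)),
            "planted_nm": planted_footprint_nm, "n_boxes": len(fps)}


def recover_bleach_rate(seed: int = 0, rate: float = 5e-5, n_kymographs: int = 5) -> dict:
    """Exponential bleach-rate recovery at the nominal (slow) rate.

    The decay is sampled with a 10 s line period so ~40% of the signal is
    lost across a 1000-line trace (temporally binned acquisition of a slow
    process).
    """
    rng = np.random.default_rng(seed)
    optics = OpticsConfig(line_period=10.0, bleach_rate_at_reference=rate)
    rates = []
    for _ in range(n_kymographs):
        truth = make_static_cluster_truth([67], duration=10000.0, optics=optics, seed=rng)
        kymo = render_kymograph(truth, optics, seed=rng)
        k, flag = estimate_bleach_rate(kymo)
        if flag == "ok":
            rates.append(k)
    return {"rate_per_s": float(np.mean(rates)), "true_rate_per_s": rate,
            "n": len(rates)}


def recover_power_exponent(seed: int = 0, powers=(2.9, 4.5, 6.4),
                           n_kymographs: int = 4) -> dict:
    """Bleach-rate vs laser-power exponent recovery (quadratic law).

    The per-kymograph rate estimate carries the binomial noise of a finite
    fluorophore pool, so each power level averages ``n_kymographs``
    independent molecules.
    """
    rng = np.random.default_rng(seed)
    rates = []
    for p in powers:
        optics = OpticsConfig(line_period=2.0, laser_power=p,
                              bleach_rate_at_reference=0.01)
        ks = []
        for _ in range(n_kymographs):
            truth = make_static_cluster_truth([150], duration=400.0, optics=optics,
                                              seed=rng)
            kymo = render_kymograph(truth, optics, seed=rng)
            k, flag = estimate_bleach_rate(kymo)
            if flag == "ok":
                ks.append(k)
        rates.append(float(np.mean(ks)))
    return {"exponent": fit_power_exponent(rates, powers), "powers": list(powers)}
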