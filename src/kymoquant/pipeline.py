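"""End-to-end analysis pipeline: simulate → track → classify → photometry →
diffusion → footprints, with provenance, logging and deterministic seeding."""

from __future__ import annotations

import logging
import time
from dataclasses import asdict

import numpy as np

from . import __version__
from .compaction import (FootprintInputs, flow_boxes_along_segment,
                         footprint_from_box, footprint_from_compaction,
                         length_at_force)
from .config import OpticsConfig
from .diffusion import fit_diffusion, msd
from .io import ResultBundle, RunConfig
from .photometry import Calibration, measure_clusters
from .synthetic import (make_static_cluster_truth, render_kymograph,
                        sample_cluster_sizes, simulate_compaction_experiment,
                        simulate_flow_image, simulate_force_distance)
from .tracking import classify_trajectory, track, trajectory_stoichiometry

log = logging.getLogger("kymoquant")


def run_pipeline(cfg: RunConfig) -> ResultBundle:
    """Run the full synthetic-experiment analysis and return a validated bundle.

    Deterministic given (config, seed): all sub-stage seeds are spawned
    from the configured seed.
    """
    t_start = time.time()
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)
    optics = cfg.optics_config()
    exp = cfg.experiment_config()
    cal = Calibration(photons_per_fluor=cfg.photons_per_fluor,
                      labels_per_tetramer=exp.fluors_per_tetramer)
    timings = {}

    # --- diffusion: track mobile tetramers in the extended phase
    t0 = time.time()
    diff_exp = type(exp)(**{**_as_dict(exp), "n_tetramers": 3,
                            "cluster_conversion_probability": 0.0,
                            "extra_phase_time": 12.0, "seed": int(seeds[0])})
    truth_d, _ = simulate_compaction_experiment(diff_exp, optics)
    n_ext = int(truth_d.phase_times["extended_end"] / optics.line_period)
    truth_d.positions = truth_d.positions[:, :n_ext]
    truth_d.times = truth_d.times[:n_ext]
    truth_d.separation = truth_d.separation[:n_ext]
    kymo_d = render_kymograph(truth_d, optics, seed=int(seeds[1]))
    trajectories = track(kymo_d, detection_threshold=cfg.detection_threshold)
    d_vals, stoich = [], []
    for tr in trajectories:
        if classify_trajectory(tr, pixel_size_nm=optics.pixel_size_d) != "diffusive":
            continue
        runs = _uniform_runs(tr, min_len=cfg.msd_fit_range[1] + 5)
        for lines, pos in runs:
            curve = msd(pos, dt=optics.line_period, max_lag=cfg.msd_fit_range[1] + 2)
            d, _, flag = fit_diffusion(curve, cfg.msd_fit_range)
            if flag == "ok":
                d_vals.append(d)
        stoich.append(trajectory_stoichiometry(tr, cal))
    timings["diffusion_s"] = time.time() - t0
    log.info("diffusion: %d trajectories, %d MSD fits", len(trajectories), len(d_vals))

    # --- cluster photometry on static-cluster kymographs
    t0 = time.time()
    sizes = sample_cluster_sizes(int(seeds[2]), 5, exp.cluster_size_mean,
                                 exp.cluster_size_range)
    truth_c = make_static_cluster_truth(sizes, tether_length=exp.extended_separation,
                                        duration=8.0, optics=optics,
                                        fluors_per_tetramer=exp.fluors_per_tetramer,
                                        seed=int(seeds[3]))
    kymo_c = render_kymograph(truth_c, optics, seed=int(seeds[4]))
    clusters = measure_clusters(kymo_c, row=0, cal=cal)
    cluster_sizes = [c.tetramers for c in clusters]
    timings["clusters_s"] = time.time() - t0

    # --- compaction footprint from force-distance curves
    t0 = time.time()
    n_tet = int(np.sum(sizes))
    n_clusters = len(sizes)
    seq_um = (2.0 * cfg.planted_footprint_nm * n_tet) * 1e-3
    free = simulate_force_distance(exp, 0.0, 0, seed=int(seeds[5]))
    comp = simulate_force_distance(exp, seq_um, n_clusters, seed=int(seeds[5]) + 1)
    inp = FootprintInputs(length_free=length_at_force(free), length_bound=length_at_force(comp),
                          n_clusters=n_clusters, n_tetramers_total=n_tet,
                          persistence_length=exp.persistence_length)
    fp_comp, fp_valid = footprint_from_compaction(inp)
    timings["footprint_fd_s"] = time.time() - t0

    # --- flow-box footprint
    t0 = time.time()
    seg = ((0.5, 1.2), (5.5, 1.2))
    img, _ = simulate_flow_image(2, [seg], optics, footprint_nm=cfg.flow_footprint_nm,
                                 labels_per_tetramer=exp.fluors_per_tetramer,
                                 image_size_um=(6.0, 3.2), seed=int(seeds[6]))
    boxes = flow_boxes_along_segment(img, optics, seg)
    fps = [fp for _, fp, ok in (footprint_from_box(b, exp.fluors_per_tetramer) for b in boxes) if ok]
    timings["footprint_flow_s"] = time.time() - t0

    bundle = ResultBundle(
        seed=cfg.seed,
        parameters={"optics": asdict(optics), "experiment": _as_dict(exp),
                    "photons_per_fluor": cfg.photons_per_fluor},
        cluster_sizes_tetramers=[float(s) for s in cluster_sizes],
        cluster_size_mean_tetramers=float(np.mean(cluster_sizes)) if cluster_sizes else None,
        diffusion_constant_um2_per_s=float(np.mean(d_vals)) if d_vals else None,
        diffusion_constant_sd=float(np.std(d_vals)) if d_vals else None,
        n_diffusive_trajectories=len(d_vals),
        stoichiometry_dyes_per_trajectory=float(np.mean(stoich)) if stoich else None,
        footprint_compaction_nm=fp_comp if fp_valid else None,
        footprint_flow_box_nm=float(np.mean(fps)) if fps else None,
        provenance={"package": "kymoquant", "version": __version__,
                    "timings_s": timings, "total_s": time.time() - t_start},
    )
    return bundle


def _as_dict(exp) -> dict:
    d = asdict(exp)
    d["cluster_size_range"] = tuple(d["cluster_size_range"])
    return d


def _uniform_runs(tr, min_len: int):
    """Split a trajectory into gap-free (uniformly sampled) runs."""
    breaks = np.flatnonzero(np.diff(tr.lines) != 1)
    starts = [0, *(breaks + 1)]
    ends = [*(breaks + 1), tr.lines.size]
    return [(tr.lines[a:b], tr.positions[a:b]) for a, b in zip(starts, ends) if b - a >= min_len]
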