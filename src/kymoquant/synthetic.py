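"""Synthetic single-molecule data generator with known ground truth.

Emulates the optical-tweezers/confocal DNA-compaction experiment: labelled
protein tetramers diffusing on a λ-DNA tether held between two beads,
cluster formation upon transient relaxation of the tether, confocal
line-scan kymograph recording with Poisson photon statistics and
exponential photobleaching, worm-like-chain force–distance curves of free
and compacted DNA, and 2D flow-cell images of bridged DNA segments.

Every stochastic operation takes an explicit seed (or ``numpy`` Generator);
sub-streams are derived deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import ceil, erf, sqrt

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .config import ExperimentConfig, OpticsConfig
from .wlc import wlc_force, wlc_extension

__all__ = [
    "GroundTruth",
    "Kymograph",
    "ForceDistanceCurve",
    "simulate_trajectory",
    "sample_cluster_sizes",
    "simulate_compaction_experiment",
    "make_static_cluster_truth",
    "make_cascade_truth",
    "render_kymograph",
    "simulate_force_distance",
    "simulate_flow_image",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Kymograph:
    """Space–time photon-count image from repeated confocal line scans.

    Rows are scan lines (time ascending), columns are pixels along the DNA
    axis from the left bead; values are integer photon counts.
    """

    counts: np.ndarray          # (n_lines, n_pixels), integer >= 0
    pixel_size: float           # nm
    line_period: float          # s
    laser_power: float = 6.4    # µW

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D matrix (lines x pixels)")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("photon counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.pixel_size <= 0 or self.line_period <= 0:
            raise ValueError("pixel_size and line_period must be positive")

    @property
    def n_lines(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Scan-line times in s."""
        return np.arange(self.n_lines) * self.line_period

    @property
    def pixel_centers_um(self) -> np.ndarray:
        """Pixel-center coordinates in µm from the left bead (pixel i covers [i·d, (i+1)·d))."""
        return (np.arange(self.n_pixels) + 0.5) * self.pixel_size * 1e-3

    def total_intensity(self) -> np.ndarray:
        """Summed photons per scan line over the full DNA length."""
        return self.counts.sum(axis=1).astype(float)


@dataclass
class ForceDistanceCurve:
    """Force–extension record of a tethered DNA molecule.

    ``samples`` is an (n, 2) array of (end-to-end distance µm, force pN)
    ordered by distance; ``label`` is ``"free"`` or ``"compacted"``.
    """

    samples: np.ndarray
    label: str = "free"
    effective_contour_um: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 2:
            raise ValueError("samples must be an (n, 2) array of (distance, force)")
        if np.any(self.samples[:, 0] <= 0):
            raise ValueError("distances must be positive")
        if np.any(self.samples[:, 1] < 0):
            raise ValueError("forces must be nonnegative")
        if self.label not in ("free", "compacted"):
            raise ValueError("label must be 'free' or 'compacted'")

    @property
    def distance(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def force(self) -> np.ndarray:
        return self.samples[:, 1]


@dataclass
class GroundTruth:
    """Per-tetramer truth emitted by the generator, for recovery tests.

    positions[i, t] is tetramer i's axial position (µm from the left bead)
    at scan line t; ``separation`` is the bead separation timeline (µm).
    ``cluster_of[i]`` is the cluster id of tetramer i, or -1 if it stayed
    diffusive.  ``bleach_times`` (s, per fluorophore) is filled in by
    :func:`render_kymograph`.
    """

    times: np.ndarray                       # (n_lines,) s
    positions: np.ndarray                   # (n_tetramers, n_lines) µm
    separation: np.ndarray                  # (n_lines,) µm
    cluster_of: np.ndarray                  # (n_tetramers,) int, -1 = diffusive
    cluster_positions: dict = field(default_factory=dict)   # cluster id -> anchor µm
    fluors_per_tetramer: int = 4
    bleach_times: np.ndarray | None = None  # (n_tetramers, fluors_per_tetramer) s
    phase_times: dict = field(default_factory=dict)
    sequestered_length_per_binding_event: float = 0.0  # nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.separation = np.asarray(self.separation, dtype=float)
        self.cluster_of = np.asarray(self.cluster_of, dtype=int)
        if self.positions.shape[1] != self.times.size:
            raise ValueError("positions and times have inconsistent lengths")
        if np.any(self.positions < -1e-9) or np.any(self.positions > self.separation[None, :] + 1e-9):
            raise ValueError("positions must lie within [0, bead separation]")
        if self.bleach_times is not None and np.any(np.asarray(self.bleach_times) < 0):
            raise ValueError("bleach times must be nonnegative")

    @property
    def n_tetramers(self) -> int:
        return self.positions.shape[0]

    def cluster_sizes(self) -> dict:
        """Cluster id -> number of member tetramers."""
        ids, counts = np.unique(self.cluster_of[self.cluster_of >= 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    def to_json(self) -> str:
        d = {
            "times_s": self.times.tolist(),
            "positions_um": self.positions.tolist(),
            "separation_um": self.separation.tolist(),
            "cluster_of": self.cluster_of.tolist(),
            "cluster_positions_um": {str(k): v for k, v in self.cluster_positions.items()},
            "fluors_per_tetramer": self.fluors_per_tetramer,
            "bleach_times_s": None if self.bleach_times is None else np.asarray(self.bleach_times).tolist(),
            "phase_times_s": self.phase_times,
            "sequestered_length_per_binding_event_nm": self.sequestered_length_per_binding_event,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            times=np.array(d["times_s"]),
            positions=np.array(d["positions_um"]),
            separation=np.array(d["separation_um"]),
            cluster_of=np.array(d["cluster_of"], dtype=int),
            cluster_positions={int(k): v for k, v in d["cluster_positions_um"].items()},
            fluors_per_tetramer=d["fluors_per_tetramer"],
            bleach_times=None if d["bleach_times_s"] is None else np.array(d["bleach_times_s"]),
            phase_times=d["phase_times_s"],
            sequestered_length_per_binding_event=d["sequestered_length_per_binding_event_nm"],
        )


# ---------------------------------------------------------------------------
# trajectories and the compaction scenario


def simulate_trajectory(config: ExperimentConfig, tether_length: float, duration: float,
                        seed=None, dt: float = 0.02, x0: float | None = None) -> np.ndarray:
    """1D Brownian path on [0, tether_length] with reflecting boundaries.

    Per-step displacement variance is 2·D·dt with D =
    ``config.diffusion_constant_true`` (µm²/s).  Returns positions (µm) at
    times 0, dt, 2·dt, ... ≤ duration.
    """
    if duration <= 0 or tether_length <= 0:
        raise ValueError("duration and tether_length must be positive")
    if config.diffusion_constant_true < 0:
        raise ValueError("diffusion constant must be nonnegative")
    rng = _rng(seed)
    n = int(np.floor(duration / dt)) + 1
    x = np.empty(n)
    x[0] = rng.uniform(0, tether_length) if x0 is None else float(x0)
    sigma = sqrt(2.0 * config.diffusion_constant_true * dt)
    steps = rng.normal(0.0, sigma, size=n - 1) if sigma > 0 else np.zeros(n - 1)
    for i in range(1, n):
        x[i] = _reflect(x[i - 1] + steps[i - 1], tether_length)
    return x


def _reflect(x: float, length: float) -> float:
    # fold into [0, length] (handles multiple crossings)
    if length <= 0:
        return 0.0
    period = 2.0 * length
    x = x % period
    return period - x if x > length else x


def sample_cluster_sizes(rng, n: int, mean: float = 67.0,
                         size_range: tuple[float, float] = (20.0, 160.0),
                         sigma: float = 0.45) -> np.ndarray:
    """Draw integer cluster sizes from a truncated lognormal.

    The log-scale sd ``sigma`` is fixed; the location is solved so the mean
    of the truncated distribution equals ``mean`` exactly.
    """
    rng = _rng(rng)
    lo, hi = size_range
    if not (lo < mean < hi):
        raise ValueError("mean must lie inside size_range")

    la, lb = np.log(lo), np.log(hi)

    def trunc_mean(mu):
        za, zb = (la - mu) / sigma, (lb - mu) / sigma
        denom = ndtr(zb) - ndtr(za)
        num = ndtr(zb - sigma) - ndtr(za - sigma)
        return np.exp(mu + 0.5 * sigma**2) * num / denom

    mu = brentq(lambda m: trunc_mean(m) - mean, la, lb)
    # inverse-CDF sampling of the truncated normal on the log scale
    u = rng.uniform(ndtr((la - mu) / sigma), ndtr((lb - mu) / sigma), size=n)
    from scipy.special import ndtri
    sizes = np.exp(mu + sigma * ndtri(u))
    return np.maximum(np.round(sizes).astype(int), int(np.ceil(lo)))


def simulate_compaction_experiment(config: ExperimentConfig,
                                   optics: OpticsConfig = OpticsConfig()) -> tuple[GroundTruth, np.ndarray]:
    """Run the extended → relaxed/hold → re-extended scenario.

    Phase 1: tetramers diffuse on the extended tether.  Phase 2: the beads
    approach at ``pull_speed``; positions advect affinely with the bead
    separation while diffusion continues.  Hold: each tetramer converts to
    a static cluster member with probability
    ``cluster_conversion_probability``; converted tetramers are partitioned
    into clusters whose sizes follow the configured distribution and pinned
    at their cluster anchor.  Phase 3: re-extension; clusters stay static
    (advecting with the tether), survivors keep diffusing.

    Returns the ground truth and the bead-separation timeline (µm/line).
    """
    rng = np.random.default_rng(config.seed)
    dt = optics.line_period
    travel = (config.extended_separation - config.relaxed_separation) / config.pull_speed
    t_phase1 = config.extra_phase_time
    t_hold_start = t_phase1 + travel
    t_hold_end = t_hold_start + config.hold_time
    t_reext_end = t_hold_end + travel
    t_total = t_reext_end + config.extra_phase_time

    n_lines = int(np.floor(t_total / dt)) + 1
    times = np.arange(n_lines) * dt
    sep = np.empty(n_lines)
    for j, t in enumerate(times):
        if t < t_phase1:
            sep[j] = config.extended_separation
        elif t < t_hold_start:
            sep[j] = config.extended_separation - config.pull_speed * (t - t_phase1)
        elif t < t_hold_end:
            sep[j] = config.relaxed_separation
        elif t < t_reext_end:
            sep[j] = config.relaxed_separation + config.pull_speed * (t - t_hold_end)
        else:
            sep[j] = config.extended_separation

    n = config.n_tetramers
    sigma_step = sqrt(2.0 * config.diffusion_constant_true * dt)
    positions = np.empty((n, n_lines))
    positions[:, 0] = rng.uniform(0, sep[0], size=n)

    # cluster conversion at the start of the hold
    hold_line = int(np.ceil(t_hold_start / dt))
    converted = rng.uniform(size=n) < config.cluster_conversion_probability
    conv_ids = np.flatnonzero(converted)
    rng.shuffle(conv_ids)
    cluster_of = np.full(n, -1, dtype=int)
    cluster_positions: dict[int, float] = {}
    if conv_ids.size:
        sizes = []
        while sum(sizes) < conv_ids.size:
            sizes.extend(sample_cluster_sizes(rng, 4, config.cluster_size_mean,
                                              config.cluster_size_range).tolist())
        start, cid = 0, 0
        for s in sizes:
            members = conv_ids[start:start + s]
            if members.size == 0:
                break
            cluster_of[members] = cid
            cluster_positions[cid] = float(rng.uniform(0.25, config.relaxed_separation - 0.25))
            start += s
            cid += 1

    is_static = np.zeros(n, dtype=bool)
    for j in range(1, n_lines):
        mobile = ~is_static
        # affine advection with the moving bead
        ratio = sep[j] / sep[j - 1]
        positions[:, j] = positions[:, j - 1] * ratio
        if sigma_step > 0:
            steps = rng.normal(0.0, sigma_step, size=int(mobile.sum()))
            positions[mobile, j] += steps
        positions[:, j] = np.clip(positions[:, j], 0.0, sep[j])
        for i in np.flatnonzero(mobile):
            positions[i, j] = _reflect(positions[i, j], sep[j])
        if j == hold_line and conv_ids.size:
            for i in conv_ids:
                positions[i, j] = cluster_positions[cluster_of[i]]
            is_static[conv_ids] = True

    truth = GroundTruth(
        times=times, positions=positions, separation=sep, cluster_of=cluster_of,
        cluster_positions=cluster_positions, fluors_per_tetramer=config.fluors_per_tetramer,
        phase_times={"extended_end": t_phase1, "hold_start": t_hold_start,
                     "hold_end": t_hold_end, "reextended": t_reext_end},
    )
    return truth, sep


def make_static_cluster_truth(cluster_sizes, tether_length: float = 16.0,
                              duration: float = 10.0, optics: OpticsConfig = OpticsConfig(),
                              fluors_per_tetramer: int = 4, seed=None) -> GroundTruth:
    """Ground truth of static, well-separated clusters on an extended tether.

    ``cluster_sizes`` is a sequence of tetramer counts; anchors are spread
    evenly (with jitter) so neighbouring clusters do not overlap optically.
    """
    rng = _rng(seed)
    cluster_sizes = np.asarray(cluster_sizes, dtype=int)
    n_clusters = cluster_sizes.size
    n_lines = int(np.floor(duration / optics.line_period)) + 1
    times = np.arange(n_lines) * optics.line_period
    margin = 0.8
    anchors = np.linspace(margin, tether_length - margin, n_clusters)
    anchors = anchors + rng.uniform(-0.2, 0.2, size=n_clusters) if n_clusters > 1 else anchors
    n = int(cluster_sizes.sum())
    positions = np.empty((n, n_lines))
    cluster_of = np.empty(n, dtype=int)
    start = 0
    cluster_positions = {}
    for cid, (s, a) in enumerate(zip(cluster_sizes, anchors)):
        positions[start:start + s, :] = a
        cluster_of[start:start + s] = cid
        cluster_positions[cid] = float(a)
        start += s
    return GroundTruth(times=times, positions=positions,
                       separation=np.full(n_lines, tether_length),
                       cluster_of=cluster_of, cluster_positions=cluster_positions,
                       fluors_per_tetramer=fluors_per_tetramer)


def make_cascade_truth(position: float = 2.0, tether_length: float = 4.0,
                       duration: float = 24.0, optics: OpticsConfig = OpticsConfig(),
                       fluors_per_tetramer: int = 4) -> GroundTruth:
    """Single immobile tetramer — the photobleaching-cascade calibration scenario."""
    n_lines = int(np.floor(duration / optics.line_period)) + 1
    times = np.arange(n_lines) * optics.line_period
    return GroundTruth(times=times,
                       positions=np.full((1, n_lines), position),
                       separation=np.full(n_lines, tether_length),
                       cluster_of=np.array([-1]),
                       fluors_per_tetramer=fluors_per_tetramer)


# ---------------------------------------------------------------------------
# kymograph rendering


def render_kymograph(truth: GroundTruth, optics: OpticsConfig, seed=None,
                     poisson: bool = True) -> Kymograph:
    """Render a photon-count kymograph from ground truth.

    Each unbleached fluorophore contributes a Gaussian intensity profile
    (sd ``psf_sd_s``, centered on its tetramer's position) with expected
    peak amplitude ``photons_per_fluor_per_line`` scaled linearly by laser
    power; pixel values are Poisson draws of signal + background.  Bleach
    times are drawn exponentially with rate
    ``bleach_rate_at_reference · (laser_power/reference_power)²`` and stored
    back into ``truth.bleach_times`` (pre-set bleach times are honoured).
    Setting ``poisson=False`` returns the rounded expectation field
    (useful for noise-free oracles).
    """
    rng = _rng(seed)
    n_tet, n_lines = truth.positions.shape
    d_um = optics.pixel_size_d * 1e-3
    n_pixels = int(ceil(float(truth.separation.max()) / d_um))
    xc = (np.arange(n_pixels) + 0.5) * d_um
    s_um = optics.psf_sd_s * 1e-3
    amp = optics.amplitude_per_fluor
    times = truth.times
    if times.size != n_lines:
        raise ValueError("truth times and positions are inconsistent")

    if truth.bleach_times is None:
        k = optics.bleach_rate
        if k > 0:
            truth.bleach_times = rng.exponential(1.0 / k,
                                                 size=(n_tet, truth.fluors_per_tetramer))
        else:
            truth.bleach_times = np.full((n_tet, truth.fluors_per_tetramer), np.inf)
    bleach = np.asarray(truth.bleach_times, dtype=float)
    if bleach.shape != (n_tet, truth.fluors_per_tetramer):
        raise ValueError("bleach_times shape mismatch")

    signal = np.zeros((n_lines, n_pixels))
    half_w = 5.0 * s_um
    for i in range(n_tet):
        pos = truth.positions[i]
        # number of unbleached fluorophores on this tetramer per line
        alive = (times[None, :] < bleach[i][:, None]).sum(axis=0).astype(float)
        if not alive.any():
            continue
        lo = max(int((pos.min() - half_w) / d_um), 0)
        hi = min(int((pos.max() + half_w) / d_um) + 2, n_pixels)
        if hi <= lo:
            continue
        if np.ptp(pos) == 0.0:
            prof = amp * np.exp(-0.5 * ((xc[lo:hi] - pos[0]) / s_um) ** 2)
            signal[:, lo:hi] += np.outer(alive, prof)
        else:
            prof = amp * np.exp(-0.5 * ((xc[None, lo:hi] - pos[:, None]) / s_um) ** 2)
            signal[:, lo:hi] += alive[:, None] * prof

    lam = signal + optics.background_rate
    counts = rng.poisson(lam) if poisson else np.round(lam).astype(np.int64)
    return Kymograph(counts=counts, pixel_size=optics.pixel_size_d,
                     line_period=optics.line_period, laser_power=optics.laser_power)


# ---------------------------------------------------------------------------
# force-distance curves


def simulate_force_distance(config: ExperimentConfig, sequestered_length: float = 0.0,
                            n_loops: int = 0, n_samples: int = 400,
                            max_force: float = 30.0, force_noise_sd: float = 0.1,
                            seed=None) -> ForceDistanceCurve:
    """Worm-like-chain force–distance curve of free or compacted DNA.

    A compacted tether has effective contour length
    ``contour_length − sequestered_length − n_loops·P`` (P = persistence
    length, one loop-closure allowance per cluster): at any distance its
    force lies at or above the free curve.  ``sequestered_length`` in µm.
    """
    if sequestered_length < 0 or n_loops < 0:
        raise ValueError("sequestered_length and n_loops must be nonnegative")
    loop_allowance_um = n_loops * config.persistence_length * 1e-3
    l_eff = config.contour_length - sequestered_length - loop_allowance_um
    if l_eff <= 0:
        raise ValueError("sequestered length exceeds the contour length")
    rng = _rng(seed)
    z_max = wlc_extension(max_force, 1.0, config.persistence_length)
    dist = np.linspace(0.3 * l_eff, z_max * l_eff, n_samples)
    force = wlc_force(dist, l_eff, config.persistence_length)
    if force_noise_sd > 0:
        force = np.maximum(force + rng.normal(0.0, force_noise_sd, size=force.shape), 0.0)
    label = "free" if (sequestered_length == 0 and n_loops == 0) else "compacted"
    return ForceDistanceCurve(samples=np.column_stack([dist, force]), label=label,
                              effective_contour_um=l_eff)


# ---------------------------------------------------------------------------
# flow-cell images


def simulate_flow_image(n_molecules: int = 2, bridged_segments=(), optics: OpticsConfig = OpticsConfig(),
                        footprint_nm: float = 3.6, labels_per_tetramer: int = 4,
                        image_size_um: tuple[float, float] | None = None,
                        seed=None) -> tuple[np.ndarray, dict]:
    """2D photon-count image of flow-stretched, protein-bridged DNA segments.

    ``bridged_segments`` is a sequence of ((x0, y0), (x1, y1)) endpoints in
    µm.  Along each segment, tetramers are planted at linear density
    1/footprint (each tetramer engages one binding domain per duplex of the
    bridged pair, so consecutive tetramers advance one footprint), each
    carrying ``labels_per_tetramer`` fluorophores.  Rendering: per-dye 2D
    Gaussian of sd ``psf_sd_s`` and peak amplitude
    ``photons_per_fluor_per_line``; Poisson noise plus uniform background.

    Returns (counts image, truth dict with planted dye positions and
    per-segment tetramer counts).
    """
    rng = _rng(seed)
    d_um = optics.pixel_size_d * 1e-3
    segs = [(np.asarray(a, float), np.asarray(b, float)) for a, b in bridged_segments]
    if image_size_um is None:
        if segs:
            allp = np.array([p for ab in segs for p in ab])
            w = allp[:, 0].max() + 1.0
            h = allp[:, 1].max() + 1.0
        else:
            w, h = 4.0, 2.0
        image_size_um = (w, h)
    n_cols = int(ceil(image_size_um[0] / d_um))
    n_rows = int(ceil(image_size_um[1] / d_um))

    dyes = []
    n_tet_per_seg = []
    f_um = footprint_nm * 1e-3
    for a, b in segs:
        seg_len = float(np.linalg.norm(b - a))
        if np.any(a < 0) or np.any(b < 0) or a[0] > image_size_um[0] or b[0] > image_size_um[0] \
                or a[1] > image_size_um[1] or b[1] > image_size_um[1]:
            raise ValueError("segment endpoints must lie within the image bounds")
        n_tet = int(round(seg_len / f_um))
        n_tet_per_seg.append(n_tet)
        if n_tet == 0:
            continue
        # jittered regular spacing along the segment
        frac = (np.arange(n_tet) + rng.uniform(0.25, 0.75, size=n_tet)) / n_tet
        pts = a[None, :] + frac[:, None] * (b - a)[None, :]
        dyes.append(np.repeat(pts, labels_per_tetramer, axis=0))
    dye_pos = np.concatenate(dyes, axis=0) if dyes else np.empty((0, 2))

    s_um = optics.psf_sd_s * 1e-3
    amp = optics.amplitude_per_fluor
    xc = (np.arange(n_cols) + 0.5) * d_um
    yc = (np.arange(n_rows) + 0.5) * d_um
    signal = np.zeros((n_rows, n_cols))
    half_w = 5.0 * s_um
    for x0, y0 in dye_pos:
        c0, c1 = max(int((x0 - half_w) / d_um), 0), min(int((x0 + half_w) / d_um) + 2, n_cols)
        r0, r1 = max(int((y0 - half_w) / d_um), 0), min(int((y0 + half_w) / d_um) + 2, n_rows)
        gx = np.exp(-0.5 * ((xc[c0:c1] - x0) / s_um) ** 2)
        gy = np.exp(-0.5 * ((yc[r0:r1] - y0) / s_um) ** 2)
        signal[r0:r1, c0:c1] += amp * np.outer(gy, gx)

    counts = rng.poisson(signal + optics.background_rate)
    truth = {
        "dye_positions_um": dye_pos,
        "n_tetramers_per_segment": n_tet_per_seg,
        "footprint_nm": footprint_nm,
        "labels_per_tetramer": labels_per_tetramer,
        "n_molecules": n_molecules,
        "segments_um": [(tuple(a), tuple(b)) for a, b in segs],
    }
    return counts, truth
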