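"""Single-particle tracking on kymographs.

Detections are local Gaussian peaks on each scan line; trajectories are
built by nearest-neighbour linking across lines with a maximum jump, gap
tolerance, and deterministic tie-breaking (smallest displacement, then
larger amplitude).  Deterministic for a fixed kymograph and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .photometry import Calibration, fit_profile
from .synthetic import Kymograph

__all__ = ["Detection", "Trajectory", "detect_peaks", "track",
           "classify_trajectory", "trajectory_stoichiometry"]


@dataclass(frozen=True)
class Detection:
    line: int
    position: float   # µm (sub-pixel Gaussian center)
    amplitude: float  # photons


@dataclass
class Trajectory:
    """Linked positions of one emitter over time."""

    lines: np.ndarray        # scan-line indices, strictly increasing
    times: np.ndarray        # s
    positions: np.ndarray    # µm
    amplitudes: np.ndarray   # photons
    classification: str = "ambiguous"   # diffusive | static | ambiguous

    def __post_init__(self):
        self.lines = np.asarray(self.lines, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.lines.size


def detect_peaks(kymo: Kymograph, line: int, threshold: float,
                 fit_halfwidth_px: int = 4, smooth_sigma_px: float = 1.0) -> list[Detection]:
    """Sub-pixel emitter detections on one scan line.

    Local maxima of the (lightly smoothed) line whose smoothed height
    exceeds background + ``threshold`` photons are refined by a local
    Gaussian fit of half-width ``fit_halfwidth_px`` pixels.
    """
    row = kymo.counts[line].astype(float)
    sm = gaussian_filter1d(row, smooth_sigma_px)
    bg = np.median(sm)
    n = row.size
    x = kymo.pixel_centers_um
    out: list[Detection] = []
    for i in range(1, n - 1):
        if sm[i] >= sm[i - 1] and sm[i] > sm[i + 1] and sm[i] - bg > threshold:
            lo = max(i - fit_halfwidth_px, 0)
            hi = min(i + fit_halfwidth_px + 1, n)
            if hi - lo < 5:
                continue
            fit = fit_profile(row[lo:hi], x[lo:hi], psf_sd_nm=100.0, fix_width=True)
            if fit.ok and fit.amplitude > 0:
                out.append(Detection(line=line, position=fit.center, amplitude=fit.amplitude))
    return out


def track(kymo: Kymograph, detection_threshold: float = 3.0,
          max_jump_px: float = 3.0, max_gap: int = 3,
          min_length: int = 10) -> list[Trajectory]:
    """Build trajectories from a kymograph.

    Per line, Gaussian peaks above ``detection_threshold`` photons (over
    background) are linked to the nearest active trajectory end within
    ``max_jump_px·(gap+1)`` pixels; ties go to the smallest displacement,
    then the larger amplitude.  Trajectories missing more than ``max_gap``
    consecutive lines are terminated; those shorter than ``min_length``
    detections are dropped.  Each detection joins at most one trajectory.
    """
    if kymo.n_lines == 0 or kymo.counts.size == 0:
        return []
    d_um = kymo.pixel_size * 1e-3
    active: list[dict] = []
    done: list[dict] = []
    for line in range(kymo.n_lines):
        dets = detect_peaks(kymo, line, detection_threshold)
        dets.sort(key=lambda d: (-d.amplitude, d.position))
        used = [False] * len(dets)
        for tr in active:
            gap = line - tr["lines"][-1]
            limit = max_jump_px * d_um * gap
            best_j, best_dist = -1, np.inf
            for j, det in enumerate(dets):
                if used[j]:
                    continue
                dist = abs(det.position - tr["positions"][-1])
                if dist <= limit and (dist < best_dist - 1e-12 or
                                      (abs(dist - best_dist) <= 1e-12 and best_j >= 0 and
                                       det.amplitude > dets[best_j].amplitude)):
                    best_j, best_dist = j, dist
            if best_j >= 0:
                det = dets[best_j]
                used[best_j] = True
                tr["lines"].append(line)
                tr["positions"].append(det.position)
                tr["amplitudes"].append(det.amplitude)
        still_active = []
        for tr in active:
            if line - tr["lines"][-1] > max_gap:
                done.append(tr)
            else:
                still_active.append(tr)
        active = still_active
        for j, det in enumerate(dets):
            if not used[j]:
                active.append({"lines": [line], "positions": [det.position],
                               "amplitudes": [det.amplitude]})
    done.extend(active)

    out = []
    for tr in done:
        if len(tr["lines"]) < min_length:
            continue
        lines = np.array(tr["lines"])
        out.append(Trajectory(lines=lines, times=lines * kymo.line_period,
                              positions=np.array(tr["positions"]),
                              amplitudes=np.array(tr["amplitudes"])))
    out.sort(key=lambda t: (t.lines[0], t.positions[0]))
    return out


def classify_trajectory(traj: Trajectory, window: int = 20,
                        static_sd_px: float = 1.5, pixel_size_nm: float = 75.0) -> str:
    """Label a trajectory static or diffusive by its positional spread.

    Static if the positional standard deviation within every ``window``-
    sample block stays below ``static_sd_px`` pixels; ambiguous if fewer
    than 10 samples.  The label is also stored on the trajectory.
    """
    if len(traj) < 10:
        traj.classification = "ambiguous"
        return "ambiguous"
    thresh_um = static_sd_px * pixel_size_nm * 1e-3
    pos = traj.positions
    window = max(min(window, pos.size), 2)
    sds = [np.std(pos[i:i + window]) for i in range(0, pos.size - window + 1, window)]
    label = "static" if max(sds) < thresh_um else "diffusive"
    traj.classification = label
    return label


def trajectory_stoichiometry(traj: Trajectory, cal: Calibration) -> float:
    """Dye count of a trajectory: mean scan-line amplitude / photons per fluorophore."""
    if len(traj) == 0:
        return 0.0
    return float(np.mean(traj.amplitudes) / cal.photons_per_fluor)
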