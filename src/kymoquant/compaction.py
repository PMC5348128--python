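"""DNA-binding footprint estimation.

Two independent estimators:

* **Force–distance compaction.**  At 25 pN (high enough to strip weak,
  non-specific interactions) the shortening of a compacted tether relative
  to the free one, less one persistence-length allowance (50 nm) per
  cluster for the loop closing each bridged region, divided by twice the
  number of tetramers (two DNA-binding ends each), gives the footprint per
  DNA-binding domain:

      f = (ΔL − n_clusters·P) / (2·N_tetramers)

* **Flow-box photometry.**  In 2D images of flow-stretched, protein-
  bridged DNA, the tetramer count inside an intensity box is
  N = (I_box − I_bg) / (4·I_ref) with I_ref = A·2π(s/d)² the total photon
  count of one fluorophore, and the footprint is box length / N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import OpticsConfig
from .synthetic import ForceDistanceCurve

__all__ = ["FootprintInputs", "FlowBox", "length_at_force",
           "footprint_from_compaction", "box_reference_intensity",
           "footprint_from_box", "flow_boxes_along_segment"]


@dataclass(frozen=True)
class FootprintInputs:
    """Per-molecule inputs to the compaction footprint formula."""

    length_free: float        # µm at 25 pN
    length_bound: float       # µm at 25 pN
    n_clusters: int
    n_tetramers_total: int
    persistence_length: float = 50.0  # nm

    def __post_init__(self):
        if self.length_free <= self.length_bound:
            raise ValueError("length_free must exceed length_bound")
        if self.n_clusters < 1 or self.n_tetramers_total < self.n_clusters:
            raise ValueError("need n_tetramers_total >= n_clusters >= 1")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")


@dataclass(frozen=True)
class FlowBox:
    """Intensity box on a flow-cell image (all intensities in photons)."""

    I_box: float
    I_bg: float
    box_length: float   # nm
    A: float = 1.5      # single-dye Gaussian amplitude, photons
    s: float = 100.0    # Gaussian sd, nm
    d: float = 75.0     # pixel size, nm

    def __post_init__(self):
        if self.I_box < 0 or self.I_bg < 0 or self.box_length <= 0:
            raise ValueError("intensities must be nonnegative and box_length positive")


def length_at_force(curve: ForceDistanceCurve, force_pn: float = 25.0) -> float:
    """End-to-end distance (µm) at a target force, by linear interpolation
    of the samples bracketing it."""
    f = curve.force
    d = curve.distance
    if force_pn < f.min() or force_pn > f.max():
        raise ValueError("target force outside the recorded curve")
    # first crossing from below (curves are monotone up to noise)
    idx = np.flatnonzero((f[:-1] <= force_pn) & (f[1:] >= force_pn))
    if idx.size == 0:
        idx = np.array([int(np.argmin(np.abs(f - force_pn))) - 1])
    i = int(idx[-1])
    f0, f1 = f[i], f[i + 1]
    if f1 == f0:
        return float(d[i])
    return float(d[i] + (force_pn - f0) / (f1 - f0) * (d[i + 1] - d[i]))


def footprint_from_compaction(inp: FootprintInputs) -> tuple[float, bool]:
    """Footprint (nm) per DNA-binding domain from tether shortening.

    Returns (footprint, valid); non-positive footprints (length change
    fully consumed by the loop allowance) are returned flagged invalid
    rather than raised.
    """
    dl_nm = (inp.length_free - inp.length_bound) * 1e3
    f = (dl_nm - inp.n_clusters * inp.persistence_length) / (2.0 * inp.n_tetramers_total)
    return float(f), f > 0


def box_reference_intensity(A: float = 1.5, s: float = 100.0, d: float = 75.0) -> float:
    """Total photon count of one fluorophore in a 2D image: I_ref = A·2π·(s/d)²."""
    if A < 0 or s <= 0 or d <= 0:
        raise ValueError("require A >= 0 and s, d > 0")
    return float(A * 2.0 * np.pi * (s / d) ** 2)


def footprint_from_box(box: FlowBox, labels_per_tetramer: int = 4):
    """Tetramer count and footprint from one flow box.

    N = (I_box − I_bg)/(labels_per_tetramer·I_ref); footprint = box length/N.
    Returns (N, footprint nm, valid); a non-positive excess intensity gives
    footprint NaN with valid=False.
    """
    i_ref = box_reference_intensity(box.A, box.s, box.d)
    n = (box.I_box - box.I_bg) / (labels_per_tetramer * i_ref)
    if n <= 0:
        return float(n), float("nan"), False
    return float(n), float(box.box_length / n), True


def flow_boxes_along_segment(image: np.ndarray, optics: OpticsConfig, segment,
                             box_length_nm: float = 1000.0,
                             band_halfwidth_nm: float = 300.0,
                             bg_offset_nm: float = 750.0,
                             end_margin_nm: float = 500.0) -> list[FlowBox]:
    """Tile intensity boxes along a horizontal bridged segment.

    ``segment`` is ((x0, y), (x1, y)) in µm (flow-stretched DNA lies along
    the image rows).  Each box spans ``box_length_nm`` along the segment
    and ±``band_halfwidth_nm`` across it; the background box is the same
    size, offset ``bg_offset_nm`` perpendicular to the DNA.  Boxes within
    ``end_margin_nm`` of the segment ends are skipped (edge spill-over).
    """
    (x0, y0), (x1, y1) = segment
    if abs(y1 - y0) > 1e-9:
        raise ValueError("flow boxes require a horizontal (flow-aligned) segment")
    d = optics.pixel_size_d
    d_um = d * 1e-3
    row = int(round(y0 / d_um - 0.5))
    half_rows = max(int(round(band_halfwidth_nm / d)), 1)
    r0, r1 = row - half_rows, row + half_rows + 1
    off_rows = int(round(bg_offset_nm / d)) + 2 * half_rows
    b0, b1 = r0 - off_rows, r1 - off_rows
    if b0 < 0:
        b0, b1 = r0 + off_rows, r1 + off_rows
    if r0 < 0 or r1 > image.shape[0] or b0 < 0 or b1 > image.shape[0]:
        raise ValueError("segment band or background band falls outside the image")

    box_px = max(int(round(box_length_nm / d)), 1)
    lo_um = min(x0, x1) + end_margin_nm * 1e-3
    hi_um = max(x0, x1) - end_margin_nm * 1e-3
    c = int(np.ceil(lo_um / d_um))
    boxes = []
    while (c + box_px) * d_um <= hi_um:
        sl = slice(c, c + box_px)
        boxes.append(FlowBox(
            I_box=float(image[r0:r1, sl].sum()),
            I_bg=float(image[b0:b1, sl].sum()),
            box_length=box_px * d,
            A=optics.amplitude_per_fluor, s=optics.psf_sd_s, d=d,
        ))
        c += box_px
    return boxes
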