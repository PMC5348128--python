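"""Configuration objects for the synthetic experiment and the confocal optics.

Units convention (project-wide): positions and distances in µm, optics
lengths and footprints in nm, time in s, force in pN, intensities in
photons, laser power in µW.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class OpticsConfig:
    """Confocal line-scan optics and photophysics.

    ``photons_per_fluor_per_line`` is the peak amplitude, in photons, of the
    Gaussian intensity profile a single fluorophore produces on one scan
    line at the reference laser power.  Emission scales linearly with laser
    power; the photobleaching rate scales quadratically (two-photon
    bleaching under pulsed excitation).
    """

    pixel_size_d: float = 75.0          # nm
    psf_sd_s: float = 100.0             # nm
    photons_per_fluor_per_line: float = 1.5
    laser_power: float = 6.4            # µW
    reference_power: float = 6.4        # µW
    bleach_rate_at_reference: float = 5e-5  # 1/s
    background_rate: float = 0.2        # photons/pixel/line
    line_period: float = 0.02           # s

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_d",
            "psf_sd_s",
            "photons_per_fluor_per_line",
            "laser_power",
            "reference_power",
            "line_period",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bleach_rate_at_reference < 0 or self.background_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.psf_sd_s < self.pixel_size_d / 4:
            raise ValueError(
                "psf_sd_s must be >= pixel_size_d/4 for a resolvable profile"
            )

    @property
    def bleach_rate(self) -> float:
        """Effective bleach rate at the configured power (quadratic law), 1/s."""
        return self.bleach_rate_at_reference * (self.laser_power / self.reference_power) ** 2

    @property
    def amplitude_per_fluor(self) -> float:
        """Expected peak amplitude per fluorophore at the configured power, photons."""
        return self.photons_per_fluor_per_line * (self.laser_power / self.reference_power)


@dataclass(frozen=True)
class ExperimentConfig:
    """Optical-tweezers DNA-compaction experiment scenario.

    The default geometry follows the standard λ-DNA protocol: the tether is
    held extended at 16 µm under ~5 pN, relaxed to 8 µm at 0.6 µm/s, held
    ~5.5 s so DNA-bridging clusters can form, and re-extended.
    """

    contour_length: float = 16.4        # µm (48,502 bp × 0.338 nm/bp)
    extended_separation: float = 16.0   # µm
    relaxed_separation: float = 8.0     # µm
    pull_speed: float = 0.6             # µm/s
    hold_time: float = 5.5              # s
    hold_force: float = 5.0             # pN
    diffusion_constant_true: float = 0.16  # µm²/s
    n_tetramers: int = 200
    fluors_per_tetramer: int = 4
    cluster_size_mean: float = 67.0     # tetramers
    cluster_size_range: tuple[float, float] = (20.0, 160.0)
    cluster_conversion_probability: float = 0.9
    persistence_length: float = 50.0    # nm
    seed: int = 0
    extra_phase_time: float = field(default=10.0)  # s observed in each extended phase

    def __post_init__(self) -> None:
        if not (0 < self.relaxed_separation < self.extended_separation <= self.contour_length):
            raise ValueError(
                "require 0 < relaxed_separation < extended_separation <= contour_length"
            )
        if self.diffusion_constant_true < 0:
            raise ValueError("diffusion_constant_true must be nonnegative")
        if self.n_tetramers < 0 or self.fluors_per_tetramer < 1:
            raise ValueError("invalid tetramer/label counts")
        lo, hi = self.cluster_size_range
        if not (1 <= lo <= hi):
            raise ValueError("cluster_size_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.cluster_conversion_probability <= 1.0):
            raise ValueError("cluster_conversion_probability must be in [0, 1]")
        if self.persistence_length <= 0 or self.pull_speed <= 0:
            raise ValueError("persistence_length and pull_speed must be positive")
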