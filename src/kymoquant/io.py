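"""File I/O: kymograph TIFF/CSV round-trips with sidecar metadata,
force–distance tables, ground-truth JSON, and result-record validation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, Field

from .config import OpticsConfig, ExperimentConfig
from .synthetic import ForceDistanceCurve, GroundTruth, Kymograph

__all__ = ["write_kymograph", "read_kymograph", "write_ground_truth",
           "read_ground_truth", "write_force_distance", "read_force_distance",
           "RunConfig", "ResultBundle", "result_schema", "validate_bundle"]

_SIDECAR_KEYS = ("pixel_size_nm", "line_period_s", "laser_power_uW")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_kymograph(kymo: Kymograph, path) -> None:
    """Write a kymograph as 16-bit grayscale TIFF (.tif) or integer CSV
    (.csv), with pixel size / line period / laser power in a YAML sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        if kymo.counts.max() >= 2**16:
            raise ValueError("counts exceed 16-bit range")
        tifffile.imwrite(path, kymo.counts.astype(np.uint16))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, kymo.counts, fmt="%d", delimiter=",")
    else:
        raise ValueError("unsupported kymograph format (use .tif/.tiff or .csv)")
    meta = {"pixel_size_nm": float(kymo.pixel_size),
            "line_period_s": float(kymo.line_period),
            "laser_power_uW": float(kymo.laser_power)}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_kymograph(path) -> Kymograph:
    """Read a kymograph written by :func:`write_kymograph`.

    TIFF input must be single-plane grayscale; CSV must be a nonnegative
    integer matrix.  The YAML sidecar with pixel size, line period and
    laser power is required.
    """
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"missing sidecar metadata {side.name}; required keys: {', '.join(_SIDECAR_KEYS)}"
        )
    meta = yaml.safe_load(side.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise ValueError(f"sidecar metadata missing required keys: {', '.join(missing)}")

    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):
            raise ValueError("RGB(A) TIFF input not supported: kymographs are single-plane grayscale")
        if arr.ndim != 2:
            raise ValueError(f"multi-plane TIFF input not supported (got {arr.ndim} dimensions)")
    elif path.suffix.lower() == ".csv":
        arr = np.loadtxt(path, delimiter=",", dtype=float)
        arr = np.atleast_2d(arr)
        if np.any(arr < 0):
            raise ValueError("negative photon counts in CSV input")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("non-integer photon counts in CSV input")
        arr = arr.astype(np.int64)
    else:
        raise ValueError("unsupported kymograph format (use .tif/.tiff or .csv)")
    return Kymograph(counts=arr, pixel_size=float(meta["pixel_size_nm"]),
                     line_period=float(meta["line_period_s"]),
                     laser_power=float(meta["laser_power_uW"]))


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_force_distance(curve: ForceDistanceCurve, path) -> None:
    """Two-column CSV (distance_um, force_pn) plus a label column."""
    df = pd.DataFrame({"distance_um": curve.distance, "force_pn": curve.force,
                       "label": curve.label})
    df.to_csv(path, index=False)


def read_force_distance(path) -> ForceDistanceCurve:
    df = pd.read_csv(path)
    for col in ("distance_um", "force_pn"):
        if col not in df.columns:
            raise ValueError(f"force-distance CSV missing column {col!r}")
    label = str(df["label"].iloc[0]) if "label" in df.columns else "free"
    return ForceDistanceCurve(samples=df[["distance_um", "force_pn"]].to_numpy(),
                              label=label)


# ---------------------------------------------------------------------------
# run configuration and result records (pydantic models double as the
# published JSON schemas, exported via ``result_schema``)


class RunConfig(BaseModel):
    """Configuration for the end-to-end pipeline run."""

    seed: int = 0
    output_dir: str = "kymoquant_out"
    optics: dict = Field(default_factory=dict)        # OpticsConfig overrides
    experiment: dict = Field(default_factory=dict)    # ExperimentConfig overrides
    photons_per_fluor: float = 1.5
    msd_fit_range: tuple[int, int] = (2, 10)
    detection_threshold: float = 3.0
    planted_footprint_nm: float = 2.7
    flow_footprint_nm: float = 3.6

    def optics_config(self) -> OpticsConfig:
        return OpticsConfig(**self.optics)

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(seed=self.seed, **self.experiment)


class ResultBundle(BaseModel):
    """Validated result record emitted by the pipeline (units in field names)."""

    seed: int
    parameters: dict
    cluster_sizes_tetramers: list[float]
    cluster_size_mean_tetramers: float | None
    diffusion_constant_um2_per_s: float | None
    diffusion_constant_sd: float | None
    n_diffusive_trajectories: int
    stoichiometry_dyes_per_trajectory: float | None
    footprint_compaction_nm: float | None
    footprint_flow_box_nm: float | None
    provenance: dict


def result_schema() -> dict:
    """JSON schema of the pipeline result bundle."""
    return ResultBundle.model_json_schema()


def validate_bundle(payload: dict) -> ResultBundle:
    """Validate a result record against the published schema."""
    return ResultBundle.model_validate(payload)


def write_schema(path) -> None:
    Path(path).write_text(json.dumps(result_schema(), indent=2))
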