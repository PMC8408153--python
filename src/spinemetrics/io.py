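"""Volume and table I/O, pipeline configuration, and shared containers.

Axis convention
---------------
All 3D arrays are indexed ``(z, y, x)`` with ``z`` the anteroposterior axis
for spine volumes.  Voxel sizes and point coordinates follow the same
``(z, y, x)`` ordering everywhere in the package; CSV outputs name their
columns ``z_um``/``y_um``/``x_um`` explicitly.

Supported on-disk formats are multipage TIFF stacks (or a directory of
per-slice TIFFs) with a JSON sidecar carrying the voxel size, and MetaImage
(``.mha``/``.mhd``) whose self-describing header stores the spacing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import SimpleITK as sitk
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

logger = logging.getLogger("spinemetrics")


class FormatError(ValueError):
    """Raised for malformed or unsupported image files."""


class ConfigError(ValueError):
    """Raised when a configuration value is missing, unknown or out of range."""


@dataclass
class Volume:
    """A 3D grayscale image with physical voxel size.

    Parameters
    ----------
    data
        3D intensity array, axes ``(z, y, x)``.
    voxel_size_um
        Edge lengths of one voxel in micrometres, per axis ``(z, y, x)``.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got shape={self.data.shape}")
        vs = tuple(float(v) for v in np.broadcast_to(self.voxel_size_um, (3,)))
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be > 0, got {vs}")
        self.voxel_size_um = vs
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size_um))


@dataclass
class LabelVolume:
    """Integer label grid sharing the shape contract of its source Volume.

    Labels are ``>= -1``: 0 is background, positive labels are objects and
    -1 marks the head region in spine phantoms.
    """

    data: np.ndarray
    label_names: Optional[dict[int, str]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {self.data.dtype}")
        if self.data.size and self.data.min() < -1:
            raise ValueError("labels must be >= -1")


class PipelineConfig(BaseModel):
    """All tunable parameters of the pipeline, with the published defaults.

    ``downsample_factor`` (0.5), ``retained_fraction`` (0.007, i.e. keep the
    brightest 0.7% of voxels), ``knn_k`` (12), ``profile_width_px`` (40) and
    ``phantom_densities`` (0.25/0.75 g·cm⁻³ CaHA) follow the published
    protocol; the remainder are exposed operational choices.
    """

    model_config = ConfigDict(extra="forbid")

    downsample_factor: float = 0.5
    retained_fraction: float = 0.007
    knn_k: int = 12
    spline_smoothing: Optional[float] = None
    profile_bin_um: float = 40.0
    peak_prominence: float = 0.1
    spacing_depth_ratio: float = 0.35
    peak_min_separation_um: float = 100.0
    core_fraction: float = 0.5
    head_density_ratio: float = 2.0
    lacuna_size_filter_um3: tuple[float, float] = (5.0, 5000.0)
    binarize_threshold: float = 0.5
    roi_side_px: int = 32
    profile_width_px: int = 40
    phantom_densities: tuple[float, float] = (0.25, 0.75)
    reference_group_label: Optional[str] = None
    seed: int = 0

    @field_validator("downsample_factor")
    @classmethod
    def _check_downsample(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("downsample_factor must be in (0, 1]")
        return v

    @field_validator("retained_fraction")
    @classmethod
    def _check_fraction(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("retained_fraction must be in (0, 1)")
        return v

    @field_validator("knn_k")
    @classmethod
    def _check_k(cls, v: int) -> int:
        if v < 1:
            raise ValueError("knn_k must be >= 1")
        return v

    @field_validator("core_fraction")
    @classmethod
    def _check_core(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("core_fraction must be in (0, 1]")
        return v

    @field_validator("profile_bin_um", "peak_min_separation_um", "head_density_ratio")
    @classmethod
    def _check_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("lacuna_size_filter_um3")
    @classmethod
    def _check_size_filter(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not 0 <= lo < hi:
            raise ValueError("lacuna_size_filter_um3 must satisfy 0 <= min < max")
        return v

    @field_validator("phantom_densities")
    @classmethod
    def _check_phantoms(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not lo < hi:
            raise ValueError("phantom_densities must be increasing")
        return v


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML (or JSON) file.

    Absent keys fall back to defaults; an empty file yields pure defaults.
    A top-level ``pipeline:`` block is used when present, so a single file
    can also carry ``synthetic:`` phantom specs for the full pipeline.
    """
    raw = parse_config_text(Path(path).read_text())
    block = raw.get("pipeline", {k: v for k, v in raw.items() if k != "synthetic"})
    return make_config(block)


def parse_config_text(text: str) -> dict:
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - malformed YAML
        raise ConfigError(f"cannot parse config: {exc}") from exc
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return raw


def make_config(values: dict) -> PipelineConfig:
    """Validate a dict of parameters into a PipelineConfig with named errors."""
    try:
        return PipelineConfig(**values)
    except ValidationError as exc:
        first = exc.errors()[0]
        key = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigError(f"config key '{key}': {first['msg']}") from exc


# ---------------------------------------------------------------------------
# Volume readers / writers


def write_volume(vol: Volume, path: str | Path, format: Optional[str] = None) -> Path:
    """Write a volume as a multipage TIFF (+ JSON sidecar) or MetaImage."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        _check_tiff_dtype(vol.data.dtype)
        tifffile.imwrite(path, vol.data)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"voxel_size_um": list(vol.voxel_size_um)}))
    elif fmt == "metaimage":
        img = sitk.GetImageFromArray(vol.data)
        # SimpleITK spacing is (x, y, z)
        img.SetSpacing(tuple(reversed(vol.voxel_size_um)))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unsupported format '{fmt}'")
    return path


def read_volume(path: str | Path, format: Optional[str] = None) -> Volume:
    """Read a volume from TIFF stack (file or slice directory) or MetaImage."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        return _read_tiff_dir(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = path.with_suffix(path.suffix + ".json")
        voxel = (1.0, 1.0, 1.0)
        if sidecar.exists():
            voxel = tuple(json.loads(sidecar.read_text())["voxel_size_um"])
        return Volume(data, voxel)
    if fmt == "metaimage":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        voxel = tuple(reversed(img.GetSpacing()))
        return Volume(data, voxel)
    raise FormatError(f"unsupported format '{fmt}'")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff"
    if suffix in (".mha", ".mhd"):
        return "metaimage"
    raise FormatError(f"cannot infer format from '{path.name}'")


def _check_tiff_dtype(dtype: np.dtype) -> None:
    if not (np.issubdtype(dtype, np.integer) or np.issubdtype(dtype, np.floating)):
        raise FormatError(f"unsupported dtype for TIFF: {dtype}")


def _read_tiff_dir(path: Path) -> Volume:
    slices = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
    if not slices:
        raise FormatError(f"no TIFF slices found in {path}")
    arrays = []
    for i, p in enumerate(slices):
        arr = tifffile.imread(p)
        if arr.ndim != 2:
            raise FormatError(f"slice {i} ({p.name}) is not 2D")
        if arrays and arr.shape != arrays[0].shape:
            raise FormatError(
                f"slice {i} ({p.name}) has shape {arr.shape}, "
                f"expected {arrays[0].shape}"
            )
        arrays.append(arr)
    sidecar = path / "voxel_size.json"
    voxel = (1.0, 1.0, 1.0)
    if sidecar.exists():
        voxel = tuple(json.loads(sidecar.read_text())["voxel_size_um"])
    return Volume(np.stack(arrays), voxel)
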