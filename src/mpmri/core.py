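"""Core in-memory containers shared by all pipeline stages.

The pipeline operates on single-slice 2D acquisitions: an :class:`ImageSeries`
is a stack of frames indexed by a physical axis (b-value, repetition time,
echo time, or dynamic-scan time), an :class:`ROIMask` selects tumor voxels,
and a :class:`ParameterMap` holds one fitted quantity per voxel together with
a per-voxel validity flag.

Series and maps serialize to NIfTI with a JSON sidecar carrying the axis
metadata that NIfTI itself has no convention for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

AXIS_KINDS = ("b_value", "repetition_time", "echo_time", "dynamic_time")

#: units conventionally attached to each axis kind
AXIS_UNITS = {
    "b_value": "s/mm^2",
    "repetition_time": "ms",
    "echo_time": "ms",
    "dynamic_time": "s",
}


@dataclass
class ImageSeries:
    """Stack of 2D frames indexed by a strictly increasing physical axis.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, ny, nx)`` with nonnegative intensities
        in arbitrary units.
    axis_kind
        One of ``b_value`` (s/mm^2), ``repetition_time`` (ms),
        ``echo_time`` (ms) or ``dynamic_time`` (s).
    axis_values
        One value per frame, strictly increasing.
    pixel_spacing
        In-plane voxel edge lengths in mm, ``(dy, dx)``.
    slice_thickness
        Slice thickness in mm.
    """

    frames: np.ndarray
    axis_kind: str
    axis_values: np.ndarray
    pixel_spacing: tuple[float, float] = (0.375, 0.375)
    slice_thickness: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_frames, ny, nx)")
        if self.frames.shape[0] != self.axis_values.size or self.axis_values.size < 1:
            raise ValueError("need one axis value per frame (and at least one frame)")
        if np.any(np.diff(self.axis_values) <= 0):
            raise ValueError("axis_values must be strictly increasing")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be nonnegative")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        self.slice_thickness = float(self.slice_thickness)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ROIMask:
    """Binary region-of-interest mask over one image grid."""

    grid: np.ndarray
    label: str = "tumor"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2D")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def require_nonempty(self) -> None:
        if self.n_voxels == 0:
            raise ValueError(f"mask {self.label!r} selects no voxels")


@dataclass
class ParameterMap:
    """One fitted quantity per voxel with a per-voxel validity flag.

    ``values`` are only meaningful (and guaranteed finite) where ``valid``
    is set; ``fit_rmse`` optionally carries the per-voxel residual RMS of
    the fit that produced the map.
    """

    values: np.ndarray
    name: str
    units: str
    valid: np.ndarray
    fit_rmse: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share one grid")
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite wherever valid")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape

    def masked_values(self, mask: ROIMask) -> np.ndarray:
        """Row-major vector of valid values inside ``mask``."""
        sel = mask.grid & self.valid
        return self.values[sel]


def _affine(pixel_spacing: tuple[float, float], slice_thickness: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = pixel_spacing[1]
    aff[1, 1] = pixel_spacing[0]
    aff[2, 2] = slice_thickness
    return aff


def save_series(series: ImageSeries, path: str | Path) -> None:
    """Write an ImageSeries as NIfTI (x, y, 1, t) plus a JSON sidecar."""
    path = Path(path)
    data = np.transpose(series.frames, (2, 1, 0))[:, :, np.newaxis, :]
    img = nib.Nifti1Image(data, _affine(series.pixel_spacing, series.slice_thickness))
    nib.save(img, str(path))
    sidecar = {
        "axis_kind": series.axis_kind,
        "axis_units": AXIS_UNITS[series.axis_kind],
        "axis_values": series.axis_values.tolist(),
        "pixel_spacing_mm": list(series.pixel_spacing),
        "slice_thickness_mm": series.slice_thickness,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))


def load_series(path: str | Path) -> ImageSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    frames = np.transpose(data[:, :, 0, :], (2, 1, 0))
    meta = json.loads(_sidecar_path(path).read_text())
    return ImageSeries(
        frames=frames,
        axis_kind=meta["axis_kind"],
        axis_values=np.asarray(meta["axis_values"], dtype=float),
        pixel_spacing=tuple(meta["pixel_spacing_mm"]),
        slice_thickness=meta["slice_thickness_mm"],
    )


def save_map(pmap: ParameterMap, path: str | Path,
             pixel_spacing: tuple[float, float] = (0.375, 0.375),
             slice_thickness: float = 1.0) -> None:
    """Write a ParameterMap as NIfTI; validity mask goes into the sidecar."""
    path = Path(path)
    data = pmap.values.T[:, :, np.newaxis]
    img = nib.Nifti1Image(data, _affine(pixel_spacing, slice_thickness))
    nib.save(img, str(path))
    sidecar = {
        "name": pmap.name,
        "units": pmap.units,
        "valid": pmap.valid.astype(int).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def load_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)[:, :, 0].T
    meta = json.loads(_sidecar_path(path).read_text())
    return ParameterMap(
        values=values,
        name=meta["name"],
        units=meta["units"],
        valid=np.asarray(meta["valid"], dtype=bool),
    )


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")
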