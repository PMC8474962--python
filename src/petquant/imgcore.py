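"""Core data model: image volumes, frame schedules, masks, scan metadata, and I/O.

Geometry convention: 0-based voxel indices; world coordinates are axis-aligned,
``world = origin + index * spacing`` (no shear, no rotation). All volumes of a
study are resampled onto a declared reference grid before any cross-modality
comparison; masks move between grids by nearest-neighbour resampling only.

Interchange formats: NIfTI-1 for volumes and masks (masks as uint8 {0,1}),
CSV (``frame,start_s,duration_s``) for frame schedules, JSON sidecars for
per-scan metadata, CSV for cohort tables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Units",
    "ImageVolume",
    "FrameSchedule",
    "DynamicSeries",
    "VOIMask",
    "TimeActivityCurve",
    "ScanMeta",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_schedule",
    "write_schedule",
    "read_dynamic",
    "write_dynamic",
    "resample_mask_to",
]


class Units(str, Enum):
    """Intensity units carried by every volume; operations refuse mismatches."""

    BQ_PER_ML = "Bq_per_ml"
    SUV = "SUV"
    SIGNAL_AU = "signal_au"
    MM2_PER_S = "mm2_per_s"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with voxel spacing (mm), world origin (mm) and units."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: Units = Units.UNKNOWN

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3D array, got ndim={arr.ndim}")
        if any(d < 1 for d in arr.shape):
            raise ValueError(f"all dimensions must be >= 1, got shape {arr.shape}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three strictly positive mm values, got {self.spacing}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        object.__setattr__(self, "units", Units(self.units))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """dx*dy*dz in mm^3 (0.064 mm^3 for the default 0.4 mm PET grid)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def with_values(self, values: np.ndarray, units: Units | None = None) -> "ImageVolume":
        """Same grid, new values (and optionally new units)."""
        return replace(self, values=values, units=self.units if units is None else Units(units))

    def same_grid(self, other: "ImageVolume | VOIMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic acquisition, in seconds from injection."""

    starts: np.ndarray
    durations: np.ndarray
    contiguous: bool = True

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise ValueError("starts and durations must be 1D arrays of equal length")
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(starts < 0):
            raise ValueError("frame starts must be >= 0 s")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be > 0 s")
        if self.contiguous and starts.size > 1:
            if not np.allclose(starts[1:], starts[:-1] + durations[:-1]):
                raise ValueError("schedule declared contiguous but start[i+1] != start[i] + duration[i]")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)

    def __len__(self) -> int:
        return int(self.starts.size)

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.starts + self.durations / 2.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.durations.sum())

    @classmethod
    def one_hour_scheme(cls) -> "FrameSchedule":
        """The 1-h dynamic scheme: 5x2 s, 5x10 s, 2x120 s, 3x300 s, 4x600 s."""
        durations = np.array([2.0] * 5 + [10.0] * 5 + [120.0] * 2 + [300.0] * 3 + [600.0] * 4)
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts=starts, durations=durations, contiguous=True)


@dataclass(frozen=True)
class DynamicSeries:
    """An ordered stack of same-grid frames plus its frame schedule."""

    frames: tuple[ImageVolume, ...]
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) == 0:
            raise ValueError("DynamicSeries requires at least one frame")
        if len(frames) != len(self.schedule):
            raise ValueError(
                f"frame count ({len(frames)}) does not match schedule length ({len(self.schedule)})"
            )
        ref = frames[0]
        for i, f in enumerate(frames[1:], start=1):
            if not ref.same_grid(f) or f.units != ref.units:
                raise ValueError(f"frame {i} grid/units differ from frame 0")
        object.__setattr__(self, "frames", frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def grid(self) -> ImageVolume:
        return self.frames[0]

    def as_4d(self) -> np.ndarray:
        """(nx, ny, nz, nframes) array view of the series."""
        return np.stack([f.values for f in self.frames], axis=-1)


@dataclass(frozen=True)
class VOIMask:
    """A boolean volume of interest congruent to a reference grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = "voi"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values).astype(bool)
        if arr.ndim != 3:
            raise ValueError(f"VOIMask requires a 3D array, got ndim={arr.ndim}")
        sp = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in sp):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return self.count == 0

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @classmethod
    def like(cls, ref: ImageVolume, values: np.ndarray, label: str = "voi") -> "VOIMask":
        return cls(values=values, spacing=ref.spacing, origin=ref.origin, label=label)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame mid-times (min) and mean concentration per frame (kBq/ml or SUV).

    ``durations_min``, when known, records the frame lengths; downstream
    quadrature can then treat each value as an exact interval average instead
    of a point sample.
    """

    times_min: np.ndarray
    values: np.ndarray
    units: Units = Units.BQ_PER_ML
    label: str = "tac"
    durations_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1D arrays of equal length")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)
        if self.durations_min is not None:
            d = np.asarray(self.durations_min, dtype=float)
            if d.shape != t.shape:
                raise ValueError("durations must match times in length")
            object.__setattr__(self, "durations_min", d)

    def __len__(self) -> int:
        return int(self.times_min.size)


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan bookkeeping needed for SUV scaling and kinetic modeling.

    ``injected_dose_mbq`` is the dose at assay; ``assay_time_offset_min`` is
    the assay time relative to injection (positive = assayed before injection,
    so the dose decays toward injection).
    """

    injected_dose_mbq: float
    body_weight_g: float
    blood_glucose_mmol_l: float = 6.0
    assay_time_offset_min: float = 0.0
    mouse_id: str = ""
    week: int | None = None
    arm: str = ""

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be > 0 MBq")
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be > 0 g")
        if self.blood_glucose_mmol_l <= 0:
            raise ValueError("blood glucose must be > 0 mmol/l")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanMeta":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine_from(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _units_sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a 3D volume as NIfTI-1 with a JSON units sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float64), _affine_from(volume.spacing, volume.origin))
    nib.save(img, str(path))
    _units_sidecar(path).write_text(json.dumps({"units": volume.units.value}))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a 3D NIfTI volume.

    Negative spacings in the affine are normalized to positive with the
    corresponding data axis flipped (and the origin moved to the new first
    voxel), so callers always see a positive-spacing, axis-aligned grid.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # malformed file
        raise ValueError(f"cannot read {path} as a NIfTI volume: {exc}") from exc
    if data.ndim == 4 and data.shape[3] > 1:
        raise ValueError(f"{path} is 4D; use read_dynamic with a frame schedule")
    if data.ndim == 4:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D; expected a 3D volume")
    aff = img.affine
    spacing = []
    origin = np.array(aff[:3, 3], dtype=float)
    values = np.asarray(data, dtype=np.float64)
    for ax in range(3):
        step = float(aff[ax, ax])
        if step == 0:
            raise ValueError(f"{path}: affine is not axis-aligned on axis {ax}")
        if step < 0:
            # flip the axis so spacing is positive; origin moves to the other end
            values = np.flip(values, axis=ax)
            origin[ax] = origin[ax] + step * (values.shape[ax] - 1)
            step = -step
        spacing.append(step)
    units = Units.UNKNOWN
    sidecar = _units_sidecar(path)
    if sidecar.exists():
        units = Units(json.loads(sidecar.read_text()).get("units", "unknown"))
    return ImageVolume(values=values, spacing=tuple(spacing), origin=tuple(origin), units=units)


def write_mask(mask: VOIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine_from(mask.spacing, mask.origin))
    nib.save(img, str(Path(path)))


def read_mask(path: str | Path, label: str = "voi") -> VOIMask:
    vol = read_volume(path)
    return VOIMask(values=vol.values > 0.5, spacing=vol.spacing, origin=vol.origin, label=label)


def write_schedule(schedule: FrameSchedule, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(len(schedule)),
            "start_s": schedule.starts,
            "duration_s": schedule.durations,
        }
    ).to_csv(path, index=False)


def read_schedule(path: str | Path, contiguous: bool = True) -> FrameSchedule:
    """Read a ``frame,start_s,duration_s`` CSV; rows may appear in any order."""
    df = pd.read_csv(path)
    required = {"frame", "start_s", "duration_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"schedule CSV must have columns {sorted(required)}, got {list(df.columns)}")
    df = df.sort_values("start_s")
    return FrameSchedule(
        starts=df["start_s"].to_numpy(float),
        durations=df["duration_s"].to_numpy(float),
        contiguous=contiguous,
    )


def write_dynamic(series: DynamicSeries, path: str | Path, schedule_path: str | Path) -> None:
    grid = series.grid
    img = nib.Nifti1Image(series.as_4d().astype(np.float64), _affine_from(grid.spacing, grid.origin))
    nib.save(img, str(Path(path)))
    _units_sidecar(Path(path)).write_text(json.dumps({"units": grid.units.value}))
    write_schedule(series.schedule, schedule_path)


def read_dynamic(path: str | Path, schedule_path: str | Path) -> DynamicSeries:
    """Read a 4D NIfTI + schedule CSV into a DynamicSeries.

    The frame count must match the schedule; frames are split on the 4th axis.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValueError(f"{path} is {data.ndim}D; expected 4D")
    schedule = read_schedule(schedule_path)
    if data.shape[3] != len(schedule):
        raise ValueError(
            f"frame-count mismatch: volume has {data.shape[3]} frames, schedule has {len(schedule)}"
        )
    aff = img.affine
    spacing = tuple(float(abs(aff[ax, ax])) for ax in range(3))
    origin = tuple(float(aff[ax, 3]) for ax in range(3))
    units = Units.UNKNOWN
    sidecar = _units_sidecar(path)
    if sidecar.exists():
        units = Units(json.loads(sidecar.read_text()).get("units", "unknown"))
    frames = tuple(
        ImageVolume(values=np.asarray(data[..., i], dtype=np.float64), spacing=spacing, origin=origin, units=units)
        for i in range(data.shape[3])
    )
    return DynamicSeries(frames=frames, schedule=schedule)


# ---------------------------------------------------------------------------
# Mask resampling


def resample_mask_to(mask: VOIMask, target: ImageVolume) -> VOIMask:
    """Nearest-neighbour resample of ``mask`` onto the grid of ``target``.

    World-coordinate overlap is preserved to within one voxel. Disjoint fields
    of view yield an empty mask with a warning.
    """
    if mask.shape == target.shape and np.allclose(mask.spacing, target.spacing) and np.allclose(
        mask.origin, target.origin
    ):
        return VOIMask.like(target, mask.values.copy(), label=mask.label)

    out = np.zeros(target.shape, dtype=bool)
    # world coordinates of the target voxel centers, mapped to source indices
    idx = []
    inside = np.ones(target.shape, dtype=bool)
    for ax in range(3):
        coords = target.origin[ax] + np.arange(target.shape[ax]) * target.spacing[ax]
        src = np.rint((coords - mask.origin[ax]) / mask.spacing[ax]).astype(int)
        valid = (src >= 0) & (src < mask.shape[ax])
        shape = [1, 1, 1]
        shape[ax] = -1
        idx.append(np.clip(src, 0, mask.shape[ax] - 1).reshape(shape))
        inside &= valid.reshape(shape)
    out[inside] = mask.values[idx[0], idx[1], idx[2]][inside]
    result = VOIMask.like(target, out, label=mask.label)
    if result.is_empty and not mask.is_empty:
        warnings.warn(
            f"mask '{mask.label}' has no overlap with the target field of view; result is empty",
            stacklevel=2,
        )
    return result
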