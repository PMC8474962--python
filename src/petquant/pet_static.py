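"""SUV scaling, tumor segmentation rules, and static metabolic metrics.

Two segmentation rules are implemented, mirroring common practice in
preclinical FDG-PET:

* 40%-of-SUVmax isocontour: find SUVmax inside a search region (minus
  exclusions), threshold at ``fraction * SUVmax``, and keep the 26-connected
  component containing the max voxel. Seeding at the max keeps the VOI a
  single lesion region instead of grabbing kidneys or bladder.
* fixed SUV threshold (default 2.5): all voxels at or above the threshold in
  the search region, no connectivity filter. An empty result is allowed and
  flagged rather than raised — small or faint lesions can fall entirely
  below a fixed threshold.

SUV = C[Bq/ml] * body_weight[g] / injected_dose[Bq] with tissue density
1 g/ml; the activity volume must already be decay-corrected to injection.
No partial-volume correction is applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .imgcore import ImageVolume, ScanMeta, Units, VOIMask

__all__ = [
    "SegRule",
    "StaticMetrics",
    "decay_correct_dose",
    "to_suv",
    "segment_iso40",
    "segment_fixed",
    "static_metrics",
    "liver_reference",
    "F18_HALF_LIFE_MIN",
]

F18_HALF_LIFE_MIN = 109.77


class SegRule(str, Enum):
    ISO40 = "iso40"
    FIXED = "fixed"


@dataclass(frozen=True)
class StaticMetrics:
    """Static tumor metrics for one VOI: SUVmax/mean, MTV (mm^3), TLG."""

    suv_max: float
    suv_mean: float
    mtv_mm3: float
    tlg: float
    threshold_used: float
    rule: SegRule

    def __post_init__(self) -> None:
        assert abs(self.tlg - self.suv_mean * self.mtv_mm3) <= 1e-9 * max(abs(self.tlg), 1.0)


def decay_correct_dose(dose_assayed_mbq: float, dt_min: float, half_life_min: float = F18_HALF_LIFE_MIN) -> float:
    """Decay the assayed dose over ``dt_min`` minutes (negative dt allowed)."""
    if half_life_min <= 0:
        raise ValueError("half-life must be > 0")
    return dose_assayed_mbq * 2.0 ** (-dt_min / half_life_min)


def to_suv(activity: ImageVolume, meta: ScanMeta) -> ImageVolume:
    """Convert a decay-corrected activity volume (Bq/ml) to SUV.

    SUV = C * weight / dose, with the dose first decayed from assay to
    injection time via ``meta.assay_time_offset_min``.
    """
    if activity.units != Units.BQ_PER_ML:
        raise ValueError(f"to_suv expects Bq/ml input, got units={activity.units.value}")
    dose_bq = decay_correct_dose(meta.injected_dose_mbq, meta.assay_time_offset_min) * 1e6
    suv = activity.values * (meta.body_weight_g / dose_bq)
    return activity.with_values(suv, units=Units.SUV)


def _effective_region(
    suv: ImageVolume, search: VOIMask, exclusions: list[VOIMask] | None
) -> np.ndarray:
    if suv.shape != search.shape:
        raise ValueError("search mask grid does not match image")
    region = search.values.copy()
    for ex in exclusions or []:
        if ex.shape != suv.shape:
            raise ValueError(f"exclusion mask '{ex.label}' grid does not match image")
        region &= ~ex.values
    return region


def segment_iso40(
    suv: ImageVolume,
    search: VOIMask,
    exclusions: list[VOIMask] | None = None,
    fraction: float = 0.40,
) -> tuple[VOIMask, float]:
    """Isocontour segmentation at ``fraction`` of SUVmax.

    Returns (mask, threshold). The mask is the 26-connected component of
    ``{SUV >= threshold}`` (within search minus exclusions) that contains the
    max voxel; >= is used rather than > so the max voxel always survives,
    including on degenerate uniform images. For display the threshold is
    conventionally rounded to 1 decimal (e.g. SUVmax 3.8 -> 1.5); the
    returned value is full precision.
    """
    region = _effective_region(suv, search, exclusions)
    if not region.any():
        raise ValueError("search region minus exclusions is empty")
    vals = np.where(region, suv.values, -np.inf)
    max_idx = np.unravel_index(np.argmax(vals), vals.shape)
    suv_max = float(vals[max_idx])
    threshold = fraction * suv_max
    above = region & (suv.values >= threshold)
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3), dtype=int))
    component = labels == labels[max_idx]
    return VOIMask.like(suv, component, label="tumor_iso40"), threshold


def segment_fixed(
    suv: ImageVolume,
    search: VOIMask,
    exclusions: list[VOIMask] | None = None,
    threshold: float = 2.5,
) -> VOIMask:
    """All voxels with SUV >= threshold inside search minus exclusions.

    No connectivity filter: the rule keeps every qualifying voxel, which is
    why bladder/kidney exclusion masks matter. Empty output is legal and
    warned about, not an error.
    """
    region = _effective_region(suv, search, exclusions)
    if not region.any():
        raise ValueError("search region minus exclusions is empty")
    mask = VOIMask.like(suv, region & (suv.values >= threshold), label="tumor_fixed")
    if mask.is_empty:
        warnings.warn(
            f"fixed-threshold segmentation at SUV {threshold} found no voxels", stacklevel=2
        )
    return mask


def static_metrics(
    suv: ImageVolume,
    mask: VOIMask,
    rule: SegRule = SegRule.ISO40,
    threshold_used: float = float("nan"),
) -> StaticMetrics:
    """SUVmean/max, MTV and TLG over a segmented VOI."""
    if suv.units != Units.SUV:
        raise ValueError("static_metrics expects an SUV volume")
    if suv.shape != mask.shape:
        raise ValueError("mask grid does not match image")
    if mask.is_empty:
        raise ValueError("cannot compute metrics on an empty mask")
    inside = suv.values[mask.values]
    suv_mean = float(inside.mean())
    mtv = mask.count * suv.voxel_volume_mm3
    return StaticMetrics(
        suv_max=float(inside.max()),
        suv_mean=suv_mean,
        mtv_mm3=mtv,
        tlg=suv_mean * mtv,
        threshold_used=float(threshold_used),
        rule=rule,
    )


def liver_reference(suv: ImageVolume, liver_mask: VOIMask) -> float:
    """Mean liver SUV, reported per scan as an uptake-normalization QC metric."""
    if suv.shape != liver_mask.shape:
        raise ValueError("liver mask grid does not match image")
    if liver_mask.is_empty:
        raise ValueError("liver mask is empty")
    return float(suv.values[liver_mask.values].mean())
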