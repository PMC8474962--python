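"""ADC parametric mapping from DWI and anatomic tumor volumetry.

ADC is fitted per voxel from the mono-exponential signal decay
``S_b = S0 * exp(-b * ADC)``. With exactly two b-values (the 0 / 1000 s/mm^2
protocol) this reduces to the two-point log formula; with more b-values an
ordinary least-squares line is fitted to -ln(S_b) versus b. Voxels with any
nonpositive signal cannot be log-transformed and are flagged invalid with a
negative sentinel, excluded from all statistics — excluding rather than
clipping avoids biasing ADC low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imgcore import ImageVolume, Units, VOIMask

__all__ = ["ADCMap", "compute_adc_map", "tumor_volume", "adc_mean", "INVALID_ADC"]

#: sentinel for voxels where the log-linear fit is undefined
INVALID_ADC = -1.0


@dataclass(frozen=True)
class ADCMap:
    """An ADC volume (mm^2/s) plus fit provenance.

    ``volume.values`` holds the fitted ADC; invalid voxels carry
    :data:`INVALID_ADC` and must be excluded via :attr:`valid`.
    """

    volume: ImageVolume
    b_values: tuple[float, ...]
    method: str

    @property
    def valid(self) -> np.ndarray:
        return self.volume.values != INVALID_ADC


def compute_adc_map(dwi: list[tuple[float, ImageVolume]]) -> ADCMap:
    """Fit an ADC map from a list of (b-value s/mm^2, signal volume) pairs.

    Two b-values: ADC = ln(S_b0/S_b1) / (b1 - b0). More: least-squares slope
    of -ln(S_b) vs b. Requires b = 0 among the inputs and congruent grids.
    """
    if len(dwi) < 2:
        raise ValueError("need >= 2 b-values to fit ADC")
    bs = np.array([b for b, _ in dwi], dtype=float)
    if len(set(bs.tolist())) != len(bs):
        raise ValueError("b-values must be distinct")
    if 0.0 not in bs:
        raise ValueError("a b=0 image is required")
    vols = [v for _, v in dwi]
    ref = vols[0]
    for v in vols[1:]:
        if not ref.same_grid(v):
            raise ValueError("all DWI volumes must share one grid")
    order = np.argsort(bs)
    bs = bs[order]
    sig = np.stack([vols[i].values for i in order], axis=-1)

    valid = np.all(sig > 0, axis=-1)
    adc = np.full(ref.shape, INVALID_ADC, dtype=float)
    if not np.any(valid):
        raise ValueError("no voxel has positive signal at every b-value; cannot fit ADC")
    logs = np.log(sig[valid])  # (nvalid, nb)
    if len(bs) == 2:
        adc[valid] = (logs[:, 0] - logs[:, 1]) / (bs[1] - bs[0])
        method = "two-point-log"
    else:
        # OLS slope of -ln(S) on b, closed form per voxel
        bc = bs - bs.mean()
        adc[valid] = -(logs @ bc) / (bc @ bc)
        method = "ols-log"
    vol = ImageVolume(values=adc, spacing=ref.spacing, origin=ref.origin, units=Units.MM2_PER_S)
    return ADCMap(volume=vol, b_values=tuple(bs.tolist()), method=method)


def tumor_volume(mask: VOIMask, spacing: tuple[float, float, float] | None = None) -> float:
    """Anatomic volume in mm^3: true-voxel count x voxel volume.

    This is the slice-summed segmented volume (vMRI) — each slice contributes
    its segmented area times slice thickness, which equals the voxel count
    times the voxel volume.
    """
    sp = mask.spacing if spacing is None else tuple(float(s) for s in spacing)
    if mask.is_empty:
        warnings.warn(f"mask '{mask.label}' is empty; volume is 0", stacklevel=2)
        return 0.0
    return mask.count * sp[0] * sp[1] * sp[2]


def adc_mean(adc: ADCMap, mask: VOIMask) -> float:
    """Whole-tumor mean ADC (mm^2/s) over valid in-mask voxels."""
    if adc.volume.shape != mask.shape:
        raise ValueError("mask grid does not match ADC map")
    sel = mask.values & adc.valid
    if not np.any(sel):
        raise ValueError("no valid ADC voxels inside the mask")
    return float(adc.volume.values[sel].mean())
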