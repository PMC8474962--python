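"""Digital phantoms with known ground truth for every analysis stage.

Everything downstream (ADC mapping, SUV metrics, Patlak kinetics, nuclei
counting, cohort statistics) is validated against these generators: noiseless
phantoms must be exactly invertible by the corresponding analysis operation,
and noisy phantoms carry the truth alongside so recovery error can be
measured.

Units follow small-animal PET conventions: activity concentration in kBq/ml,
time in minutes for kinetics (frame schedules are in seconds), rate constants
K1 [ml/min/ml] and k2, k3 [1/min], ADC in mm^2/s, b-values in s/mm^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .imgcore import (
    DynamicSeries,
    FrameSchedule,
    ImageVolume,
    TimeActivityCurve,
    Units,
    VOIMask,
)

__all__ = [
    "AIFParams",
    "TwoTCParams",
    "PhantomScene",
    "feng_aif",
    "simulate_2tc_tac",
    "frame_averaged_aif",
    "simulate_noisy_tac",
    "simulate_kinetic_cohort",
    "build_dynamic_phantom",
    "build_dwi_phantom",
    "build_nuclei_image",
    "EffectSpec",
    "simulate_cohort",
    "FINE_STEP_MIN",
]

#: fine-grid step for kinetic integration: 0.1 s, in minutes
FINE_STEP_MIN = 0.1 / 60.0


@dataclass(frozen=True)
class AIFParams:
    """Tri-exponential bolus input function (Feng model).

    Cp(t) = (A1*t - A2 - A3) e^(-lam1 t) + A2 e^(-lam2 t) + A3 e^(-lam3 t),
    which is zero at t = 0 by construction. Defaults are scaled to a mouse
    bolus whose downstream tumor uptake lands in a realistic SUV range for an
    ~8.3 MBq injection in a ~25 g animal.
    """

    A1: float = 12000.0  # kBq/ml/min
    A2: float = 330.0  # kBq/ml
    A3: float = 310.0  # kBq/ml
    lam1: float = 4.13  # 1/min
    lam2: float = 0.12  # 1/min
    lam3: float = 0.0105  # 1/min

    def __post_init__(self) -> None:
        if min(self.lam1, self.lam2, self.lam3) <= 0:
            raise ValueError("all decay rates must be > 0")


@dataclass(frozen=True)
class TwoTCParams:
    """Irreversible two-tissue-compartment FDG kinetics (k4 = 0).

    Defaults give Ki = K1*k3/(k2+k3) ~ 0.039 ml/min/ml, the cohort-mean
    net influx (MR_FDG ~ 0.39 umol/(min*ml) at glucose/LC = 10).
    """

    K1: float = 0.12  # ml/min/ml
    k2: float = 0.25  # 1/min
    k3: float = 0.12  # 1/min
    vb: float = 0.05  # blood volume fraction

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0 <= self.vb < 1:
            raise ValueError("vb must be in [0, 1)")

    @property
    def ki(self) -> float:
        """Net influx constant Ki = K1*k3/(k2+k3); 0 when k2 + k3 = 0."""
        denom = self.k2 + self.k3
        return self.K1 * self.k3 / denom if denom > 0 else 0.0


def feng_aif(params: AIFParams, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the bolus input function at time(s) ``t`` (minutes).

    Raises if the parameter set produces negative concentration anywhere on
    a 0-60 min validation grid.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")

    def _cp(x: np.ndarray) -> np.ndarray:
        p = params
        return (
            (p.A1 * x - p.A2 - p.A3) * np.exp(-p.lam1 * x)
            + p.A2 * np.exp(-p.lam2 * x)
            + p.A3 * np.exp(-p.lam3 * x)
        )

    check = _cp(np.linspace(0.0, 60.0, 6001))
    if np.any(check < -1e-9):
        raise ValueError("AIF parameters produce negative Cp on [0, 60] min")
    out = _cp(tt)
    return float(out) if np.isscalar(t) else out


def _fine_grid(schedule: FrameSchedule, step_min: float = FINE_STEP_MIN) -> np.ndarray:
    """Uniform fine grid (minutes) from 0 to the end of the last frame."""
    t_end = float(schedule.starts[-1] + schedule.durations[-1]) / 60.0
    n = int(round(t_end / step_min))
    return np.linspace(0.0, t_end, n + 1)


def _solve_2tc_fine(aif: AIFParams, kin: TwoTCParams, t: np.ndarray) -> np.ndarray:
    """Tissue concentration CT on a uniform fine grid.

    The linear ODE system
        dC1/dt = K1 Cp - (k2+k3) C1,    dC2/dt = k3 C1
    is integrated by an exact exponential update per step (Cp treated as
    linear within each step), realised as an IIR filter; C2 by trapezoid.
    """
    h = t[1] - t[0]
    cp = np.asarray(feng_aif(aif, t))
    a = kin.k2 + kin.k3
    c0, c1 = cp[:-1], cp[1:]
    if a > 0:
        E = np.exp(-a * h)
        # integral of (linear Cp) * exp(-a*(h-s)) over one step
        drive = kin.K1 * (c0 * (1.0 - E) / a + (c1 - c0) * (a * h - (1.0 - E)) / (a * a * h))
        x = np.concatenate([[0.0], drive])
        C1 = signal.lfilter([1.0], [1.0, -E], x)
    else:
        C1 = kin.K1 * np.concatenate([[0.0], np.cumsum(h * (c0 + c1) / 2.0)])
    if kin.k3 > 0:
        inc = kin.k3 * h * (C1[:-1] + C1[1:]) / 2.0
        C2 = np.concatenate([[0.0], np.cumsum(inc)])
    else:
        C2 = np.zeros_like(C1)
    return (1.0 - kin.vb) * (C1 + C2) + kin.vb * cp


def _frame_average(curve: np.ndarray, t: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Time-average of a fine-grid curve over each frame interval."""
    h = t[1] - t[0]
    out = np.empty(len(schedule))
    for i, (s, d) in enumerate(zip(schedule.starts / 60.0, schedule.durations / 60.0)):
        j0 = int(round(s / h))
        j1 = int(round((s + d) / h))
        j1 = min(j1, len(curve) - 1)
        out[i] = np.trapezoid(curve[j0 : j1 + 1], dx=h) / ((j1 - j0) * h)
    return out


def simulate_2tc_tac(
    aif: AIFParams, kin: TwoTCParams, schedule: FrameSchedule
) -> TimeActivityCurve:
    """Frame-averaged tissue curve of the irreversible 2TC model.

    Each frame value is the average of CT(t) over the frame interval (what a
    reconstructed frame measures), not a point sample at the mid-time.
    """
    t = _fine_grid(schedule)
    ct = _solve_2tc_fine(aif, kin, t)
    return TimeActivityCurve(
        times_min=schedule.mid_times_min,
        values=_frame_average(ct, t, schedule),
        label="tumor_2tc",
        durations_min=schedule.durations / 60.0,
    )


def frame_averaged_aif(aif: AIFParams, schedule: FrameSchedule) -> TimeActivityCurve:
    """The input function averaged over each frame, as an IDIF would see it."""
    t = _fine_grid(schedule)
    cp = np.asarray(feng_aif(aif, t))
    return TimeActivityCurve(
        times_min=schedule.mid_times_min,
        values=_frame_average(cp, t, schedule),
        label="aif",
        durations_min=schedule.durations / 60.0,
    )


#: detector sensitivity in counts per decay used by the count-based noise
#: model; chosen in the range of modern small-animal PET ring sensitivity
#: less reconstruction losses.
DEFAULT_SENSITIVITY = 0.05


def simulate_noisy_tac(
    tac: TimeActivityCurve,
    schedule: FrameSchedule,
    voi_volume_ml: float,
    rng: np.random.Generator,
    sensitivity: float = DEFAULT_SENSITIVITY,
) -> TimeActivityCurve:
    """Add count-statistics noise to a region-mean curve.

    Expected counts per frame are concentration x VOI volume x frame duration
    x sensitivity; a Poisson draw is converted back to concentration. Short
    early frames are therefore noisy and long late frames quiet, as in real
    reconstructions.
    """
    if voi_volume_ml <= 0 or sensitivity <= 0:
        raise ValueError("voi_volume_ml and sensitivity must be > 0")
    factor = 1000.0 * voi_volume_ml * schedule.durations * sensitivity  # counts per kBq/ml
    expected = np.clip(tac.values, 0.0, None) * factor
    noisy = rng.poisson(expected) / factor
    return replace(tac, values=noisy, label=tac.label + "_noisy")


def simulate_kinetic_cohort(
    n_scans: int = 24,
    seed: int = 42,
    aif: AIFParams | None = None,
    schedule: FrameSchedule | None = None,
    tumor_volume_ml: float = 0.3,
    idif_volume_ml: float = 7 * 0.4**3 / 1000.0,
    sensitivity: float = DEFAULT_SENSITIVITY,
    noise: bool = True,
) -> list[dict]:
    """A cohort of noisy (tumor TAC, IDIF) pairs with known Ki.

    Per scan, Ki is drawn uniformly over the physiologic band implied by the
    cohort's metabolic-rate range (MR_FDG 0.12-0.61 at glucose/LC = 10, i.e.
    Ki 0.012-0.061 ml/min/ml) and k3 is back-computed from fixed K1, k2.
    Returns a list of dicts with keys ``tumor``, ``idif``, ``kin``,
    ``ki_true``.
    """
    rng = np.random.default_rng(seed)
    aif = aif or AIFParams()
    schedule = schedule or FrameSchedule.one_hour_scheme()
    scans = []
    for _ in range(n_scans):
        ki = rng.uniform(0.015, 0.055)
        K1, k2 = 0.12, 0.25
        k3 = ki * k2 / (K1 - ki)  # so that K1*k3/(k2+k3) == ki
        kin = TwoTCParams(K1=K1, k2=k2, k3=k3, vb=0.05)
        tumor = simulate_2tc_tac(aif, kin, schedule)
        idif = frame_averaged_aif(aif, schedule)
        if noise:
            tumor = simulate_noisy_tac(tumor, schedule, tumor_volume_ml, rng, sensitivity)
            idif = simulate_noisy_tac(idif, schedule, idif_volume_ml, rng, sensitivity)
        scans.append({"tumor": tumor, "idif": idif, "kin": kin, "ki_true": kin.ki})
    return scans


# ---------------------------------------------------------------------------
# 4D image phantom


@dataclass(frozen=True)
class PhantomScene:
    """Geometry, blur, and noise description of the abdominal PET phantom.

    All positions/sizes in mm on an axis-aligned grid with the PET voxel size.
    The tumor carries a center-to-rim uptake gradient (``tumor_heterogeneity``
    scales tissue uptake by 1 + amp*(1 - (r/R)^2)) so SUVmax exceeds SUVmean
    as in real lesions.
    """

    shape: tuple[int, int, int] = (48, 48, 64)
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    tumor_center_mm: tuple[float, float, float] = (12.0, 9.0, 13.0)
    tumor_semiaxes_mm: tuple[float, float, float] = (4.5, 4.0, 4.0)
    tumor_heterogeneity: float = 2.0
    cava_center_xy_mm: tuple[float, float] = (4.0, 10.0)
    cava_radius_mm: float = 1.1
    kidney_centers_mm: tuple = ((6.0, 15.0, 20.0), (15.5, 15.0, 20.0))
    kidney_radius_mm: float = 1.8
    bladder_center_mm: tuple[float, float, float] = (9.5, 4.0, 4.5)
    bladder_radius_mm: float = 2.2
    psf_fwhm_mm: float = 1.0
    sensitivity: float = DEFAULT_SENSITIVITY
    background_kbq_ml: float = 30.0
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.tumor_semiaxes_mm) <= 0:
            raise ValueError("tumor semi-axes must be > 0")
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        for c, a in zip(self.tumor_center_mm, self.tumor_semiaxes_mm):
            if c - a < 0 or c + a > max(extent):
                pass  # bounds checked structure-wise below
        for ax in range(3):
            if not 0 <= self.tumor_center_mm[ax] <= extent[ax]:
                raise ValueError("tumor center outside grid")


def _coords_mm(scene: PhantomScene) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) + 0.5) * s for n, s in zip(scene.shape, scene.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _scene_masks(scene: PhantomScene) -> dict[str, np.ndarray]:
    X, Y, Z = _coords_mm(scene)
    cx, cy, cz = scene.tumor_center_mm
    ax, ay, az = scene.tumor_semiaxes_mm
    tumor_r2 = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2
    tumor = tumor_r2 <= 1.0
    vx, vy = scene.cava_center_xy_mm
    cava = ((X - vx) ** 2 + (Y - vy) ** 2) <= scene.cava_radius_mm**2
    kidneys = np.zeros(scene.shape, dtype=bool)
    for kc in scene.kidney_centers_mm:
        kidneys |= ((X - kc[0]) ** 2 + (Y - kc[1]) ** 2 + (Z - kc[2]) ** 2) <= scene.kidney_radius_mm**2
    bc = scene.bladder_center_mm
    bladder = ((X - bc[0]) ** 2 + (Y - bc[1]) ** 2 + (Z - bc[2]) ** 2) <= scene.bladder_radius_mm**2
    masks = {"tumor": tumor, "cava": cava, "kidneys": kidneys, "bladder": bladder}
    # overlap check: structures must be disjoint
    total = sum(m.astype(int) for m in masks.values())
    if np.any(total > 1):
        raise ValueError("phantom structures overlap; adjust the scene geometry")
    masks["tumor_r2"] = tumor_r2  # stashed for the heterogeneity profile
    return masks


def build_dynamic_phantom(
    scene: PhantomScene,
    aif: AIFParams | None = None,
    kin: TwoTCParams | None = None,
    schedule: FrameSchedule | None = None,
    noise: bool = True,
    psf: bool = True,
) -> tuple[DynamicSeries, dict]:
    """Voxelize a 1-h dynamic FDG acquisition with known kinetic truth.

    Tumor voxels follow the 2TC curve (scaled by the heterogeneity profile),
    the cava carries the input function, kidneys and bladder carry excretion
    ramps, background a low constant. The stack is blurred by the scanner PSF
    and Poisson count noise is applied per voxel per frame.

    Returns the series plus a truth dict: VOI masks, the noiseless tumor TAC,
    the true Cp on the frame grid, and Ki.
    """
    aif = aif or AIFParams()
    kin = kin or TwoTCParams()
    schedule = schedule or FrameSchedule.one_hour_scheme()
    rng = np.random.default_rng(scene.seed)
    masks = _scene_masks(scene)
    t = _fine_grid(schedule)
    cp_fine = np.asarray(feng_aif(aif, t))
    ct_fine = _solve_2tc_fine(aif, kin, t)
    tissue_fine = ct_fine - kin.vb * cp_fine  # (1-vb)(C1+C2): the profiled part

    tmid = t  # fine time in minutes
    kidney_fine = 0.35 * cp_fine + 900.0 * (tmid / 60.0)
    bladder_fine = 1500.0 * (tmid / 60.0) ** 1.5
    bg_fine = scene.background_kbq_ml * (1.0 - np.exp(-tmid / 2.0))

    frames_curves = {
        "cp": _frame_average(cp_fine, t, schedule),
        "tissue": _frame_average(tissue_fine, t, schedule),
        "kidney": _frame_average(kidney_fine, t, schedule),
        "bladder": _frame_average(bladder_fine, t, schedule),
        "bg": _frame_average(bg_fine, t, schedule),
        "ct": _frame_average(ct_fine, t, schedule),
    }

    # center-to-rim uptake gradient, normalized to unit mean over the tumor so
    # the VOI-mean TAC stays exactly the 2TC curve regardless of heterogeneity
    amp = scene.tumor_heterogeneity
    raw = 1.0 + amp * np.clip(1.0 - masks["tumor_r2"], 0.0, None)
    profile = np.where(masks["tumor"], raw / raw[masks["tumor"]].mean(), 0.0)
    voxvol_ml = float(np.prod(scene.spacing)) / 1000.0
    sigma_vox = (scene.psf_fwhm_mm / 2.3548) / np.asarray(scene.spacing)

    frames = []
    for i in range(len(schedule)):
        vol = np.full(scene.shape, frames_curves["bg"][i])
        vol[masks["tumor"]] = (
            frames_curves["tissue"][i] * profile[masks["tumor"]]
            + kin.vb * frames_curves["cp"][i]
        )
        vol[masks["cava"]] = frames_curves["cp"][i]
        vol[masks["kidneys"]] = frames_curves["kidney"][i]
        vol[masks["bladder"]] = frames_curves["bladder"][i]
        vol *= 1000.0  # curves are kBq/ml; voxel values are stored in Bq/ml
        if psf and scene.psf_fwhm_mm > 0:
            vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
        if noise:
            factor = voxvol_ml * schedule.durations[i] * scene.sensitivity
            vol = rng.poisson(np.clip(vol, 0, None) * factor) / factor
        frames.append(
            ImageVolume(values=vol, spacing=scene.spacing, units=Units.BQ_PER_ML)
        )
    series = DynamicSeries(frames=tuple(frames), schedule=schedule)

    ref = series.grid
    truth = {
        "masks": {
            name: VOIMask.like(ref, masks[name], label=name)
            for name in ("tumor", "cava", "kidneys", "bladder")
        },
        "tumor_tac": TimeActivityCurve(
            times_min=schedule.mid_times_min,
            values=frames_curves["ct"] * 1000.0,  # Bq/ml, matching the frames
            label="tumor_truth",
            durations_min=schedule.durations / 60.0,
        ),
        "cp": TimeActivityCurve(
            times_min=schedule.mid_times_min,
            values=frames_curves["cp"] * 1000.0,
            label="cp_truth",
            durations_min=schedule.durations / 60.0,
        ),
        "ki_true": kin.ki,
        "kin": kin,
        "aif": aif,
        "seed": scene.seed,
    }
    return series, truth


# ---------------------------------------------------------------------------
# DWI phantom


def build_dwi_phantom(
    shape: tuple[int, int, int] = (64, 64, 12),
    spacing: tuple[float, float, float] = (0.3, 0.3, 1.0),
    tumor_center_mm: tuple[float, float, float] = (9.6, 9.6, 6.0),
    tumor_semiaxes_mm: tuple[float, float, float] = (5.0, 4.5, 4.0),
    tumor_adc: float = 1.07e-3,
    background_adc: float = 2.0e-3,
    adc_gradient: float = 0.15,
    b_values: tuple[float, ...] = (0.0, 1000.0),
    s0: float = 1000.0,
    sigma: float = 0.0,
    seed: int = 42,
) -> tuple[list[tuple[float, ImageVolume]], ImageVolume, VOIMask]:
    """Two-(or more-)b-value DWI stack with a known ADC map.

    The tumor is an ellipsoid whose ADC varies linearly from center
    (``tumor_adc*(1-adc_gradient)``) to rim (``tumor_adc*(1+adc_gradient)``)
    with volume-mean exactly ``tumor_adc``; signal decays mono-exponentially
    S_b = S0 exp(-b*ADC). Rician noise of scale ``sigma`` is applied to each
    b-value image when sigma > 0.

    Returns (stack as [(b, volume), ...], truth ADC map, tumor mask).
    """
    if len(b_values) < 2 or 0.0 not in b_values:
        raise ValueError("need >= 2 b-values including b=0")
    if tumor_adc <= 0 or background_adc <= 0:
        raise ValueError("ADC values must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    cx, cy, cz = tumor_center_mm
    ax, ay, az = tumor_semiaxes_mm
    r2 = ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2
    tumor = r2 <= 1.0
    # linear-in-r2 profile with zero volume-mean: mean of r2 over the ellipsoid is 3/5
    profile = 1.0 + adc_gradient * (r2 - 0.6) / 0.6
    adc = np.full(shape, background_adc)
    adc[tumor] = tumor_adc * profile[tumor]
    adc_map = ImageVolume(values=adc, spacing=spacing, units=Units.MM2_PER_S)
    stack = []
    for b in b_values:
        sig = s0 * np.exp(-b * adc)
        if sigma > 0:
            sig = np.sqrt((sig + sigma * rng.standard_normal(shape)) ** 2
                          + (sigma * rng.standard_normal(shape)) ** 2)
        stack.append(
            (float(b), ImageVolume(values=sig, spacing=spacing, units=Units.SIGNAL_AU))
        )
    mask = VOIMask(values=tumor, spacing=spacing, label="tumor")
    return stack, adc_map, mask


# ---------------------------------------------------------------------------
# Nuclei phantom


def build_nuclei_image(
    density_cells_per_mm2: float = 11.3e3,
    field_mm2: float = 0.25,
    pixel_size_um: float = 0.5,
    radius_um: float = 3.0,
    overlap_frac: float = 0.0,
    seed: int = 42,
) -> tuple[np.ndarray, int]:
    """Synthetic hematoxylin-like field: dark elliptical nuclei on a bright
    background, at a prescribed cell density.

    ``overlap_frac`` is the fraction of nuclei placed without a minimum
    separation constraint (allowed to merge); the rest keep >= 2.1 radii
    between centers. Returns (uint8 image, exact placed count).
    """
    if density_cells_per_mm2 <= 0:
        raise ValueError("density must be > 0")
    if not 0 <= overlap_frac <= 0.3:
        raise ValueError("overlap_frac must be in [0, 0.3]")
    n_target = int(round(density_cells_per_mm2 * field_mm2))
    area_um2 = field_mm2 * 1e6
    packing = n_target * np.pi * radius_um**2 / area_um2
    if packing > 0.5:
        raise ValueError(
            f"density {density_cells_per_mm2:.0f}/mm^2 infeasible for radius {radius_um} um "
            f"(packing fraction {packing:.2f} > 0.5)"
        )
    rng = np.random.default_rng(seed)
    side_um = np.sqrt(area_um2)
    npx = int(round(side_um / pixel_size_um))
    img = np.full((npx, npx), 220.0)

    margin = radius_um * 1.5
    n_free = int(round(n_target * overlap_frac))
    n_sep = n_target - n_free
    min_d2 = (2.1 * radius_um) ** 2
    centers: list[tuple[float, float]] = []
    # grid-accelerated dart throwing for the separated nuclei
    cell = 2.1 * radius_um
    ngrid = max(1, int(side_um / cell))
    grid: dict[tuple[int, int], list[int]] = {}
    attempts = 0
    while len(centers) < n_sep and attempts < 200 * n_target:
        attempts += 1
        x = rng.uniform(margin, side_um - margin)
        y = rng.uniform(margin, side_um - margin)
        gi, gj = int(x / cell), int(y / cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((gi + di, gj + dj), ()):
                    cx, cy = centers[k]
                    if (x - cx) ** 2 + (y - cy) ** 2 < min_d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gi, gj), []).append(len(centers))
            centers.append((x, y))
    if len(centers) < n_sep:
        raise ValueError("could not place nuclei at the requested density/separation")
    for _ in range(n_free):
        centers.append(
            (rng.uniform(margin, side_um - margin), rng.uniform(margin, side_um - margin))
        )

    yy, xx = np.meshgrid(np.arange(npx), np.arange(npx), indexing="ij")
    for (cx, cy) in centers:
        rx = radius_um * rng.uniform(0.85, 1.15)
        ry = radius_um * rng.uniform(0.85, 1.15)
        theta = rng.uniform(0, np.pi)
        shade = rng.uniform(50.0, 90.0)
        ci, cj = cy / pixel_size_um, cx / pixel_size_um
        ri, rj = ry / pixel_size_um, rx / pixel_size_um
        ext = int(np.ceil(max(ri, rj))) + 2
        i0, i1 = max(0, int(ci) - ext), min(npx, int(ci) + ext + 1)
        j0, j1 = max(0, int(cj) - ext), min(npx, int(cj) + ext + 1)
        di = yy[i0:i1, j0:j1] - ci
        dj = xx[i0:i1, j0:j1] - cj
        u = np.cos(theta) * dj + np.sin(theta) * di
        v = -np.sin(theta) * dj + np.cos(theta) * di
        inside = (u / rj) ** 2 + (v / ri) ** 2 <= 1.0
        patch = img[i0:i1, j0:j1]
        patch[inside] = np.minimum(patch[inside], shade)
    img += rng.normal(0.0, 4.0, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), len(centers)


# ---------------------------------------------------------------------------
# Longitudinal cohort generator


@dataclass(frozen=True)
class EffectSpec:
    """Calibration of the longitudinal growth / treatment-effect generator.

    Weekly volume means and the MTV~vMRI power-law are calibrated to the
    untreated-cohort trajectory; treatment multipliers to the endpoint group
    means. Within-arm spreads sit at the tight end of the observed per-arm
    ranges so the generated study reproduces the reported group separation.
    """

    vmri_week_means: dict = field(
        default_factory=lambda: {3: 177.0, 4: 666.0, 5: 936.0}
    )
    growth_sigma: float = 0.35  # per-mouse lognormal size factor
    week_noise_sigma: float = 0.10  # per-scan multiplicative noise
    mtv_coeff: float = 7.4  # MTV = coeff * vMRI**exponent
    mtv_exponent: float = 0.65
    mtv_noise_sigma: float = 0.12
    adc_intercept: float = 1.65e-3  # ADC = intercept - slope*ln(vMRI) + noise
    adc_slope: float = 0.093e-3
    adc_noise_sigma: float = 0.06e-3
    suv_mean_center: float = 2.2
    suv_sigma: float = 0.12
    suv_max_ratio: float = 1.77
    ki_center: float = 0.039
    ki_sigma: float = 0.25
    density_center: float = 11.3e3  # cells/mm^2, untreated
    density_sigma_control: float = 0.4e3
    density_sigma_treated: float = 0.8e3
    # treatment effects at endpoint (week 7/8)
    control_endpoint_vmri: float = 2245.0
    treated_endpoint_vmri: float = 779.0
    endpoint_vmri_sigma_control: float = 0.30
    endpoint_vmri_sigma_treated: float = 0.35
    treated_adc_mult: float = 1.2
    treated_density_mult: float = 8.7 / 11.3
    endpoint_adc_sigma: float = 0.05e-3


def _lognormal_factor(rng: np.random.Generator, sigma: float, size=None):
    """Multiplicative lognormal noise with unit mean."""
    if sigma == 0:
        return 1.0 if size is None else np.ones(size)
    return rng.lognormal(-0.5 * sigma**2, sigma, size=size)


def _adc_of_volume(spec: EffectSpec, vmri: float, rng, sigma: float | None = None) -> float:
    s = spec.adc_noise_sigma if sigma is None else sigma
    adc = spec.adc_intercept - spec.adc_slope * np.log(max(vmri, 2.0)) + rng.normal(0, s)
    return float(np.clip(adc, 0.5e-3, 2.0e-3))


def simulate_cohort(
    n_mice: int = 18,
    arms: dict | None = None,
    effect_spec: EffectSpec | None = None,
    seed: int = 42,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the weekly imaging study: naive growth weeks 3-5 plus a
    treated-vs-control endpoint arm.

    ``arms`` maps arm name to mouse count; default
    ``{"naive": 9, "control": 4, "treated": 5}`` (18 mice total, 9 in the
    treatment sub-study). Naive and control mice contribute weekly growth
    scans; control and treated mice additionally get endpoint (week 7/8)
    anatomic volume, ADC and cell density with the treatment multipliers
    applied to the treated arm.

    Returns (cohort table, truth dict with the per-mouse growth factors).
    Negative volumes cannot arise (multiplicative model); the table column
    conventions are documented in the README.
    """
    spec = effect_spec or EffectSpec()
    arms = arms or {"naive": 9, "control": 4, "treated": 5}
    if sum(arms.values()) != n_mice:
        raise ValueError(f"arm sizes {arms} do not sum to n_mice={n_mice}")
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict = {"seed": seed, "growth_factor": {}}
    mouse_no = 0
    # weekly participation mirroring the study design: 14/10/8 T2 scans over
    # weeks 3/4/5 among the 14 growth-phase mice (naive + control + one treated pair)
    weekly_mice: list[str] = []
    for arm, n in arms.items():
        for _ in range(n):
            mouse_no += 1
            mid = f"M{mouse_no:02d}"
            truth["growth_factor"][mid] = {}
            g = _lognormal_factor(rng, spec.growth_sigma)
            truth["growth_factor"][mid]["g"] = float(g)
            truth["growth_factor"][mid]["arm"] = arm
            if arm in ("naive", "control"):
                weekly_mice.append(mid)
            base_suv = spec.suv_mean_center * _lognormal_factor(rng, spec.suv_sigma)
            for week, mean_v in spec.vmri_week_means.items():
                if arm == "treated":
                    continue
                vmri = mean_v * g * _lognormal_factor(rng, spec.week_noise_sigma)
                suv_mean = float(np.clip(base_suv * _lognormal_factor(rng, 0.05), 1.4, 3.0))
                suv_max = suv_mean * spec.suv_max_ratio * _lognormal_factor(rng, 0.05)
                mtv = (
                    spec.mtv_coeff
                    * vmri**spec.mtv_exponent
                    * _lognormal_factor(rng, spec.mtv_noise_sigma)
                )
                ki = float(
                    np.clip(
                        spec.ki_center
                        * (suv_mean / spec.suv_mean_center) ** 1.2
                        * _lognormal_factor(rng, spec.ki_sigma),
                        0.012,
                        0.061,
                    )
                )
                rows.append(
                    {
                        "mouse": mid,
                        "week": week,
                        "arm": arm,
                        "modality": "T2+PET",
                        "vmri_mm3": vmri,
                        "adc_mean_mm2_s": np.nan,
                        "suv_mean": suv_mean,
                        "suv_max": suv_max,
                        "mtv_mm3": mtv,
                        "tlg": suv_mean * mtv,
                        "ki_ml_min_ml": ki,
                        "mrfdg_umol_min_ml": ki * 10.0,
                        "cell_density_per_mm2": np.nan,
                    }
                )
            if arm in ("control", "treated"):
                # endpoint week 7/8: DWI + T2, histology at sacrifice
                if arm == "control":
                    vm = spec.control_endpoint_vmri * _lognormal_factor(
                        rng, spec.endpoint_vmri_sigma_control
                    )
                    adc = _adc_of_volume(spec, vm, rng, spec.endpoint_adc_sigma)
                    dens = spec.density_center + rng.normal(0, spec.density_sigma_control)
                else:
                    vm = spec.treated_endpoint_vmri * _lognormal_factor(
                        rng, spec.endpoint_vmri_sigma_treated
                    )
                    adc = spec.treated_adc_mult * _adc_of_volume(
                        spec, vm, rng, spec.endpoint_adc_sigma
                    )
                    dens = spec.density_center * spec.treated_density_mult + rng.normal(
                        0, spec.density_sigma_treated
                    )
                rows.append(
                    {
                        "mouse": mid,
                        "week": 7,
                        "arm": arm,
                        "modality": "DWI+T2",
                        "vmri_mm3": vm,
                        "adc_mean_mm2_s": adc,
                        "suv_mean": np.nan,
                        "suv_max": np.nan,
                        "mtv_mm3": np.nan,
                        "tlg": np.nan,
                        "ki_ml_min_ml": np.nan,
                        "mrfdg_umol_min_ml": np.nan,
                        "cell_density_per_mm2": float(max(dens, 100.0)),
                    }
                )
    df = pd.DataFrame(rows)
    return df, truth
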