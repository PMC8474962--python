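"""End-to-end reproducible study runner.

Generates a full simulated imaging study mirroring a weekly small-animal
protocol — 18 mice, weekly T2 volumetry and dynamic FDG-PET during the
growth phase (weeks 3-5), endpoint DWI + histology for a 5-treated vs
4-control chemotherapy sub-study — quantifies every scan with the analysis
modules (never with the generator's truth), assembles the cohort table, and
runs the statistical layer.

Scan design (per weekly schedule): 14/10/8 T2 scans in weeks 3/4/5 (32
total), 12/10/4 PET scans (26 total, two of them static-only), and 9
endpoint DWI scans — so the output table carries 32 T2, 26 PET and 9 DWI
rows. Everything is seeded from one master seed; rerunning the same config
reproduces the CSV outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import linear_r2, shapiro_wilk, spearman_r, treatment_report
from .histo_density import ROI, count_nuclei
from .imgcore import FrameSchedule, ImageVolume, ScanMeta, Units, VOIMask, write_dynamic, write_mask
from .mri_quant import adc_mean, compute_adc_map, tumor_volume
from .pet_kinetics import KineticConfig, derive_idif, extract_tac, mrfdg, patlak_fit
from .pet_static import SegRule, segment_iso40, static_metrics, to_suv
from .phantom import (
    AIFParams,
    EffectSpec,
    PhantomScene,
    TwoTCParams,
    build_dwi_phantom,
    build_nuclei_image,
    build_dynamic_phantom,
    _lognormal_factor,
    _adc_of_volume,
)

__all__ = ["RunConfig", "run_pipeline"]

#: reference tumor volume (mm^3) of the default scene ellipsoid (4.5 x 4 x 4 mm)
_BASE_TUMOR_MM3 = 4.0 / 3.0 * np.pi * 4.5 * 4.0 * 4.0


@dataclass(frozen=True)
class RunConfig:
    """All knobs of one pipeline run; serialized verbatim into the run dir."""

    seed: int | None = 42
    out_dir: str = "petquant_run"
    # module defaults, overridable
    iso_fraction: float = 0.40
    fixed_threshold: float = 2.5
    t_star_min: float = 20.0
    idif_voxels: int = 7
    lumped_constant: float = 0.6
    blood_glucose_mmol_l: float = 6.0
    b_values: tuple[float, ...] = (0.0, 1000.0)
    dwi_sigma: float = 15.0
    injected_dose_mbq: float = 8.3
    body_weight_g: float = 25.0
    # stage toggles
    run_stats: bool = True
    write_exemplar: bool = False
    effects: EffectSpec = field(default_factory=EffectSpec)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if not (0 < self.iso_fraction < 1):
            raise ValueError("iso_fraction must be in (0, 1)")

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), indent=2, default=enc)


def _study_design() -> list[dict]:
    """The per-mouse scan schedule: arm and weekly T2/PET/DWI participation."""
    design = []
    for i in range(1, 19):
        mid = f"M{i:02d}"
        arm = "naive" if i <= 9 else ("control" if i <= 13 else "treated")
        t2_weeks = [w for w, n in ((3, 14), (4, 10), (5, 8)) if i <= n]
        pet_weeks = [w for w, n in ((3, 12), (4, 10), (5, 4)) if i <= n]
        static_only = [(4 if i in (9, 10) else None)]  # two scans lost dynamics
        design.append(
            {
                "mouse": mid,
                "arm": arm,
                "t2_weeks": t2_weeks,
                "pet_weeks": pet_weeks,
                "static_only_weeks": [w for w in static_only if w],
                "endpoint": arm in ("control", "treated"),
            }
        )
    return design


def _quantify_pet_scan(
    cfg: RunConfig,
    target_mtv_mm3: float,
    ki_true: float,
    seed: int,
    dynamic: bool,
) -> dict:
    """Build one PET scan phantom sized to the target MTV and quantify it."""
    scale = (target_mtv_mm3 / _BASE_TUMOR_MM3) ** (1.0 / 3.0)
    scene = PhantomScene(
        tumor_semiaxes_mm=(4.5 * scale, 4.0 * scale, 4.0 * scale), seed=seed
    )
    K1, k2 = 0.12, 0.25
    k3 = ki_true * k2 / (K1 - ki_true)
    kin = TwoTCParams(K1=K1, k2=k2, k3=k3, vb=0.05)
    series, truth = build_dynamic_phantom(scene, AIFParams(), kin)
    meta = ScanMeta(
        injected_dose_mbq=cfg.injected_dose_mbq,
        body_weight_g=cfg.body_weight_g,
        blood_glucose_mmol_l=cfg.blood_glucose_mmol_l,
    )
    # static image: average of the 30-60 min frames
    late = series.schedule.starts >= 1800.0 - 1e-9
    weights = series.schedule.durations[late] / series.schedule.durations[late].sum()
    static_vals = sum(
        w * series.frames[i].values for w, i in zip(weights, np.nonzero(late)[0])
    )
    static = ImageVolume(values=static_vals, spacing=scene.spacing, units=Units.BQ_PER_ML)
    suv = to_suv(static, meta)

    ref = series.grid
    search = VOIMask.like(ref, np.ones(ref.shape, dtype=bool), label="search")
    excl = [truth["masks"]["kidneys"], truth["masks"]["bladder"], truth["masks"]["cava"]]
    tumor_mask, thr = segment_iso40(suv, search, excl, fraction=cfg.iso_fraction)
    metrics = static_metrics(suv, tumor_mask, rule=SegRule.ISO40, threshold_used=thr)

    row = {
        "suv_max": metrics.suv_max,
        "suv_mean": metrics.suv_mean,
        "mtv_mm3": metrics.mtv_mm3,
        "tlg": metrics.tlg,
        "iso_threshold": thr,
        "ki_ml_min_ml": np.nan,
        "mrfdg_umol_min_ml": np.nan,
        "patlak_rel_se_pct": np.nan,
        "patlak_gate_ok": np.nan,
        "ki_true": ki_true,
    }
    flags = []
    if dynamic:
        kcfg = KineticConfig(
            lumped_constant=cfg.lumped_constant,
            blood_glucose_mmol_l=cfg.blood_glucose_mmol_l,
            t_star_min=cfg.t_star_min,
            idif_voxels=cfg.idif_voxels,
        )
        tac = extract_tac(series, tumor_mask)
        idif = derive_idif(series, truth["masks"]["cava"], k=kcfg.idif_voxels)
        fit = patlak_fit(tac, idif, t_star_min=kcfg.t_star_min)
        row.update(
            ki_ml_min_ml=fit.ki,
            mrfdg_umol_min_ml=mrfdg(fit.ki, kcfg),
            patlak_rel_se_pct=fit.rel_se_percent,
            patlak_gate_ok=fit.passes_quality_gate,
        )
        if not fit.passes_quality_gate:
            flags.append(f"patlak rel_se {fit.rel_se_percent:.1f}% >= 10%")
    return {"row": row, "flags": flags, "series": series, "truth": truth, "suv": suv}


def _t2_vmri(target_vmri_mm3: float) -> float:
    """Measure vMRI by volumetry of an ellipsoid mask on the T2 grid.

    T2 protocol grid: 160 x 160 in-plane at 0.2 mm, 1 mm slices. The mask is
    the voxelization of an ellipsoid with the target volume; the measured
    volume differs from the target only by voxelization error.
    """
    shape, spacing = (160, 160, 20), (0.2, 0.2, 1.0)
    r = (3.0 * target_vmri_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    semi = (r * 1.1, r, r / 1.1)
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    c = [n * s / 2.0 for n, s in zip(shape, spacing)]
    inside = (
        ((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2 + ((Z - c[2]) / semi[2]) ** 2
        <= 1.0
    )
    mask = VOIMask(values=inside, spacing=spacing, label="tumor_t2")
    return tumor_volume(mask)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full simulated study; returns the output directory.

    Layout: ``config.json``, ``cohort.csv``, ``stats/*.csv``, ``run.log``,
    and (optionally) an exemplar dynamic phantom under ``phantoms/``.
    """
    config.validate()
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    cfg_hash = hashlib.sha256(config.to_json().encode()).hexdigest()[:12]

    spec = config.effects
    master = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    scan_seeds = iter(np.random.SeedSequence(config.seed + 1).generate_state(500) % (2**31))

    log_lines = [
        f"petquant {__version__} | config sha256:{cfg_hash} | seed {config.seed}",
        f"thresholds: iso_fraction={config.iso_fraction} fixed={config.fixed_threshold} "
        f"t*={config.t_star_min}min k={config.idif_voxels} LC={config.lumped_constant} "
        f"glucose={config.blood_glucose_mmol_l}mmol/l",
    ]
    rows: list[dict] = []
    exemplar_written = False

    for mouse in _study_design():
        g = _lognormal_factor(rng, spec.growth_sigma)
        base_suv_noise = _lognormal_factor(rng, spec.suv_sigma)
        for week in (3, 4, 5):
            if week not in mouse["t2_weeks"] and week not in mouse["pet_weeks"]:
                continue
            v_true = spec.vmri_week_means[week] * g * _lognormal_factor(rng, spec.week_noise_sigma)
            if week in mouse["t2_weeks"]:
                rows.append(
                    {
                        "mouse": mouse["mouse"],
                        "week": week,
                        "arm": mouse["arm"],
                        "modality": "T2",
                        "vmri_mm3": _t2_vmri(v_true),
                    }
                )
            if week in mouse["pet_weeks"]:
                target_mtv = (
                    spec.mtv_coeff
                    * v_true**spec.mtv_exponent
                    * _lognormal_factor(rng, spec.mtv_noise_sigma)
                )
                ki_true = float(
                    np.clip(
                        spec.ki_center * base_suv_noise * _lognormal_factor(rng, spec.ki_sigma),
                        0.013,
                        0.060,
                    )
                )
                dynamic = week not in mouse["static_only_weeks"]
                res = _quantify_pet_scan(
                    config, target_mtv, ki_true, int(next(scan_seeds)), dynamic
                )
                rows.append(
                    {
                        "mouse": mouse["mouse"],
                        "week": week,
                        "arm": mouse["arm"],
                        "modality": "PET",
                        **res["row"],
                    }
                )
                for fl in res["flags"]:
                    log_lines.append(f"QC {mouse['mouse']} week {week}: {fl}")
                if config.write_exemplar and not exemplar_written:
                    pdir = out / "phantoms"
                    pdir.mkdir(exist_ok=True)
                    write_dynamic(
                        res["series"], pdir / "exemplar_dynamic.nii.gz", pdir / "exemplar_schedule.csv"
                    )
                    write_mask(res["truth"]["masks"]["tumor"], pdir / "exemplar_tumor_mask.nii.gz")
                    exemplar_written = True
        if mouse["endpoint"]:
            treated = mouse["arm"] == "treated"
            if treated:
                v_end = spec.treated_endpoint_vmri * _lognormal_factor(
                    rng, spec.endpoint_vmri_sigma_treated
                )
                adc_true = spec.treated_adc_mult * _adc_of_volume(
                    spec, v_end, rng, spec.endpoint_adc_sigma
                )
                dens_true = spec.density_center * spec.treated_density_mult + rng.normal(
                    0, spec.density_sigma_treated
                )
            else:
                v_end = spec.control_endpoint_vmri * _lognormal_factor(
                    rng, spec.endpoint_vmri_sigma_control
                )
                adc_true = _adc_of_volume(spec, v_end, rng, spec.endpoint_adc_sigma)
                dens_true = spec.density_center + rng.normal(0, spec.density_sigma_control)

            stack, _, tumor_mask = build_dwi_phantom(
                tumor_adc=adc_true,
                b_values=config.b_values,
                sigma=config.dwi_sigma,
                seed=int(next(scan_seeds)),
            )
            amap = compute_adc_map(stack)
            measured_adc = adc_mean(amap, tumor_mask)

            img, _ = build_nuclei_image(
                density_cells_per_mm2=max(dens_true, 1000.0),
                field_mm2=0.16,
                seed=int(next(scan_seeds)),
            )
            side = img.shape[0]
            third = side // 3
            rois = [
                ROI(0, 0, third, third),
                ROI(0, side - third, third, third),
                ROI(side - third, 0, third, third),
                ROI(side - third, side - third, third, third),
            ]
            dens = count_nuclei(img, rois, pixel_size_um=0.5)
            rows.append(
                {
                    "mouse": mouse["mouse"],
                    "week": 7,
                    "arm": mouse["arm"],
                    "modality": "DWI",
                    "vmri_mm3": _t2_vmri(v_end),
                    "adc_mean_mm2_s": measured_adc,
                    "cell_density_per_mm2": dens.mean_density,
                }
            )

    cohort = pd.DataFrame(rows)
    col_order = [
        "mouse", "week", "arm", "modality", "vmri_mm3", "adc_mean_mm2_s",
        "suv_max", "suv_mean", "mtv_mm3", "tlg", "iso_threshold",
        "ki_ml_min_ml", "mrfdg_umol_min_ml", "patlak_rel_se_pct",
        "patlak_gate_ok", "ki_true", "cell_density_per_mm2",
    ]
    cohort = cohort.reindex(columns=col_order)
    cohort.to_csv(out / "cohort.csv", index=False)

    if config.run_stats:
        sdir = out / "stats"
        sdir.mkdir(exist_ok=True)
        _run_stats_stage(cohort, sdir, log_lines)

    n_by_mod = cohort["modality"].value_counts().to_dict()
    log_lines.append(f"scan rows by modality: {json.dumps(n_by_mod, sort_keys=True)}")
    log_lines.append(f"elapsed {time.time() - t0:.1f} s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


#: marker pairs of the default regression/correlation panels
_PANELS = [
    ("vmri_mm3", "mtv_mm3"),
    ("vmri_mm3", "tlg"),
    ("vmri_mm3", "adc_mean_mm2_s"),
    ("suv_mean", "suv_max"),
    ("mrfdg_umol_min_ml", "suv_max"),
    ("vmri_mm3", "suv_mean"),
]


def _weekly_markers(cohort: pd.DataFrame) -> pd.DataFrame:
    """Merge per-(mouse, week) T2 and PET rows into one marker record."""
    t2 = cohort[cohort["modality"] == "T2"][["mouse", "week", "arm", "vmri_mm3"]]
    pet_cols = ["mouse", "week", "suv_max", "suv_mean", "mtv_mm3", "tlg", "mrfdg_umol_min_ml"]
    pet = cohort[cohort["modality"] == "PET"][pet_cols]
    merged = t2.merge(pet, on=["mouse", "week"], how="outer")
    dwi = cohort[cohort["modality"] == "DWI"][["mouse", "week", "arm", "vmri_mm3", "adc_mean_mm2_s"]]
    return pd.concat([merged, dwi], ignore_index=True)


def _run_stats_stage(cohort: pd.DataFrame, sdir: Path, log_lines: list[str]) -> None:
    markers = _weekly_markers(cohort)
    panel_rows = []
    for xcol, ycol in _PANELS:
        sub = markers.dropna(subset=[xcol, ycol])
        if len(sub) < 4:
            continue
        x, y = sub[xcol].to_numpy(float), sub[ycol].to_numpy(float)
        slope, intercept, r2 = linear_r2(x, y)
        rho, p_rho = spearman_r(x, y)
        panel_rows.append(
            {
                "x": xcol, "y": ycol, "n": len(sub),
                "slope": slope, "intercept": intercept, "r2": r2,
                "spearman_rho": rho, "spearman_p": p_rho,
            }
        )
    pd.DataFrame(panel_rows).to_csv(sdir / "regressions.csv", index=False)

    normality = []
    for col in ("vmri_mm3", "suv_max", "suv_mean", "mtv_mm3", "tlg", "adc_mean_mm2_s"):
        vals = markers[col].dropna().to_numpy(float)
        if vals.size >= 3 and np.ptp(vals) > 0:
            res = shapiro_wilk(vals)
            normality.append({"marker": col, "W": res.statistic, "p": res.p_two_sided, "n": res.n1})
    pd.DataFrame(normality).to_csv(sdir / "normality.csv", index=False)

    endpoint = cohort[cohort["modality"] == "DWI"]
    if set(endpoint["arm"]) >= {"treated", "control"}:
        report = treatment_report(endpoint)
        report.to_csv(sdir / "treatment_report.csv", index=False)
        for _, row in report.iterrows():
            log_lines.append(
                f"treatment {row['marker']}: p={row['p_two_sided']:.4f} "
                f"direction_ok={row['direction_ok']}"
            )
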