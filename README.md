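# petquant

Quantitative preclinical FDG-PET and MRI tumor analysis for small-animal
(orthotopic mouse) cancer studies, with digital phantoms for validation.

Longitudinal imaging of tumor-bearing mice produces a family of markers that
are tedious and error-prone to compute by hand across vendors and tools:
anatomic volume from T2-weighted MRI (vMRI), apparent diffusion coefficient
from DWI (ADCmean), standardized uptake values (SUVmean/SUVmax), metabolic
tumor volume (MTV) and total lesion glycolysis (TLG = SUVmean × MTV) from
static FDG-PET, and the net influx constant Ki from dynamic PET via Patlak
graphical analysis with an image-derived input function (IDIF), converted to
a metabolic rate MR_FDG = Ki · glucose / lumped constant. `petquant`
implements this full pipeline as a tested Python library, together with
histology nuclei counting (cells/mm²), exact small-sample statistics, and
synthetic-data generators with known ground truth so every stage is
validated by parameter recovery.

## Core quantities

* **ADC** per voxel from mono-exponential DWI decay:
  ADC = ln(S₀/S_b)/b for the two-point b = 0/1000 s/mm² protocol.
* **SUV** = C · body weight / injected dose (decay-corrected, density 1 g/ml).
* **Tumor VOI** by either a 40%-of-SUVmax isocontour (26-connected component
  seeded at the hottest voxel) or a fixed 2.5 SUV threshold; MTV is the VOI
  volume and TLG = SUVmean × MTV exactly.
* **Patlak**: with x(t) = ∫₀ᵗCp dτ / Cp(t) and y(t) = CT(t)/Cp(t), the late
  points (t ≥ t* = 20 min) fall on a line with slope Ki; the IDIF Cp comes
  from the 7 hottest vena-cava voxels ranked in the bolus window. Fits are
  gated at < 10% relative standard error of Ki.
* **MR_FDG** = Ki · (blood glucose 6.0 mmol/l) / (lumped constant 0.6).
* **Exact Mann–Whitney**: two-sided p by full enumeration of group
  assignments (p = 2/126 for complete separation at n = 5 vs 4), plus
  Shapiro–Wilk screening, regression r², and Spearman correlation.

See `docs/methods.md` for models, assumptions, numerical choices and
limitations.

## Worked example

Quantify a simulated 1-h dynamic scan end to end
(`examples/patlak_kinetics.py`):

```python
from petquant import KineticConfig, derive_idif, extract_tac, mrfdg, patlak_fit
from petquant.phantom import PhantomScene, build_dynamic_phantom

series, truth = build_dynamic_phantom(PhantomScene(seed=42))
cfg = KineticConfig()
tumor_tac = extract_tac(series, truth["masks"]["tumor"])
idif = derive_idif(series, truth["masks"]["cava"], k=cfg.idif_voxels)
fit = patlak_fit(tumor_tac, idif, t_star_min=cfg.t_star_min)
```

prints

```
Ki (Patlak slope)  : 0.0361 ml/min/ml   (truth 0.0389)
intercept V        : 0.269
fit rel. SE        : 0.24 %  (quality gate: < 10%)
fit r^2            : 1.0000
MR_FDG             : 0.361 umol/(min*ml)
```

The fitted Ki lands within ~10% of the generator's ground truth despite PSF
blur and count noise (the residual deficit is the uncorrected blood-fraction
and partial-volume effect), the fit quality is far inside the 10% gate, and
MR_FDG = 10 × Ki under the default glucose and lumped-constant values.

Each script in `examples/` demonstrates one capability (ADC mapping, static
PET metrics, Patlak kinetics, nuclei density, cohort statistics, the full
demo study) and prints the numbers it computes with a note on what they
mean.

## Command line

A thin CLI wraps the library:

```bash
petquant phantom out/ --seed 42        # write a dynamic phantom + truth
petquant adc b0.nii.gz b1000.nii.gz --b 0 --b 1000 --mask tumor.nii.gz
petquant petstatic activity.nii.gz --meta scan.json --rule iso40
petquant kinetics dyn.nii.gz --schedule frames.csv --tumor-mask t.nii.gz --cava-mask c.nii.gz
petquant histo slide.png --pixel-size-um 0.5
petquant stats cohort.csv
petquant run --seed 42                 # full demo study
```

`petquant run` generates an 18-mouse simulated study (32 T2 / 26 PET / 9 DWI
scan rows, matching the weekly design it emulates), quantifies every scan
with the analysis modules, and writes `cohort.csv`, regression/correlation
panels, the treated-vs-control report and a run log; reruns with the same
config are byte-identical.

## Cohort table columns

`cohort.csv` uses stable column names: `mouse`, `week`, `arm`
(naive/control/treated), `modality` (T2/PET/DWI), `vmri_mm3`,
`adc_mean_mm2_s`, `suv_max`, `suv_mean`, `mtv_mm3`, `tlg`, `iso_threshold`,
`ki_ml_min_ml`, `mrfdg_umol_min_ml`, `patlak_rel_se_pct`, `patlak_gate_ok`,
`ki_true` (generator audit), `cell_density_per_mm2`.

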