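# Methods

`petquant` implements the quantitative imaging-marker pipeline used in
orthotopic small-animal tumor studies — anatomic volumetry and diffusion MRI,
static and dynamic FDG-PET, histology cell density, and the small-cohort
statistics that tie them together — plus digital phantoms with known ground
truth so that every stage can be validated by parameter recovery rather than
by eyeballing.

## Image model and geometry

Volumes are 3D scalar grids with strictly positive voxel spacing and an
axis-aligned world frame (`world = origin + index * spacing`; no shear or
rotation). Units (Bq/ml, SUV, arbitrary signal, mm²/s) are mandatory
metadata; operations refuse unit-mismatched inputs rather than guessing.
Masks move between grids only by nearest-neighbour resampling in world
coordinates — adequate for transferring a manual segmentation between
modalities, and deliberately short of full image registration, which is out
of scope. NIfTI-1 is the interchange format for volumes and masks; frame
schedules and cohort tables are CSV; per-scan metadata (injected dose, body
weight, blood glucose) is a JSON sidecar.

The default PET grid is 0.4 mm isotropic (voxel volume 0.064 mm³); the
default dynamic framing is 5×2 s, 5×10 s, 2×120 s, 3×300 s, 4×600 s — a 1-h
acquisition whose short early frames resolve the bolus and whose 10-min late
frames give quiet Patlak points.

## Diffusion MRI

ADC is fitted per voxel from the mono-exponential decay `S_b = S0 exp(-b·ADC)`.
With the standard two-point protocol (b = 0 and 1000 s/mm²) this is the log
ratio `ADC = ln(S_0/S_1000)/1000`; with more b-values an OLS line on
`-ln(S_b)` vs `b`. Voxels with any nonpositive signal are flagged with a
negative sentinel and excluded from all statistics — clipping them instead
would bias ADC systematically low, excluding them only loses voxels. No
spatial smoothing is applied before fitting. Whole-tumor ADC is the
arithmetic mean of valid in-mask voxels; anatomic volume (vMRI) is the voxel
count times voxel volume, i.e. the sum of segmented slice volumes.

## Static PET

SUV = C·w/D with tissue density 1 g/ml, where C is decay-corrected activity
concentration (Bq/ml), w body weight (g) and D injected dose (Bq); dose decay
between assay and injection uses the 109.77-min half-life of F-18.

Two segmentation rules are provided:

* **iso40** — threshold at 40% of SUVmax within a search region (minus
  exclusion masks) and keep the 26-connected component containing the max
  voxel. Seeding at the max keeps the VOI one lesion; unseeded thresholding
  at murine SUV levels would also capture kidneys and bladder, which is
  exactly what exclusion masks and the seeded component avoid. The mask uses
  `>=` rather than a strict inequality so the max voxel survives degenerate
  uniform images; thresholds are reported at full precision and displayed
  rounded to one decimal (SUVmax 3.8 → displayed threshold 1.5).
* **fixed** — all voxels at or above an absolute SUV threshold (default
  2.5), no connectivity filter. An empty result is legal and flagged: small
  or faint murine lesions routinely fall below a clinical fixed threshold,
  which is the practical argument for the isocontour rule in mice.

MTV is the VOI volume; TLG = SUVmean × MTV holds as an exact identity by
construction. Liver SUVmean over a liver mask is reported as a per-scan QC
reference (mouse liver sits near 0.5 SUV, far below the 2–3 SUV of human
liver — the scale argument for not using fixed clinical thresholds). No
partial-volume correction is applied anywhere in the package.

## Dynamic PET

Tumor TACs are per-frame VOI means against frame mid-times. The input
function is image-derived: voxels in a vena-cava box are ranked by summed
uptake over the bolus window (frame mid-times ≤ 60 s) and the top k
(default 7, ties broken by voxel index) form a fixed set averaged across all
frames. Ranking on the early window targets the first-pass bolus and avoids
selecting voxels contaminated by late tissue spill-in; using a fixed voxel
set keeps the curve consistent across frames. A QC warning fires when the
IDIF does not peak within the first 5 min. The whole-blood IDIF is used as
the plasma input with no metabolite, plasma/whole-blood, or partial-volume
correction.

The Patlak transform `y = CT/Cp` vs `x = ∫Cp/Cp` is fitted by unweighted OLS
over frames with mid-time ≥ t\* (default 20 min, matching the switch from
rapid early uptake to slow late accumulation; configurable). The plasma
integral is anchored at (0, 0) — acquisition starts at injection. When the
curves carry frame durations, the integral uses the exact
interval-average identity `∫₀^mid = Σ dur·Cp − dur·Cp/2`; this halves the
quadrature bias of a mid-time trapezoid with 10-min frames and is what the
pipeline uses throughout (trapezoid remains the fallback for bare curves).
Fit quality is the relative standard error of the slope,
`100·SE(Ki)/Ki`; fits at or above 10% are flagged as failing the quality
gate. MR_FDG = Ki·glucose/LC with defaults glucose 6.0 mmol/l and lumped
constant 0.6 (factor 10), reported per ml of tissue (µmol·min⁻¹·ml⁻¹); the
per-volume denominator is made explicit here even where field shorthand
writes only µmol/min.

Two structural properties worth knowing:

* With the tissue model `CT = (1−vb)(C1+C2) + vb·Cp`, the Patlak slope
  estimates `(1−vb)·Ki`, i.e. a −5% offset at vb = 0.05. This is shared with
  real whole-VOI Patlak and is left uncorrected; the closed-form identity
  `Ki = K1·k3/(k2+k3)` is exact only at vb = 0.
* Slow kinetics (k2+k3 ≲ 0.2 min⁻¹) equilibrate late; at k2+k3 = 0.18 the
  transient alone biases the 20-min-window slope by ~3.5% even noiselessly.
  The 2%-recovery guarantee in the tests therefore applies to the default
  rate range (k2+k3 ≥ 0.25 min⁻¹).

## Histology

Nuclei are counted per rectangular ROI: threshold the dark (hematoxylin)
class, remove objects below a minimum area (default 9 µm²), split merged
blobs by a distance-transform watershed seeded at local maxima at least half
a nucleus radius apart, and report count/area in cells/mm². The threshold is
Otsu's by default — a fixed darkest-percentile cutoff undercounts whenever
nuclei cover more than that percentile of the field, which is already true
at untreated-tumor densities (~11×10³ cells/mm² ≈ 30% coverage); a
percentile override exists for stains where Otsu is inappropriate. Half-radius
seed separation was chosen over a full radius because merged pairs at
realistic overlap rates otherwise stay fused (−6% counts vs −2%). Absolute
agreement with any particular interactive detector on real slides is not
claimed; the density statistic is the downstream quantity.

## Cohort statistics

Group comparisons use the Mann–Whitney U test, exact by full enumeration of
all C(n1+n2, n1) assignments of the pooled mid-ranks whenever n1+n2 ≤ 20.
The two-sided p is the probability of |U − n1n2/2| at least as large as
observed — a symmetric-null definition that is deterministic and handles
ties through mid-ranks. At the study's n = 5 vs 4, full separation gives
exactly p = 2/126 ≈ 0.016; asymptotic approximations are unreliable at such
n and are used only above 20 observations (with tie correction). Shapiro–Wilk
is reported as a normality screen only; group tests stay nonparametric
regardless of its outcome. Linear-regression r² (goodness of fit) and
Spearman rank correlation (exact permutation p for n ≤ 9, t-approximation
above) are reported separately and never conflated. No multiple-testing
correction is applied, matching standard practice in exploratory preclinical
reports. The treatment report compares endpoint ADC, vMRI and cell density
between arms with directional flags (effective chemotherapy: ADC up, volume
down, density down).

## Phantoms: what they emulate, and what they do not

**Input function.** A tri-exponential bolus (Feng form)
`Cp = (A1·t − A2 − A3)e^(−λ1 t) + A2 e^(−λ2 t) + A3 e^(−λ3 t)`, zero at
injection by construction and validated nonnegative on [0, 60] min. The
default amplitudes are scaled so downstream tumor uptake lands in a
realistic murine SUV range for an ~8.3 MBq injection in a ~25 g animal; peak
before 2 min, monotone washout.

**Tissue kinetics.** The irreversible 2TC system
`dC1/dt = K1·Cp − (k2+k3)·C1`, `dC2/dt = k3·C1`,
`CT = (1−vb)(C1+C2) + vb·Cp` is integrated on a 0.1-s grid by an exact
exponential update per step (Cp linear within steps, realized as an IIR
recursion) — sub-frame resolution is required because the earliest frames
are 2 s. Frame values are true interval averages of CT, not mid-time
samples. Defaults K1 = 0.12, k2 = 0.25, k3 = 0.12, vb = 0.05 give
Ki ≈ 0.039 ml/min/ml, the cohort-mean net influx.

**4D image phantom.** An abdominal scene (48×48×64 at 0.4 mm): tumor
ellipsoid with a center-to-rim uptake gradient normalized to unit tumor
mean (so the VOI-mean TAC equals the 2TC curve exactly while SUVmax/SUVmean
≈ 1.5–1.8 as in real lesions), vena-cava cylinder carrying Cp (radius
1.1 mm — a realistic murine cava calibre; thinner vessels lose most of the
bolus to the PSF), kidney and bladder excretion ramps, low constant
background. Frames are blurred with a 1.0-mm-FWHM Gaussian PSF, then voxel
counts `C·voxel volume·frame duration·sensitivity` are Poisson-sampled and
converted back to concentration. The sensitivity constant (0.05 counts per
decay, in the range of modern small-animal ring sensitivity less
reconstruction losses) controls the noise scale; it reproduces the
qualitative duration dependence (noisy 2-s frames, quiet 10-min frames) but
is not validated against any scanner's noise spectrum, and no reconstruction
noise correlations, motion, or attenuation effects are modeled. TAC-level
simulation (`simulate_kinetic_cohort`) applies the same count model to VOI
curves directly (tumor VOI 0.3 ml, IDIF 7 voxels), drawing per-scan Ki
uniformly over the physiologic band 0.015–0.055 ml/min/ml.

**DWI phantom.** Mono-exponential signal with a tumor ADC field whose
linear-in-r² profile has exactly the specified volume mean (default
1.07×10⁻³ mm²/s); Rician noise (magnitude images) of scale σ. Noiseless
stacks invert exactly through the ADC fit.

**Nuclei phantom.** Dark ellipses (radius ~3 µm, shade and eccentricity
jittered) on a bright noisy background; a configurable fraction of nuclei is
placed without a separation constraint to create merged pairs. The placed
count is the exact truth. Real stain variability, out-of-focus blur and
touching tissue architecture are not modeled — recovery there says nothing
about absolute accuracy on real slides.

**Cohort generator.** Weekly volumes follow per-mouse lognormal growth
factors around calibrated weekly means (177/666/936 mm³ at weeks 3/4/5);
MTV couples to volume through the power law MTV = 7.4·vMRI^0.65 (fitted to
the weekly mean pairs); ADC declines with log volume around 1.07×10⁻³ mm²/s;
endpoint treatment effects multiply volume by 0.35, ADC by 1.2 and density
by 0.77 (group-mean ratios). Within-arm spreads sit at the tight end of the
observed per-arm ranges so that a typical simulated study reproduces the
reported group separation; the directional effects hold in every replicate,
significance at n = 5 vs 4 in the vast majority. Growth-factor spread
(σ = 0.35) was set to the ±15% weekly-mean calibration target at the study's
weekly sample sizes and is narrower than the widest printed per-week ranges —
matching both simultaneously is not possible with a single lognormal factor.

## Demo study and determinism

The pipeline runner mirrors the study design: 18 mice (9 naive, 4 control,
5 treated), weekly T2 volumetry (14/10/8 scans in weeks 3/4/5) and PET
(12/10/4 scans, two of them static-only), endpoint DWI + histology for the
9 treatment-study mice — 32 T2, 26 PET and 9 DWI rows. Every PET scan is a
full image phantom sized to the scan's target metabolic volume and
quantified with the analysis modules only (the generator's truth is carried
alongside for audit, never used in the measurement). All randomness derives
from one master seed; rerunning a config reproduces every CSV byte for byte.
Quality gates (Patlak rel. SE, IDIF shape, empty masks) warn and annotate
rows rather than dropping them, so the cohort table is always complete and
auditable. Problem sizes (48×48×64 PET grids, 0.16 mm² histology fields,
24-scan TAC cohorts, 50–100-seed recovery loops) are chosen so the whole
validation suite runs on a single desktop CPU in a couple of minutes.

## Known limitations

* No partial-volume correction: image-level Ki carries a residual positive
  bias (~5–8% on the default phantom) from PSF spill-over and the blood
  fraction; MTV from iso40 under-covers the geometric tumor rim.
* Nearest-neighbour mask transfer only; no deformable or rigid registration.
* The IDIF is whole blood, uncorrected for plasma/metabolites or dispersion.
* The exact Mann–Whitney enumerates up to 20 total observations; beyond that
  the normal approximation is used.
* Phantom realism is structural, not reconstruction-accurate: noise is
  independent Poisson per voxel, the PSF is stationary Gaussian, anatomy is
  geometric primitives.
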