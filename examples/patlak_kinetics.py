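"""Quantify tumor FDG influx from a dynamic scan with an image-derived input.

Extracts the tumor time-activity curve and the vena-cava IDIF (7 hottest
voxels) from a simulated 1-h dynamic series, runs the Patlak graphical fit
past t* = 20 min, and converts Ki to the FDG metabolic rate.
"""

from petquant import KineticConfig, derive_idif, extract_tac, mrfdg, patlak_fit
from petquant.phantom import PhantomScene, build_dynamic_phantom

series, truth = build_dynamic_phantom(PhantomScene(seed=42))
cfg = KineticConfig()  # LC 0.6, glucose 6.0 mmol/l, t* 20 min, 7 IDIF voxels

tumor_tac = extract_tac(series, truth["masks"]["tumor"])
idif = derive_idif(series, truth["masks"]["cava"], k=cfg.idif_voxels)
fit = patlak_fit(tumor_tac, idif, t_star_min=cfg.t_star_min)

print(f"Ki (Patlak slope)  : {fit.ki:.4f} ml/min/ml   (truth {truth['ki_true']:.4f})")
print(f"intercept V        : {fit.intercept:.3f}")
print(f"fit rel. SE        : {fit.rel_se_percent:.2f} %  (quality gate: < 10%)")
print(f"fit r^2            : {fit.r2:.4f}")
print(f"MR_FDG             : {mrfdg(fit.ki, cfg):.3f} umol/(min*ml)")
# Ki lands within ~10% of truth despite PSF blur and count noise; the small
# residual bias is the uncorrected partial-volume/blood-fraction effect.
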