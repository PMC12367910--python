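# rphmri

Quantitative **extracellular pH mapping** from dual-injection dynamic
contrast-enhanced MRI (ratiometric pH MRI, "RpH-MRI"), as a tested Python
library with a thin command-line interface and a built-in digital phantom
simulator.

## The problem and the method

Solid tumors acidify their extracellular space; imaging that acidosis
voxel-by-voxel is a long-standing goal in quantitative MRI. A single
pH-responsive contrast agent cannot do it alone, because the signal change it
produces confounds *how much agent* is present with *how acidic* the tissue
is. RpH-MRI separates the two with **two sequential injections at equal
dose**:

1. a **pH-insensitive control chelate**, whose T1 relaxivity
   r1 (mM⁻¹ s⁻¹) is a known constant — its enhancement reports
   **concentration**;
2. a **pH-sensitive chelate**, whose relaxivity follows a four-parameter
   logistic (Hill) curve in pH — given the concentration from step 1, its
   enhancement reports **pH**.

The processing chain implemented here:

* **VFA T1 mapping** — pre-contrast T1 and S₀ per voxel from spoiled
  gradient-echo images at flip angles α ∈ {2°, 5°, 15°, 30°, 50°, 70°}
  (TR = 13 ms), using the SPGR steady state
  `S(α) = S₀ (1 − E₁) sin α / (1 − cos α · E₁)`, `E₁ = e^(−TR/T1)`
  (DESPOT1 linearization + bounded Gauss–Newton refinement). A variable-TR
  saturation-recovery fitter is included for spin-echo phantom data.
* **Signal → R1(t)** — the dynamic series is converted to relaxation-rate
  maps through the equilibrium magnetization
  `M₀ = S₀ (1 − cos θ·E₁₀) / (sin θ (1 − E₁₀))` and the exact SPGR inverse
  `R1(t) = −(1/TR) ln[(1 − (A+B)) / (1 − cos θ (A+B))]`.
* **Temporal peak per injection** — a per-voxel maximum of R1(t) in each
  post-injection window (equivalent to a temporal maximum-intensity
  projection of the signal, since SPGR signal is monotone in R1).
* **Ratiometric step** — concentration `C = ΔR1_control / r1_control`;
  per-voxel sensor relaxivity `r1 = ΔR1_sensor / C` under the
  equal-concentration assumption; pH from the Hill inverse
  `pH = logIC50 + log₁₀((Top − r1)/(r1 − Bottom)) / HillSlope`.
* **ROI statistics** — whole-tumor ROI, core by 0.7 centroid-scaling, rim by
  XOR; means/SDs, paired t-test, Pearson correlation with tumor size.

Because no public scanner data exist for this protocol, the package ships a
**digital phantom**: an ellipsoidal tumor with an acidic, poorly perfused
core (pH 6.51, lower peak concentration) and a less acidic rim (pH 6.74),
imaged through the full forward physics with gamma-variate bolus kinetics
and Rician noise. Both injections share one ground-truth peak-concentration
field, so the method's central assumption is exact and every pipeline stage
is testable against known truth.

The default sensor calibration is a **documented reconstruction** (Top 2.5,
Bottom 0.75 mM⁻¹ s⁻¹ assumed; midpoint and slope solved so the curve passes
through r1 = 0.86 mM⁻¹ s⁻¹ at pH 7.4 and 2.7 × that at pH 5.5, serum, 7 T);
all pipeline code takes the calibration as an input.

## Worked example

```python
import numpy as np
from rphmri import make_phantom, simulate_session, run_rph
from rphmri.roi import RoiMask, summarize_ph

phantom = make_phantom()                      # acidic core 6.51, rim 6.74
session = simulate_session(phantom, baseline_snr=50.0, seed=7)
result = run_rph(session.vfa_stack, session.vfa_params, session.dce,
                 session.schedule, session.control_cal, session.sensor_cal,
                 noise_sd=session.noise_sd)

rois = [RoiMask(phantom.tumor_mask, "whole"),
        RoiMask(phantom.core_mask, "core"),
        RoiMask(phantom.rim_mask, "rim")]
print(summarize_ph(result.ph_map, rois).round(3).to_string(index=False))
print("TMI control %.2f min, sensor %.2f min" %
      (result.qc["tmi_control_min"], result.qc["tmi_sensor_min"]))
```

which prints

```
label  n_valid  mean    sd   min   max  flagged
whole     3071 6.649 0.096 6.369 6.845    False
 core     1047 6.534 0.053 6.369 6.695    False
  rim     2024 6.709 0.046 6.538 6.845    False
TMI control 1.08 min, sensor 1.08 min
```

At a baseline SNR of 50 the recovered core mean (6.534) and rim mean (6.709)
sit within a few thousandths of the phantom's ROI-mean truth; the identical
times-to-maximal-intensity of the two injections confirm the shared bolus
kinetics that justify the equal-concentration assumption. With noise
switched off (`noise_sd=0.0`) the pH map matches the truth to ~1e-8 pH
units.

## Command line

```bash
rphmri simulate --out session/ --seed 1 --baseline-snr 50   # synthetic session + truth
rphmri t1map    --config session/session.json --out t1/     # T1 and S0 maps
rphmri rph      --config session/session.json --out maps/   # conc / r1 / pH / mask + QC
rphmri stats    --config stats.json --out stats.csv          # whole/core/rim table
```

All volumes are NIfTI-1 with frame times in a JSON sidecar; every run writes
a provenance record (package version, seed, config hash). Exit codes: 0 ok,
1 validation error, 2 runtime failure.

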