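# Methods

This note records the models, conventions and design choices behind
`rphmri`, in enough detail to audit or extend the package.

## Signal model and T1 mapping

All dynamic and multi-flip-angle data are modelled as spoiled gradient-echo
(SPGR/FLASH) steady-state magnitude images,

    S(α) = S₀ (1 − E₁) sin α / (1 − cos α · E₁),   E₁ = exp(−TR/T1),

with TR in milliseconds at every interface (converted to seconds only where
R1 in s⁻¹ is produced). Flip angles are nominal: no B1⁺ or slice-profile
correction is applied, so absolute T1 accuracy inherits any transmit-field
error of the input data.

`fit_vfa` initializes per voxel with the DESPOT1 linearization — regressing
S/sin α on S/tan α, whose slope is E₁ — and refines (T1, S₀) with a damped,
step-capped Gauss–Newton iteration (30 iterations, analytic Jacobian,
T1 bounded to [1, 10000] ms). The linearization is algebraically exact on
noiseless data, so the refinement matters only under noise. Voxels that are
flat across angles (no T1 information, e.g. all-zero) are masked invalid,
never raised; when a noise SD is supplied, voxels whose maximum signal is
below 5×SD are masked as background. The signal floor is opt-in because the
digital phantom contains no air from which to estimate one automatically.

`fit_vtr` fits the spin-echo saturation-recovery model
S = S₀(1 − e^(−TR/T1)) over a variable-TR series (the phantom-relaxometry
protocol, TRs 100–1000 ms), initialized by an 80-point log-grid search over
T1 (S₀ is linear given T1) before the same refinement. A series in which all
TRs greatly exceed T1 is flat and masked: T1 is unidentifiable there.

## Dynamic conversion to R1(t)

The baseline S₀ map is the mean of the pre-contrast frames; the equilibrium
magnetization follows as M₀ = S₀(1 − cos θ·E₁₀)/(sin θ(1 − E₁₀)) with E₁₀
from the VFA T10 map, and each frame inverts exactly through

    A(t) = (S(t) − S₀)/(M₀ sin θ),   B = (1 − E₁₀)/(1 − cos θ·E₁₀),
    R1(t) = −(1/TR) ln[(1 − (A+B)) / (1 − cos θ (A+B))].

Signal at or above the SPGR ceiling M₀ sin θ has no solution; such voxels
carry a saturation flag and propagate as mask bits. One VFA acquisition
serves both injections (no re-mapping mid-session); each injection gets its
own baseline from the frames immediately preceding it, so residual signal
of the first agent is absorbed into the second injection's baseline rather
than modelled. ΔR1 per injection is the within-window temporal peak of
R1(t) minus that injection's baseline R1.

The temporal peak is computed **per voxel** over the post-injection window,
not from a single globally chosen frame, because wash-in timing varies
across a tumor; by SPGR monotonicity in R1 this is equivalent to a temporal
maximum-intensity projection of the raw signal (tested). Ties resolve to the
earliest frame.

## Calibration

The control agent's relaxivity is the least-squares slope of R1 versus
concentration (the in-vitro series uses 0, 0.5, 2.5, 5 mM); the default
value 1.98 mM⁻¹ s⁻¹ is the control chelate's serum relaxivity at 7 T.

The sensor follows a four-parameter logistic in pH with the convention

    r1(pH) = Bottom + (Top − Bottom)/(1 + 10^((pH − logIC50)·HillSlope)),

HillSlope > 0, so relaxivity *decreases* with pH and the closed-form
inverse pH = logIC50 + log₁₀((Top − r1)/(r1 − Bottom))/HillSlope is exact.
All logs are base 10; logIC50 is read directly as the midpoint pH (the
abscissa is pH, not a log concentration). Inversion uses a guard band of
1% of (Top − Bottom) at both plateaus — relaxivities inside the band return
the invalid marker (NaN) so that noise cannot push the logarithm to ±∞ —
and pH values outside the calibration's trusted range (default 5.5–7.4, the
in-vitro tested interval) are masked rather than extrapolated.

The shipped default calibration is **reconstructed, not a measured fit**:
plateaus Top = 2.5 and Bottom = 0.75 mM⁻¹ s⁻¹ are assumed, and midpoint
(≈6.35) and slope (≈1.12) are solved in closed form so the curve passes
through the two serum anchors r1(7.4) = 0.86 and r1(5.5) = 2.7 × 0.86
mM⁻¹ s⁻¹. Every pipeline function takes the calibration as an argument, so
a measured curve substitutes trivially.

`fit_hill` wraps bounded nonlinear least squares with data-driven starting
values. An information caveat worth stating: with a 7-point titration and
measurement noise of 1% of Top, the Fisher information of the 4PL design
bounds the achievable slope precision near 5% relative SD, so individual
noisy fits can and do exceed 5% error on the slope while the curve itself is
determined to ~1%; Monte-Carlo recovery is therefore summarised by
per-parameter medians.

## Ratiometric step and its assumptions

C = ΔR1_control / r1_control, thresholded at c_min = 0.05 mM (guards the
subsequent division; below it the concentration estimate is noise-dominated).
The sensor's per-voxel relaxivity is ΔR1_sensor / C under the assumption
that the two equal-dose injections deposit the same peak concentration in
every voxel — justified in vivo by matched pharmacokinetics (the QC block
reports both times-to-maximal-intensity so users can check it per session)
and exact by construction in the simulator. The concentration map from
injection 1 is used unchanged for injection 2; no decay correction is
applied between the two peaks, which is appropriate when the first agent has
washed out before the second baseline.

## Digital phantom

`make_phantom` builds a 48×64×8 ellipsoidal tumor (semi-axes 14×18×3
voxels) in background tissue. Within the tumor, pH and peak concentration
ramp smoothly (cubic smoothstep in normalized elliptical radius ρ, constant
for ρ<0.5, rim value from ρ>0.9) between core values (pH 6.51,
0.4 mM) and rim values (pH 6.74, 0.8 mM) — the acidic core is the *less*
concentrated region, so the simulation reproduces the confound the
ratiometric method exists to break. T10 is 2000 ms in tumor, 1800 ms in
background (plausible 7 T soft-tissue values); background pH 7.2,
background uptake 0.2 mM. The core mask is ρ ≤ 0.7, consistent with
0.7-centroid-scaling of the whole-tumor ROI for an ellipse.

Bolus kinetics are a gamma-variate surrogate, C(t) = c_peak·(τ/tp)^a·
exp(a(1 − τ/tp)) with onset 5 s after injection, tp = 60 s, a = 3 — chosen
so the peak equals c_peak exactly and washout is effectively complete
(<1e−8 of peak) before the second injection's baseline at the default
schedule (injections at 30 s and 630 s, 5 s frames, 300 s peak-search
windows, 30 s baselines). These timings are a desk-scale compression of an
in-vivo session — minutes instead of an hour — chosen so that a full
simulated session processes in seconds while preserving every structural
feature the pipeline depends on (pre-contrast baseline, distinct
non-overlapping injection windows, complete inter-injection washout).
Relaxation is fast-exchange linear, R1 = R1₀ + r1·C, matching the linear
in-vitro concentration dependence of these chelates.

Noise is Rician (magnitude MRI): independent Gaussian perturbations of SD
σ on the real and imaginary channels, specified in signal units at baseline
or as a baseline SNR. Every stochastic call takes an explicit seed; truth
maps are deterministic functions of the geometry parameters only.

What the phantom does **not** emulate: arterial-input-function physiology,
two-compartment exchange, B1 inhomogeneity, motion, partial volume at the
tumor boundary, or spatial noise correlation. Passing tests on the phantom
therefore demonstrate correctness of the *computation*, not robustness to
every property of scanner data.

## ROI machinery and statistics

Core ROIs are produced by scaling the whole-tumor mask by 0.7 about its
centroid (the centroid anchor keeps the core centred; the alternative —
bounding-box corner anchoring — was rejected as it displaces the core for
asymmetric tumors). Rasterization maps each output pixel centre through the
inverse scaling and rounds half-up (floor(q + 0.5)), giving half-open
interval semantics: a 10-pixel square at factor 0.7 yields exactly 7 pixels
a side regardless of the mask's parity or position. The scaled mask is
intersected with its parent, so core ⊆ whole and the whole = core ⊎ rim
identity hold for non-convex masks too. ROIs are typically drawn per slice
on the largest-area tumor slice (`largest_area_slice` helper); the phantom's
native 3D masks work identically.

`summarize_ph` computes statistics over valid voxels only and flags (rather
than fails on) empty-after-masking ROIs. `compare_regions` implements the
two-tailed paired t-test t = mean(d)/(sd(d)/√n) on n−1 df, reporting an
exact-tie flag when the differences have zero variance, and a Pearson
correlation of tumor size against whole-tumor mean pH; since its inputs are
per-region means, the whole-tumor mean is an optional argument, defaulting
to the core/rim average when not supplied.

## Numerical conventions

* Times in seconds, 0-based frame indices; TR in ms at interfaces.
* R1 in s⁻¹; T1 in ms; relaxivity in mM⁻¹ s⁻¹; concentration in mM.
* Invalid voxels are NaN plus a False mask bit; exceptions are reserved for
  precondition violations (bad geometry, bad config, degenerate designs).
* No global random state anywhere; seeds are explicit arguments.
* NIfTI-1 interchange; frame times in a JSON sidecar (NIfTI time-axis
  metadata is unreliable across tools); affines carried unchanged onto all
  output maps (note NIfTI-1 stores affines in float32).

## Known limitations

* Nominal flip angles; VFA-based relaxivity can differ slightly from
  variable-TR measurements at low pH, and no cross-calibration is applied.
* The equal-concentration assumption is enforced, not estimated; sessions
  with mismatched pharmacokinetics will bias pH without warning beyond the
  TMI QC values.
* The temporal-peak estimator takes a per-voxel maximum over noisy R1(t),
  which carries a small positive extreme-value bias in both ΔR1 maps; the
  bias largely cancels in the ratio (observed ROI-mean pH bias ≈ −0.02 at
  baseline SNR 50) but grows at lower SNR.
* The reconstructed default calibration's plateaus are assumptions; absolute
  pH accuracy with real data requires the measured in-vitro curve.
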