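# Methods

This note documents the models, parameters, and design choices behind
`cerevasc`, in the order data flows through the package.

## The aCBV statistic

For an ROI with voxel intensities `SI`, the apparent cerebral blood volume
is the percentage of voxels with `SI >= mean + k*SD`, default `k = 2.5`.
Choices the definition leaves open, and how this package resolves them:

- **SD denominator**: sample SD (n−1), matching common image-analysis
  software defaults.
- **Moments**: computed once over *all* ROI voxels, vessels included; the
  threshold is not re-estimated iteratively.
- **Inequality**: inclusive (`>=`), as printed.
- **Degenerate input**: a constant-intensity ROI yields 100% with a
  warning — the literal consequence of the formula at SD = 0 — rather than
  an error, and the result carries a `degenerate` flag.

Two useful consequences are tested as invariants: aCBV is invariant to
affine intensity rescaling (mean and SD transform together), and it is
non-increasing in `k`.

SNR is mean signal over the measured SD of a signal-free background ROI —
the prevailing MR convention; the package never Rician-corrects a measured
background SD, it only accounts for the Rayleigh factor when *calibrating*
the generator (below).

Percent changes are always relative to the youngest (reference) group:
`100*(ref − later)/ref` for losses, `100*(later − ref)/ref` for gains.

## Relaxometry

- T1: two-parameter magnitude inversion-recovery model
  `|S0(1 − 2exp(−TI/T1))|`, nonlinear least squares, initialised at
  `T1₀ = TI_null/ln 2` from the minimum-magnitude point. A two-parameter
  model (no inversion-efficiency term) is the documented choice.
- T2: mono-exponential `S0 exp(−t/T2)`, log-linear initialisation.
- Rates: `R = 1000/T(ms)` in s⁻¹.
- Relaxivities: per-channel OLS of rate on concentration **with a free
  intercept** — the diamagnetic baseline of the solvent. The slope is exact
  on collinear input and equals the two-point formula when only two
  concentrations are given.
- Reports round relaxivities and ratios to 2 decimals; internal values keep
  full precision.

## Deformation-based morphometry

- Jacobians: `det(I + ∇u)` with central differences in mm, one-sided at the
  boundary faces. Exact for affine fields in the interior; second-order
  convergent on smooth warps (verified by grid halving).
- Displacement convention: `u` maps the subject grid into common space, so
  `det > 1` is local expansion of the subject relative to the template.
- Group testing: per-voxel two-sample t (two groups) or one-way F (three or
  more) on **log**-Jacobians, which symmetrises expansion and contraction.
  Boundary voxels (one-sided stencils) are excluded from testing; voxels
  with no within-group variance get p = 1 and are flagged rather than
  propagating NaNs.
- FDR: Benjamini–Hochberg step-up at q = 0.05 across the voxels of an
  explicit analysis mask only (background voxels do not inflate m). The
  implementation delegates to `statsmodels.multipletests`; the test suite
  checks it against a literal step-up enumeration.
- Volumetry is exact: voxel count × spacing³, no tolerance.

Nonlinear registration itself is out of scope; displacement fields are
consumed as inputs or generated synthetically with analytic determinants.

## Histology

- Detection: 8-connected components of suprathreshold pixels in the chosen
  channel (red for CD31 rhodamine), with a configurable minimum area
  (default one square micrometre, i.e. effectively off). 8-connectivity is
  the documented choice; a diagonal-touch case in the tests pins the
  difference against 4-connectivity.
- Sizing: minor axis of the moment-equivalent ellipse, scaled by pixel
  size; single-pixel regions floor at one pixel.
- Bins: `[0,50)`, `[50,100]`, `(100,∞)` µm — the printed labels leave the
  edges open, and 50/100 are assigned to the middle bin here.
- ROI membership: centroid-in-mask, so a vessel straddling an ROI border is
  counted exactly once; the ROI area is the mask area.
- Tissue area: from a provided tissue mask when available, else the full
  frame; densities scale inversely with this choice, so it is explicit.

## The synthetic-data generator

The generator provides the study conditions the analyses are validated
against. Defaults are calibrated to the published summary tables for aging
female C57BL/6 cohorts kept in `cerevasc.calibration` (aCBV by ROI × age,
whole-brain/ventricular volumes, vessel densities, relaxivities, SNR);
group sizes default to 14/12/8 subjects at 2–4, 14–16, and 24–26 months,
and 5 sections per group for histology.

**Anatomy.** A schematic ellipsoidal brain with shell compartments (both
cortices, entorhinal cortex), interior compartments (hippocampus,
striatum), four ventricular CSF pockets, and a parenchyma remainder. It is
deliberately not a real mouse atlas; it exists to exercise ROI bookkeeping
with regions of plausible relative size. For volumetry fixtures a separate
builder produces label volumes with *exact* voxel counts (sorted
ellipsoidal distance), so Table-style volumes are reproduced to half a
voxel.

**Vessel trees.** Recursive binary branching with Murray-law radius decay
(child = parent × 2^(−1/3)) and randomised branch angles (~35°). Radii are
calibrated per ROI: a forest grows until its analytic tube volume covers
the target blood volume, radii are pre-scaled analytically, then corrected
iteratively (≤5 rounds) against the measured rasterized in-ROI occupancy —
occupancy scales as radius², so each correction is `sqrt(target/measured)`.
Each ROI's occupancy is clipped to that ROI, making per-region fractions
independent of their neighbours; per-ROI fractions land within ~2% of
target and the stored `truth_fraction_by_roi` is exactly
`100·Σocc/N_voxels` per ROI. Fractions above 20% are rejected as saturated.

Vessel calibre adapts to the target fraction (≈3.2–3.5 voxel root radii,
unbranched at sparse fractions, branching at dense ones). This is
deliberate: the aCBV statistic counts whole voxels, so its accuracy against
a planted fraction is limited by the partial-volume rim of each tube, a
fixed share of the cross-section. With sub-voxel vessels the statistic
would measure "apparent" volume far above truth — the very effect that
makes real aCBV apparent. The phantoms therefore plant *resolvable*
vessels, and passing recovery tests demonstrate correctness of the
statistic, not that real (100 µm)³ data measure true microvascular volume.

**Rasterization.** 2× supersampled sub-voxels, each contributing a
linear-ramp coverage `clip((r−d)/w + ½, 0, 1)` of its radial distance to
the segment axis (ramp width w = sub-voxel size), with axial ramps closing
the cylinder ends. The ramp integrates to the analytic tube volume with
bias ~πw²/12 per unit length and suppresses the lattice aliasing a hard
inside/outside test suffers for grid-aligned vessels; accuracy is within
5% for radii ≥ 0.75 voxel.

**MR signal.** Steady-state spoiled-GRE (Ernst) signal per compartment,
with the published protocol as defaults: TR 50 ms, TE 4.07 ms, FA 34°,
(100 µm)³ voxels. Tissue values are literature-typical for mouse at 7 T and
documented as such, not source-derived: blood T1/T2* 2200/25 ms, parenchyma
1700/30 ms (PD 0.8), CSF 4000/60 ms. Contrast shortens blood relaxation by
linear rate additivity `1/T_post = 1/T_pre + r·C` with the Gd-micelle
relaxivities (r1 12.90, r2 17.80 mM⁻¹s⁻¹).

Three calibrations close the loop with the published measurements:

1. **Blood Gd concentration** (0.12 mM): chosen so the post/pre vascular
   *signal* gain equals the measured 3.19-fold SNR improvement.
2. **Noise sigma**: set so the measured post-contrast vascular SNR is
   115.13 under the convention above; since the background of a magnitude
   image is Rayleigh, `sigma = S_blood_post/(115.13·sqrt(2−π/2))`. With
   (1) in place the pre-contrast SNR then lands on its own 36.14 target
   automatically.
3. **Pre-contrast inflow**: without contrast, only large-calibre vessels
   are visible in vivo (time-of-flight effect); this is modelled crudely as
   an elevated effective proton density in segments ≥150 µm radius, scaled
   to the pre-contrast SNR target (≈1.0 after calibration (1)), and is
   illustrative, not quantitative.

**Tissue texture.** Parenchymal heterogeneity (grey/white contrast, coil
bias) is modelled as a multiplicative **uniform** modulation ±43% of the
local base signal. Uniform rather than Gaussian is deliberate: bounded
texture can never cross the vessel threshold on its own, so noiseless
phantoms have zero false-positive voxels by construction. The width makes
the ROI intensity SD behave like real heterogeneous tissue relative to the
vessel-tissue contrast.

**Noise.** Rician: `|S + n₁ + i·n₂|` with iid Gaussian components —
the standard magnitude-MRI model. `sigma = 0` is an exact identity.

**Seeding.** One master seed; every (subject, stage) pair draws from a
sub-stream derived via CRC32-hashed `SeedSequence` entropy, so generators
are pure functions of spec + seed and adding a stage never perturbs others.

**IHC sections.** Non-overlapping ellipses (aspect 1–2, minor axis from a
mixture dominated by 8–42 µm diameters with small 50–100 and >100 µm
tails, weights matching the published composition) at foreground intensity
220 over background 30 in the red channel. Sampled diameters keep a margin
from the 50/100 µm bin edges so moment-based sizing cannot flip a bin.
Placement is rejection sampling with a 1.5-px moat (regions stay distinct
under 8-connectivity); infeasible densities fail explicitly.

**What the generator does not emulate:** real neuroanatomy, hemodynamic
flow, k-space acquisition, registration error, pharmacokinetics beyond a
scalar concentration, stain variability, or histological shrinkage.
Passing tests therefore validate the *analysis* implementations against
known truth — they do not certify accuracy on real scanner or slide data.

## Statistics

- Normality: D'Agostino–Pearson omnibus, Shapiro–Wilk, and Lilliefors
  (the estimated-parameter KS correction) at α = 0.05, normal iff ≥2 of 3
  pass. Below n = 8 the omnibus test is not applicable; the battery
  degrades to the remaining tests and records how many ran.
- t-tests are pooled-variance (Student), two-tailed.
- Tukey HSD uses the studentized range with Tukey–Kramer for unequal n
  (via `scipy.stats.tukey_hsd`; cross-checked against statsmodels in the
  tests). Degenerate zero-variance layouts yield p = 1 with a flag.
- Two-way ANOVA is restricted to complete balanced designs (where Type-I
  sums of squares are unambiguous); the age × size-bin layout it serves is
  balanced. Interaction is reported when the design is replicated.
- Stars: `*` p<0.05, `**` p<0.01, `***` p<0.001, `****` p<0.0001, strict
  inequalities (p = 0.05 exactly earns no star).

One replicated quirk: cohorts containing longitudinally re-imaged animals
are analysed with between-subjects ANOVA, as in the workflow this package
reproduces, rather than a repeated-measures model; a mixed-effects
treatment is an explicit non-goal.

## Problem sizes and numerical tolerances

- Recovery phantoms: 64³ voxels at 100 µm. Cohort-replicate phantoms: 40³
  — the detection statistic depends on between-subject spread, not grid
  size, and 40³ keeps a 20-replicate × 22-subject simulation to seconds.
- Cohort-loss detection power: with group means 1.64 vs 1.24%, SDs
  0.18/0.29, and n = 14/8, the two-sample noncentrality is ≈4.0, putting
  per-replicate detection probability near 0.95; 18–20 detections out of
  20 replicates is the expected range, and occasional 17s are consistent
  with that binomial, not a pipeline defect.
- Rasterization accuracy: 5% on tube volume for radii ≥ 0.75 voxel;
  per-ROI fraction calibration stops at 2% relative.
- Curve fits: noiseless IR/CPMG round trips are asserted at 0.1%;
  relaxivity on collinear input at 1e-9 relative.
- Null-calibration tests use 2000 replicates with a ±3.3-SE band (~±0.016
  around 0.05); Lilliefors gets twice that band because its p-values come
  from an approximation table.

## Known limitations

- The schematic anatomy makes no claim of anatomical validity; ROI-level
  effects in real atlases (partial-volume at ROI borders, registration
  error) are not represented.
- aCBV recovery accuracy is specific to resolvable-calibre phantoms; on
  real data the statistic remains "apparent" by design.
- The TOF (no-contrast) arm is qualitative.
- Analyze-mode orchestration covers the per-analysis CLI commands; the
  end-to-end `run_pipeline` orchestrates the simulated study only.
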