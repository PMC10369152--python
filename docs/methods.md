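# Methods

`fdopa` quantifies presynaptic dopamine synthesis capacity from dynamic
6-[¹⁸F]fluoro-L-DOPA (FDOPA) PET using the cerebellar reference-region
Gjedde–Patlak graphical method, with rigid-body motion quality control,
total-variation (TV) denoised parametric maps, SUVr, and a test–retest
reliability battery.  Because real FDOPA archives are institutional and
restricted, the package carries a compartmental phantom generator whose
ground truth is known by construction; every pipeline stage is validated
against it.

## Quantification model

For an irreversibly trapped tracer with reference-region input, plotting

y(t) = C_T(t)/C_ref(t)  against  x(t) = ∫₀ᵗ C_ref dτ / C_ref(t)

yields a line for t ≥ t\* whose slope is the net influx rate constant
Ki^cer (min⁻¹).  Implementation choices:

- Integration is trapezoidal on frame mid-times with an implicit (0, 0)
  sample — frames begin at injection, when activity is zero.
- t\* = 20 min, applied inclusively to frame mid-times.
- Points where C_ref ≤ 10⁻⁶ × max(C_ref) are dropped and counted.
- The fit is unweighted ordinary least squares (a frame-duration
  weighted option was considered and left out: on the phantom the late
  frames have equal duration, so the two coincide).  Negative slopes are
  retained, not clipped — low-uptake regions legitimately fit slightly
  negative.
- Voxelwise maps share the reference-derived x design across voxels, so
  the per-voxel fit reduces to a closed-form slope/intercept; voxels
  with non-finite or all-zero time courses are NaN.

SUVr is the ratio of target to cerebellar mean activity over 60–75 min,
with frame weights equal to the overlap (minutes) between each frame's
interval and the window.  Under the default 32-frame schedule the three
300-s frames tile the window exactly, making the rule exact there.

Decay correction multiplies each frame by 2^(mid/half-life) with the
frame mid-time and the F-18 half-life (109.77 min) by default; a guard
refuses double correction.

## Motion correction and QC

Frames are realigned to the frame whose mid-time is nearest 15 min (the
usual signal/contrast optimum for bolus FDOPA).  Per frame, a 6-DOF
rigid transform (translations in mm; pitch/yaw/roll about the volume
centre) is estimated by minimizing an intensity-rescaled mean-squared
difference: the optimal global intensity scale is solved analytically
inside the cost, because tracer kinetics change overall frame intensity
and a plain MSE converts that contrast change into spurious geometry.

Estimation is multi-resolution with deliberate interpolation hygiene:

1. a Nelder–Mead pass on 8-mm-FWHM-smoothed, half-sampled grids
   (capture range ≈ the simplex scale, 2 mm / 0.04 rad);
2. a coordinate-wise parabolic polish on the unsmoothed full grid using
   cubic-spline interpolation.  Trilinear interpolation slightly blurs
   the moving frame at sub-voxel shifts; combined with smoothing this
   biases the optimum by a few tenths of a millimetre whenever frame
   contrast differs from the reference, which is why the polish uses
   cubic interpolation on unsmoothed data.

Rotations are optimized as arc length at a 50 mm radius so all six
parameters share millimetre units.  Frames whose smoothed signal energy
is below 25% of the reference frame's keep the identity transform: the
15-s frames in the first ~2 min carry almost no tracer and would be
matched on noise alone, while contributing negligibly to Patlak
quantification (t\* = 20 min).

Framewise displacement combines the parameter steps as
fd = ‖Δt‖ + r·‖Δθ‖ with r = 50 mm (the common head-radius convention);
steps are consecutive-frame differences by default, with a
frame-to-reference option.  A step strictly greater than 5 mm is a
spike (5 mm ≈ the nominal spatial resolution of clinical PET) and flags
the scan; a scan whose maximum fd reaches 8 mm fails QC.  "Total
motion" is the sum of fd over steps; the maximum feeds the 8 mm rule.

## TV denoising

Before the voxelwise fit each realigned frame is denoised with
Chambolle's dual projection algorithm for the ROF objective
‖u−f‖²/(2·weight) + TV(u), with per-iteration primal energy tracked
(and asserted non-increasing in the tests).  The iteration mirrors the
scikit-image implementation — which the tests use as an independent
cross-check — but exposes the energy trace.  Stopping: relative energy
change below `tol` (2×10⁻⁴) or `max_iter` (200).

The default weight is 0.02 × the image's robust maximum (99.5th
percentile).  A stronger default (0.1 ×) was evaluated and rejected: at
the phantom's 4-mm voxels the striatal blobs span only a few voxels,
and that weight over-regularizes them, biasing the striatal voxel-mean
Ki by about −10%; 0.02 keeps the bias under 2% while still reducing
voxel noise.  On higher-resolution data a larger weight may be
appropriate; it is a config key (`tv_weight_rel`, CLI `--tv-weight`).
Denoising is 3D per frame; denoising the finished Ki map instead is
available as a library call.

## Phantom generator

The phantom emulates the 95-min bolus acquisition: 32 frames
(8×15 s, 3×60 s, 5×120 s, 16×300 s) on a 32×32×24 grid of 4-mm voxels
with bilateral ellipsoidal striatal blobs, a cerebellar blob, and brain
background inside a head ellipsoid.

- **Plasma input**: a Feng-type bolus (fast rise, tri-exponential
  decay), time-dilated so its peak sits at a configurable time (default
  1 min) and scaled to a configurable peak activity (default
  100 kBq/mL).  The acquisitions being emulated are blood-free; the
  reference-region method needs no plasma input, but the simulator
  does.
- **Tissue model**: two-tissue irreversible system
  dC₁/dt = K₁C_p − (k₂+k₃)C₁, dC₂/dt = k₃C₁ (reference: k₃ = 0),
  solved on a dense grid with an exact exponential update per step
  (plasma piecewise linear); an adaptive-ODE solve is the independent
  oracle in the tests.  Peripheral metabolite compartments are omitted
  — the emulated protocol premedicates with carbidopa/entacapone,
  suppressing peripheral metabolism — but a low-uptake background term
  stands in for non-specific signal.
- **Default kinetics**: cerebellum K₁ = k₂ = 0.10 (distribution volume
  1, so the reference-Patlak slope approximates the plasma net influx);
  striatum K₁ = 0.13, k₂ = 0.10, k₃ solved so K₁k₃/(k₂+k₃) = 0.0137
  min⁻¹ (the population mean).  These rates equilibrate the reversible
  pools well before t\* (Patlak slope within 1% of its asymptote) and
  put the late striatum/cerebellum ratio near the population mean SUVr
  of ≈2.3.  Background: K₁ = k₂ = 0.10 with k₃ for Ki = 0.0005 min⁻¹
  (occipital-like).
- **Texture**: a smooth multiplicative tissue-heterogeneity field (10%
  SD, zero-mean within each region so regional mean TACs equal the
  generator TACs exactly).  Without within-region structure, rigid
  rotations are nearly unidentifiable — a geometric artefact of
  piecewise-constant phantoms, not a property of real brains.  The
  texture seed is separable from the noise seed so test–retest
  "subjects" keep their anatomy across sessions.
- **Noise**: i.i.d. Gaussian per voxel and frame with SD
  σ₀·√(mean brain activity / frame duration) — a reconstruction-noise
  proxy reproducing the shorter-frame/noisier behaviour.  The default
  σ₀ = 0.5 gives ≈3–5% voxel noise on late striatal frames, a mild
  regime for modern scanners.  Real PET noise is spatially correlated
  and non-Gaussian at low counts; conclusions about absolute noise
  robustness do not transfer, trends (e.g. reliability falling with
  noise) do.
- **Motion**: optional per-frame rigid transforms applied by trilinear
  resampling (the inverse operation of realignment).
- **Exact-recovery oracle**: `patlak_consistent_tac` constructs a
  target TAC whose Patlak plot is exactly linear using the same
  anchored-trapezoid convention as the transform, so slope recovery is
  exact to numerical precision regardless of the schedule.

## Reliability statistics

Two-way mixed-model, single-measure ICC from the subject×session ANOVA
decomposition.  "Two-way mixed" (SPSS terminology) is ambiguous between
consistency and absolute agreement; the default is the consistency form
ICC(3,1) = (BMS − EMS)/(BMS + (k−1)EMS), which ignores a constant
session/pipeline offset — the right behaviour when comparing pipelines
that may differ by calibration.  `kind="agreement"` adds the session
variance component.  %VAR is the mean over subjects of
100·|test−retest|/pair-mean (a session-1 denominator is available);
Bland–Altman limits are bias ± 1.96·SD(differences) with sample SD;
agreement between two pipelines is Pearson r plus the mean absolute
percentage difference.  F-distribution confidence intervals for the
ICC are provided but have no external check.

## Validation experiments and problem sizes

Desk-scale sizes are part of each experiment's definition:

- **Motion recovery**: 20 phantoms, 24×24×18 grid, a 15-frame
  "desk schedule" (4×2.5, 5×5, 6×10 min — same 95-min span, no
  sub-minute frames so every frame is realignable), default noise,
  per-axis perturbations U(±2.8 mm)/U(±1.7°) on frames after 5 min.
  Medians of the absolute parameter errors are the outcome.
- **End-to-end reliability**: 8 subjects × 2 sessions × 3 noise levels
  (σ₀ = 0.2, 1.5, 4.0 — chosen widely separated a priori), 20×20×14
  grids, desk schedule, full pipeline runs (realignment, QC, regional
  Patlak, SUVr; the voxelwise map is skipped since the outcome is the
  regional Ki).  Subject Ki drawn from N(0.0137, 0.0015²); anatomy
  (texture) fixed within subject, noise independent across sessions.
- **ICC calibration**: 500 replicated 50×2 tables from the
  variance-components model; the mean estimate should sit within 0.05
  of σ_b²/(σ_b²+σ_w²).

## Degenerate inputs and numerical conventions

- Realignment: a frame whose optimizer does not converge keeps the
  identity transform and is reported via a warning; a signal-free
  reference frame is an error.
- Patlak: fewer than 3 usable late points is an error; an all-dropped
  point set is an error.
- TV: non-finite input is an error; weight 0 is the exact identity.
- `decay_correct` refuses an already-corrected image.
- All grids are assumed co-registered; masks must be supplied in image
  space (atlas-to-image registration is out of scope).
- Randomness: every stochastic path takes a mandatory integer seed
  (numpy `default_rng`); identical seeds give bit-identical phantoms.

## Known limitations

- The phantom has no attenuation, scatter, partial-volume or
  point-spread physics; recovery coefficients and PVE-driven biases
  cannot be studied with it.
- Rigid realignment is frame-to-frame only; within-frame motion and
  attenuation-map misalignment detection are out of scope.
- The noise law is a stand-in (see above); acceptance tolerances are
  defined under it.
- The plasma input is parametric, not fitted to measured blood data.
- Reference-Patlak slopes carry the usual small negative bias when the
  reference distribution volume has not fully equilibrated; with the
  default kinetics this is under 1% but it grows for slower k₂.
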