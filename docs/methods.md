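# Methods

This note documents the models, numerical choices and limitations behind
`thermorun`. The package analyses infrared-thermography (IRT) recordings of
the calves during treadmill running together with synchronized sensor
streams (heart rate, oxygen uptake, core temperature, perceived exertion,
ambient conditions), and ships a synthetic-data generator that stands in
for raw camera recordings, which are not redistributable.

## The measurement setting being emulated

A radiometric camera (30 fps, 0.02 K thermal resolution, range set to
25–35 °C, emissivity 0.98) views the posterior lower legs from a fixed
position while a runner completes one of three 49-min sessions:

* 10-min warm-up at 60 % of the velocity at the individual anaerobic
  threshold (vIAT), treadmill incline 1.5 %;
* a 36-min main block with an 85 % vIAT *average* load — T1 runs it
  entirely continuously (CON); T2 runs 18 min CON then 18 min
  intermittent (INT: three alternations of 3 min at 105 % and 3 min at
  65 % vIAT); T3 runs the same two halves in reverse order;
* 3 min of recovery walking at 4 km/h.

Four skin-temperature metrics are computed per analysed frame from a
4-label segmentation (background / non-vessel calf / superficial vein /
perforator vessel): T_MEAN over the whole calf, T_NV over non-vessel
tissue, T_V over veins, T_P over perforators, each with the Shannon
entropy of its pixel temperatures. Empirically these metrics keep a fixed
ordering, T_V > T_P > T_MEAN > T_NV.

## Synthetic physiology

Reported exercise physiology is *described*, not mechanistically modelled,
in the source literature; the generator therefore uses the simplest
dynamical structure that reproduces the reported magnitudes — linear
first-order systems driven by the commanded load u(t) (% vIAT, piecewise
constant):

* HR and VO2 relax toward load-proportional targets
  (`hr_rest + hr_gain·u`, τ_HR = 40 s; `vo2_rest + vo2_gain·u`,
  τ_VO2 = 45 s).
* Core temperature is a saturating ramp,
  dT_C/dt = (u/85)·(T_max − T_C)/τ_C with T_max = baseline + 1.2 °C and
  τ_C = 2400 s — monotone for u ≥ 0, ≈ +1 °C over a session.
* Non-vessel skin temperature combines three terms:
  T_NV = baseline − A·x_fast + g·(T_C − T_C0) + r, where x_fast relaxes
  toward u/85 with τ_fast = 60 s (sympathetic vasoconstriction,
  A = 1.8 °C), g = 0.5 couples stored heat back to the skin, and the
  rebound r relaxes toward 0.5 °C with τ = 90 s only while the protocol
  is in its walking phase (post-exercise cutaneous vasodilation).
* Vein and perforator temperatures are constant offsets above T_NV
  (+1.2 / +0.7 °C), matching the observed metric ordering.
* A small Ornstein–Uhlenbeck term (sd 0.02 °C, τ = 240 s) represents slow
  vasomotor variability. It is part of the *ground truth* (not
  measurement noise), so repeated sessions of one runner can share it
  (same physiology seed) while frame and sensor noise differ — the
  repeated-measures design the reliability statistics are built for. Its
  scale was fixed once so that the default warm-up drop stays inside the
  calibration window below.

All states are advanced with the exact exponential-integrator step for
piecewise-constant inputs (dt = 1 s). For these linear systems the step is
exact, so noise-free step responses agree with the closed-form solution
`y(t) = rest + gain·u·(1 − e^(−t/τ))` to machine precision — this is
asserted at 1e-6 in the tests.

With default parameters the generator is calibrated to the reported
response magnitudes: the warm-up T_NV drop lies in [−1.3, −1.1] °C within
3 min of onset, and the mean post-exercise 3-min rise across the four
metrics lies in [1.1, 1.8] °C (≈ +1.4 °C).

## Synthetic scene

Frames are rendered as a linear combination of static unit fields:
`ambient + (T_NV(t) − ambient)·body + ΔV·vein + ΔP·perf (+ noise)`,
where the body field covers two elliptical calves, the vein field is a set
of smooth curvilinear strokes and the perforator field a set of compact
blobs. Vessels are painted flat-top (full offset within one cross-profile
sigma of the centreline, Gaussian falloff outside), so the mean over the
labelled vessel core equals the nominal offset exactly; ground-truth
metric series are then exact linear functions of the physiology targets
with precomputed geometric coefficients. During the swing (flight) half of
each gait cycle the calf area shrinks by 35 % and the component fields are
pre-blurred with a σ = 3 px Gaussian (motion blur); this makes rendering a
handful of array operations per frame.

Desk-scale defaults: 96×128 px frames at 2 fps for the full 49-min
timeline (5 881 frames per session), with the gait slowed to 0.4 Hz so a
gait cycle remains resolvable at the reduced frame rate; full-rate
acquisition (30 fps, ~2.8 Hz cadence) is available through `SceneConfig`.
Pixel noise is i.i.d. Gaussian, σ = 0.05 °C. Geometry derives from the
scene seed, so one runner keeps one vessel pattern across sessions.

Deliberately not modelled: biomechanical gait realism, perspective and
occlusion geometry, atmospheric radiometry, sweat films, and any
day-to-day drift of camera calibration. Consequently, passing tests
demonstrate the correctness of the *pipeline* (segmentation contract,
selection, metrics, fusion, statistics) under controlled conditions; they
do not certify segmentation accuracy on real thermograms, where texture
and occlusions are far richer.

## Segmentation

The learned segmentation models of the original acquisition chain (and
their training images) are not available, so the package fixes the stage's
contract — frame → 4-label mask — and ships two implementations plus an
injection point for external masks:

* **classical**: Otsu (or fixed) threshold for the body, morphological
  opening (radius 2), hole filling, keep the ≤ 2 largest components above
  a minimum area; then vessel enhancement as the pixelwise max of
  multiscale Hessian tubeness (Sato, bright ridges, scales {1, 1.5, 2.5} px)
  and a white top-hat, computed after inpainting the background with the
  body median so the calf outline itself contributes no edge response;
  candidates are thresholded at a within-body quantile (default 0.78) with
  an absolute floor (0.3) so structure-poor frames promote nothing;
  components with major/minor axis ratio ≥ 3 become veins, other
  components with area in [6, 200] px become perforators, the rest return
  to non-vessel calf.
* **oracle**: passthrough of the generator's ground-truth masks, which
  isolates every downstream stage from segmentation error.

On the default 20-scene battery the classical mode reaches body Dice
≈ 1.0 (noise-free and at default noise) and vein∪perforator Dice ≈ 0.75
(floor asserted at 0.6).

## Frame selection and fusion

Only stance-phase frames are analysed: the timeline is partitioned into
windows of one gait cycle (`round(fps / step_frequency)` frames;
step frequency defaults to 2.8 Hz for full-rate data and to the scene gait
frequency for synthetic sessions) and the frame with the largest
segmented calf wins each window, ties toward the earlier frame. Windows
whose best area falls below half the running median of selected areas are
rejected as occluded.

Sensor traces are linearly resampled onto the selected-frame timeline
(endpoints held), gaps are filled linearly (nearest value at the ends),
and series are smoothed with a Savitzky–Golay filter (polyorder 3). The
reference window of 151 samples corresponds to ≈ 54 s at the full-rate
selected-frame cadence; the pipeline therefore fixes the *physical* window
(54 s) and converts it to an odd sample count at whatever rate the data
has, so desk-scale runs are smoothed over the same time span. For cohort
visual series a 3rd-order zero-phase Butterworth low-pass (cutoff 0.04 of
Nyquist — the conventional normalised parameterisation) and a rolling
median (window 350 samples on the 1-s cohort grid) are provided.

Each treadmill stage is summarised by the mean over its final 5 s with
samples inside treadmill acceleration/deceleration ramps excluded (ramp
model: 1 (km/h)/s plus a 2-s margin on both sides — the exclusions are
stated upstream but not their durations). Phase deltas (ΔT_NV, ΔT_P, …)
are differences of 5-s anchor means at Pre / WU-end / FH-end / SH-end /
REC-end.

## Derived physiology

* BSA by Mosteller: √(height_cm · mass_kg / 3600).
* Metabolic rate from VO2 with the energy equivalent of oxygen
  interpolated between fat (19.62 kJ/L at RER 0.7) and carbohydrate
  (21.13 kJ/L at RER 1.0); RER clamped to [0.7, 1.0] with a warning.
* External work on the inclined treadmill as vertical lifting power
  m·g·v·grade (small-angle; level-running external work 0).
* MHP = (metabolic rate − external work)/BSA [W/m²]; sweat loss as the
  pre/post body-mass difference; core-to-skin gradient T_CORE − T_NV.
* Dickhuth individual anaerobic threshold from a lactate–velocity table:
  the lactate equivalent lactate/velocity is minimised (parabolic
  refinement through the three stages around the discrete minimum) and
  the IAT is the velocity where lactate exceeds the threshold value by
  1.5 mmol/L, by piecewise-linear interpolation above the threshold. The
  original formulation divides by VO2 when available; velocity is used
  here as the running-specific equivalent.

## Reliability statistics

Written from first principles (libraries are used only as test-side
cross-checks):

* Pearson/Spearman correlation with two-sided t-approximation p-values
  and Cohen magnitude bands (|r| < 0.1 trivial, < 0.3 small, < 0.5
  moderate, ≥ 0.5 large).
* Repeated-measures correlation: common within-subject slope after
  removing per-subject intercepts; r_rm = sign(slope)·√(SS_x/(SS_x+SS_e))
  on within-subject-centred data, df = N − n_subjects − 1, p from the F
  statistic; 95 % CI by subject-cluster percentile bootstrap (default
  2000 replicates, seeded). Subjects with fewer than two observations are
  dropped; no within-subject x variance is an error.
* Two-way single-measure ICCs from the two-way ANOVA mean squares:
  consistency ICC(3,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E) and absolute
  agreement ICC(2,1) = (MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C −
  MS_E)), with the standard F-based confidence intervals and reliability
  bands (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent;
  the shared boundary values fall in the closed lower band). Rows with
  missing cells are dropped listwise. Both estimators agree with
  independent sum-of-squares/design-matrix oracles to 1e-10 and with
  `pingouin` to machine precision in the tests.
* Median split of participants on an attribute: with odd n the median
  participant joins the lower group; ties break by id.

Section-wise reproducibility compares aligned fused T_NV series across
sessions per participant over six exercise sections — warm-up (T1·T2·T3),
the continuous-load half-blocks pairwise (T1–T2, T1–T3, T2–T3), the
intermittent half-block (T2–T3) and recovery (T1·T2·T3) — on a 5-s
within-section grid. Pooled estimates stack the per-participant matrices
(participants with a deviating session count are excluded from the pool,
flagged in the table); per-participant ICCs are reported alongside, since
the appropriate pooling is a design choice rather than a derived fact.
No multiple-testing correction is applied to the correlation panels by
default; a Holm step-down (`stats.holm_bonferroni`) is available for
callers who want adjusted p-values.

## Orchestration and problem sizes

`run_session_analysis` chains the seven stages (synthdata → segment →
frameselect → metrics → fuse → physio → stats), records a JSON manifest
(seeds, parameter hash, stage list) and is bit-identical on rerun with the
same config. In classical mode the body pass runs on every frame (for the
area series) and the vessel pass only on selected frames.
`run_reproducibility` runs T1/T2/T3 per participant — one physiology seed
per runner across sessions, fresh noise seeds per session — and emits the
section ICC table, the cohort median T_NV series and rmcorr panels
(T_P vs HR and VO2 over the intermittent block, entropy of T_P vs T_CORE
over the warm-up).

Default problem sizes were chosen so a full single session analyses in
~10 s and the 11-runner, 3-session reproducibility study in a few minutes
on one CPU: 96×128 px frames, 2 fps over the full 49-min timeline,
≈ 1 176 selected stance frames per session.

## Known limitations

* Constant vessel offsets mean all four metrics share one post-exercise
  rise; the reported spread between T_NV and T_V rises is not reproduced,
  only their mean magnitude.
* The entropy of T_P carries little physiological signal in the synthetic
  scenes (it is driven by noise and geometry, not by perfusion state), so
  the warm-up entropy–T_CORE correlation panel is computed but weak.
* The classical segmenter is tuned to the synthetic vessel morphology; on
  real thermograms a learned model injected through the external-mask
  interface should replace it.
* ICCs on low-variability sections are noise-dominated by construction —
  the same statistical caveat the reliability literature attaches to ICC
  under restricted range.
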