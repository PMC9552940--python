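# Methods

## Problem and scope

`pulseicp` implements a noninvasive intracranial-pressure (ICP) estimation
analysis for multi-channel hemodynamic recordings: near-infrared
spectroscopy (NIRS) hemoglobin-concentration changes at 50 Hz (two
wavelengths, 690/830 nm), an optional relative cerebral-blood-flow (CBF)
index at 100 Hz, arterial blood pressure (ABP) and invasive ICP at 100 Hz,
and an R-peak event train.  The premise is physiological: the cardiac
pulse waveform in cerebral hemodynamic signals broadens and skews
rightward as ICP rises, so shape features of an ensemble-averaged pulse,
together with mean arterial pressure (MAP), carry enough information for a
regression model to recover ICP in the 0–30 mmHg range.

Because no public recordings of this kind exist, the package ships a
first-class synthetic-data generator that emulates the stepped-ICP
experimental design and provides sample-aligned ground truth for every
latent quantity, so the whole chain is testable end to end.

## Synthetic-data generator (`synthgen`)

Each subject contributes `trials_per_subject` trials (default 8: a
baseline plus stepped targets 5–30 mmHg), each a continuous recording at
one ICP level.  Defaults use desk-scale 600-s trials; the full-scale
(~90-min) experiment is the same generator with `trial_duration_s=5400`.

**Pulse model.**  One beat is a sum of three positive Gaussian lobes
(percussion, tidal, dicrotic) on the [0, 1] beat-phase axis, with the
linear baseline through the endpoints removed so the beat starts and ends
exactly at its diastolic minimum.  ICP enters through three linear
sensitivities:

- `width_per_mmHg` (default 0.02): all lobe widths grow by this fraction
  per mmHg (broadening);
- `skew_per_mmHg` (default 0.003): lobe centers shift rightward
  (skewness);
- `notch_decay_per_mmHg` (default 0.01): the dicrotic lobe amplitude
  decays as `exp(-c·ICP)`.

These defaults are a declared calibration: they were chosen (once) as the
region of coefficient space where both the waveform-centroid abscissa
(COMx) and the half-prominence peak width (P1w) are strictly increasing
in ICP across the physiological heart-rate range, with an effect size
that makes the downstream regression good but imperfect at the default
noise level.  They are configuration, not empirical claims.

**Beat grid.**  Beat onset times accumulate `60/hr_k` seconds with AR(1)
fractional heart-rate jitter (`hr_jitter_sd`, default 0.02); boundary
sample indices are the nearest 50-Hz samples, so rounding error never
accumulates and consecutive beats tile the record sharing their boundary
sample.  Subject heart rates are drawn uniformly from (93, 184) bpm, so
120 consecutive beats span 39–78 s.

**Coupling and noise.**  The latent ICP trace is the trial target plus a
smooth drift (two random-phase sinusoids, amplitude `icp_drift_mmHg`,
default 1 mmHg) plus a zero-mean pulsatile component.  MAP is linearly
coupled, `MAP = map_base + map_slope·ICP + slow noise`, where the noise
(default SD 3 mmHg) is a random-phase sinusoid sum with 40–400-s periods —
deliberately slow so it survives 120-beat window averaging and MAP stays
only loosely informative about ICP, reproducing the observed poor raw
MAP–ICP correlation.  Optical channels are amplitude-scaled pulse trains
plus white Gaussian noise (`noise_sd`, default 0.2 of pulse amplitude per
50-Hz sample).  Step (1–3 s) and spike instability artifacts are planted
at `artifact_rate_per_h` (default 2/h) across the optical channels, and
rare beats are emitted at 3x amplitude (`outlier_beat_rate`, default
0.002).  All planted corruption is logged in `GroundTruth`.

**What the generator does not emulate:** photon transport, DCS
autocorrelation physics, respiration and ventilation coupling,
autoregulation dynamics, inter-subject morphology idiosyncrasies beyond
heart rate, and electrode/probe drift.  Passing tests therefore show the
*pipeline* is correct and the *statistical machinery* behaves as
documented — not that the regression accuracies transfer to real
recordings.

## Processing chain (`hemo`, `beats`, `acpw`)

- **MBLL conversion.**  Optical-density changes are converted to
  hemoglobin changes by solving the 2x2 modified Beer–Lambert system per
  sample.  Extinction coefficients default to the Gratzer/Prahl
  compilation values at 690/830 nm (stored in `hemo.py`, overridable).
  Only the DPF *ratio* (default 1.1 = DPF690/DPF830) affects waveform
  shape after amplitude normalization; the absolute DPF830 (default 4.0)
  sets the concentration scale and cancels downstream.
- **Resampling.**  Continuous channels are brought to 50 Hz by polyphase
  anti-alias filtering (`resample_poly` with line-extension padding —
  zero padding leaks edge transients of ~1e-4 into window-mean labels).
  Event trains are index-remapped to the nearest grid sample.
- **Artifact masking.**  First differences scoring above
  `jump_sd_thresh` (default 10) robust SDs (median/MAD) are masked and
  padded by 2 s per side.  This is an automated surrogate for manual
  removal of visually identified laser instabilities, not a reproduction
  of it.  The threshold sits between the clean pulse's steepest systolic
  upstroke (robust z up to ~7 on noiseless data) and planted instability
  jumps (z ≈ 30–50).
- **R peaks.**  When no hardware event train exists, QRS complexes are
  enhanced by summing the stationary-wavelet (undecimated, `sym4`)
  detail levels covering ~10–45 Hz, squaring, and peak-picking with a
  0.25-s refractory distance and an adaptive median-based threshold;
  detections are refined to the local EKG extremum within ±40 ms.
- **Segmentation.**  The diastole for each R peak is the signal minimum
  in [R−0.25 s, R+0.05 s] (earliest sample on ties); a beat spans
  consecutive diastoles inclusive of both boundary samples.  Beats
  overlapping masked samples or with inter-beat intervals outside
  [0.25, 1.5] s are dropped whole.
- **Averaging.**  120 consecutive beats are averaged with a 20-beat step
  (83.3% window overlap).  Each beat is first cubic-spline resampled to
  66 points (1.32 s at 50 Hz) and min–max scaled — pointwise averaging
  across varying beat lengths requires per-beat normalization first —
  then the window mean is re-min–max scaled.  Window ICP/MAP labels are
  the means of the member beats' raw means.  Windows never span trial
  boundaries.
- **Outlier rejection.**  Within a trial, each waveform's score is the
  mean over the 66 points of |y − mean|/SD against the trial's pointwise
  statistics; scores above 3 are rejected.  This mean-absolute-pointwise-z
  reading is symmetric and scale-free and flags whole-waveform outliers.
- **Kalman smoothing.**  A 66-dimensional ideal-pulse state with
  independent per-point random-walk dynamics (process noise `q`, default
  1e-3) is updated by each waveform with scalar gain `K = P/(P+r)`
  (observation noise `r`, default 1e-2).  The emitted waveform is the
  observation corrected toward the ideal pulse,
  `y' = y − (1−w)(y − x̂)` with blend weight `w = P/(P+r)`: the
  observation is trusted in proportion to the state uncertainty.  As
  `q → ∞` the filter trusts observations fully and the output equals the
  input; identical inputs are a fixed point.  At the defaults the filter
  cuts waveform RMSE to the noiseless template by ~40% at additive noise
  SD 0.1.  The defaults are an empirical calibration (configuration).
- **ICP ceiling.**  Waveforms with window-mean ICP above 30 mmHg are
  discarded as too scarce to learn from.

## Features (`features`)

Eight features per waveform, all on the normalized [0, 1] beat axis so
heart rate is removed exactly: P1pk/P1pos/P1p/P1w (height, position,
topographic prominence, half-prominence width of the most prominent
interior peak; ties broken earliest; all four 0 if no interior peak
exists), COMx/COMy (shoelace centroid of the polygon closed by the y=0
baseline), AUC (trapezoidal area), and MAP (window-mean arterial
pressure, mmHg).  P1pk is 1.0 whenever the global maximum is an interior
peak, so its learned importance acts as a noise sentinel.

## Regression and evaluation (`mlcore`)

A scikit-learn random forest with 100 trees, each grown to purity on an
80% bootstrap subsample with 50% feature sampling (applied per split, as
that estimator defines it) and the squared-error criterion.  Labels are
the invasively measured window-mean ICP values.  Evaluation uses random
fivefold 80/20 cross-validation, stratified by subject so every subject
appears in every train and test block.  Note the deliberate protocol
property: windows overlap by 83.3%, so random splitting leaks correlated
windows between train and test; this replicates the published protocol
and inflates absolute accuracy relative to a grouped split.

Reported statistics: per-fold and fold-mean r2 (= 1 − MSE/var, population
variance, an identity the code maintains to 1e-9) and MSE (mmHg²);
Bland–Altman mean difference and 1.96-SD limits of agreement on pooled
out-of-fold predictions; split-fraction feature importance (fraction of
internal node splits per feature, averaged over trees, with between-tree
SD) alongside impurity-decrease importance; a bootstrap model comparison
drawing 50% of each test set 10,000 times with replacement and testing
whether the (alpha, 1−alpha) percentile interval of the per-draw r2
difference excludes zero (draws are independent streams paired by index);
and two ablations — dropping MAP from the feature set, and rebalancing
the low-ICP-heavy label distribution by removing half of the rows with
labels in [5, 10] mmHg.

## Numerical and design choices

- 0-based sample indices; time = index/fs; all waveform abscissae
  normalized to [0, 1] with 66 points spanning `i/65`.
- Constant (zero-amplitude) inputs normalize to all-zeros with a warning
  and a degenerate flag; zero-area polygons return a (0, 0) centroid
  sentinel; undetected peaks return zeros rather than NaN.
- Determinism: every stochastic component is driven by
  `numpy.random.default_rng` seeded from configuration; per-subject
  streams are spawned via `SeedSequence([seed, subject_index])`; fixed
  seeds give bit-identical recordings, splits, forests and reports.
- Desk-scale problem sizes (600-s trials, 8 subjects) are the package's
  default study conditions; they yield ~3,700 waveforms per modality and
  fivefold dHbT recovery of r2 ≈ 0.94, MSE ≈ 3.8 mmHg² on the default
  seed — computed, like every number in this note, by the test suite or
  acceptance script.

## Known limitations

- The artifact detector is edge-based: a slow coherent drift with no
  sharp jump is not masked.
- The z-score rule needs ≥3 waveforms per trial; below that everything
  is kept.
- Amplitude-only beat corruption is invisible after min–max
  normalization by design; only shape-affecting corruption is
  detectable downstream.
- The random-CV protocol measures within-cohort interpolation, not
  generalization to unseen subjects; a grouped split would be required
  for the latter claim.
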