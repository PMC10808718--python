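# Methods

## The paradigm being simulated

`faceloop` models a closed-loop emotional-face neurofeedback session. A
participant watches a face whose expression morphs between neutral and an
emotional extreme (happy or fearful) in 31 discrete steps (indices 0–30).
The displayed morph step is driven by the participant's ongoing bilateral
amygdala BOLD signal, processed causally volume-by-volume. Four groups
arise from crossing the emotion of the stimulus (happy/fear) with the
instructed regulation direction (up/down). The two task-congruent groups
(happy-up, fear-down) run a positive loop — more amygdala activity, more
intense expression — and the two incongruent groups run the mirrored
negative loop.

A session has four runs; each run contains four 40-s regulation blocks
interleaved with four 20-s baseline blocks (fixation with mental counting,
no face), preceded by 5 dummy volumes at TR = 1 s that are discarded. The
printed block design sums to 240 task seconds; optional pre/post rest
padding is exposed (`pad_pre`, `pad_post`) but defaults to zero because no
lead-in/lead-out periods are described for the paradigm.

## Generative model

Neural dynamics follow the one-state bilinear form used in dynamic causal
modelling, over four regions in the fixed order V1, FFA, Amy, mOFC:

    dz/dt = (A + u_face·B_face + u_int·B_int) z + C·[u_face, u_int]^T + ε

* `u_face` — 1 while a face is displayed (regulation blocks), else 0;
* `u_int` — the displayed emotional intensity, morph_index/30, updated
  once per volume with a one-volume lag (a display cannot react to a
  volume before it is measured);
* `C` — driving input, entering V1 only;
* `ε` — optional Wiener process noise (`neural_noise_sd`, default 0.05).

Integration is Heun's method (second-order in the drift) at
`integration_dt` = 0.1 s; forward Euler leaves O(dt) errors of ~2·10⁻³
against the matrix-exponential solution of the linear system, Heun is
~10⁻⁵ at the same step.

Default intrinsic coupling: self-decays **differ per region** — V1 −0.6,
FFA −0.7, Amy −0.5, mOFC −0.25 Hz — reflecting faster sensory and slower
prefrontal dynamics. This heterogeneity matters beyond realism: with equal
decay rates the FFA and mOFC latent time courses are nearly proportional
(both are essentially filtered V1 input), and no estimator can then
attribute amygdala afferent influence between them. Off-diagonal defaults
are sub-Hz (ventral stream V1→FFA 0.4, V1→Amy 0.15, V1→mOFC 0.15,
FFA→Amy 0.2, Amy→FFA 0.05, mOFC→Amy −0.1, Amy→mOFC 0.2), with face
modulation (B_face) on FFA→Amy and mOFC→Amy and intensity modulation
(B_int) on FFA→Amy.

Hemodynamics are canonical-HRF convolution: the double-gamma kernel in the
SPM parameterization (response delay 6 s, undershoot delay 16 s,
dispersions 1 s, peak:undershoot ratio 6, 32-s support), normalized to
unit peak. Note that in this parameterization (gamma shape = delay /
dispersion) the kernel's positive lobe peaks at the gamma **mode**,
delay − dispersion = 5 s; the kernel agrees with nilearn's independent SPM
implementation to 5·10⁻³. A balloon model is deliberately not used: the
offline analysis itself assumes the canonical kernel, so convolution keeps
the generative and analysis models on the same footing and the inversion
desk-scale. BOLD is sampled at the last integration step of each volume,
with i.i.d. Gaussian observation noise (`obs_noise_sd`, default 0.2).

Regulation ability is modelled as an additive endogenous drive to the
amygdala during regulation blocks (`regulation_effort`, signal units;
negative = downregulation), optionally declining across the four blocks of
a run (`habituation_slope` per block). The *effect scenario* sets these
per group and run. The reference scenario encodes the qualitative study
outcome being emulated: fear-down downregulates in runs 3–4 with within-run
habituation, fear-up upregulates early and habituates in run 4, happy
groups show no reliable change, and psychometric scores (PANAS positive/
negative, SDS — simulated as plain numbers around healthy-adult baselines
30±5, 14±4, 33±6) do not shift. A null scenario zeroes all effort terms.

Motion nuisance columns are smoothed low-amplitude random walks whose only
purpose is to exercise the offline GLM's six realignment regressors.

## Online chain

Per volume, in order:

1. **Kalman de-spiking** — scalar random-walk Kalman filter; an innovation
   beyond 1.96 innovation-SDs is flagged, the output replaced by the
   prediction and the state update damped (process variance 0.05,
   observation variance 1.0: a flat stream converges within ~10 samples).
2. **Cumulative detrending** — expanding-window least squares on
   [constant, linear trend] via running sufficient statistics; equals the
   batch fit on every prefix to ~10⁻¹⁴. Below 3 samples, the running mean
   is subtracted.
3. **AR(1)** — running lag-1 autocorrelation estimate (clipped at ±0.95)
   and the whitened innovation, both reported per volume.
4. **Dynamic-range scaling** — map onto [0, 1] using the running mean of
   the top and bottom ceil(0.05·n) values seen so far (minimum one; below
   10 samples both tails pool the full history). A degenerate range maps
   to 0.5 so the display sits mid-continuum rather than frozen.

The **displayed** signal is by default the *detrended level* (step 2), not
the whitened innovation: an innovation tracks signal change rather than
state, which would decouple the face from the amygdala level the paradigm
is meant to feed back (empirically it also destroys the loop-polarity
property). `ChainSettings.apply_ar1 = True` scales the whitened series
instead; all intermediates are returned either way for audit.

The normalized value maps to a morph index by round-half-away-from-zero of
30·s, with s the normalized signal for the positive loop and its mirror
for the negative loop. Face stimuli are abstract parameter vectors
(landmark-like); blending is affine, and per-participant face assignment
draws 16 unique identities, 8 of each gender, from a 30-face stimulus set.

## Offline analysis

**Run-level GLM.** Columns: x1 = regulation boxcar ⊗ cHRF (built on the
fine grid, sampled at TR); x2 = normalized online feedback ⊗ cHRF (the
parametric stimulus-intensity modulator); x3 = the normalized amygdala
signal with an intercept, x1 and x2 regressed out (orthogonal to both by
construction, |corr| < 10⁻⁶ on every simulated run); six motion columns;
intercept. x2 is *not* orthogonalized to x1 — their collinearity is
reported as a diagnostic (`collinearity_x1_x2`) instead of silently
reassigned. Fitting is OLS with an explicit rank check that names
collinear columns.

**Block betas.** The amygdala series that the loop actually consumed (the
Kalman-processed signal) is modelled with one HRF-convolved boxcar per
regulation block plus an intercept; the four coefficients are the
block betas. Motion columns are excluded by default (the series is already
cleaned) and can be passed explicitly. **Habituation** is the OLS slope of
the four block betas over block index 1–4, one per participant × run,
tested against zero per group × run with one-sample t-tests (df = n−1).
Degenerate cells (zero variance, nonzero mean) are flagged, not silently
dropped.

**Mixed models.** The run × group model takes the per-run mean block beta
as outcome (the run-level reading is the one compatible with t(90) at
2 groups × 16 × 4 runs), with run (reference run 1), congruency (reference
congruent) and their interaction as fixed effects and a random intercept
per participant, fitted by REML. For balanced data the fit uses the exact
between/within stratum decomposition: within effects carry
df = n_subj(r−1) − p_within (= 90 here), the group effect df = n_subj − 2
(= 30), and intercept/group coefficient SEs blend the two strata with the
Satterthwaite combination rule. This reproduces lme4/lmerTest
(REML + Satterthwaite, type-III F) to all printed digits on balanced data
— verified against Rscript/lmerTest and statsmodels MixedLM in the test
suite — while being fast enough for 2000-replicate calibration studies.
Unbalanced data fall back to statsmodels MixedLM with residual df, flagged
in the `method` tag. P-values are uncorrected, matching the analysis style
being mirrored; a Holm-adjusted column is available opt-in
(`holm_adjust`). The same machinery fits the psychometric pre/post × group
models per scale.

**Connectivity comparisons** report within-group run-1 vs run-4 paired
t-tests, and between-group comparisons both as Welch two-sample tests and
as the pair-by-participant-index df = 15 variant, because pairing across
independent groups is a reporting convention rather than a statistical
pairing — both are emitted rather than guessing intent.

## Dynamic causal modelling

The model space holds the 2⁷ = 128 on/off combinations of the optional
edges V1→FFA, V1→Amy, V1→mOFC, FFA↔Amy, mOFC↔Amy; self-connections and
the V1 driving input are always present, and each model's modulation masks
(B_face, B_int) coincide with its A mask. Priors are independent
Gaussians: self-connections mean −0.5 Hz, variance 0.0625; other A/B
entries mean 0, variance 0.25; C mean 0, variance 1.

Inversion is MAP estimation: Levenberg-damped Gauss–Newton on the
penalized least-squares objective, with per-region noise variances
re-estimated from residuals each iteration and the Jacobian computed by
batched forward differences (all parameter perturbations integrated in one
vectorized time sweep). The forward model is the same bilinear
ODE + canonical-HRF observation as the simulator — one state per region,
no hemodynamic parameters estimated. The log evidence is the Laplace
approximation F = accuracy − complexity (complexity = prior Mahalanobis
penalty + ½ log |posterior precision|/|prior precision|). Inversion is
deterministic given data (initialization at the prior mean, no stochastic
steps).

Model weights are the per-subject softmax of F under a uniform model
prior; group-level weighting averages subject posteriors — a documented
simplification of the Dirichlet random-effects scheme, which is out of
scope. BMA parameters are posterior means weighted across models (absent
edges contribute zero), and "total" connectivity is A + B_face + B_int per
edge. Reported "±" values are between-subject SDs and are labelled as
such.

Identifiability caveat: the amygdala's three afferents (V1, FFA, mOFC) are
driven by the same block input, so attribution among them rests on
differences in regional dynamics and on within-block variation of the
intensity input. At SNR 2 an inversion can reach the noise-floor fit
(explained variance ≈ 0.8) in more than one basin; recovery studies
therefore pool over subjects and report the sign pattern and pooled
correlation, not per-subject point estimates.

## Simulation studies and problem sizes

`faceloop.studies` packages the recovery/calibration experiments the
acceptance checks run:

* **Type-I error** of the run main effect: 2000 null replicates at
  2 × 16 × 4 (random-intercept SD 0.5, residual SD 1.0); the exact
  stratum F makes the rejection rate land inside the binomial 95% band
  around 0.05.
* **Power**: 500 replicates with a −1 residual-SD shift in runs 3–4 of one
  group; detection = run or run × group p < 0.05.
* **Block-beta recovery**: noiseless recovery is exact to ~10⁻¹⁶; with
  noise SD 0.5, bias over 500 replicates stays within Monte-Carlo error.
* **DCM recovery**: 16 subjects, one run each, generated from a
  fear-down-like template (strong positive FFA→Amy face modulation,
  net-negative mOFC→Amy), observation noise at SNR 2, 8-model reduced
  space (the densest models; the full model always included). The study
  reports the pooled correlation between generating and BMA totals and
  the group-mean signs. The 8-model space keeps a full study at roughly
  a quarter-hour on one core; `--models full` runs all 128.
* **Loop polarity**: noiseless closed-loop runs for all four groups;
  correlation between the morph trace and the latent amygdala state
  lagged by the HRF peak delay (6 volumes), over regulation volumes.

## What the synthetic data does and does not show

The generator emulates the block design, the closed-loop coupling with
group-dependent polarity, hemodynamic lag, measurement noise, slow drifts
implicitly (via the chain's detrending of the simulated signal path),
motion nuisance columns, and numeric psychometric outcomes. It does not
emulate spatial structure (no voxels, no realignment, no smoothing),
physiological noise spectra, habituation of the stimulus response itself,
individual HRF variability, or learning within a session. Passing tests
therefore certify the *analysis chain* — its causality, orthogonalization,
calibration, and recovery properties under the stated generative
assumptions — not the neuroscientific claims about real participants.

## Numerical choices and degenerate inputs

* Round-half-away-from-zero for morph indices (platform-stable at .5).
* Scaling with hi = lo returns 0.5; empty history is an error.
* Rank-deficient designs raise with the offending column named; x3
  falls back to the maximal independent column subset.
* LMM zero-variance strata yield NaN inference (flagged degenerate paths)
  rather than exceptions; one-participant-per-group data cannot estimate
  between-subject variance and report NaN there.
* DCM divergence (|z| > 10⁴ during inversion, 10³ during simulation)
  raises an unstable-parameters error; the Levenberg loop treats a
  diverging candidate step as rejected.
* Seeds: every public entry point takes a seed; the cohort derives
  per-participant streams from the master seed via `SeedSequence.spawn`.

## Known limitations

* One-state bilinear DCM with fixed canonical hemodynamics; no balloon
  model, no stochastic or two-state variants.
* Group-level BMA averages subject posteriors instead of the Dirichlet
  exceedance machinery.
* The balanced-stratum LMM covers two groups and one within factor (the
  designs used here); anything else delegates to statsmodels.
* The online chain's constants are plausible defaults, not calibrated to
  any specific real-time implementation; all are exposed in
  `ChainSettings`.
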