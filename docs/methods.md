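# Methods

`midbrainfb` re-implements, as a tested pipeline, the computational analysis
of a real-time fMRI (rt-fMRI) neurofeedback experiment targeting the
dopaminergic midbrain (substantia nigra / ventral tegmental area, SN/VTA):
the online feedback computation, the degree-of-regulation-transfer (DRT)
statistic, temporal-difference (TD) learning signals and their GLM-based
tracking, psychophysiological-interaction (PPI) connectivity, monetary
incentive delay (MID) reward-sensitivity contrasts, and the group-level
statistics tying them together.  Because the underlying participant data are
not redistributable, the package ships a synthetic-data generator that
emulates the study's designs and learning dynamics; every downstream stage
is exercised end to end against it.

## Experimental design

A neurofeedback session is four runs — baseline, two training runs,
transfer — each built from nine alternating 20 s block pairs of REST
(neutral imagery) and IMAGINE_REWARD (reward imagery) at TR = 2 s,
preceded by a 10-volume lead-in, for 190 volumes per run.  The lead-in
reconciles the printed 190-volume run length with the 180 volumes the 9+9
blocks account for; its first five volumes double as the "first 5 TRs"
nuisance the first-level model uses.  Runs begin with REST so a feedback
reference exists before the first regulation block.  Feedback is shown only
during training; baseline and transfer are feedback-free, which is what
makes the transfer-versus-baseline comparison interpretable.  The MID task
presents cues for a large (0–2.00 CHF), small (0–0.40 CHF) or zero reward,
a 2.5–3.0 s delay, then a speeded target; 24 trials per cue type by default
(a realistic run length; the original count is not documented).

## Online feedback

The engine is a streaming state machine.  At each volume it forms a
3-volume moving average of the raw SN/VTA signal (current volume plus two
preceding; one-volume latency), computes percent signal change (PSC)
against a reference — the mean of the last five volumes of the most recent
completed REST block, reset at every REST→IMAGINE transition, which
suppresses slow drift — applies the arm's polarity (the control arm sees
the exact negative), and maps PSC to the display with saturation at ±2%
PSC.  Whether the original moving average included the current volume and
whether the display saturated are undocumented; both choices here are
configurable (`window`, `clamp_psc`).  Streaming and batch replay are
bit-identical by construction and by test.

## Generative model

**Agent.**  Each subject owns K = 5 mental strategies with latent
efficacies e_k ∈ [0, 1].  One strategy is chosen per IMAGINE block by a
softmax over strategy values V_k (temperature τ); after each block the
chosen value moves toward the perceived feedback,
V ← V + α·(feedback − V), a block-level TD/Rescorla–Wagner update.  The
perceived feedback is the displayed value averaged over the block at a 5 s
hemodynamic lag (the delay participants were familiarized with).  Values
start at a mildly optimistic prior (1.0 display unit) to drive early
exploration, and are floored at the neutral prior 0: a strategy whose
feedback is persistently negative is abandoned, not aversively valued —
participants were instructed to upregulate, and this floor is what makes
the inverted arm unable to learn any association (it cycles through
strategies near-uniformly) instead of obediently learning to
*down*-regulate, which would contradict the observed control-group
behaviour.  Selection additionally follows an instructed
explore-then-exploit schedule (temperature multipliers 5.0 / 1.5 / 1.0 for
training 1 / training 2 / transfer): participants try strategies out early
and commit later.  This fixes the *timing* of learning by design; without
it, fast learners converge inside run 1 and the run2−run1 training slope
decouples from transfer success.  A non-learner has α = 0 **and** a flat
strategy set (undiscriminable repertoire); the latter matters because a
non-learner with a spread repertoire would generate large true — but
slope-uncorrelated — transfer fluctuations purely from random strategy
sampling.

**BOLD forward model.**  Strategy efficacy drives a boxcar neural
amplitude, convolved with a canonical double-gamma HRF (peak ≈ 5 s,
undershoot ≈ 16 s, unit peak).  The regulation convolution is normalized by
the kernel sum so the regulation gain g is the *sustained* PSC a
full-efficacy strategy produces; this makes the noise convention (below)
and the ±2% display clamp meaningful.  Noise per region: AR(1) with
φ = 0.3 and stationary SD 2.0 signal units (contrast-to-noise ≈ 0.5 at
g = 1), a slow linear drift (0.002 units/s), and two physiological
sinusoids (0.25 and 1.0 Hz, aliased on the TR grid) shared with 60 CSF/WM
voxels that also carry white noise; six AR(1) motion traces are generated
per run.  The dlPFC series adds a task-engagement component, a TD-tracking
component w·(HRF-convolved stick series of the collapsed TD trace) whose
weight decays with realized learning progress
(w_run2 = w0·(1 − 0.85·progress)), and independent cortical noise
(SD 1.0).  During training runs an IMAGINE-specific dlPFC→SN/VTA coupling
of strength 0.6 (centered condition indicator × centered dlPFC) is added to
the SN/VTA series — the quantity the PPI analysis estimates.  The online
engine consumes the SN/VTA signal prior to this zero-mean perturbation.

**Cohort archetypes.**  A regulator draws one clearly effective strategy
(e_best ~ U(0.6, 0.95)) among four mediocre ones (U(0.1, 0.4)),
α ~ U(0.3, 0.5), τ = 0.10; a non-regulator draws a flat repertoire around
U(0.2, 0.45) with α = 0.  Regulation gain is log-normal (median 4,
σ_log = 0.35) sustained-PSC units for all subjects.  These magnitudes are
calibration choices, not reported values: the study reports no generative
effect sizes, and the chosen regime is the one in which between-subject
variation in true transfer is comparable to its measurement noise — the
regime implied by the reliability-scale training–transfer correlation the
study observed.  Under these defaults a mixed 20/20 standard-arm cohort
yields Spearman(training slope, DRT) ≈ 0.4–0.7 and the inverted arm
≈ 0, reproducing the sign structure of the manipulation check.  MID gains:
general gain ~ N(1.0, 0.2) CHF⁻¹; adaptive gain 0.2 + 0.8·capacity (+ small
noise) when the generative coupling between reward sensitivity and
regulation capacity is enabled (default), else ~ N(0.5, 0.15).

**What the generator does not emulate.**  No voxelwise spatial structure,
motion-by-susceptibility interactions, cardiac/respiratory waveforms,
habituation or frustration dynamics, or session-to-session scanner
differences.  Passing tests therefore certify the *analysis logic* —
estimator correctness, calibration under the modelled null, recovery of
imposed effects — not performance on real data.

## Analysis

**Preprocessing.**  Probability-weighted ROI averaging (weights normalized
to sum 1) and the physiological-noise model: the global mean plus the first
six temporal principal components of the pooled CSF/WM voxel matrix
(temporally centered; components unit-norm, variance-ordered, orientation
fixed by making the largest-magnitude loading positive).  Spatial
preprocessing is out of scope; synthetic data are generated in
"preprocessed" space.

**First-level GLMs.**  The block design has exactly 15 columns: two
HRF-convolved condition boxcars, the first-5-TR indicator, six motion and
six PCA regressors.  Those 15 contain no constant, so the fit adds an
internal intercept that absorbs the raw-signal offset and enters no
contrast.  The TD design uses per-TR event regressors per condition with a
parametric modulator equal to the one-volume backward difference of the
SN/VTA series (first volume 0, difference taken across consecutive volumes
regardless of the previous volume's condition), mean-centered within
condition.  The linear-time control design carries an increasing or
decreasing centered linear modulator.  The MID design has cue-onset
regressors per cue type plus magnitude modulators centered within type;
because the per-type magnitude slope is general + adaptive/range, the two
modulator betas identify both generative gains exactly
(`recover_mid_gains`).  The PPI design follows the gPPI scheme in the
measured-signal domain (no deconvolution — acceptable for 20 s blocks):
psychological regressors, the centered seed, and per-condition interactions
(centered condition indicator × centered seed); the inferential statistic
is the IMAGINE−REST difference of the interaction betas, which is the
well-identified direction when the two interaction columns are nearly
opposite.  Estimation is OLS; dof = n − rank(X); contrast
t = c'β/√(σ²·c'(X'X)⁻¹c).  A single Cochrane–Orcutt AR(1) prewhitening
pass is available behind `prewhiten=True`; it is used for PPI inference,
where plain OLS on AR(1) noise is visibly anticonservative (one-sided
rejection ≈ 0.14 instead of 0.05 at α = 0.05; prewhitened ≈ 0.09 — a known
residual of single-pass correction).

**Subject measures.**  Midbrain DRT = (IMAGINE − REST)_transfer −
(IMAGINE − REST)_baseline from condition means of the normalized SN/VTA
series, with a configurable hemodynamic label shift (default 4 s = 2 TRs; 0
recovers exact block means).  Normalization is per-run PSC by default;
`normalize='center'` removes only the run mean, which makes the statistic
exactly invariant to a constant offset (PSC rescales by the run mean, so
its invariance is approximate).  Non-midbrain DRT is the difference of
block-design contrast estimates; the training slope is run2 − run1 of the
SN/VTA contrast; the TD slope is run2 − run1 of the dlPFC TD-modulator
beta (negative when TD coupling declines with learning); the per-subject
PPI estimate is the mean training-run interaction contrast.

**Group statistics.**  Spearman (midranks; exact permutation p below
n = 10, t approximation otherwise), Pearson, one-way ANOVA, tie-corrected
Kruskal–Wallis, pooled-variance two-sample t (df = n1 + n2 − 2), Fisher's z
for independent correlations (z = (atanh r1 − atanh r2)/√(1/(n1−3) +
1/(n2−3)), one-sided by default), percentile bootstrap CIs under paired
case resampling (seed-required; 10,000 reps default), study-covariate
adjustment by residualizing both variables on the study indicator,
conjunction/disjunction partitions of thresholded region effects, and
Benjamini–Hochberg FDR as the region-level multiplicity control standing in
for voxelwise cluster correction (whole-brain mapping is out of scope; the
synthetic data are region-resolved).

## Numerical and edge-case conventions

Time is in seconds, 0-based, half-open block intervals; hemodynamic shifts
must sit on the TR grid.  Reference computation requires exactly five REST
samples; a zero reference is an error.  Rank-deficient designs raise an
error naming the suspect columns (QR with column pivoting).  Degenerate
PCA inputs warn and return fewer informative components.  All stochastic
procedures take explicit seeds; cohort generation spawns per-subject
`SeedSequence` children, so datasets are bit-reproducible.

## Problem sizes

Default problem sizes were chosen so the full validation runs quickly on a
single CPU: null calibration uses a 200-subject non-learner cohort with
1,000 label permutations; the headline-pattern check uses 40 standard-arm
plus 17 inverted-arm subjects; TD-coupling recovery uses 100 replicates of
12-subject cohorts; MID recovery uses 200 subjects; PPI power uses 200
single-run simulations.  The acceptance script uses the same designs at
slightly smaller replicate counts.

## Known limitations

The agent is a bandit over discrete strategies; it does not model
within-block strategy refinement or effort.  The explore-then-exploit
schedule is imposed, not learned.  The inverted-arm value floor is a
bounded-rationality assumption chosen to reproduce the control group's
observed inability to learn; alternatives (e.g. contingency-confusion
models) would also be consistent with the data.  Single-pass prewhitening
leaves mild anticonservatism in autocorrelated noise.  The amygdala series
of the control-arm finding is generated as structured noise only when
enabled; no mechanism is claimed for it.
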