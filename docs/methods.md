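# Methods

This note documents the models, parameter choices and numerical conventions
behind `prepcirc`, and what the synthetic-data experiments do and do not
establish about real recordings.

## Conventions

Times are seconds (float) from recording start; every window is half-open
`[a, b)`; event-aligned lag 0 is the event time. Positions are cm from the
corridor start with reward at 360 cm by default. Spike trains are analyzed
on a 1 kHz grid (1-ms bins), behavior at 100 Hz. Every randomized
operation takes an explicit integer seed (numpy `SeedSequence`-derived
child streams per unit, so rosters are reproducible unit by unit).

## Firing rates and Z scores

The continuous rate of a unit is the Gaussian kernel density of its spike
times, each spike carrying unit mass, with the kernel σ equal to the unit's
median inter-spike interval — fast, regular units get fine temporal
resolution, sparse units get stability. The kernel is truncated at 6σ, so
mass is conserved to well under 1% away from recording edges. Z-scoring
subtracts the whole-recording mean rate and divides by the whole-recording
SD; event-aligned analyses that need a local reference instead use a
baseline window, by default [−10, −5) s before the event. A constant-rate
unit has no Z scale and raises a degenerate-unit error rather than
returning infinities.

## Poisson GLM and unit typing

Event covariates (reward, licks, cue appearances) enter as delta trains
convolved with raised-cosine bumps b_j(t) = ½(1 + cos(π(t − c_j)/(2Δ))) for
|t − c_j| ≤ 2Δ, Δ = 25 ms (π/2 phase separation), centers spanning
−4..2 s around reward and −2..2 s around licks and cues. Centers extend 2Δ
beyond each window edge so summed coverage is flat at the boundaries (the
bump family at this spacing sums to a constant inside the window). Running
speed enters as one z-scored continuous column; an intercept completes the
design.

The Poisson regression (log link) is maximized by damped Newton/IRLS on a
sparse design (peri-event columns are zero almost everywhere), with a small
ridge (1e-4) on non-intercept weights for rank safety, a backtracking line
search, and convergence on the penalized gradient max-norm scaled by the
spike count. An all-zero response returns a large negative intercept
without errors. On small dense problems the solver agrees with the
`statsmodels` Poisson GLM to 1e-5 (tested).

Scoring follows the per-trial R² recipe: the covariate's kernel
(basis × weights) placed at that trial's events is linearly regressed
(slope + intercept) against the single-trial PSTH smoothed with a 25-ms
(licks) or 50-ms (reward, speed) Gaussian; the reward covariate is also
scored separately on [−4, 0) and [0, 2). A covariate with mean R² across
trials strictly exceeding 0.17 classifies the unit; the reward sub-window
pattern defines type 1 (pre only), 2 (both), 3 (post only). For lick
covariates (many events per trial) the prediction superposes kernels and is
scored over the whole trial; single-event covariates are scored over their
window. Increasing/decreasing signs come from the mean whole-recording-Z
PSTH in [−1, 0) and [0, 1) s; no single canonical rule exists for sign
assignment, so this one is config-exposed.

## Cross-correlogram connectivity

`compute_ccg` counts target spikes in 1-ms lag bins over ±50 ms around each
reference spike, implemented with `searchsorted` range expansion and tested
bin-exact against an O(n²) double loop. Lag binning adds a 1e-6 ms epsilon
before flooring so that lags sitting exactly on a bin edge (common in
constructed data) land deterministically in the upper bin. A pair is
modulated when ≥2 consecutive bins in the 10 ms after the reference spike
deviate (two-sided by default; flag for one-sided) by >3 SD from the raw
count baseline in [−50, −10) ms; strength is the mean Z over lags 1–6 ms
(the 1–7 ms window with half-open bins), its sign giving inhibited versus
excited. The shuffle-corrected CCG restricts both trains to the last 10 s
before each reward, pairs trial n's reference train with trial n+1's target
train (both re-referenced to their own reward) and computes
(CC_raw − CC_shuffled)/√CC_shuffled; trial-locked co-modulation cancels in
expectation, which the null experiments verify. Rate-level cross-covariance
uses 5-ms bins, the same adjacent-trial shuffle and normalization by
√(var_PC · var_DN). The strength-versus-profile regression takes Spearman ρ
between baseline-Z reward profiles over [−5, 0) s and fits OLS
(statsmodels) of strength on ρ with 95% CIs and the F-test p.

## Cerebellar unit typing

ISI distributions are fitted by maximum likelihood lognormal (mean/SD of
log ISIs); fit quality is the negated KS distance of log-ISIs to the fitted
normal. k-means (k=2, 10 restarts, seeded) on the standardized (μ, σ) plane
labels the cluster with the larger centroid sum — slower, more irregular —
as non-PC.

Complex-spike detection requires a baseline rate above 15 Hz and ≥3 ms of
waveform after the peak. The per-spike "late peak" is the maximum amplitude
in (0, 3] ms after the peak; spikes above median + 3 MAD seed the CS
template (mean waveform), the rest the SS template; each spike is a CS iff
its Spearman correlation with the CS template is positive and exceeds its
correlation with the SS template. The CS/SS sets partition the spikes
exactly, and a "CS" set that is not a minority is rejected as
non-physiological. Confirmation requires the SS rate in (0, 20] ms after
CSs to fall below half the [−50, −10) ms baseline (pauses of tens of ms are
typical; the 50% ratio is config-exposed).

Fat-spike units are waveforms whose FWHM (of the absolute trace about its
dominant peak, half-max crossings linearly interpolated) exceeds 0.5 ms,
the scale that separates wide climbing-fiber events from ordinary somatic
spikes (config-exposed). Reward modulation compares per-trial counts in
[−0.5, 0) vs [0, 0.5) s by two-sided rank-sum (α = 0.05, increase
required); the first 100-ms bin whose per-trial spike probability exceeds
the pre-reward bin-wise mean + 3 SD yields the firing probability, onset
(mean first-spike time in the bin) and jitter (mean absolute pairwise
difference of those first-spike times, a symmetric and robust dispersion
measure).

## Speed-tuning model and the residual test

Running speed is low-pass filtered at 100 Hz (a no-op at the default
100 Hz sampling; a zero-phase 4th-order Butterworth when sampled above
200 Hz) and binned at 5 cm/s from the rounded minimum to maximum. The
binned rate curve is fitted with an occupancy-weighted cubic smoothing
spline (`make_smoothing_spline`, GCV-chosen smoothing unless overridden);
evaluation clamps speeds outside the fitted range to the boundary value and
rectifies predictions at 0. Cells with a learned pre-reward decrease
satisfy mean(FR[−4,−3)) > mean(FR[−2,0)) + 2·SD(FR[−4,−3)), with the SD
taken over time bins of the trial-averaged PSTH (over-trials is the other
defensible reading; config-exposed).

The residual test computes decel_diff = mean(model − actual) in the 2 s
before deceleration events outside the reward zone, partitions rewards
chronologically into blocks of the same number of trials (remainder
dropped) and computes each block's reward_diff identically; the unit is
flagged when reward_diff(i) > decel_diff in ≥80% of blocks, i.e. the
speed-only model overestimates firing specifically before rewards.
`printed_direction=True` inverts the inequality, kept for comparability
with conventions that define the difference with the opposite sign.

**Known statistical property.** Under an exchangeable null (a pure-speed
unit, no reward suppression), the pooled decel_diff and the k block
reward_diffs are k+1 exchangeable means of equal sample size, so the
probability that decel_diff ranks low enough to flag the unit is
(k+1−⌈0.8k⌉)/(k+1) ≈ 0.2–0.27 *for any k and any noise level*. The
suppressed-unit flag rate is essentially 1 at a 30% suppression, so the
test separates populations clearly, but its single-unit null flag rate
cannot be pushed below ~20% with this rule; treat single-unit flags as
screening, not inference.

## Photoactivation analysis

Modulation compares per-trial mean rates in [onset, onset + 1 s) between
photostimulation trials and control trials at the matched "virtual onset"
(the time the mouse crossed the light-trigger position, 20 cm before
reward) by two-sided rank-sum at α = 0.05; inhibited means control > photo.
Onset latency is the left edge of the first 2-ms bin after onset whose
across-trial count leaves the mean ± 2 SD band of the preceding 50 ms in
the direction of the modulation. Being a 2σ rule, each baseline-rate bin
has an irreducible ~0.5–2% chance of grazing the band, so cohort latencies
are best summarized by the median across units (what the validation
experiment reports). The ramp regression fits OLS of effect size on
(ramp size, control rate) with an intercept; ramp size is defined here as
the mean whole-recording-Z rate in the second before the (virtual) onset on
control trials, and effect size as the Z difference photo − control in the
1-s window; there is no single standard definition of ramp size, so both
are config-exposed and echoed in the outputs. Across-type comparisons use
rank-sum with Bonferroni correction (α = 0.05/6 = 0.0083 for four types).

## Synthetic sessions: what they emulate, and what they do not

The generator integrates a per-trial speed profile (cruise at ~45 cm/s with
OU noise, braking ~35 cm before reward to a 12 cm/s approach, a 2.5-s
post-reward hold, optional mid-corridor false decelerations in ~10–25% of
trials), places pattern-appearance cues at segment boundaries, emits
anticipatory lick bursts starting 0.5 ± 0.15 s before reward at 7 Hz plus
occasional false bouts, and marks 40% of trials for photostimulation
triggered 20 cm before reward (1-s pulses; control trials record the
matched virtual onset). Spikes are Bernoulli-thinned at 1 kHz from
per-unit intensities: linear ramps cue→reward for type 1/2 (type 1
collapses with a 50-ms decay; type 2 persists 1 s), post-reward bumps for
type 3, tuning-of-speed for run/PC units with a multiplicative reward
suppression ramp for PCs, multiplicative rectified inhibition of DN by each
presynaptic PC spike through an exponential kernel (1-ms latency, 3-ms
decay), and low-rate climbing-fiber units with one reward-locked event at
175 ± 30 ms. Waveforms are templates plus band-limited Gaussian noise;
complex spikes carry a broader initial deflection and a slow positive
dendritic envelope whose late peak is `cs_snr` × noise SD, and a per-spike
uniform repolarization amplitude (0.05–0.25 of peak) spreads the late-peak
bulk without fattening its tail (afterpotential variability, as in real
units).

Passing the recovery experiments therefore shows that each analysis
recovers the structure it targets *when the generative assumptions hold*:
Poisson spiking given the intensity, multiplicative inhibition, trial-locked
co-modulation, stationary tuning. Real recordings add sorting errors,
bursting and refractory structure, electrode drift, correlated noise across
units and non-stationary behavior, none of which the generator emulates;
recovery rates here are upper bounds, not field performance claims.

## Problem sizes and runtime

The validation experiments use 30-minute sessions with 100 PC–DN pairs for
connectivity, 200-trial sessions for GLM type recovery (reward + speed
covariates; licks are exercised in the unit tests), 100-trial sessions for
the residual and photostimulation experiments, ~8000-spike waveform
streams at 1% CS, and 100–200 Monte-Carlo repetitions for the regression
and null controls. The full suite and the acceptance script each run in
roughly 10–20 minutes on one CPU.
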