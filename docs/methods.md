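# Methods

`dyadcoord` quantifies how closely a person's rhythmic movement is
coordinated with a partner's, and models what that coordination depends
on. The target design is a dyadic virtual-reality movement task: on each
trial a participant performs paced arm curls (metronome at 84 bpm, i.e. a
1.4 Hz movement fundamental) opposite an avatar doing the same, with one
uninstructed (spontaneous) and one instructed (intentional) trial per
participant, a between-participant avatar-gaze factor (direct vs.
averted), continuous symptom covariates (LSAS for social anxiety, AQ for
autistic traits) and eye-tracked gaze on the avatar. The package takes
per-trial 1-D displacement series at 50 Hz and produces per-trial
coordination metrics plus mixed-effects inference.

## Preprocessing

Each trace passes through trim → length standardisation → centring →
filtering:

* **Transient trim** (`trim_s`, default 6 s): the movement-onset transient
  is removed from the start of every 90 s trial.
* **Length standardisation** (`target_s`, default 84 s): longer traces are
  truncated; shorter ones are linearly resampled onto the
  `round(target_s · fs)` grid. On nominal 90 s trials this is a no-op
  after the trim, but real recordings jitter; truncation-when-longer /
  resample-when-shorter is the least surprising rule that preserves the
  dynamics.
* **Centring**: mean subtraction.
* **Low-pass filter** (`cutoff_hz` 10 Hz, `filter_order` 2): Butterworth,
  applied forward–backward (zero phase), so the effective magnitude
  response is the squared, doubled-order one. Order 2 is a common default
  for movement kinematics and is configurable; the step order (centre
  before filter) is likewise a convention, surfaced in the config, and is
  immaterial for the phase and coherence metrics because both are
  invariant to a constant offset after filtering.

## Coordination stability (rho)

Instantaneous phases come from the analytic signal (Hilbert transform) of
each centred, band-limited trace. The relative phase φ = θ_participant −
θ_avatar is wrapped to (−180°, 180°]; stability is the mean resultant
length

    rho = | mean_t exp(i φ_t) |  ∈ [0, 1],

1 for perfect phase locking, 0 for no preferred phase relation. Two
deliberate choices:

* rho is computed on the **signed** wrapped phase. Folding to 0–180°
  first would make a symmetric {−90°, +90°} distribution look like
  perfect quarter-cycle locking; the signed convention treats it
  correctly as dispersed. The folded series is kept for descriptive
  distributions only.
* The first and last second of each trial are excluded from the phase
  statistics (`edge_discard_s`, default 1 s) because the Hilbert
  transform is unreliable at the signal edges.

For linear modelling rho is Fisher-transformed, z = atanh(min(rho,
1 − 10⁻⁶)); the clip keeps z finite at perfect synchrony.

## Frequency matching (weighted coherence)

Welch-averaged spectra (1024-sample Hann segments, 50% overlap — about
20 s windows and 7 segments per 84 s trial) give the magnitude-squared
coherence coh(f) = |Pxy|² / (Pxx·Pyy). The per-trial index is
Σ w(f)·coh(f) over 0.2–10 Hz with weights proportional to the mean of the
two **band-normalised** auto-spectra, w(f) ∝ (Pxx/ΣPxx + Pyy/ΣPyy)/2.
Power weighting concentrates the index where the movement energy actually
lies; normalising each spectrum first makes the index exactly invariant
to rescaling either signal (raw-power weights would not be). Cross-power
and flat weightings are available as configuration alternatives.

## Cross-recurrence quantification (CRQA)

Both series are z-scored, delay-embedded and compared point against
point: R[i,j] = 1 when the embedded points are within a radius
(Euclidean). Summary statistics:

* **%REC** — percentage of recurrent pairs;
* **MaxLine** — longest diagonal run of recurrent points (runs shorter
  than `min_line` = 2 ignored). All diagonals are counted: cross-
  recurrence between distinct signals has no identity-line artefact, so
  no Theiler window is applied.

Embedding parameters follow the standard protocol. The delay is the first
local minimum of the average mutual information (equal-width histograms
with ⌈√N⌉ bins capped at 64; global minimum with a warning if no local
minimum exists). The dimension is the first local minimum of the Kennel
false-nearest-neighbour fraction (Rtol = 15, Atol = 2 × series SD;
fallback: first dimension below 1%, then global minimum). In a study run
the pipeline estimates these per trial and applies the **median across
trials** as a single shared setting — one embedding for the whole dataset
is the convention in this literature — with a config override to pin any
fixed pair such as (dim 7, delay 24).

Because a fixed radius is only meaningful in a declared unit system, the
primary mechanism is a tuner: bisection on the radius (recurrence rate is
exactly monotone in it) until %REC is within 0.5 points of a 5% target,
capped at 60 iterations; an unattainable target (e.g. coincident points
flooring the rate) raises an error reporting the closest achieved rate.
On this package's z-scored series the tuned radius is in pooled-SD units.

## Participant gaze

The eye-tracker stream is reduced to avatar/room/missing area-of-interest
hits; the per-trial index is the fraction of samples on the avatar.
Missing samples (blinks, tracking loss) are excluded from the denominator
by default (`as_room` keeps them in it). Gaze series are trimmed to the
same 6–90 s analysis window as the movement data.

## Mixed-effects inference

One linear mixed model per outcome (Fisher-z rho, coherence, %REC,
MaxLine, gaze proportion): fixed effects for coordination type
(0 = spontaneous, 1 = intentional), avatar gaze (0 = direct, 1 = averted),
at most one questionnaire score per model (LSAS and AQ are fit
separately, enforced by validation), optionally the participant-gaze
proportion, and their interactions; a by-participant random intercept;
REML estimation via statsmodels MixedLM. Continuous predictors are
mean-centred before fitting and the centring constants recorded.

* **Degrees of freedom.** The backend exposes no Satterthwaite
  approximation, so t-tests use residual df (nobs − number of fixed
  parameters), recorded in `ModelResult.df_method`. At ~130-participant
  scale the difference is small; the null simulations in the test suite
  confirm a ~5% type-I rate for both between- and within-participant
  terms at n = 40.
* **Simple slopes.** Interactions are decomposed as conditional slopes of
  the focal predictor at moderator levels M − SD / M / M + SD (continuous)
  or at both levels (0/1 factors), other covariates held at their sample
  means; SEs by the delta rule on the fixed-effect covariance.
* **Pairwise contrasts.** Estimated-marginal-mean differences over the
  factor cells, Tukey-adjusted via the studentised-range distribution
  (`scipy.stats.studentized_range`); Bonferroni is available and the
  adjustment used is recorded in the output.
* **Degenerate inputs.** A zero-variance outcome returns a flagged
  singular result (both variance components zero) rather than an
  optimizer error; boundary fits (random-intercept variance ≈ 0) are
  flagged singular and logged.
* **Imputation.** Missing questionnaire items are replaced by the
  respondent's mean over the observed items of the same subscale; an
  entirely missing subscale is an error.

## Synthetic studies

The generator emulates the study design so every stage is testable
without external data. The avatar is a 1.4 Hz oscillator with a smooth
fractional frequency jitter (SD 1%, clipped at 2%) mimicking a recorded
human mover; the participant is a stochastic Kuramoto-type phase
oscillator,

    dθ_p = [ω_p + K sin(θ_a − θ_p)] dt + σ_η dW,

Euler–Maruyama at 50 Hz, with natural-frequency detuning N(0, 0.05 Hz)
per participant, process noise σ_η = 0.7 rad/√s, displacement
x = sin(θ_p) plus measurement noise (SD 0.05). This is the simplest model
with a tunable coupling→rho relationship; the bistable in-phase/anti-phase
structure of full HKB-style dynamics is out of scope.

All condition and covariate effects enter through the coupling
K = K₀ + ΔK_int·[intentional] + ΔK_direct·[direct] +
β_lsas,averted·lsas_c·[averted] + β_lsas,direct·lsas_c·[direct] +
β_aq·aq_c, floored at 0. Defaults (K₀ = 1, ΔK_int = 2, ΔK_direct = 0.5,
β_lsas,averted = +0.02, β_lsas,direct = −0.005, β_aq = −0.01 rad/s per
centred point) were chosen once to reproduce the qualitative orderings
the design targets — direct > averted in spontaneous trials, saturation
under intentional coordination, a positive anxiety–coordination slope
only under averted gaze, weak negative AQ effects — at magnitudes a
movement-coordination researcher would call moderate. No published raw-
unit effect sizes exist for these coupling differences, so magnitudes are
calibrated to sign and ordering only.

LSAS and AQ are truncated normals on [9, 119] and [1, 25]; the underlying
(μ, σ) are solved numerically so the truncated moments equal the target
sample moments (M = 55.43, SD = 23.52; M = 9.99, SD = 4.83). Gaze
conditions are assigned by balanced randomisation. Gaze behaviour is a
two-state avatar/room Markov chain with geometric dwell times (mean
switching timescale 2 s) whose stationary avatar-probability is
logistic(0.8 + 0.7·[direct] + 0.5·[intentional] − 0.06·aq_c).

What the generator does **not** emulate: movement harmonics and amplitude
drift of real arm curls, broken or asymmetric coupling regimes,
item-level questionnaire responses, saccade/fixation kinematics, and any
dependence of gaze on the moment-to-moment movement state (gaze and
coupling are linked only through shared covariates, mirroring the
separate analyses). Passing tests therefore demonstrate internal
consistency and statistical calibration of the pipeline, not validity on
any particular empirical dataset.

## Numerical and design choices

* Recurrence-radius bisection: tolerance 0.5 percentage points, ≤ 60
  iterations, deterministic.
* AMI binning ⌈√N⌉ capped at 64; FNN thresholds Rtol 15 / Atol 2.
* Fisher clip ε = 10⁻⁶; phase edge discard 1 s per end.
* Welch: 1024-sample Hann, 50% overlap, constant detrend, band 0.2–10 Hz.
* Batch resilience: a corrupt trial is logged and rowed as missing; a
  study run never aborts on one bad file.
* Reproducibility: every stochastic component draws from
  `numpy.random.default_rng` seeded from the study master seed; study
  regeneration from the same (config, seed) is byte-identical.

Problem sizes in the test and acceptance suites are chosen to exercise
the study geometry at full per-trial resolution (90 s at 50 Hz) while
keeping replicate counts modest: 50 seeds per coupling level for the
monotonicity checks, 100 recovery and 500 null replicates at 40
participants for inference calibration, and brute-force oracle
comparisons on series up to 200 samples where exhaustive enumeration is
cheap.

## Known limitations

* Residual-df p-values are mildly anti-conservative for between-
  participant effects relative to Satterthwaite when the intra-class
  correlation is high; at the design's scale the simulations show the
  effect is negligible, but very small samples deserve caution.
* Only 1:1 frequency locking is indexed; polyrhythmic coordination would
  need frequency-ratio extensions.
* The coherence index depends on the chosen weighting; alternatives ship
  in the config, and the default is recorded in every run log.
* MaxLine at full trial resolution scales with O(n²) matrix construction
  (~4000² points per trial); trials much longer than a few minutes at
  50 Hz would need windowed variants, which are out of scope.
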