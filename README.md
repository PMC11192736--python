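# dyadcoord

Coordination dynamics of dyadic rhythmic movement: a tested, reusable
pipeline from raw paired movement time series to phase, spectral and
cross-recurrence coordination metrics, through mixed-effects models of
condition and symptom effects — plus a synthetic coupled-oscillator dyad
generator so every stage runs without any external data.

It is written for researchers in movement and social coordination who
record paired 1-D displacement series (e.g. a participant's arm curls
opposite a virtual partner at 50 Hz) together with condition factors
(partner gaze direct/averted; spontaneous vs. intentional coordination),
continuous symptom measures (LSAS, AQ) and area-of-interest gaze data,
and want the standard battery of coordination indices with calibrated
inference on top.

## What it computes

For each trial with participant and avatar traces x_p, x_a (trimmed,
standardised to 84 s, centred, 10 Hz low-passed):

* **Coordination stability** rho: instantaneous phases θ from the Hilbert
  transform, relative phase φ = θ_p − θ_a wrapped to (−180°, 180°], and

      rho = | ⟨e^{iφ_t}⟩_t | ∈ [0, 1],    z = atanh(rho)

  (1 = perfect phase locking; Fisher z for linear modelling).
* **Frequency matching**: weighted average of the magnitude-squared
  coherence coh(f) = |P_xy|²/(P_xx P_yy) over 0.2–10 Hz, weights
  proportional to the band-normalised movement power.
* **Cross-recurrence (CRQA)**: z-scored series are delay-embedded (delay
  from the first AMI minimum, dimension from the first FNN minimum), the
  recurrence radius is tuned by bisection to a 5% recurrence rate, and
  the matrix is summarised by %REC (recurrence rate) and MaxLine
  (longest diagonal line — coupling strength).
* **Participant gaze**: proportion of the trial spent looking at the
  avatar (missing samples excluded from the denominator).

The inference stage fits linear mixed models per outcome (REML,
by-participant random intercept; coordination coded 0 = spontaneous /
1 = intentional, gaze 0 = direct / 1 = averted; centred predictors; at
most one questionnaire per model), and decomposes interactions with
simple slopes (moderators at M ± 1 SD) and Tukey-corrected pairwise
contrasts. See `docs/methods.md` for the full model descriptions and
design choices.

## Worked example

```python
from dyadcoord.simulate import SimConfig, simulate_dyad_trial
from dyadcoord.preprocess import preprocess_trial
from dyadcoord.phase import phase_coordination
from dyadcoord.spectral import coherence_pair
from dyadcoord.crqa import CRQAParams, crqa_metrics

row = {"participant_id": "p001", "gaze_condition": "averted",
       "lsas": 70.0, "aq": 12.0}
pair, truth = simulate_dyad_trial(row, "spontaneous", SimConfig(), seed=42)
pp = preprocess_trial(pair)

stab, _ = phase_coordination(pp)
coh = coherence_pair(pp)
res = crqa_metrics(pp.participant.x, pp.avatar.x, CRQAParams(delay=24, dim=7))
```

which prints (via the obvious f-strings):

```
true coupling K = 1.271 rad/s (detuning -0.019 Hz)
rho      = 0.911   (Fisher z = 1.534)
coherence = 0.908
%REC     = 4.95   (radius 0.933, tuned to 5%)
MaxLine  = 225
```

The simulated participant is phase-coupled to the avatar at
K ≈ 1.27 rad/s (the averted-gaze LSAS effect raises it above the 1.0
baseline for this high-LSAS participant), which yields high but imperfect
phase locking (rho 0.91), closely matched movement frequencies
(coherence 0.91), a recurrence rate sitting on the 5% target by
construction, and a longest shared-trajectory run of 225 embedded samples
(4.5 s).

## Command line

```sh
dyadcoord simulate --seed 1 --out study --override sim.n_participants=20
dyadcoord metrics  --input study --out results
dyadcoord analyze  --out results
dyadcoord all      --seed 1 --out results        # the three steps in one go
```

`metrics` writes `results/metrics.csv` (one row per participant × trial);
`analyze` writes tidy coefficient, simple-slope and contrast CSVs under
`results/models/` and a `run.log` recording every analysis decision in
effect. Configuration is a flat YAML file of dot-separated keys
(`--config`), with `--override KEY=VALUE` taking precedence.

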