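# Methods

`tdsliking` predicts temporal liking (TL) curves of foods and cracker–spread
pairings from temporal dominance of sensations (TDS) curves with echo state
networks, and ships a synthetic sensory-panel generator so the whole pipeline
is testable end to end without human panel data. This note documents the
models, their assumptions, the defaults, and what the synthetic experiments
do and do not show.

## Pipeline overview

1. **Panel simulation** (`panel`) — raw per-trial event logs for a
   16-panelist × 8-condition × 3-repetition design with two real-time tasks
   (TDS attribute selection; TL liking presses on a 9-point scale).
2. **Curve building** (`curves`) — time-normalized dominance-proportion
   curves (12 attributes) and mean-liking curves, per panelist and condition.
3. **Bootstrap augmentation** (`bootstrap`) — 100 resampled curve pairs per
   condition, each the average of 16 panelist curve pairs drawn with
   replacement.
4. **Encoding** (`encoding`) — 12 attribute channels plus 0–7 constant
   binary context flags (total input dimension 12–19).
5. **ESN regression** (`esn`) — fixed random reservoir, leaky-tanh update,
   ridge readout trained on pooled time steps of all training sequences.
6. **Evaluation** (`evaluate`) — leave-one-pairing-out: train on the seven
   other conditions (700 curve sets at B=100), test on the held-out
   pairing's 100 replicates; summarize per-curve-set RMSE by median and IQR;
   rank all 32 (4 neuron counts × 8 encodings) architectures.

## Synthetic panel generator

The generator is a semi-Markov model over dominant attributes. Each
condition has a `ConditionProfile`:

- **Phases**: ordered intervals tiling normalized time [0, 1], each with a
  selection probability vector over the 12 attributes. Episodes have
  exponential dwell times (mean `dwell_mean_s`; 2 s for spreads, 3 s for
  crackers, 2.5 s for pairings); the attribute of an episode is drawn from
  the phase active at the episode's start. Consecutive draws of the same
  attribute merge (a panelist does not re-press the same button), which
  leaves the dominance trajectory unchanged.
- **Liking**: TL presses form a Poisson stream (`press_rate` = 12 presses
  per normalized-time unit — roughly one press per second on a 10–20 s
  tasting) whose value is the hedonic weight of the currently dominant
  attribute plus `N(0, noise_sd = 0.8)`, rounded and clipped to 1–9. Before
  any attribute is dominant the press reports `baseline_liking` (5, the
  scale midpoint).
- **Onsets**: the first TDS selection follows an exponential delay with
  mean 5% of the trial duration, the first TL press 10%, so the
  zero-before-first-press convention is always exercised.
- **Durations**: lognormal around the condition-class mean (20 s for
  conditions involving a cracker, 10 s for spreads alone) with 15% CV.

Default profiles are hand-set to mimic the qualitative structure reported
for these foods: strawberry jam runs sour → wet → sweet with liking peaking
above 6 mid-tasting; crackers show dry/salty/wheat-like (plain) or
sesame/burned (sesame) dominance with lower liking; pairings show spread
attributes early and cracker attributes late with an earlier liking peak
(the pairing profiles carry mildly elevated sweet/wet weights, reflecting
hedonic enhancement of complementary pairings).

What the generator deliberately does **not** model: panelist-specific
biases, fatigue or order effects, carry-over between samples, or correlated
attribute confusion. Passing tests on this generator therefore demonstrate
that the pipeline recovers structure *of this generative form* — phase-driven
dominance with attribute-conditioned liking — not that the trained models
transfer to any particular real panel.

Reproducibility: one session seed expands to per-trial streams through
`numpy.random.SeedSequence` spawn keys (panelist, condition, repetition,
task), so any trial can be regenerated in isolation and generation is a pure
function of (design, profiles, seed).

## Curves

- Grid: 101 evenly spaced points on [0, 1] (0.01 resolution; ample for
  10–20 s tastings). Each trial is sampled last-event-carried-forward on
  normalized time t' = t/duration.
- Per-panelist aggregation happens before any cross-panelist averaging:
  dominance proportions over that panelist's three TDS repetitions, mean
  over the three TL repetitions. The pre-first-selection period is kept as
  an explicit "none" mass so attribute + none mass = 1 at every grid point
  (a conservation check); the "none" row is never fed to the model, whose
  input stays 12-dimensional plus flags.
- TL curves live in [0, 9]: 0 only encodes "no press yet".

## Bootstrap augmentation

Replicates resample the panelist as the unit — TDS and TL curves drawn
together — preserving the within-panelist coupling the regression must
learn. Draws are independent across conditions. This is augmentation only:
replicates of the same condition share the 16 underlying panelists and are
not independent samples of a consumer population, so no confidence
intervals are derived from them.

## Encoding

Flag blocks follow fixed semantics: *combination* (1 iff pairing);
*cracker/spread* (presence; both 1 for pairings); the *exclusive triple*
(cracker, spread, combination; exactly one set); *brand* (premium, sesame,
peanut, strawberry by ingredient presence). Composite configurations (5–7
flags) concatenate blocks with their own semantics; in the 7-flag
configuration the cracker/spread pair follows the exclusive convention
(choosing the both-1 convention instead only relabels two constant columns
the readout can absorb). Flags are constant channels: context, not
dynamics.

## Echo state network

Update rule: `x(t) = (1-α)x(t-1) + α tanh(W x(t-1) + W_in u(t))`, `x(0)=0`.
Defaults: α = 1, spectral radius 0.9, recurrent density 0.1, dense inputs
in [−1, 1], ridge λ = 1e-6 — conventional ESN settings, all exposed in
`ESNParams`. `W` is rescaled so its largest eigenvalue magnitude equals the
target radius exactly (verified to 1e-6 against an independent ARPACK
eigensolver); a measure-zero degenerate draw is redrawn with an incremented
sub-seed. Sequences are short and all start from the same quiescent state,
so states reset to zero between sequences and the default washout is 0
(configurable).

The readout is a single linear map trained by closed-form ridge on the
pooled time steps of all training sequences, with a bias column appended;
the penalty applies to the bias too (matching the pooled closed form; a
practically negligible choice at λ = 1e-6, and switchable by rescaling).
`fit_readout` refuses a singular system at λ = 0 and warns when pooled rows
are fewer than coefficients. Predictions are raw (unclipped) by default;
RMSE is computed on raw predictions, with clipping to [0, 9] available as
an evaluation option.

Echo-state property: with radius 0.9 and α = 1, trajectories from different
initial states driven by dominance-scale inputs contract below 1e-6 within
one 101-step sequence (tanh saturation makes the effective contraction
faster than the spectral radius alone suggests); this is probed directly in
the tests.

## Evaluation

Per held-out pairing a fresh reservoir is initialized (sub-seeded from the
run seed), trained on the 700 training curve sets, and scored on the 100
held-out replicates. Median and IQR use linear-interpolation ("type 7")
quantiles. The pooled ranking statistic is the median over the concatenated
4×B RMSE values (median-of-medians is available as an option). Reservoir
state computation is vectorized across same-length sequences, so the full
32-architecture sweep at B = 100 runs in about a minute on one CPU.

The numeric RMSE table of any real study cannot be reproduced here — the
human panel data is not public and the exact reservoir hyperparameters
behind published numbers are under-determined — so the sweep on the default
synthetic panel serves as a structural analog. It reproduces the
qualitative pattern: architectures with 0–3 auxiliary flags and mid-sized
reservoirs achieve sub-0.5 pooled median RMSE on the 9-point scale, while
brand-flag-heavy encodings generalize poorly to the held-out pairing
(their flag pattern never occurs in training) and can err by several liking
points.

## Recovery benchmark

`linear_liking_dataset` keeps realistic TDS dynamics but replaces every
replicate's liking with a fixed known linear functional of the current
dominance vector plus `N(0, 0.3)` noise. The acceptance requirement is that
the 128-neuron single-flag model's pooled median LOCO RMSE be below half
the constant-mean predictor's, across three seeds; in practice it reaches
about a third (≈0.33 ratio), close to the noise floor.

## Numerical and degenerate-input choices

- Quantiles: NumPy default linear interpolation (type 7).
- Empty trials (no presses) are legal: all-"none"/all-zero step functions.
- Ties at grid points: events exactly at a grid time take effect at that
  point (right-closed carry-forward).
- Curve CSV and event-log CSV writers emit full-precision floats and the
  readers parse in round-trip mode, so write-read cycles are exact.
- All derived seeds are reduced mod 2^31.

## Problem sizes used by the shipped experiments

The acceptance script and tests run the study-scale configuration: 16
panelists, 8 conditions, 3 repetitions, B = 100 bootstrap replicates
(700-train / 100-test splits), the full 4 × 8 architecture grid, and three
seeds for the recovery benchmark. Unit tests use reduced replicate counts
(B = 5–10) where the full scale adds nothing to the property under test.
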