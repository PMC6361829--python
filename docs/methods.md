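# Methods

`ethotrack` turns fixed-rate video-tracking exports of individual insects in
three-zone T-maze arenas into behavioral events, summary statistics and
two-choice preference estimates. This note records the models, the defaults
and the reasoning behind the choices that were genuinely open.

## Movement-state model

Each track sample is assigned one of three states — *moving*, *halting*,
*not-detected* — by a rule cascade with two tunables: a velocity threshold
`v_threshold` (mm/s) and a look-ahead window of `lookahead_n` samples.

1. **moving** if (start) the previous state is not moving, the current
   velocity is at or above threshold, and some velocity among the *next* `n`
   samples is also at or above threshold; or (remain) the previous state is
   moving and some velocity among the current or next `n` samples is at or
   above threshold;
2. else **halting** if (start) the previous state is not halting and the
   sample has a tracking fix; or (remain) the previous state is halting and
   some sample among the current or next `n` has a fix;
3. else **not-detected**.

The first sample's previous state is *unknown* (neither moving nor halting).
Samples without a fix have no velocity, which counts as below threshold.
The look-ahead deliberately smooths the state sequence: an isolated
above-threshold spike shorter than the window never starts a movement, and a
dip of at most `n` samples inside sustained movement never splits it. The
same mechanism bridges halts across dropouts of up to `n` samples.

Defaults: `v_threshold = 0.05` mm/s — the antimode of the bimodal
("camel-shaped") velocity histogram of walking thrips, with a halting mode
near zero (tracking jitter) and a moving mode around 0.2–0.4 mm/s — and
`lookahead_n = 4` samples (1.2 s at the nominal 3.33 samples/s), the setting
found to separate the two modes most reliably for thrips.

Two boundary questions are not settled by the rule statement and are resolved
as follows (the alternative is exposed as `empty_window_passes`):

* the start-moving window is strictly future; when it is *empty* (`n = 0`,
  or the last sample of the track) it counts as "no qualifying sample", so
  movement is never fabricated at track end;
* the remain rules include the current sample, so their window is never
  empty.

## Events

Maximal runs of constant (state, zone) become events; a state change *or a
zone change* ends an event, so one physical movement crossing a zone boundary
is split — this is why two-choice data typically show 30–40% more moving than
halting events. Event time spans abut exactly (each event ends where the
next begins; the last ends one sample interval after the last sample), so
events partition the trial timeline — an invariant every later stage
preserves. Moving-event distance is the summed sample-to-sample path length
(not endpoint displacement), which keeps `mean_velocity × duration ≈
distance`. Samples classified moving/halting while the tracker had no fix
(bridged by the look-ahead) inherit the zone of the previous sample.

**Halt recovery.** A halt / not-detected / halt triplet is merged into one
halt when both halts are in the same zone and the second starts within a
radius of where the first ended; the radius is the first halt's own
start-to-end displacement. Because pixel quantisation makes exactly-zero
displacement common, the radius has a floor (`recover_radius_floor`, default
0.05 mm ≈ one pixel at 20 px/mm). The scan repeats to fixpoint. Merging is
restricted to same-zone halts because recovered halts feed zone-specific
choice statistics; a cross-zone merge would move time between genotypes.

## Quality filters

Event filters convert artifact events to not-detected events of identical
span — never delete — so the timeline partition and detection accounting stay
exact. Order: extreme velocity (mean velocity above `v_extreme`, default
5 mm/s: tracking glitches such as reflections mistaken for the insect), zone
boundary (moving events that do not both start and end at same-zone halting
events), incomplete (moving/halting events adjacent to a tracking dropout,
whose true start or end is unknown). "Adjacent to a dropout" means adjacent
to an event that was not-detected *in the segmentation output*; events
converted by other filters do not count as dropouts — the only reading under
which the filter is idempotent — and trial edges are not dropouts either.

Record filters drop whole arenas, with strict comparisons: longest single
halting event > 3600 s (a dead or torpid insect), detected-time fraction
< 50%, or fewer than 1000 moving+halting events. "Inactivity" is read as the
longest single halt; the event count is taken after segmentation but before
event filters, so triage reflects raw data quality.

## Statistic catalogue

38 statistics per record × zone (× time bin), in three overarching
categories (choice, halting, movement): choice (detected time in zone /
trial duration); average velocity; halting and moving total durations with
short/medium/long duration subcategories (halts split at 2 and 10 s, moves
at 2 and 5 s — the cuts that separate brief probing from sustained bouts)
and slow/medium/fast velocity subcategories for moving (cuts 0.025 and
0.075 mm/s); the matching frequencies; total moving distance; per-event
averages of halting/moving duration and moving distance; and four ratios
(halting/trial, halting/detection, moving/halting, moving/detection).

Binning: totals are clipped exactly at bin boundaries (distance pro rata by
time), so hourly values sum to whole-trial values; frequencies and per-event
averages attribute each event to the bin containing its start, keeping counts
integral. 14 statistics are reported per hourly bin by default; all 38 are
computable per bin.

**Detection correction** divides observed totals by the record's *overall*
detected-time fraction in the same bin — not the zone's own occupancy, which
would erase the choice signal (time in a zone is the signal, not a detection
artifact). Frequencies are left uncorrected by default (`correct_frequencies`
flips this); per-event averages need no correction; ratios are formed from
corrected components, so detection-relative ratios are unchanged by
correction. For display, per-hour values are log-transformed before
averaging across records (zeros excluded) because the corrected totals are
strongly right-skewed.

## Choice models

For a statistic with zone means μ_A, μ_B and per-arena observations
(y_A, y_B), preference is parameterised as π_A = μ_A/(μ_A+μ_B), so
logit(π_A) = log(μ_A/μ_B) and the estimate back-transforms to the ratio of
means.

**Logit quasi-binomial GLMM** (default). The conditional distribution of y_A
given m = y_A + y_B is taken as quasi-binomial: variance φ·π(1−π)/m with free
dispersion φ. The values act as "trials" even when they are continuous
amounts (durations in seconds) — φ absorbs the scale, and the logit estimate
is invariant to rescaling all observations. Unlike the log-ratio model this
handles zero observations. Random effects: the plant providing the A leaf,
the plant providing the B leaf (leaves are drawn from finite plant pools and
randomised over arenas, so these are crossed, not nested) and, across
multiple trials, the trial.

Fitting is iterative re-weighted REML (penalised quasi-likelihood): from
current η, form the working response z = η + (p − π)/(π(1−π)) with weights
w = m·π(1−π), fit a weighted linear mixed model of z on an intercept by REML,
update η from the fixed estimate plus predicted random effects, and iterate
until the sup-norm change in η is below 1e-6 (max 100 iterations; φ floored
at 1e-8). η is clamped to ±12: under quasi-separation (an arena at p = 0 or
1 carrying its own random-effect level) η would otherwise drift without
bound and the loop could not converge; the clamp pins such arenas at a
negligible weight. With no (or zero-variance) random effects the procedure
is exactly IRLS for a quasi-binomial GLM with Pearson-based dispersion,
which the tests verify against an independent GLM implementation.

The inner weighted mixed model is fitted directly: with
V₀(γ) = W⁻¹ + Σ γ_k Z_k Z_kᵀ and γ_k = σ²_k/φ, the REML criterion
log|V₀| + log|XᵀV₀⁻¹X| + (n−p)·log(yᵀP₀y) is minimised over γ ≥ 0
(L-BFGS-B; multistart on the first IRREML iteration, warm-started
thereafter) and φ is profiled out. Problem sizes are tens of arenas, so
dense n×n algebra is appropriate.

**Satterthwaite degrees of freedom.** Tests and 95% intervals use
t statistics with df = 2g²/(∇gᵀA∇g), where g(θ) = cᵀ(XᵀV(θ)⁻¹X)⁻¹c over the
variance parameters θ = (σ²₁…σ²_K, φ) and A is the inverse observed REML
information (finite differences). Components estimated on the zero boundary
are held fixed and dropped; with no random effects the exact residual df
n − p is used. The implementation reproduces reference values from
lme4/lmerTest on a crossed, weighted fixture to ≤0.1%.

**Log-ratio LMM**: REML linear mixed model of log(y_A/y_B) with the same
random-effect structure. Arenas with a zero on either side are excluded and
counted — the practical drawback that motivates the logit model.

Raw p-values are reported (with log₁₀(p) and log₂(ratio) columns);
Benjamini–Hochberg adjustment is available but off by default, since the
appropriate correction depends on how many statistics a downstream analysis
actually screens.

## Synthetic tracks

The simulator exists so every stage can be scored against known ground
truth; it emulates the features of real thrips tracks that the engine is
sensitive to, not thrips biology in general.

* **Geometry**: the 1-D channel axis through the T-maze — two 6 mm leaf-disc
  zones joined to a 6 mm central zone by 2 mm channels (channels count as
  neutral zone 3).
* **Behavior**: a two-state semi-Markov walker. Halt and move bout
  durations and moving speeds are lognormal per zone (right-skewed, as bout
  data generically are): on leaves, median halt 8 s (sdlog 1.0), median move
  2.5 s (sdlog 0.8), median speed 0.3 mm/s (sdlog 0.4); in the neutral zone
  halts are shorter (median 3 s). Halting positions jitter at ~0.01 mm/s —
  together with the moving mode this reproduces the bimodal velocity
  histogram with its antimode near 0.05 mm/s.
* **Choice**: a movement starting in the neutral zone heads toward zone 1
  with probability `p_choose_zone1`; later neutral-zone moves keep their
  heading with probability 0.8, so the walker actually crosses to the other
  leaf instead of diffusing back to the nearest one. The persistence value
  was set so that arenas show frequent zone transitions, matching the
  reported excess of moving over halting events in real two-choice records.
  Preference effects are injected as shifts of the halt-duration meanlog
  (multiplicative on the median halt length).
* **Dropout**: geometric-length not-detected gaps (mean 5 samples) at random
  onsets, totalling ~10% of samples — the typical tracking-failure level —
  with half the onsets placed inside halts to exercise halt recovery.
* **Design**: per trial, each arena receives one leaf per genotype, drawn
  without replacement from pools of 10 plants × 4 leaves; per-plant and
  per-trial lognormal multipliers on halt duration inject the variance
  components the mixed models are meant to recover.

What the simulator does *not* emulate: 2-D path shape (movement lives on the
channel axis), posture or feeding-waveform substructure, tracker velocity
smoothing, identity swaps, or time-varying preference. Passing tests
therefore demonstrate the correctness of the extraction/statistics/inference
chain under a faithful two-state generative model, not robustness to every
artifact of real video tracking.

One consequence worth knowing: because leaf visits are long relative to a
short trial window, the *realized* occupancy contrast is attenuated below
the parametric effect (a 2-fold halt-duration effect yields roughly 1.3–1.7×
more halting time on the preferred leaf over a 2 h window). The inference
tests detect the effect, they do not assume the realized ratio equals the
injected one.

## Problem sizes in the test suite

The study records 8 h per arena. The test suite and the acceptance script
use 1–2 h simulated trials with 40 arenas (and correspondingly scaled
record-filter thresholds, e.g. a minimum of 100 events for a 2 h trial),
which keeps the full suite fast while leaving all rates and distributions at
their defaults. Simulation-based calibration checks use 200 null replicates
(rejection rate asserted within [0.03, 0.07] at α = 0.05 at the observation
level, [0.02, 0.09] for the full pipeline — the 95% binomial band around 5%
at that replicate count) and 500 replicates for CI coverage (asserted within
[0.92, 0.98]).

## Numerical notes

* Timeline identities (events partition the trial; binned totals sum to
  whole-trial totals) hold to float round-off; tests assert them at 1e-9
  relative.
* The velocity histogram pools values ≥ `v_max` into a final overflow bin so
  counts are conserved.
* An isolated detected sample (both neighbours not detected) gets velocity 0
  when deriving velocities from positions: it carries no displacement
  evidence, and 0 avoids fabricating movement starts.
* Spearman correlations use average ranks for ties; constant statistics have
  undefined correlations and are reported as missing.
* The IRREML estimate's label-swap antisymmetry (swapping A and B negates
  logit(π̂_A)) is exact to machine precision; p-values agree to optimizer
  noise (~1e-3 relative) because the Satterthwaite df is computed by finite
  differences at independently optimized variance parameters.

## Known limitations

* The zone-boundary filter converts moving events at trial edges (no
  flanking halt exists); over 8 h this is negligible, in very short windows
  it is visible.
* With a single trial the trial variance component is not estimable and is
  dropped; with unique plants per arena the plant components absorb
  arena-level overdispersion jointly with φ.
* The state machine's remain rules intentionally bridge sub-window halts and
  dips; ground-truth agreement on simulated tracks is therefore bounded by
  the frequency of sub-window bouts in the generator (≥99% in the
  well-separated regime, ~98% at the default bout mixture).
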