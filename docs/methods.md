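# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `attractorchoice`.

## The task and its relational quantities

Each trial offers a **small-and-near (SN)** and a **large-and-far (LF)**
coin. Rewards are integer credits in [1, 99]; distances are integer grid
fields in [2, 15]. Three relations describe a trial:

* reward ratio `r = reward_SN / reward_LF ∈ (0, 1)`,
* interval `I = distance_LF − distance_SN ∈ [1, 13]`,
* manipulation point `m = r − p*(I)`,

where `p*(I)` is the participant's indifference point: the reward ratio at
which, for interval `I`, both options are subjectively equal. `m < 0` means
the LF option is subjectively superior, `m > 0` the SN option.

## Subjective value

The task gives no closed form for how reward and distance combine. We adopt
hyperbolic discounting over distance,

    ω(reward, distance) = reward / (1 + k · distance),

with individual discount rate `k ≥ 0`, by analogy to hyperbolic delay
discounting. This yields the analytic indifference ratio

    p*(I; d_SN) = (1 + k·d_SN) / (1 + k·(d_SN + I)),

strictly decreasing in `I` for `k > 0`. Because the design crosses SN
distances 2 and 3 with every interval while the analysis treats `p*` as a
function of the interval alone, the package's reference truth for a
synthetic participant is the mean of the two `d_SN` values; the two differ
by less than 0.03 everywhere in the design range. Any other strictly
monotone value function could be substituted if the analytic indifference
curve is updated consistently.

## The one-dimensional attractor model

The decision variable `x` lives in the quartic double-well potential

    V(x, c) = x⁴/4 − x²/2 − c·x.

This is the minimal bistable family whose two attractors' relative depth is
set by a single control parameter: `V(1, c) − V(−1, c) = −2c`, so `c > 0`
deepens the SN well (`+x` ↔ SN by convention). The control parameter is a
linear map of the manipulation point, `c = gain · m` (default gain 1; only
the analogy between the two quantities is fixed by the design, not a
scale).

Within a trial the state follows the overdamped Langevin equation
`dx = (x − x³ + c) dt/τ_trial + σ dW`, integrated by Euler–Maruyama with
fixed step `dt`. A choice is read out when `|x|` crosses the bound `θ`;
reaching the deadline `t_max` first is recorded as a timeout (timeouts are
kept in the trial log and excluded from choice ratios; with the default
noise they are practically absent).

During the 1.3-s inter-trial interval the stimulus is off and the state
relaxes **linearly toward the neutral point**, `dx = −(x/τ_iti) dt +
σ_iti dW`. A monostable restoring force is used deliberately: continuing
the double-well dynamics through the ITI would relax the state toward the
previous attractor rather than toward neutral. Because `τ_iti` is long
against the ITI, a residual bias toward the previous choice survives into
the next trial — the mechanism of perseveration and hysteresis.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `noise_sd` (σ) | 0.35 /√s | within-trial diffusion |
| `threshold` (θ) | 0.8 | decision bound on \|x\| |
| `dt` | 1e-3 s | Euler–Maruyama step |
| `tau_trial` | 0.1 s | within-trial time constant |
| `tau_iti` | 2.0 s | ITI relaxation time constant |
| `t_max` | 10 s | trial deadline |
| `iti_duration` | 1.3 s | inter-trial interval (task value) |
| `control_gain` | 1.0 | m → c map |
| `ceiling` | 1.5 | hard bound against numerical escape |
| `iti_noise_sd` | = σ | ITI diffusion |

Only `iti_duration` is fixed by the task. The rest were chosen once so
that stochastic runs produce graded psychometric curves and a positive
perseveration index; they are not fitted to human data. With these
defaults the post-ITI residual is `θ·e^(−1.3/2) ≈ 0.42`, which exceeds the
largest basin-boundary displacement inside the ±0.3 control range
(≈ 0.36 at c = 0.3): the **noiseless** system would never switch within a
sweep, and the disfavoured well at c = ±0.3 (|x*| ≈ 0.79) sits just below
θ. Noise resolves both in stochastic runs. Deterministic hysteresis
demonstrations therefore use `tau_iti = 1.0` (residual ≈ 0.22), for which
the noiseless ascending/descending sweeps each flip exactly once, four
steps later than a memoryless chooser would.

### Numerics

Euler–Maruyama with fixed `dt` is used because the ITI dynamics then have
an exact closed form (`x(T) = x₀·e^(−T/τ)` at σ = 0) that serves as an
integrator oracle; the σ=0 integration error at `dt = 1e-3` is below 1e-4,
and halving `dt` changes noiseless response times by under 1 %. The
production path runs in a numba-compiled kernel whose arithmetic is
identical, operation for operation, to the pure-Python `step`/`relax_iti`
reference; a test asserts exact noiseless agreement between the two.
Per-participant noise streams are seeded deterministically from the cohort
master seed.

## Design generation

* **Assessment block**: the full 8 (reward ratios 20–99 %) × 2 (SN
  distance) × 4 (interval) factorial, 64 trials per set, order shuffled
  within set, 5 sets; LF rewards uniform on {55..99}; SN reward =
  ratio × LF reward rounded to the nearest credit (round-half-up, clipped
  to [1, LF−1]).
* **Indifference points**: per interval, `P(SN)` is fitted as a logistic
  function of the reward ratio by maximum likelihood with a tiny ridge
  (1e-4) that keeps the optimum finite under perfect separation; the
  inflection `p* = −a/b` is clamped to (0.01, 0.99). Intervals with
  one-option-only data or a non-increasing psychometric get no estimate; a
  profile with fewer than two estimated intervals is flagged (the
  synthetic-cohort analogue of excluding participants whose choices cannot be sequentially manipulated).
  Between fitted intervals `p*` is interpolated piecewise-linearly, with
  constant extrapolation beyond the endpoints — the simplest
  monotone-preserving choice.
* **Manipulation schedule**: 12 equally spaced points spanning
  [−0.3, +0.3]; direction `SN_to_LF` runs the schedule descending,
  `LF_to_SN` ascending. Each experimental block holds 8 sequences per
  direction (16 sequences, 192 trials), sequence order shuffled.
* **Reward (value) block**: one interval, valid for every schedule point
  simultaneously (requires `0.3 < p*(I) < 0.7`), is fixed per sequence;
  only the SN reward changes.
* **Distance block**: the reward ratio is drawn once per sequence,
  uniformly between `p*(7)` and `p*(6)`; the interval steps through the
  twelve consecutive values 1…12 (ascending when the manipulation runs
  LF-to-SN). The 1…12 grid matches the assessment's interval endpoints.
  Manipulation points are computed post hoc from the fitted curve, the
  same translation the trial-level analysis applies.
* **Combined block**: per schedule point an interval is drawn from the set
  where `0 < p*(I) + m < 1`; the SN reward then realises the scheduled
  ratio, so both features change within a sequence.

A pre-rounding round-trip invariant holds by construction for the reward
and combined blocks: re-deriving `m` from the generated real-valued ratios
reproduces the schedule to 1e-12; after integer rounding the realised `m`
is within `0.5 / reward_LF` of the schedule.

## Synthetic cohorts

A cohort (default 40 participants) draws
discount rates log-normally (`log k ~ N(log 0.15, 0.4²)`), chosen so that
indifference points at the design intervals fall inside the assessment
ratio range for nearly all draws. Each participant runs assessment →
fitting → individually generated blocks → simulated choices; the designs
use the *fitted* profile while the chooser acts on the participant's
*true* valuation, exactly mirroring the estimation error a real experiment
carries. Block orders cycle through all six permutations of the three
experimental blocks. Infeasible participants (flagged profiles or
infeasible designs) are replaced by fresh draws. Time-limited blocks are
emulated by trial counts — 134 assessment trials (a typical yield of an 8-minute block) and
full 192-trial experimental blocks — since wall-clock simulation adds
nothing statistically. The indifference-point recovery analysis uses a
doubled assessment (10 sets, 160 choices per interval): at the logistic
chooser's sensitivity (s = 8) that is the sample size at which the ML
inflection estimator's mean absolute error falls safely below 0.03,
whereas 80 choices per interval leave it near 0.036 for information-
theoretic reasons, not implementation ones.

Choosers: `logistic`/`lagged-logistic` (`P(SN) = expit(s·m + b·h)` with
lag-one history `h ∈ {−1, 0, +1}`; `b = 0` is the null model),
`attractor` (above), and `pcs` (below). The carryover state resets at
block boundaries and threads through all sequences within a block.

## The PCS comparison model

The parallel-constraint-satisfaction network has a clamped validity node,
four feature nodes (SN/LF distance, SN/LF reward) and two mutually
inhibiting option nodes. Features are min-max scaled to [−1, 1] over the
design ranges (nearer = more favourable for distance). The validity →
feature weights encode feature importance per layer; each feature node
excites its own option and inhibits the rival in proportion to its scaled
value (base weight 0.1). Updates follow the interactive-activation rule
with decay 0.1; the network settles when the change in the energy
`E = Σ_{i<j} w_ij·a_i·a_j` falls below 1e-5, and the more active option
node is the response. Post-decision option activations shrink by
`ρ = e^(−1.3/2)` over the ITI and seed the next trial.

Two defaults were calibrated once, qualitatively: the option-option
inhibition is −0.05 (a textbook −0.2 lets the carried activation dominate
every feature-evidence gap, producing absolute perseveration and
degenerate psychometrics), and the per-trial feature-input noise is 0.3
(graded choices near indifference). Note that with min-max scaling the
PCS indifference line is approximately linear in the interval, so at
equal importance weights the largest assessment interval is SN-dominated
at every ratio level; that interval simply contributes no fitted point and
the curve extrapolates — a property of the linear PCS valuation, not an
error path.

Empirically (seeded cohorts), equal importance weights give statistically
indistinguishable distance- and reward-block perseveration indices,
whereas unequal weights order them, the block sweeping the more strongly
weighted feature perseverating more. This reproduces, in mechanism, the
possibility that feature-specific weighting differentiates block-wise
perseveration strength.

## Analysis

Per participant and block, the perseveration index is

    PI = P(SN | direction SN_to_LF) − P(SN | direction LF_to_SN),

pooled over a direction's trials (timeouts excluded). This orientation
makes perseveration positive. Direction-split curves report mean %LF per
manipulation-point bin (or per interval for the distance block), averaged
first within and then across participants; with the balanced designs the
PI equals the bin-mean direction gap of the SN-coded curves exactly.
One-sample tests are one-sided (> 0) with `t = mean/(sd/√n)` and Cohen's
`d = mean/sd`; no multiple-testing correction is applied (three separate
tests, as reported). Block comparisons are descriptive only — means ± SE
and pairwise differences with seeded bootstrap percentile intervals (2000
resamples); inferential repeated-measures machinery is intentionally out
of scope, and tidy per-trial tables are exported for external mixed-model
tools.

## Problem sizes

The heavy validation runs use 20 replicate attractor cohorts and 10-cohort
acceptance summaries of 40 participants × (134 + 3·192) trials each, a
40-participant null cohort, a 40-participant recovery cohort with the
doubled assessment, and three 40-participant PCS cohorts.

## What the synthetic data does and does not emulate

Emulated: the cohort size, the factorial assessment and its fitted
indifference points, the individually tailored sequential designs with
both directions and all three manipulated feature sets, lag-one choice
carryover, estimation error propagating from assessment into design.
Not emulated: mouse trajectories and motor noise, response-time
distributions of the human task, fatigue and learning across blocks, the
monetary incentive scheme, or the human sample's specific effect sizes —
passing tests show the pipeline's internal consistency and the direction
of its effects, not quantitative agreement with any human dataset.

## Known limitations

* The attractor's noiseless regime with default `tau_iti = 2.0` is
  absorbing within the ±0.3 schedule (see above); all perseveration
  statements at the defaults are about the stochastic system.
* The logistic-fit ridge introduces a negligible but nonzero shrinkage;
  under perfect separation the reported `p*` is the penalized optimum, an
  interior point of the separating gap.
* PCS parameters are illustrative, not fitted; only ordinal block
  contrasts are meaningful.
* The distance-block interval grid (1…12) is an assumption; the realised
  manipulation points are computed post hoc either way.
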