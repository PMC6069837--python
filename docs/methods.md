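# Methods

This note documents the models, estimators and numerical choices behind
the package, and what the synthetic-subject generator does and does not
emulate.

## Error dynamics and the adaptation-rate estimator

Per-trial error angles are generated by the first-order process

    e_{n+1} = (1 − a) · e_n + η,   η ~ N(0, sd²)

with `a` the true adaptation rate. This is the unique linear generative
model for which ordinary least squares applied to the first-difference
regression `e_{n+1} − e_n = β₁ e_n + β₀` returns `−β₁ = a` in
expectation. The estimator is a closed-form two-parameter OLS on the
consecutive-trial pairs; with `sd = 0` it recovers `a` to machine
precision for any `a ∈ (0, 2)`, and rates above 1 (overshoot — the next
trial over-corrects) are reported as-is.

Defaults: 40 adaptation trials, execution-noise SD 2°, initial error
e₀ = 30°. The initial error is not reported for this paradigm; 30° is a
plausible initial misdirection between the two gated DOFs (one third of
the full 90° control-space extreme) and is large relative to the noise,
which keeps the finite-sample OLS bias of the autoregressive fit small:
over 500 seeds at n = 40, |bias| < 0.014 across a ∈ {0.2 … 1.2}
(measured by the acceptance suite). With a purely stationary series
(e₀ ≈ 0) the classic AR(1) small-sample bias would be several times
larger.

The per-trial error angle is the angle between the mean activation
vector over the first 500 ms of the trial and the hand-close axis,
signed by the thumb component. The mean (rather than the endpoint) is
robust to within-window noise. Trials with an all-zero analysis window
are flagged missing and both consecutive-trial pairs touching them are
dropped from the fit.

## The two-interval perception task

The observer is a cumulative Gaussian with guess rate 0.5 (fixed by the
two-interval design) and lapse rate λ ≤ 0.06:

    ψ(x) = 0.5 + (0.5 − λ) · Φ((x − μ) / σ)

parameterized by its **threshold** — the stimulus at which ψ equals the
staircase target probability 0.84 — from which the location μ is derived.
This makes "threshold 40°" mean exactly "the 84 %-correct rotation".

The staircase is a single-track weighted up-down rule: correct responses
step the rotation down by `step_down` (default 2°), incorrect responses
step it up by `step_up = step_down · p/(1−p) = 5.25 · step_down`. The
stationary point of this rule is the stimulus with P(correct) = 0.84.
The track starts at 75°, is clamped to [0°, 90°], stops at 23 reversals,
and estimates the JND as the mean of the last 16 reversal stimuli (the
first 7 are the approach phase from the high start and are discarded).
A move truncated by a clamp leaves the direction state untouched, so
saturation at a boundary cannot create spurious reversals. A trial cap
(default 1000) guards against observers that never reverse.

Numerical behaviour, measured over 200 seeded runs against the
(40°, 10°, λ = 0.02) observer: mean JND 41.3° ± 3.3°, mean ψ(JND) =
0.855, ≈ 96 trials per staircase. The small positive offset from 0.84 is
inherent to averaging reversal extrema under a 5.25 : 1 step asymmetry:
upward reversal peaks overshoot the equilibrium by more than the
downward valleys undershoot it. Reversal-estimator conventions that
average only valleys would remove most of this offset but are not the
convention adopted here.

## Internal-model uncertainty

No single canonical formula exists for combining adaptation rate and JND
into one uncertainty number; the framework literature this battery
descends from does not expose its rule in closed form. The default rule
here,

    P̂ = (JND/90)² · (1 + |1 − rate|),

is a transparent surrogate satisfying the contract the group-level
results depend on: strictly increasing in JND at fixed rate, strictly
increasing in |1 − rate| at fixed JND, and zero only in the limit of a
vanishing threshold with unity rate. Fed the group-mean reference values
for the two feedback conditions, it reproduces their ordering. The rule
is pluggable via `formula_id`; absolute uncertainty magnitudes from
group studies are consequently *not* comparable to this score —
orderings are.

## Grasp-force profiles and submovement counting

A submovement is modelled as a smooth sigmoidal force increment whose
rate is a raised-cosine-cubed bell, `r(τ) ∝ sin⁶(πτ)` on a compact
support — C⁵ at the support edges, so the force profile's third
derivative is well defined and traces exactly one +/−/+ sign cycle per
pulse. A k-submovement trial is a monotone staircase of such increments
(the first establishes 0.65 · peak, the rest share a further
0.25 · peak), pulse supports never overlap, and the profile's maximum
stays below the requested peak. All-positive increments are deliberate:
concatenating pulses of opposite sign would merge adjacent third-
derivative lobes and break the one-pair-per-pulse identity.

The counter low-pass filters the force (4th-order zero-phase Butterworth,
8 Hz default at fs = 100 Hz — triple differentiation amplifies noise as
ω³ and no filter is reported for the original instrument), applies
central differences three times, discards samples below 1 % of the peak
third-derivative magnitude (amplitude hysteresis against numerical
chatter, plus an absolute floor of order eps·|F|·fs³ so a constant
profile counts zero), and returns sign changes // 2. The count is
invariant to force offset and positive scaling. On noise-free generated
profiles the count equals the generative k exactly for k ≤ 5.

## Virtual-egg performance

A trial breaks the egg when any force sample strictly exceeds 3.1 N
("larger than" the preset threshold; the comparison is strict and the
break is latched). Completion rate is the percentage of successful
break-free transfers; mean completion time averages successful trials
only and is a declared-missing value when nothing succeeded. Transfer
trials in the generator draw a per-trial peak grip force from the
subject's `peak_force_range` (default 2.4–4.0 N, ≈ 46 % break
probability — between the completion rates of the two reference
conditions) and a completion time from the subject's own
`completion_time_mean` (default 8.35 s ± 0.7 s against the 10 s limit).

## Statistics

Each paired contrast is gated by Levene's test at α = 0.05: homogeneous
variances → two-sample paired t-test; nonhomogeneous → Wilcoxon
signed-rank (exact distribution for n ≤ 25, normal approximation with
continuity correction above). Test–retest reliability is the
single-measure, absolute-agreement ICC from the two-way model —
McGraw–Wong ICC(A,1) — computed through pingouin and verified in the
tests against a from-scratch ANOVA variance-components decomposition to
1e-9. Confidence intervals follow the reported convention
mean ± 1.97 · SD; the 1.97 multiplier is kept verbatim rather than
normalized to 1.96. All tests are two-sided at α = 0.05 and no
multiple-testing correction is applied, matching the reporting
conventions of the assessment battery this package implements.

## What the generator does and does not emulate

It emulates: the protocol block structure (40 adaptation trials at 5 s,
staircase trials at 4 s until 23 reversals, 20 transfer trials at 10 s);
first-order trial-to-trial error dynamics; a stationary psychometric
observer; force profiles with a known submovement count; break/success
logic tied to the 3.1 N threshold; and per-subject trait variance
(grip-force tendency, typical transfer pace) that gives the test–retest
ICC a meaningful between-subject variance component.

It does not emulate: EMG waveforms or the SVR decoder (the generator
emits post-decoder control activations directly), within-trial feedback
corrections (activations are constant-direction ramps, an explicit
simplification — the study only analyzes the first 500 ms), fatigue or
learning drift across a block, non-stationary psychometric behaviour, or
audio rendering beyond the event stream. Passing recovery tests
therefore show the estimators are correct for data satisfying the
battery's own modelling assumptions, not that those assumptions hold for
any particular human dataset.

## Problem sizes

The shipped experiments are sized for a desk run: 7 subjects × 3
sessions in the cohort analysis, 500 seeds per grid point in the
adaptation-recovery suite, 200 staircases in the convergence experiment,
200 subjects in the ICC recovery check. The full test suite runs in
about ten seconds; the acceptance script in a few seconds.
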