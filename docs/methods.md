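# Methods

`rivalnorm` simulates perceptual dominance during chromatic interocular-switch
rivalry (ISR) with a feature-tuned, pooled divisive-normalization model. This
note records the model as implemented, the parameter choices, and the design
decisions taken where more than one reading was defensible.

## Stimulus and normalization pools

A condition describes a dichoptic display: a 4.5° × 4.5° fusion box per eye,
two rivalrous disks of 1.5° diameter centered ±1.5° from fixation on the
vertical meridian, dark annuli extending each disk's footprint to 1.75°, and a
background that is a stable chromatic field (green or red), neutral gray, or
dichoptically rivalrous (one eye green, one eye red). Disks are patchwork: at
every instant each eye shows one red and one green disk, in opposite
positions across eyes. Chromaticities are carried as symbolic channel labels
(with MacLeod–Boynton coordinates as metadata); the model consumes only
channel identity and area.

The rivalry mask f(x̄) is binary: 1 on the two disk interiors, 0 elsewhere
(annuli, Nonius lines, fixation, box edges). Binarity is pinned down by the
model itself: the red drive on a green background must be exactly 1, which
requires f = 1 wherever disk signal is present and makes graded masks
ineffective for these displays. A graded-mask hook exists for other stimuli.

Each channel C is reduced to a normalized drive

    Ŝ_C = Σ f(x̄)∘S_C(x̄) / Σ S_C(x̄),

with both sums pooled over the two eyes. Because pooling is binocular, the
drives are provably invariant under the eye swap, so the 3.75 Hz ISR schedule
is represented symbolically rather than frame by frame. The default
analytic-area mode evaluates the sums with exact circle/rectangle geometry
(including the exact circular-segment clipping of the annuli, which overhang
the box edge by 0.125° at the default layout); a raster mode with
pixel-center sampling exists for arbitrary masks and inspection, and
converges to the analytic ratios as resolution grows. Raster pixel-count
error oscillates between adjacent resolutions, so convergence checks sample
resolutions a factor of 4 apart.

### Calibrated background pool weight

With the stated geometry, pure area accounting gives the background-matching
channel a drive of 0.102 (annulus-punched background) and cannot go below
0.080 under any discrete accounting variant (the numerator is pinned by the
fully-masked channel's drive of 1, and the denominator is bounded by the box
area). The model's worked value for that drive is 0.069, which implies the
background contributes to its channel's pool about 1.53× its geometric area.
We therefore expose a single `background_pool_weight` on the accounting
(default 1.5292287), calibrated once against the worked value and frozen. A
plausible physical reading is that a large, contiguous, temporally stable
surface recruits disproportionately many similarly tuned neurons compared
with small transient patches; we treat the weight simply as the calibration
constant of the pool accounting. The weight only rescales the
background-matching drive; it cancels in the symmetric (gray and rivalrous
background) conditions, and the qualitative staircase does not depend on it.

Resulting drives at defaults: green background → red 1.0, green 0.069 (red
background mirrored); gray background → both 1.0; rivalrous backgrounds →
both 0.129 (equal by construction, which is all that matters: the dynamics
are homogeneous of degree 1 in the drives, so only their ratio is
observable).

## Competition dynamics

Two channel strengths P_C compete. Each carries a ceiling P_M equal to its
normalized drive, fixed for the whole trial. Three clocks:

| clock | default | role |
|---|---|---|
| base step | 1 ms | bookkeeping grid for traces/durations |
| adaptation update | 10 ms | explicit-Euler adaptation and recovery |
| sampling interval Δt | 250 ms (4 Hz) | noise resampling, gain lottery, winner-take-all |

Per 10 ms, the dominant strength decays as P ← P − dt·P/τ_D (τ_D = 2.5 s)
and the suppressed strength relaxes toward its ceiling as
P ← P + dt·(P_M − P)/τ_R (τ_R = 1.5 s). Between sampling events these
updates are deterministic, so the trial loop applies the exactly equivalent
closed form (1 − dt/τ)^25 per interval; unit tests exercise the single-step
operators directly. One Euler step tracks the exact exponential to ~1e−5
relative (decay) and ~2e−5 of the ceiling (recovery from 0).

Per Δt, in a documented order:

1. ξ_C is drawn per channel from N(0, σ²) truncated to [−0.35, 0.35]
   (σ = 1), sampled from the renormalized truncated density so the effective
   SD (0.2004) is exact in distribution. Noise is multiplicative,
   η_C = P_C·ξ_C, and is retained in the stored strengths; this also keeps
   strengths nonnegative, since 1 + ξ ≥ 0.65.
2. The gain g = 1.3 is assigned by lottery: with p = 0.55 to the currently
   dominant percept ("the currently stronger signal"), else to the
   suppressed one. The gain is transient — it multiplies the comparison
   values only and is never compounded into the stored strengths
   (compounding 1.3× at 4 Hz would diverge; a `store_gained` flag exposes
   the alternative for exploration).
3. Winner-take-all: the larger gain-modulated, noise-perturbed value wins;
   exact ties retain the incumbent (ties have measure zero under noise).

On a switch, the winner is re-driven by the stimulus to its ceiling P_M and
the loser is fully suppressed to 0, from which it recovers. This strong-WTA
reading makes the noise-free, p = 1 alternation period the crossing time of
g·e^(−t/τ_D) with 1 − e^(−t/τ_R) (≈1.66 s; observed 1.75 s, the next point
on the 0.25 s grid), which is verified against an independent root-finder.
The alternative "continue from current strength" reading yields a period of
τ_D·ln g ≈ 0.66 s and couples the period to g alone; the reset reading was
adopted because it reproduces the intended adaptation/recovery crossing
dynamics and a physically sensible re-drive of the winning representation by
the stimulus.

Trials last 70 s; the first 10 s are discarded and 60 s are measured,
mirroring the reporting protocol. The simulated trial length is not stated
for the original simulations; we use the empirical window.

### Randomness and reproducibility

Each trial uses one `numpy` PCG64 generator. Draws are consumed in a fixed
documented order: the full ξ stream for the structurally first channel (the
one on the left eye's top disk), the ξ stream for the other channel, then
the gain-lottery uniforms. Ordering channels by stimulus structure rather
than by label makes a global red↔green relabel map each channel onto the
same draw stream, so mirrored conditions produce exactly mirrored
trajectories under matched seeds (asserted exactly in tests). Campaign
seeds spawn per-condition and per-trial seeds via `SeedSequence`, so
campaigns with different seeds are independent and a (config, seed) pair
determines every output byte.

## Experiments

Experiment 1 (stable backgrounds): green, gray, and red backgrounds ×
n_runs trials; per-condition green/red dominance proportions with SD across
runs. Defaults produce the background staircase (green percept ≈ 0.04 on
green, ≈ 0.50 on gray, ≈ 0.96 on red background at n = 100) and the
ordering is robust down to small n. Campaign means at n = 25 and n = 100
agree within ~1 percentage point (max over the six cells), comfortably
inside the ~2-point convergence regime.

Experiment 2 (rivalrous backgrounds): each whole-field color hypothesis
pools one background plus one disk per eye, so the two drives are equal and
the reachable percepts are exactly the two similarity-enhanced (uniform)
ones. Difference-enhanced percepts are structurally impossible — the
summary reports them with proportion identically 0 — and the similarity
percepts split 50/50 up to sampling error.

Sensitivity sweeps vary one parameter at a time (noise bound, g, gain bias,
τ_D, τ_R) and report proportions, mean dominance durations, and switch
rates. Averaged over the three backgrounds, the switch rate rises
monotonically with the noise bound over {0.05, 0.2, 0.35, 0.7}; on the
neutral background alone the adaptation-driven alternation imposes a rate
floor at low noise, so the monotone trend is a property of the
condition-averaged rate. τ_D = 25 s preserves the staircase while cutting
the switch rate by more than half.

## Statistics

The staircase scorer applies the strict predicted ordering (green percept:
green < neutral < red background; red percept mirrored); ties count as
failures — the prediction is one of the six strict orderings, and ties have
probability zero for continuous proportions. Exactly 1 of the 6 orderings
succeeds, so the per-staircase null is 1/6, and the per-observer variant
(both staircases matching) uses 1/36 as an independent test, without
modeling dependence between an observer's two staircases. Tail
probabilities are exact binomial sums (scipy), cross-checked in tests
against direct summation.

Dominance summaries take labeled report intervals (observer, day, trial,
percept, onset, offset), require non-overlap within a trial, assign
unreported time to no percept, and compute SEM across day means; a single
repeat reports SEM as absent (NaN).

## Synthetic observers

`synth` generates button-press streams for testing the statistics surface
only: gamma-distributed dominance durations (shape 3, mean 2 s — the
standard empirical description of rivalry duration histograms), i.i.d.
percept labels at target proportions, optional unreported gaps. It emulates
alternation timing and report bookkeeping, not serial dependence, day
effects, or any perceptual mechanism — passing round-trip tests shows the
statistics are computed correctly, not that the model fits human data. The
staircase fixture draws proportion triplets around a monotone pattern with
i.i.d. normal jitter; at effect size 0 the cells are exchangeable, making
the 1/6 null exact by construction.

## Numerical and scale choices

- Analytic areas are exact; raster mode uses pixel-center sampling.
- CSV floats are written with 6 significant digits; full precision is kept
  internally.
- Default campaign sizes in tests (15–100 runs per condition, 30 per sweep
  point) were chosen as the smallest sizes at which the assertions are
  statistically stable; a single 70 s trial costs ~3 ms, so a full
  Experiment 1 campaign at n = 100 runs in about a second.
- Degenerate inputs: empty normalization pools, overlapping geometry,
  overlapping report intervals, and infeasible synthetic targets raise
  typed errors naming the offending element.

## Known limitations

- Piecemeal/mixed percepts are not modeled; the readout is binary, so
  simulated proportions partition the measured window, unlike human
  reports, which leave unreported time.
- The background pool weight is a calibration constant, not a measurement;
  only its symmetric-condition-cancelling role is structurally constrained.
- Eye-of-origin dynamics are absent by construction (binocular pooling),
  so the package cannot address phenomena that depend on them.
- The sensitivity claims are qualitative regime statements (monotone
  trends), not quantitative fits.
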