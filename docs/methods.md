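# Methods notes

This note records the modelling assumptions, defaults and numerical choices
behind `dotcomp`, and what the synthetic-data tests do and do not establish
about real data.

## Task and design

The task is a two-alternative forced choice between two dot arrays whose
counts (12–32 dots) stand in one of four exact ratios — 4:3, 5:4, 8:7, 10:9,
ordered easy to hard — crossed with two incentive conditions (reward:
±3 points per correct/error; control: 0 points) signalled by a cue colour
counterbalanced across participants. A session is 32 blocks × 24 trials =
768 trials. The published description leaves the within-block composition
open beyond "randomized"; we fix a balanced policy — 12 reward and 12
control trials per block, each ratio three times per incentive per block,
the larger array on the left in exactly half of each cell's 96 trials —
because equal cell sizes make the per-cell summaries well defined.
Numerosity pairs are drawn uniformly from the exhaustive set of exact-ratio
pairs in range. Points map onto 15 equal-width levels over [0, 1152] (the
maximum attainable), three levels per prize (5 prizes); totals below zero
floor at level 1. Actual stimulus images are out of scope: the analysis
consumes numerosities only.

## Behaviour generator

Choices and RTs come from a Wiener diffusion with absorbing boundaries:
evidence starts at a/2 (no response bias, matching the EZ assumption),
drifts at v with scale s = 0.1, and the first passage through 0 or a plus
the non-decision time t_ER gives the RT. Simulation is Euler–Maruyama at
dt = 0.5 ms with absorption at the first crossing. Discrete monitoring of a
continuous barrier misses excursions between grid points, biasing the
crossing probability by O(√dt) (~0.003 in Pc at these parameters); we
therefore shift both barriers inward by the Broadie–Glasserman continuity
correction 0.5826·s·√dt, after which the simulated (Pc, MRT, VRT) agree
with the closed-form moments to within Monte-Carlo error (verified at
50,000 trials in the test suite). An optional trial-to-trial drift
variability `sv` exists to produce data that violate the pure model — used
only by the suitability diagnostic's tests.

Default condition parameters (the generator's ground truth) satisfy the
orderings the study design implies, with magnitudes in the conventional
s = 0.1 scale: control drift 0.32/0.26/0.16/0.12 across the four ratios,
reward +0.04 at every ratio; boundary 0.11 (control) vs 0.13 (reward);
non-decision time 0.30 vs 0.33 s. Boundary and non-decision time are held
constant across ratios for parsimony — difficulty acts on drift only.

## Pupil generator

A recording is baseline (4.5 mm) plus one phasic kernel per trial event,
white per-eye noise (SD 0.01 mm), and blink gaps (Poisson arrivals at
0.05 Hz, uniform 80–400 ms, both eyes missing, capped at 10% of samples).
The kernel is the Erlang-gamma pupil response function
h(t) = t^n·e^(−n·t/t_max), peak-normalized, n = 10.1, t_max = 930 ms — the
standard phasic kernel; any smooth unimodal kernel would do for the tests.
Sampling rate defaults to 250 Hz. Kernel amplitudes per (incentive, ratio,
phase) are reward > control in all three phases (cue 0.25 vs 0.10 mm,
stimulus 0.30 vs 0.18, feedback 0.35 vs 0.20) with a small linear
difficulty gradient in the stimulus (0.01 mm/level) and feedback
(0.015 mm/level) phases, so that the feedback-phase linear trend contrast
has a true positive slope. A per-participant lognormal gain (σ = 0.2) and
per-trial amplitude jitter (σ = 0.15) provide realistic between- and
within-subject variability. Trials are laid out back to back (cue 1500 ms,
stimulus window 3000 ms, feedback 1500 ms) after a 1000 ms lead-in so the
first baseline window is recorded. The non-decision time is split evenly
before and after the decision only conceptually; event placement uses the
full RT, which is all the preprocessing consumes.

What the generator does **not** emulate: pupil foreshortening and gaze
artifacts, luminance responses, slow tonic drifts, overlapping-response
deconvolution error, asymmetric eyes. Passing tests show the preprocessing
recovers additive event amplitudes under these idealized conditions; they
do not certify artifact handling on real eye-tracker output.

## Behaviour preprocessing

Two single-pass outlier rules, statistics computed once on the input of the
pass (no iterative re-filtering): (1) correct trials beyond 3.5 SD of the
participant's mean correct RT (participant grand mean, not per condition —
the rule that contrasts with the condition-wise item rule); (2) items —
unique (n_left, n_right) pairs, which encode side — whose mean RT lies
beyond 3.5 SD of the item-mean distribution of the same incentive × ratio
condition. Degenerate SD = 0 groups remove nothing; participants with fewer
than two correct trials skip rule 1 with a warning. The 250–1500 ms RT
window (boundaries inclusive, since "under/above" excludes only the strict
exterior) applies on the diffusion-model branch only. Summaries use all
kept trials for Pc and correct trials for MRT/VRT (unbiased variance),
seconds internally, milliseconds at file boundaries.

## EZ estimation

Scale convention s = 0.1, recorded in every output row so results convert
to other conventions (estimates scale linearly in s; t_ER is invariant —
a tested property). Edge cases of Pc (0, ½, 1) receive the half-a-trial
correction (1/(2n)) and are flagged. The forward–inverse identity holds to
better than 1e−8 relative error over the tested grid.

The suitability diagnostic simulates 200 cells from the fitted pure
diffusion and flags the cell when the observed correct-RT skewness falls
outside the central 95% band of the simulated skewness — the symptom of
unmodelled drift variability, which also biases the drift estimate
downward. A power caveat, verified empirically: at 96-trial cells the
skewness sampling band is wide (roughly 0.9–3.0) and even strong drift
variability (SD equal to the mean drift) usually stays inside it; the
diagnostic becomes sensitive only with a few thousand trials per cell. The
false-flag rate at the nominal band is ~5–10% regardless of cell size.

A second ceiling artifact worth knowing: cells whose true accuracy is near
1 (here reward at ratio 4:3, Pc ≈ 0.99, so ~40% of 96-trial cells come out
at Pc = 1) rely on the edge correction, which caps the drift estimate and
distorts cell means nonadditively. At study scale this can mimic a small
Incentive × Ratio interaction in the estimated drift even when the
generator is purely additive. The α-calibration of the interaction test is
therefore asserted on a cell-level Gaussian generator, where the null is
exactly true.

## Inference

Every dependent variable enters as one row per participant × incentive ×
ratio. The model is a linear mixed-effects model with a participant random
intercept (maximum likelihood); F-tests for the within-subject terms use
containment denominator df — N − n_participants − 7, i.e. (1, 217) and
(3, 217) in the full design. On a balanced complete design these F
statistics equal those of the projection ANOVA that treats participants as
fixed blocks, which is how they are computed (this makes them exactly
F-distributed under the null; the type-I error of the Incentive test is
0.05 within Monte-Carlo tolerance over 2000 simulated null datasets). The
ML variance components from statsmodels' MixedLM are reported alongside.
η_p² = F·df1/(F·df1 + df2).

The linear trend contrast uses weights (−3, −1, 1, 3) over the ordered
ratio levels against the residual of a one-way `dv ~ ratio` analysis
(df2 = N − 4), matching the aov convention of the original analysis
workflow rather than the mixed model. The permutation fallback shuffles the
eight condition labels within each participant (5000 permutations by
default, seeded) and reports p = (1 + #{F* ≥ F}) / (1 + n_perm), alongside
the Shapiro–Wilk residual-normality check that motivates its use. Post-hocs
are Holm-corrected paired t-tests, one-tailed only where a direction is
declared. Reward modulation of peak dilation is
(peak_reward − peak_control)/((peak_reward + peak_control)/2), correlated
with the achieved bonus level (1–5) by one-tailed Spearman rank correlation
with average-rank ties, Holm-corrected over the three phases.

The power routine uses the repeated-measures noncentral-F convention
λ = f²·n·m/(1 + (m−1)ρ), df1 = m − 1, df2 = (n − 1)(m − 1), and searches
the smallest integer n reaching the target power.

## Problem sizes in the test suite

Simulation-based tests run at sizes chosen to give decisive answers in
minutes on one CPU: moment convergence at 50,000 trials; EZ recovery at
10,000-trial cells (±0.01) and one hundred 96-trial cells (the study's cell
size); type-I calibration over 2000 null datasets of 32 participants;
behavioural power over 20 full 32-participant × 768-trial replicates; pupil
power over 10 replicates of 32 participants × 6 blocks (144 trials each),
which keeps continuous-trace simulation tractable while leaving every cell
above the 10-epoch reliability minimum. Suitability-diagnostic sensitivity
uses 3000-trial cells for the power reasons described above.

## Known limitations

- The EZ model ignores starting-point bias and parameter variability; the
  suitability diagnostic detects gross violations only at large cell sizes.
- Containment df and the projection equivalence assume a complete balanced
  design; with missing cells the model fit raises rather than silently
  switching df conventions.
- The pupil pipeline assumes uniform sampling and additive kernels; epochs
  overlapping the recording edges are discarded, not padded.
- The trend contrast requires equal cell counts per ratio level.
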