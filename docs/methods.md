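# Methods

This note documents the model, the estimators, the synthetic-study
design and the numerical decisions behind `gripalpha`, in enough detail
to reproduce or audit any stage.

## 1. The neural mass model

A single cortical column is represented by three lumped populations:
pyramidal cells, excitatory interneurons and inhibitory interneurons.
Two primitives define the dynamics.

**Rate conversion.**  Average membrane potential v (mV) maps to average
firing rate (s⁻¹) through the sigmoid `S(v) = 2·e0/(1 + exp(r·(v0 − v)))`
with e0 = 2.5 s⁻¹, v0 = 6 mV, r = 0.56 mV⁻¹.  S is strictly increasing,
bounded in (0, 2·e0), and equals e0 at v = v0.

**Synaptic kinetics.**  A firing-rate input is converted to a
postsynaptic potential by `h(t) = G·ω·t·exp(−ω·t)` (t ≥ 0), i.e. a
critically damped second-order linear system `y'' = G·ω·u − 2ω·y' − ω²·y`.
The excitatory kinetic uses Ge = 3.25 mV, 1/ωe = 10.8 ms; the inhibitory
kinetic Gi = 22 mV, 1/ωi = 20 ms.  h peaks at t = 1/ω with value G/e and
integrates to G/ω.

The populations are wired in the canonical single-column arrangement:
the pyramidal population output (state y0, through S) excites both
interneuron loops; the pyramidal population receives excitatory feedback
C2·S(C1·y0) plus the external drive p(t), and inhibitory feedback
C4·S(C3·y0).  Connectivities scale with the average synaptic connection
number J = 135: C1 = J, C2 = 0.8·J, C3 = C4 = 0.25·J.  The output signal
is y1 − y2.  The explicit state equations appear in the
`gripalpha.model_core` module docstring; since the three kinetics are
second order the state is 6-dimensional.

**Drive and integration.**  p(t) is Gaussian, mean 220 s⁻¹, SD 22 s⁻¹,
one independent draw per integration step, held constant across the four
RK4 stages (zero-order hold).  This treats the drive as a sampled input
signal rather than white noise in the SDE sense, which keeps classical
RK4 well-defined and makes every trajectory an exact function of the
seed.  Draws are not clipped at zero (a negative draw has probability
~10⁻²³ at mean/SD = 10; clipping would add an undocumented
nonlinearity).  Step size is locked to the sampling interval,
dt = 1/fs = 1 ms; the membrane rate constants (ω ≤ 93 s⁻¹) put ω·dt ≈
0.09, far inside RK4's accuracy and stability range, and the convergence
test measures an empirical order of ~4 at this scale.  Integration
starts from the all-zero state and the first 2 s are discarded
(transients decay in well under 1 s); simulations retain 30 s unless
stated otherwise.

At these settings the output oscillates at ~10 Hz with alpha-band
(8–12 Hz) average power ≈ 5.7 mV², and the spectral peak stays inside
the alpha band for every seed tested.

## 2. Spectral estimation

PSDs are estimated with the averaged, windowed, overlapped-segment
periodogram (Welch's method): 1-s Hann segments (1 Hz resolution at
fs = 1000 Hz), 50% overlap, per-segment mean removal, window-energy
normalization, one-sided density scaled so that its integral over
[0, fs/2] approximates the signal variance (Parseval — the testable
contract of the normalization).  Band power is the trapezoidal integral
of the density over [lo, hi] Hz with linear interpolation at non-grid
endpoints, which makes band powers exactly additive over partitions.
"Alpha average power" throughout is the raw band integral over 8–12 Hz,
not divided by bandwidth; all comparisons in the package are relative,
so the convention only fixes units.  Peak frequency is the argmax bin in
a search band (1–45 Hz unless stated), ties broken toward the lower
frequency.

## 3. Preprocessing

The cleaning chain for single-channel scalp EEG at 1000 Hz:

- **High-pass**, zero-phase 4th-order Butterworth, cutoff 0.5 Hz
  (matching a 0.5–200 Hz acquisition band), removing DC and baseline
  drift.
- **Mains cancellation** by a dual-quadrature LMS adaptive canceller
  referenced to 50 Hz sine/cosine, adaptation rate 0.005 (notch
  bandwidth ≈ μ·fs/π ≈ 1.6 Hz).  Measured: ≥ 30 dB suppression of a
  stationary 50 Hz tone after 2 s of adaptation, < 2% alpha-band power
  change on out-of-band signals.
- **Segmentation** into 5-s non-overlapping windows (the remainder at
  the end is discarded), then **artifact rejection** of any segment
  whose peak absolute amplitude (after drift removal) exceeds 100 µV —
  the conventional scalp-EEG bound, exposed as a parameter.  Rejected
  segments are retained in the segment set for audit.
- **Alpha extraction** by a zero-phase 4th-order Butterworth band-pass
  with −3 dB points at 8 and 12 Hz.

Analysis windows: hold-phase recordings delivered by the synthetic
generator are analyzed in full (the generator emits only the sustained
hold); a configurable `(start_s, end_s)` crop is available for
recordings that include onset/offset transients.

Per (subject, grip level), alpha power is the mean over all kept
segments of all trials of the 8–12 Hz band power of the alpha-filtered
segment.

## 4. Statistics

Group differences across the three grip levels use a classical one-way
ANOVA (between/within sum-of-squares decomposition, F = MSB/MSW,
df = (groups − 1, N − groups)), preceded by a Shapiro–Wilk normality
check per group, with Tukey HSD for pairwise contrasts; the significance
threshold is 0.05.  Subjects are treated as independent observations
within each level (plain one-way layout, not repeated measures).  The
implementation is the direct decomposition (a few lines) and is
cross-checked in the tests against an independent library routine.

## 5. Parameter sweeps and the power-matching fit

**Sweeps.**  One parameter of {J, Ge, Gi} is varied on a grid, the
others held at typical values; per grid value the model is simulated
once per seed and the seed-mean alpha power and PSD peak frequency
recorded.  Simulations that diverge are recorded as missing (NaN), never
silently dropped — hyper-excitable regimes are outside the scope of the
alpha analysis.

Empirically the alpha regime is local: increasing J beyond ≈ 141 or Gi
beyond ≈ 24 (with the others at baseline) slows the oscillation out of
the 8–12 Hz band, while Ge keeps a stable 10 Hz peak over a much wider
span.  Within the alpha-preserving spans (J up to ≈ +5, Ge up to ≈ +0.3,
Gi up to ≈ +1.6) alpha power grows monotonically with each parameter and
the spectral peak does not move — the headline mechanism.  The test
suite's "coarse" sweeps use 20 steps of 0.25 (J), 0.015 (Ge), 0.08 (Gi):
2.5–80× the native increments, inside these spans.

**Fit.**  A single measured alpha power cannot identify three free
parameters, so "synchronous adjustment" is formalized as a
one-dimensional ray through parameter space,

    (J, Ge, Gi)(k) = (135, 3.25, 22) + k · (0.1, 0.001, 0.01),  k ∈ ℤ,

the direction given by the parameters' native step sizes.  The fit
evaluates the seed-mean alpha power P(k) on an integer grid and returns
the k minimizing |P(k) − target| (ties toward smaller |k|, then smaller
k).  Common random numbers — the same seed list at every k — make P(k)
deterministic and the grid argmin exactly optimal; the evaluator caches
P(k), so a whole study fit costs one grid evaluation.

The default grid is k ∈ [−60, 45].  This is the window over which the
measured P(k) is strictly increasing: the profile peaks at k ≈ 48
(P ≈ 10.5 mV²) and then declines as the oscillation leaves the alpha
band, so a wider window would let one power target alias two indices on
opposite branches.  Targets outside the attainable range are flagged
`boundary`.  With 10 seeds and 30-s simulations the seed noise of P(k)
is tiny (SD ≈ 0.01 mV² against a local slope ≈ 0.1 mV² per index), so
model-generated targets are recovered to within ±1–2 indices; the
calibration helper `calibrate_fit_tolerance` computes this tolerance
from disjoint-seed batches and the measured local slope.

## 6. The synthetic study

The generator emulates the study design — 11 subjects × 3 grip levels
(20/40/60% MVC) × 10 trials of a 15-s sustained hold, one channel at
1000 Hz — with the neural mass model itself as the alpha source, so
every downstream inference has exact ground truth.

- **Grip-level encoding**: level → ray index k = {20%: 0, 40%: 15,
  60%: 30}, plus a per-subject integer jitter uniform on [−4, 4] shared
  across that subject's levels.  The mapping sits inside the strictly
  monotone part of P(k) with margin for jitter and fit bias; clean alpha
  power rises ≈ 27% and ≈ 21% between consecutive levels — comfortably
  detectable with 11 subjects yet far from saturating the regime.  The
  mapping is a testbed construction, not a biological claim about how
  grip force maps to synaptic parameters.
- **Calibration**: model output (mV) is scaled by `scale_uV` = 1.0 to
  scalp microvolts, putting clean-trial alpha power at ≈ 5.8 µV², a
  plausible scalp value.  The constant is pure bookkeeping (measured
  power units are unlabeled in this literature) and is divided back out
  when fitting.
- **Nuisances** (amplitudes all configurable): 1/f background shaped
  over 1–100 Hz, SD 2 µV (its 8–12 Hz share is ≈ 0.35 µV², biasing
  measured alpha power < 10% upward); baseline drift, a 0.1 Hz sinusoid
  of 50 µV; mains, a 10 µV 50 Hz sinusoid; artifacts, a 500 µV / 200 ms
  raised-cosine transient per 5-s segment with probability 0.05,
  positions recorded in the recording's annotations.
- **Determinism**: everything derives from a single master seed; trials
  are bit-reproducible.

What the generator does *not* emulate: ocular/myogenic mixtures (hence
no ICA/CCA stage in the pipeline), electrode pops, within-hold
non-stationarity of the alpha source, inter-subject spectral shape
differences, or volume conduction.  Passing tests therefore certify the
pipeline's correctness and sensitivity under this model of the data, not
robustness to everything real EEG can do.

**End-to-end recovery tolerance.**  Fitted indices recover the
generating indices with a small positive systematic offset whose main
cause is the in-band share of the 1/f background; the recovery test
predicts that bias analytically (in-band pink power divided by the local
power slope, ≈ +3 indices at the default settings) and allows a further
±3 indices for filter losses and measurement noise.  Within-cohort
*ordering* of fitted parameters across grip levels is insensitive to
this common bias and is tested separately across repeated cohorts.

## 7. Problem sizes in the test suite

Simulation-backed tests use 30-s simulations with 5–10 seeds per
condition; study-level properties (ANOVA detection, fitted-parameter
ordering) are checked across 10 independently generated full-design
cohorts, asserting the property in ≥ 90% of them.  Short 8-s
configurations are used where only algebraic contracts (determinism,
argmin optimality, degenerate cases) are exercised.

## 8. Known limitations

- The ODE wiring is the canonical single-column realization; the
  block-diagram lineage it implements does not pin down, e.g., the noise
  entry point, and a different wiring would change absolute power
  levels.
- Absolute power units of the model output are not comparable to any
  published figure; only relative changes are meaningful, which is why
  the fit matches a scalar power and reports a grid index.
- The one-dimensional ray makes the three fitted parameters perfectly
  collinear by construction; distinguishing the individual contributions
  of J, Ge and Gi from one scalar target is not identifiable and is not
  attempted.
- The plain one-way ANOVA ignores the repeated-measures structure
  (subjects appear at every level); with the generator's effect sizes
  this is conservative in the tested direction.
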