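# Methods

This note documents the models, algorithms and numerical choices behind
`nremdyn`, and what the synthetic-data tests do and do not establish.

## The rate-adaptation model

The core object is a Wilson-Cowan-type mean-field model of a recurrently
connected neuronal population with slow spike-frequency adaptation:

    tau_r dr/dt = -r + R_inf(w r - b a + I + xi(t))
    tau_a da/dt = -a + A_inf(r)

`r` is the population rate, `a` the adaptation variable, `w >= 0` the
recurrent excitation, `b >= 0` the adaptation gain, `I` the tonic drive
and `xi(t)` an Ornstein-Uhlenbeck input noise.  Both transfer functions
are bounded, monotone logistic sigmoids.  All times are in dimensionless
model units; the mapping to seconds is deferred to the duration-matching
step (one free time-scale factor).

### Default parameters and their calibration

The sigmoid shapes are not uniquely determined by the model's qualitative
behaviour, so the defaults were *calibrated once* against the published
operating points and then frozen:

| parameter | default | meaning |
|---|---|---|
| `R_inf` | logistic(gain 1, half 4.9, max 1) | input -> rate |
| `A_inf` | logistic(gain 8, half 0.4, max 1) | rate -> adaptation |
| `tau_r` | 1 | rate time constant (model unit) |
| `tau_a` | 20 | adaptation time constant |
| OU `theta` | 0.05 | inverse noise correlation time |
| OU `sigma` | 0.25 | stationary noise s.d. |
| OU/solver `dt` | 0.1 | noise grid and solver step |

The calibration constraints were: (w=6.3, b=1, I=2.35) is bistable,
(w=6, b=1, I=2.4) and (w=6, b=1, I=1.9) are Excitable_DOWN, and
(w=6.28, b=1, I=2.64) is Excitable_UP, with dwell-time statistics under
the default noise in the empirically observed ranges (CV of the
neocortical-like transient DOWN state near 0.4, CV of the
hippocampal-like transient UP state near 0.3).  With a logistic of unit
gain the critical recurrence for a folded rate nullcline is `w = 4/sat`,
so `w ~ 6` sits comfortably in the folded region.  `tau_a = 20` makes the
transient-state duration (a few times `tau_a`) map onto ~0.2 s at a
~5 ms/unit time scale, consistent with the in-vivo slow-wave DOWN state.

### Regime classification

Fixed points are roots of `g(r) = r - R_inf(w r - b A_inf(r) + I)`,
located by a sign-change scan on a 2000-point grid over `[0, sat]`
refined by Brent's method to 1e-10, with stability from the 2x2 Jacobian.
The r-nullcline is folded iff `gain * w * sat > 4`; the two fold rates
split it into DOWN / middle / UP branches.  Labels:

- **oscillatory** - no stable fixed point (a bounded planar flow then has
  a stable limit cycle; a noise-free probe of length 50 tau_a confirms
  sustained alternation, declared when >= 5 consecutive inter-peak
  intervals agree within 5%);
- **bistable** - two stable fixed points (one per outer branch) and a saddle;
- **excitable_up / excitable_down** - a single stable fixed point on the
  UP / DOWN branch of a folded nullcline;
- **monostable_no_alternations** - otherwise (unfolded nullcline, or the
  stable point on the middle branch).

I/O curves trace the fixed-point set against drive; saddle-node
bifurcations are reported where the fixed-point count changes between
grid drives and Hopf points where a tracked branch flips stability (both
to grid resolution -- no continuation is attempted).  The curve's shape
label reflects the regime at its centre (bistable-, oscillatory-centered,
or monotonic).

## The adapting inhibition-stabilized network (aISN)

The E-I extension replaces the single transfer function with threshold
power laws `R(x) = k [x - x0]_+^p` (the fluctuation-driven regime;
defaults k=0.1, x0=1, p=2) and adds fast inhibition:

    tau_e dr_e/dt = -r_e + R_e(w_ee r_e - w_ei r_i - b a + I_e + xi_e)
    tau_i dr_i/dt = -r_i + R_i(w_ie r_e - w_ii r_i + I_i + xi_i)
    tau_a da/dt   = -a + A_inf(r_e)

Defaults: `w_ee = w_ie = 4` (the excitatory weight onto both
populations), `w_ei = 3`, weak inhibitory self-coupling `w_ii = 1`,
`tau_e = tau_i = 5 ms`, `tau_a = 200 ms`, `A_inf = logistic(8, 0.4, 1)`,
`b = 1`, `I_e = 2.4`.  A strictly by-presynaptic-population reading
(`w_ei = w_ii = 3`) cancels the net recurrence exactly in the high-gain
limit (`w_ee - w_ei w_ie / w_ii = 0`) and admits no self-maintained UP
state, so the weak-`w_ii` form is used.  At the default operating point
the frozen-adaptation system is bistable for effective drive in
[1.50, 1.62]; the full system has a single stable UP fixed point that is
an attracting spiral (damped E-I oscillation at the DOWN->UP transition),
and its frozen-a phase plane is bistable, so a separatrix bounds the UP
basin and brief excitatory input can evoke a transient DOWN state.

Because `r_i*` is the unique root of a monotone scalar equation, the
frozen-a system reduces to one dimension in `r_e`; fixed points use the
same scan-and-refine strategy (vectorized bisection for `r_i*`, 80
iterations).  The separatrix grows by reverse-time integration
(`solve_ivp`, rtol 1e-8) from +-1e-6 along the saddle's stable
eigenvector until it leaves the phase-plane bounding box; point
classification uses the cross-product sign against the nearest segment,
oriented by the UP fixed point.  The full 3-variable system is classified
by intersecting the effective I/O curve with the adaptation curve,
mirroring the 2-variable taxonomy.  At strong drive the E-I subsystem can
Hopf-destabilize; the resulting fast E-I oscillation is labeled
"oscillatory" even though it is not an UP/DOWN alternation -- a known
limitation of mapping the 2-variable taxonomy onto the aISN.

## Stochastic simulation

Input noise follows the discrete update
`xi[k+1] = xi[k](1 - theta dt) + sigma sqrt(2 theta dt) N_k` (forward
Euler) on its own grid, precomputed per simulation and held
piecewise-constant over solver steps, which keeps realizations
bit-reproducible for a given seed and makes the half-step accuracy check
(`dt` vs `dt/2` on the same realization) meaningful.  The state equations
are integrated with a fixed-step Heun scheme at the noise step
(default 0.1).  Statistics use 60,000-unit runs; parameter maps use
10,000-30,000-unit runs per cell with correspondingly wider tolerances.
Evoked-event protocols settle the system at its stable fixed point, apply
a square drive pulse, and flag an event iff the rate crosses to the far
side of the middle branch (2-variable model) or of the frozen-a saddle
(aISN) within 5 tau_a of pulse onset.

## UP/DOWN detection on simulated traces

A trace is segmented only if the distribution of r(t) is bimodal by
Hartigan's dip test.  The dip is computed from its definition -- the
smallest sup-norm distance from the empirical CDF to any unimodal CDF --
via convex/concave band feasibility around every candidate mode split
(including atom-at-observation modes), with a closed-form fast path for
tie-free samples; the implementation is validated in the test suite
against an independent linear-programming oracle and exact small-sample
values.  Significance uses a uniform null (the asymptotically
least-favourable unimodal null for the dip; 500 bootstrap draws at a
reference size of 10^4, scaled by sqrt(n), alpha = 0.05).  The sqrt(n)
scaling lets full-length traces be gated without subsampling, which
matters for hippocampal-like regimes where the UP mode holds only ~1% of
samples.

Sticky thresholds come from the rate histogram (Freedman-Diaconis bins
capped at 1000, 3-bin moving-average smoothing): among peak pairs
separated by a trough that dips below half the smaller peak, the most
separated pair defines the low/high modes; the trough is placed at the
centre of the minimum of a coarsely re-smoothed density between them, so
noise notches beside a mode cannot capture it.  The DOWN->UP threshold is
the midpoint of the high peak and the trough, the UP->DOWN threshold the
midpoint of the low peak and the trough, and the hysteresis scan switches
state only at these outer thresholds.  Partial first/last states are
discarded; no minimum duration is imposed on simulated states (the 40 ms
floor belongs to LFP slow-wave detection).  Detection depends only on the
rate distribution, so it is invariant to affine rescaling of the trace.

## Duration matching

Similarity between simulated and observed dwell-time samples is
`s = (1 - KS_UP)(1 - KS_DOWN)` with the exact two-sample KS statistic
(supremum over both one-sided limits at all pooled step points).  The
single free parameter, the time-scale factor tau (ms per model unit), is
scanned over 1-25 ms in 0.1 ms steps; ties break toward the smallest tau.
Hippocampal data map SWR -> UP and inter-SWR -> DOWN.  Similarity maps
evaluate every grid cell against every recording; cells without
alternations contribute s = 0 so maps stay comparable, and the constraint
region marks cells whose CV_UP, CV_DOWN and mean-duration ratio all fall
within 2 SD of the experimental values.

A note on identifiability: the free time scale makes the map nearly
invariant along a ridge in the (I, w) plane (higher drive with weaker
recurrence trades off against a rescaled tau).  Per-recording best-fit
cells scatter along that ridge rather than concentrating at the
generating cell, and the effect persists when event counts are equalized
across cells and raised to in-vivo scale (hundreds to thousands of
events), so joint point recovery of (I, w) through this statistic is not
generally possible -- the similarity optimum is a band, and the 2-SD
constraint region should likewise be read as a regime-level, not
point-level, localization.  The parameter-recovery acceptance test
documents this behaviour rather than hiding it.

## LFP event detection

All filters are 4th-order zero-phase Butterworth band-passes, so event
times are unbiased; all thresholds act on z-scored or robustly normalized
signals, making detection invariant to a global gain.

**NREM scoring.** Spectrogram in 10 s windows at 1 s steps, log power
interpolated onto 100 log-spaced 1-100 Hz frequencies and z-scored per
frequency, projected onto a spectral weight vector (default +1 below
6 Hz, -1 above 20 Hz, normalized -- a fixed stand-in for the
dataset-derived principal-component weights used with real recordings).
The metric must be bimodal (dip test); the threshold is the trough
between its two modes, and single-window flickers are removed by a 3-bin
median filter.  Boundary resolution is limited by the 10 s window.

**Slow waves.** Detection signals are the 0.5-8 Hz filtered LFP
(z-scored over NREM) and the negated 100-400 Hz power (80 ms smoothing,
robust local z-score `(x - median)/(1.4826 MAD)` over a sliding 20 s
window computed at a 2 s hop and interpolated).  Thresholds are
calibrated against spiking: candidate peaks above 0.25 sd are binned by
magnitude (0.1 sd bins); each bin's spike PETH (+-1 s, 20 ms bins) is
normalized by the grand mean; the peak threshold is the smallest bin
whose PETH at lag zero drops below the sensitivity (default 0.5), and the
window threshold averages the signal value at the PETH's crossings of the
sensitivity level over qualifying bins (clipped to the peak threshold in
degenerate cases).  Events are suprathreshold epochs of the window
threshold containing a peak-threshold sample, >= 40 ms in each signal;
DOWN states are overlaps of delta and gamma events (again >= 40 ms)
without within-event spiking above the sensitivity level; gaps inside
NREM become UP states.

**SWRs.** Sharp waves are 2.5 sd negative deflections of the 2-50 Hz
deep-channel signal kept if 20-500 ms; ripples are 2.5 sd excursions of
10 ms-smoothed 80-250 Hz power on the superficial channel kept if
>= 25 ms; overlapping pairs merge into SWR intervals.

**Delta stratification.** 1-4 Hz power averaged over the 8 s window
centered on each state, normalized to the median over NREM, split into
quantile groups (default 6; tests use 3 for stable group statistics).

## Synthetic data

The generator emulates only the statistical structure the detectors rely
on: alternating UP/DOWN tilings (lognormal stable states, mean 1.7 s,
CV 1.1; gamma transient states, mean 0.21 s, CV 0.38 -- the in-vivo
neocortical values), spikes as exact-thinning inhomogeneous Poisson
processes whose rate collapses during DOWN states, one-lobe Hann delta
deflections with lognormal amplitude spread during DOWN states, gated
band-filtered gamma noise during UP states, and SWRs as deep negative
deflections plus superficial ripple oscillations under a near-flat Tukey
envelope (so the nominal event duration is the detectable suprathreshold
span, as it is for real detected events; SWR durations gamma, mean 60 ms,
CV 0.33, inter-event exponential at 0.5 Hz).  White-noise floors stand in
for background LFP.  Passing detector tests therefore establishes
correctness of the algorithms against controllable ground truth -- not
performance on real recordings, which have 1/f backgrounds, artifacts,
non-stationary states, and imperfect spike sorting.

## Numerical and degenerate-case conventions

- Intervals are half-open `[start, stop)` in seconds (or model units,
  declared); detected UP/DOWN sequences strictly alternate.
- Duration-limit filters are inclusive with 1e-12 tolerance.
- Constant traces are reported unimodal with a warning; flat detection
  signals raise.
- The dip feasibility bisection uses tolerance 1e-9 (the statistic is
  accurate to that level).
- Ties in the tau scan and in grid argmaxes resolve to the smallest
  index for determinism; identical seeds reproduce every pipeline output
  bit-for-bit.

## Known limitations

- Bifurcation points are located to grid resolution; no continuation.
- The aISN taxonomy inherits the 2-variable labels; fast E-I limit
  cycles at strong drive are reported as "oscillatory".
- The uniform dip null is conservative for autocorrelated rate traces
  (samples are not i.i.d.); gating power comes from trace length.
- The NREM spectral weight vector is a fixed default, not learned from
  data.
- Synthetic LFP is statistically, not biophysically, realistic.
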