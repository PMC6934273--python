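# Methods

## The adaptive coincidence counting model

The model neuron abstracts a globular bushy cell (GBC) of the
anteroventral cochlear nucleus as a coincidence counter with an adaptive
spike threshold.  Each of `m_e` auditory-nerve (AN) input fibers delivers
spikes that are converted into rectangular postsynaptic counts of duration
`w_e` (the coincidence window) and amplitude `a_e`, expressed relative to
the static threshold `theta_S = 1`.  The summed input

    v(t) = a_e * #{input spikes across fibers in (t - w_e, t]}

is compared against `theta(t) = theta_S + theta_D(t)`.  The dynamic part
relaxes toward `s_a * v(t)` with time constant `t_a`:

    t_a * d(theta_D)/dt = -theta_D(t) + s_a * v(t).

When `v(t) >= theta(t)` and the model is not refractory, an output spike is
emitted and no further spikes can occur for `t_r` ms.  The dynamic
threshold depends only on the input history: it is not reset by output
spikes and keeps integrating during refractoriness.  There are no membrane
potentials, conductances, synaptic depression, inhibition, or
AN-to-GBC conduction delays; with rectangular inputs, output spikes always
coincide with the grid step of some active input.

Because `v(t)` is piecewise constant on the `dt = 0.01` ms grid, the
threshold ODE is advanced by its exact per-step solution

    theta_D(t+dt) = exp(-dt/t_a) * theta_D(t) + (1 - exp(-dt/t_a)) * s_a * v(t)

rather than by numerical approximation.  Internally the recursion is
evaluated as a first-order linear filter (`scipy.signal.lfilter`), which
is bit-identical to the stepwise update and makes long silence simulations
cheap.  Because the threshold trajectory is independent of the output, the
simulation reduces to computing an eligibility mask (`v >= theta`) and a
greedy left-to-right refractory selection over eligible steps, which is
exactly the sequential event rule.

Numerical conventions (chosen where the rule itself leaves freedom, all
tested): per-step order is (1) update `v`, (2) test threshold and emit,
(3) advance `theta_D` using the current `v`, so the threshold tested at a
step integrates input strictly before that step; an input spike at `s`
contributes on the half-open interval `[s, s + w_e)` (no double counting
at the trailing edge); `w_e` and `t_r` are quantized to the grid by
round-half-up, `w_e` at least one step; "reaches or exceeds" is an exact
`>=` on `v = a_e *` (integer count), so no float tolerance is needed;
`theta_D(0) = 0` and the model starts non-refractory.

### Parameters

| symbol | meaning | unit | default (exemplar) |
|--------|---------|------|--------------------|
| `m_e`  | number of excitatory AN inputs | – | 20 |
| `w_e`  | coincidence window | ms | 0.32 |
| `a_e`  | input amplitude (relative to `theta_S = 1`) | – | 0.40 |
| `t_r`  | absolute refractory period | ms | 1.20 |
| `t_a`  | adaptation time constant | ms | 0.25 |
| `s_a`  | adaptation strength | – | 0.80 |

The full screening grid varies these over 7 × 10 × 9 × 9 × 10 × 10 =
567,000 combinations; the exemplar above is the median of the accepted
population at 20 inputs and is used for all single-instance examples.

## Surrogate auditory-nerve input

The AN front end is a descriptor-level phenomenological generator of
high-spontaneous-rate fiber spike trains; it emulates the input statistics
the GBC stage relies on without modeling cochlear filtering, hair-cell
transduction, power-law adaptation, or fractional-Gaussian-noise
spontaneous activity.  Passing tests therefore demonstrate properties of
the GBC stage under realistic input statistics, not fidelity to any
specific peripheral model; externally computed AN spike trains can be
substituted through the plain-text spike-file adapter.

Components, with defaults:

* **Rate-level function.** Driven rate = `(max_driven_rate - spont_rate)`
  × logistic in level, anchored at 5% / 95% at 0 / 40 dB SPL;
  `spont_rate` 70 spikes/s, `max_driven_rate` 250 spikes/s.  The linear
  amplitude ramps (3.9 ms for tone bursts) act in the *level* domain
  (20·log10 of instantaneous amplitude), so a suprathreshold tone saturates
  the driven rate within a small fraction of the ramp.  This produces the
  steep, across-fiber-coincident onset that gives the GBC its pronounced
  onset peak; a multiplicative ramp on the rate would smear the onset over
  several milliseconds and is not what the periphery does.
* **Onset adaptation.** The driven term is multiplied by
  `1 + (onset_peak_ratio - 1) * exp(-(t - t_on)/onset_tau)` with ratio 3
  and `onset_tau` 3 ms, where `t_on` is the instant the ramp reaches the
  saturation level.  The AN PSTH then peaks at about three times the
  sustained driven rate and is back near sustained by 10 ms, matching the
  onset-adapted shape of real high-spontaneous-rate fibers.
* **Phase-locking.** Spikes are drawn from an inhomogeneous Poisson
  process and then snapped to the preferred stimulus phase plus
  wrapped-Gaussian jitter.  The jitter SD maps to vector strength in
  closed form, `VS = exp(-(2*pi*f*sigma)^2/2)` (the Fourier coefficient of
  the wrapped-normal density), so the target VS curve
  `vs_max / (1 + (f/vs_corner_freq)^vs_slope)` (0.85, 1300 Hz, 2.5) is hit
  without calibration loops.  The *fraction* of snapped spikes follows the
  same level sigmoid as the rate, shifted 10 dB toward lower levels:
  phase-locking emerges slightly below the rate threshold and saturates
  roughly 20 dB above it.  At the 70 dB selection battery every spike is
  snapped; at the low levels of a frequency-response-area scan, locking
  vanishes along with the drive, which is what keeps the tuning curve
  V-shaped.
* **Refractoriness.** Absolute dead time 450 µs plus relative
  refractoriness with exponential recovery (512.5 µs), applied by
  sequential thinning.  The driving rate is inflated by inverting the
  renewal mean-ISI relation `ISI ≈ t_abs + 1/lambda + t_rel(1 - lambda
  t_rel)` with a damped fixed point (capped at 3000 spikes/s, relevant
  only at onset peaks), so the thinned output matches the requested
  envelope; measured spontaneous rate is 70.0 ± 0.3 spikes/s over 15 × 50 s.
* **Tuning filter.** V-shaped attenuation in log-frequency: 60 dB/octave
  above CF, 30 dB/octave below, with the low side capped at
  `tail_threshold_shift` = 40 dB.  The cap reproduces the "tail" of real
  tuning curves: intense low-frequency tones (e.g. 500 Hz at 95 dB SPL)
  drive and phase-lock high-CF fibers.
* **Seeding.** A master seed spawns one child per (fiber, trial) via
  `SeedSequence(entropy=seed, spawn_key=(fiber, trial))`; fibers and
  trials are exactly independent and individually reproducible, and
  adding fibers or trials never perturbs existing ones.
* **SAM tones.** The driven term is modulated by
  `1 + mod_depth*sin(2*pi*f_mod*t)` (rectified); envelope locking arises
  from rate modulation alone, with no carrier snapping at the high carrier
  frequencies used.

## Output measures

All sustained measures use the 10–25 ms window after onset for 25-ms tone
bursts (for 600-ms SAM tones the first 10 ms are discarded).  Interspike
intervals (ISIs) never straddle trial boundaries.  Undefined measures
(no spikes, fewer than two ISIs, mean ISI at or below the dead-time
correction) propagate as explicit `None` flags, never silent zeros.

* **SR / DR** — spontaneous rate over one continuous stretch of silence
  (100 s by default, 20 s in the desk preset); driven rate from the
  sustained window.
* **VS** — vector strength `(1/N)|sum_k exp(2*pi*i*f*t_k)|` over pooled
  sustained-window spikes (pooling across trials before the sum, the
  standard convention for this formula).
* **EI** — entrainment index: fraction of ISIs strictly inside
  `(0.5/f, 1.5/f)`; 1 means one spike per stimulus cycle.
* **CV′** — `sigma_ISI / (mu_ISI - mu_0)` with dead-time correction
  `mu_0 = 0.5` ms; `sigma` is the population (divide-by-N) standard
  deviation — at the spike counts involved the choice is immaterial, but
  it makes small analytic fixtures exact.
* **PSTH** — 0.1-ms bins, five-point triangular smoothing with kernel
  (1,2,3,2,1)/9 (unit sum, so counts are preserved away from edges),
  converted to spikes/s.

## PSTH shape classification

The primary-like-with-notch (PL_N) shape rules operate on the smoothed
PSTH.  The first peak is the global maximum within 0–5 ms of onset.
Notches are contiguous spans where the smoothed rate falls below 90% of
the sustained rate, searched between the first peak and 15 ms — onset
phenomena, deliberately excluding slow sustained fluctuations; a notch
that would extend past 15 ms already fails the width criterion.  When the
rate grazes the 90% line several times, the first sub-threshold span is
the first notch (documented tie-break).  The second peak is the rate
maximum between the first and second spans (or to 15 ms when no second
span exists) — a plateau therefore counts as its own "first local
maximum".  The four criteria: (P1) first notch below 90% of the sustained
rate; (P2) first notch width within 0.15–1.5 ms; (P3) second peak below
half the first peak; (P4) second notch absent or shorter than 0.85 ms.

A full instance is PL_N iff SR < 30 spikes/s, DR ≥ 150 spikes/s,
0.65 ≤ CV′ ≤ 0.95, VS > 0.9, EI > 0.9, and P1–P4 all hold; On_L iff the
same with DR in [50, 150).  The half-open DR split and closed CV′ interval
make the categories disjoint and exhaustive at the boundaries.  Instances
passing the rate criteria but failing P3 are labeled choppers; failing P4,
or P2 through an over-long notch, dippers; the visual-inspection step used
with real recordings is replaced by these deterministic rules alone, so
borderline PSTHs are classified strictly by P1–P4.

## Population screening

AN spike trains are generated once per (stimulus, `m_e`) and shared across
all instances with that input count: instance differences are purely
postsynaptic, sharing the presynaptic drive mirrors that design, and it is
also what makes the screen tractable.  Caching cannot change any result
(verified by cold/warm cache tests).  The screen is chunk-wise
restartable from a checkpoint CSV.

The desk-scale preset uses 3 values per dimension — the exemplar value and
its two grid neighbors (729 instances) — with 100 trials per tone and 20 s
of silence.  These sizes keep a full screen around one minute on one core
while leaving classification noise acceptable: at 100 trials the smoothed
PSTH has a per-bin SE of tens of spikes/s, so shape flags near the 90%
line can flip between seeds; the full-grid mode uses the standard 1000
trials and 100 s of silence.

Cubic polynomial fits are undefined on the desk grid: with only three
levels per parameter, `z^3` is collinear with `{1, z, z^2}`, and the fit
correctly refuses the rank-deficient design rather than regularizing
silently.  Cubic fits require the full grid (7–10 levels per dimension).

## Frequency response areas

Rates over a frequency × level grid yield, per frequency, the rate-level
threshold where the driven rate crosses SR + 10 spikes/s, linearly
interpolated between level points.  The crossing must be *sustained* (the
rate stays at or above the criterion at all higher levels); with finite
trial counts, isolated upward fluctuations at low levels would otherwise
produce spurious zero thresholds.  Frequencies where the criterion is
never met are marked unbounded.  Q10 is CF divided by the bandwidth of
the threshold curve 10 dB above its minimum, interpolating crossings
linearly in log2-frequency.  With the defaults (CF 3500 Hz, 80 trials)
the exemplar instance gives a V-shaped curve with a ~40 dB low-frequency
tail plateau and Q10 ≈ 4.7, inside the empirical 2–8 range for these
units.

## Parameter-space analyses

* **Connectivity.** Order-n neighbors differ by at most one grid step in
  at most n dimensions; an interior point has `sum_k C(6,k) 2^k` neighbors
  (12 at order 1).  Components are labeled with `scipy.ndimage.label`
  using `generate_binary_structure(6, n)`, which realizes exactly this
  neighbor relation.
* **Convexity.** Random accepted parent pairs are interpolated at
  fractions 1/4, 1/2, 3/4 (three evenly spaced interior points); `m_e` is
  rounded to the nearest integer (an input count is physical), all other
  parameters stay continuous and off-grid — the evaluator accepts
  arbitrary parameter vectors, so children are not snapped to the grid.
  The default bookkeeping is 3500 pairs × 3 children = 10,500 evaluations.
* **Correlations.** Pearson r on raw parameter values (r is
  scale-invariant, so z-scoring would not change it), flagged when
  |r| > 0.2 with p < 1e-9.
* **Regression.** Inputs are z-scored; outputs are transformed to
  log(SR), log(DR), CV′ (untransformed), log(1−VS), log(1−EI) — natural
  log, immaterial to R².  Rows outside a transform's domain (SR or DR of
  zero, VS or EI of exactly 1) are excluded per measure with the count
  reported.  Bases: 6 linear terms, +21 quadratic (6 squares + 15 cross),
  83 total cubic.  OLS with intercept; rank-deficient designs raise
  instead of being silently regularized.
* **Variance decomposition.** Terms are added one at a time and the
  incremental R² recorded (computed by sequential Gram–Schmidt
  orthogonalization, which equals refitting nested OLS models).  Linear
  mode enumerates all 720 orderings of the six parameters, so the
  per-term mean gains are exactly the Shapley values of R² and sum to the
  total (verified against a direct Shapley oracle).  Quadratic mode
  starts from the full linear fit — no quadratic term is added before its
  linear components — and averages over sampled orderings of the 21
  quadratic terms (40,000 by default, configurable down; the sampling RNG
  stream is seeded and documented).

## Known limitations

* The surrogate front end has no cochlear dynamics: no two-tone
  suppression, no level-dependent tuning shifts, a single onset-adaptation
  time constant, and envelope phase-locking to SAM tones that is weaker
  than real medium/low-spontaneous-rate fibers.  Absolute population
  counts from a screen therefore depend on the front end and are not
  comparable across front ends.
* No inhibition: frequency response areas lack inhibitory sidebands, and
  rate-level functions are monotone.
* Desk-scale screens trade classification stability for speed (see
  above); single-instance conclusions near criterion boundaries should be
  checked across seeds or at 1000 trials.
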