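# Methods

## Scope and phases

`vestibsim` models the *acute* interaction between a unilateral vestibular
implant and the vestibulo-ocular pathway: from stimulation onset, through the
attenuation of onset nystagmus by synaptic adaptation, to the eye-velocity
response evoked by sinusoidal modulation of the stimulation parameters.  The
simulation always proceeds through three phases:

1. **Healthy** — synaptic weights are initialized push–pull (positive for the
   left canal's afferents, negative for the right) and the offset is set so
   the resting state is exactly silent.
2. **BVL** — both sides revert to residual resting discharge.  Because the
   model never simulates head rotation, the healthy resting balance already
   satisfies the zero-error condition and this phase converges immediately;
   it is kept explicit so states can be checkpointed per phase.
3. **Baseline onset** — tonic, unmodulated stimulation entrains the recruited
   afferents and the resulting error drives weight/offset adaptation until
   the output is quiet again.

Modulation experiments then run on the frozen post-adaptation weights,
mirroring acute clinical sessions (adapt ~30 min, then modulate and measure).

Out of scope by design: closed-loop (head-driven) modulation, chronic
adaptation, multi-axis responses and current spread to adjacent canals,
otolith function, biophysical spiking or electrode field models.

## Afferent population

Each side carries `n_per_side` (default 1000) afferents.

* Mean residual resting rates are lognormal with **arithmetic** mean
  26.3 spikes/s and SD 6.6 spikes/s; the printed moments are converted
  analytically to the log-scale location/scale.
* Exactly `round(0.67 · n)` afferents per side are regular
  (CV ~ U(0.01, 0.1)); the rest are irregular (CV ~ U(0.1, 0.3)).  Only the
  CV = 0.1 class boundary is empirically anchored; the range endpoints are a
  modelling choice and configurable.
* Per time bin, each afferent's residual rate is redrawn from
  N(u_i, (cv_i·u_i)²) clipped at zero — the rate description of irregular
  inter-spike intervals at the bin scale.
* Each afferent carries a fixed random **recruitment rank** per side,
  conceptually its electrical distance from the electrode.  Nested
  recruitment (lower-rank sets are prefixes of higher-rank sets) is required
  for the ensemble-rate-change bookkeeping to be well defined.

**Recruitment law.**  The recruited fraction is
`baseline_fraction · (1 + m)^e` with exponent `e = 2` by default, `m` the
signed instantaneous amplitude modulation.  The quadratic (area-type) law is
the one consistent with all printed recruitment numbers: ±25% around a 40%
baseline gives 22.5%–62.5%.  The exponent is exposed
(`recruitment_exponent`) for sensitivity studies.

**Entrainment.**  A recruited afferent fires at
`max(stimulation rate, residual sample)`; all others emit their residual
sample.  At 200 pps this is a near-deterministic lock; the max matters at low
pulse rates, where residual discharge can exceed the stimulus and PAM loses
its purchase (the origin of the PRM-favourable region at low baseline rates).

## Vestibular-nuclei perceptron

`v = output_gain · tanh(input_scale · (Σ w_i r_i − b))` with
`r_i = fr_i / rate_scale`.

* **rate_scale = 26.3 spikes/s** (the typical spontaneous rate).  Feeding the
  perceptron rates in units of the spontaneous rate puts weights, offset and
  the two learning rates on a common dimensionless scale; with raw rates in
  spikes/s the hetero/homosynaptic balance point would shift by the square of
  the unit, making learning-rate ratios unit-dependent.  At the default
  condition the summed squared input is ≈ 2.5×10⁴, which is what places the
  adaptation-regime transition of the learning-ratio scan in the 10⁴ decade.
* **output_gain = 10 a.u.** — the saturation velocity; arbitrary since every
  reported comparison is a ratio.
* **input_scale = 3.5×10⁻⁴** — chosen so that the strongest protocol studied
  (25% amplitude + 100% rate comodulation at 200 pps) drives the output to
  roughly 85% of saturation, i.e. the experiments span the nonlinearity's
  operating range without clipping.  The healthy resting point sits exactly
  at zero drive.
* Healthy weight magnitudes are N(1.0, 0.2), floored at 0.05, signed by side;
  the absolute scale is unconstrained by data, so results are reported as
  ratios (a gain-invariance test enforces this).
* Other central inputs to the nuclei are omitted: over the time scale of one
  adaptation session they are constant and cancel in every differential
  comparison.

## Adaptation rule

Per time bin (online learning):

```
e   = d_v − v                 (retinal slip; d_v = 0, head stationary, dark)
δ   = e · (1.1 − v̂²)          (v̂ = v / output_gain)
w  += α_s · δ · r             (homosynaptic component, activity-scaled)
b  −= α_b · δ                 (heterosynaptic component, activity-blind)
```

The `(1.1 − v̂²)` factor is the Fahlman substitute for the tanh derivative:
its 0.1 floor keeps learning alive when the onset transient saturates the
output.  Evaluating it on the *normalized* output makes the 1.1/0.1 constants
meaningful regardless of `output_gain`.  The offset update uses the
error-reducing sign implied by the offset's negative position in the drive.
A unit test verifies that the step equals the finite-difference gradient of
the squared error with the Fahlman substitution.

* **Epoch** = 200 bins (one 2-Hz cycle's worth, dt = 2.5 ms) of fresh
  residual noise with no modulation; convergence requires the epoch-mean |e|
  to remain at or below `tolerance` (default 0.05 a.u., 0.5% of saturation)
  for a full epoch *after* first crossing it, so the converged epoch does not
  contain the settling transient.  A strictly per-bin criterion is
  unattainable near the noise floor (bin-noise maxima exceed it), hence the
  epoch-mean form.
* Defaults `α_s = 10⁻⁴`, `α_b = ratio · α_s` with ratio 2×10³ converge in
  ≤ ~10 epochs at every scanned condition; a divergence guard aborts if the
  epoch error doubles ten epochs running (reachable only at pathological
  learning rates, where the bounded output otherwise just oscillates).
* The learning-ratio scan covers 10⁰–10⁵.  Stability holds across the whole
  scan because the per-step correction fraction stays well below 1.

Why PAM wins acutely: adaptation depresses each synapse in proportion to its
activity, so the 400 entrained synapses end far below the rest (mean ≈ 0.25
vs ≈ 0.90 at ratio 2×10³, with ~10% inverted).  PRM speaks only through those
depressed synapses; the positive half-cycle of PAM recruits fresh afferents
with near-healthy weights *and* jumps their rates from ~26 to 200 spikes/s.
At very large `α_b/α_s` the offset absorbs the onset error, the weights
survive, PRM output rises and PAM's positive/negative asymmetry shrinks —
though not to exactly 1, because quadratic recruitment itself is asymmetric
(+25% adds 225 afferents, −25% removes 175).

## Peak eye velocity

Traces are simulated for 4 modulation cycles (200 bins/cycle); the first
cycle is discarded, the rest are phase-averaged, and a sinusoid amplitude
plus intercept is least-squares fitted to each half-cycle separately.
PEV/NEV are the clamped amplitudes (PEV ≥ 0 ≥ NEV).  The per-half intercept
mirrors the offset term of the clinical per-cycle fits and keeps residual
resting nystagmus (the small DC left at the adaptation stopping point) from
leaking into the modulation amplitude — without it, cross-baseline PRM
comparisons acquire a spurious few-percent bias.

The equipotent-contour search bisects the rate-modulation depth (≤ 30
iterations, 1%-of-target tolerance); unreachable targets are reported as NaN
rather than extrapolated.

## Eye-trace analysis

The clinical pipeline is: zero-phase (forward–backward) 3rd-order Butterworth
low-pass at 5 Hz on position (DC gain exactly 1; pass-band amplitude of a
2-Hz component is `1/(1+(2/5)⁶) ≈ 0.996` after the squared response), central
differences to velocity, phase-folding into a mean cycle with per-bin SEM,
and alternatively per-cycle sinusoid fits (amplitude, phase, offset)
differentiated analytically.  Edges are handled by reflection padding of
three filter lengths.  The synthetic generator produces sinusoid-plus-white-
noise traces at 250 Hz (configurable; real eye trackers vary) with a vertical
component two-thirds of the horizontal one by default, mimicking
current-spread misalignment.  It emulates stationary amplitude and white
measurement noise only — no saccadic fast phases, blinks, drift or
pink-noise components — so passing tests demonstrate correctness of the
processing chain, not robustness to every artefact of patient recordings.

## Reproducibility and problem sizes

Every stochastic operation draws from a stream derived from a master seed
via `SeedSequence` spawn keys; scan cells and multi-seed averages are
bit-for-bit reproducible and statistically independent.  The default
experiment sizes (1000 afferents per side, 4-cycle runs, 10-seed averages,
11-point ratio scans, 12×12 baseline scans) were chosen so that every
experiment, and the full acceptance recomputation, runs in seconds to a few
minutes on a single CPU; population-size effects were checked to be
resolution-only.

## Known limitations

* The absolute output scale (a.u.) is not fitted to patient data; only
  ratios are meaningful.  The comodulation boost factor depends on the
  saturation calibration (`input_scale`); the equipotent contour does not,
  since equipotency is decided in drive space by monotonicity.
* The PRM invariance to baseline rate is approximate (~10% change from 200
  to 100 pps at ratio 2×10³): the offset share of adaptation and the
  non-recruited variance break the exact inverse scaling between baseline
  rate and depressed-weight magnitude.
* The model is rate-based; refractoriness, partial entrainment and
  stochastic spike-timing effects are outside its vocabulary.
* Chronic adaptation — under which PRM demonstrably works in animals — is
  deliberately not modelled; conclusions apply to acute sessions only.
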