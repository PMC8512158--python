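# Methods

`myobelt` analyses recordings from a belt-worn capacitive stretch sensor
("muscle-relaxation belt") together with surface EMG and vertical ground
reaction force (GRF). The scientific question the chain answers: does the
circumference of a limb segment, read from the belt, track the state of the
muscles underneath — including co-contraction, which produces no visible
motion — and can it be predicted from the muscles' electrical activity?

## Sensor model and calibration

The belt is a silicone dielectric between stretchable flocked-silver
electrodes; its capacitance grows with the elastic part's elongation. The
transfer function is quadratic,

    L(C) = a2 C² + a1 C + a0          [L in mm, C in nF],

fitted by ordinary least squares to a bench sweep (`fit_calibration`, at
least three distinct capacitances). The built-in `BELT_CURVE` carries the
prototype's coefficients (a2 = 0.00223, a1 = −1.72592, a0 = 416.9272) with a
valid range of 465–606 nF. Only the increasing branch of the parabola
(above the vertex, ≈387 nF) is physical, so the inverse `length_to_capacitance`
always takes the larger quadratic root; a length below the parabola minimum
has no solution and raises. Samples outside the valid range warn but do not
fail — walking data may transiently exceed the bench sweep. Fit quality is
reported as 100·R² ("percent agreement"); hysteresis between a stretch and a
release sweep is the maximum absolute capacitance difference after linear
interpolation onto the union of the two sweeps' length grids, restricted to
their overlap.

## Signal conditioning

All filters are Butterworth, designed per application at the series' own
rate:

* **EMG envelope**: 20 Hz second-order zero-lag high-pass → full-wave
  rectification → 10 Hz second-order low-pass. The final low-pass is causal
  by default with a `zero_lag_lowpass` switch; the source text does not
  state its phase behaviour, so both readings are available. Residual
  negative undershoots of the final low-pass are clipped to 0.
* **Circumference**: capacitance → length via the calibration curve, then a
  10 Hz second-order low-pass (same causal-default/zero-lag switch); the
  rate of change is a central finite difference (one-sided at the ends).
* **Zero-lag mode** applies the designed filter forward then backward
  (odd-reflection padding of 3×order samples), squaring the magnitude
  response: gain at the cutoff is 1/√2 causal, 0.5 zero-lag.
* **Causal mode** seeds the filter state with the first sample
  (`scipy.signal.lfilter_zi`), so a large DC offset (the belt idles near
  96 mm) produces no startup transient.

Activity is expressed as a fraction of maximum voluntary contraction (MVC):
per muscle, the maximum envelope value across co-contraction trials in
standing and sitting. Dynamic activity may exceed 1.

## Gait segmentation and cycle statistics

Heel contact is the first frame with vertical GRF above 20 N. Two guards
make the rule robust (both configurable): the signal must have been
continuously below threshold for 50 ms before the crossing, and contacts
closer than 300 ms to the previous one are discarded. Cycles (contact to
next contact) are linearly resampled to a 101-point 0–100 % grid — the
biomechanics convention; "% gait cycle" alone does not fix a grid — and
summarised per grid point by the ensemble mean and sample SD (divisor n−1;
SD = 0 for a single cycle).

Per condition, three cycle statistics are computed: the **average
amplitude** (mean over cycles of the cycle-mean offset from a reference —
the belt's natural length for circumference, zero for activity; the
reference is an explicit parameter because what "natural length" includes is
a setup choice), the **average deviation** (mean over the grid of the
across-cycle SD), and their ratio as a **CV in percent**. A zero amplitude
flags the CV undefined rather than dividing. Because averaging five muscles
admits two CV conventions that genuinely differ, both are reported and
labelled: ratio-of-averages and mean of per-muscle CVs. The within-cycle
peak-to-peak range of the ensemble mean is additionally reported
(`range_units`), since "amplitude in the cycle" sometimes means the swing
rather than the offset.

## Cross-modal model

Circumference is modelled as a quadratic form of the five thigh-muscle
activities (fixed order VL, RF, VM, BFL, BFS):

    L̂(t) = Σᵢ [ wᵢ₁ Aᵢ(t) + wᵢ₂ Aᵢ²(t) ] + b .

The 11 coefficients minimise Σₜ (Lₜ − L̂ₜ)² (numpy `lstsq`; rank-deficient
or under-determined designs — heavy co-contraction makes the activities
collinear — get the minimum-norm solution with a warning rather than a
failure). Agreement between measured and estimated circumference is scored
by RMSE, by the OLS regression of measured on estimated, and by ICC(2,1) —
the Shrout–Fleiss two-way random-effects, absolute-agreement, single-measure
intraclass correlation with paired frames as targets and
(measured, estimated) as two raters. Fitting uses the native rate (1 kHz by
default); the agreement metrics use pairs decimated to 10 Hz
(configurable), matching how such scatter evaluations are sampled and the
fact that both traces are band-limited to 10 Hz anyway.

## Synthetic sessions

No recordings are distributed with the study, so `myobelt.simulate`
generates complete sessions with known ground truth. What it emulates:

* **Activations**: per-muscle sums of Gaussian bursts on the cycle phase.
  Walking uses staggered loading-response quadriceps bursts and
  pre-contact/mid-swing hamstring bursts; running the same phasing at
  roughly double amplitude; squats a mid-cycle burst on all five muscles;
  maximal co-contraction a wide plateau at 1.0 MVC. Stride-to-stride
  variability has two independent components per muscle: each burst's
  amplitude is jittered per cycle (Gaussian, SD 0.30 — surface-EMG burst
  amplitudes vary by tens of percent between strides) and a slow tonic
  fluctuation (low-passed white noise at ~1 Hz, SD 0.10 %MVC) rides under
  everything. This independent variability is also what renders the 11
  model coefficients identifiable; with lock-step templates the activity
  design is collinear and no amount of data separates the muscles.
  Gait styles: `cocontraction` adds a 0.10 tonic offset to all muscles,
  `relaxation` scales swing-phase activity by 0.6.
* **Raw EMG**: unit-RMS band-limited (20–450 Hz) Gaussian noise, amplitude-
  modulated by the activation — the standard surface-EMG surrogate; no
  motor-unit structure is modelled.
* **Vertical GRF**: walking stance is two Gaussian humps (1.1× and 1.0×
  body weight, 650 N default) over 62 % of an 1.1 s cycle; running a single
  2.4× hump over 35 % of a 0.7 s cycle; swing is exactly zero. Heel contact
  is placed 60 ms after the generated cycle start so the first contact is a
  detectable rising edge. Ground-truth contacts are the first sample above
  20 N per cycle.
* **Circumference**: the quadratic model applied to the true activations,
  plus additive Gaussian noise (default SD 1.8 mm) and an optional passive-
  deformation term — a swing-phase (or, for passive-flexion trials,
  whole-cycle) negative half-sine, reproducing the circumference dip seen
  under passive joint motion with silent EMG. The default truth model
  (w1 = [6, 4, 6, 3, 3] mm, w2 = [−2, −1.5, −2, −1.5, −1] mm — mild
  saturation at high effort — b = 96.5562 mm) gives a ~14 mm rise at full
  co-contraction and millimetre-scale swings during walking.
* **Capacitance**: the calibration curve's inverse applied per sample.

One seed drives independent substreams per channel (activation jitter, each
EMG carrier, circumference noise), so adding a channel never perturbs the
others, and the same config + seed is byte-identical.

What the generator does **not** model: motion artifact and electrode-contact
drift, soft-tissue/belt slip, treadmill dynamics, cross-talk between EMG
channels, temperature or pressure sensitivity of the belt. Tests passing on
synthetic data therefore show the processing chain is correct under the
stated signal model, not that the belt behaves this way on any subject.

## Problem sizes and numerical choices

The stochastic checks run on ~60 s sessions at 1 kHz (T ≈ 60 000 frames):
a protocol block of four 8 s maximal seated co-contractions followed by ten
3 s squats, or 27 walking strides plus ten squats, each over 20 seeds —
enough for the law-of-large-numbers margins the checks assert while keeping
a full run in seconds. Noiseless sessions verify exactness (ICC = 1,
RMSE < 1e−8 mm) when the evaluation consumes the generator's own activations
and circumference; any causal filter in the path adds phase lag far above
machine precision, which is why the evaluation's activity/circumference
sources are configurable. Coefficient recovery under the study noise
(1.8 mm) is assessed on the measured-capacitance path with zero-lag
filtering (phase-aligned) and the true activations as regressors: median
relative error across the 11 coefficients, median ~2% over 20 seeds.
Through the full EMG-envelope path the per-coefficient recovery is biased by
tens of percent — the envelope is a noisy, smoothed estimate of activation
(errors-in-variables attenuates and distorts coefficients, and an MVC taken
as the maximum of a noisy envelope is biased high) — while the functional
agreement stays excellent (ICC > 0.98). This is an inherent property of
envelope-based regression, not an implementation artifact; per-coefficient
claims from real data should be read accordingly.

Other numerical choices: time-normalisation by linear interpolation with
endpoints preserved; velocity by central differences; calibration inversion
rejects lengths below the parabola minimum naming the offending sample; CSV
round trips keep 17 significant digits; ICC returns undefined (None) for
zero-variance data instead of 0/0.

## Known limitations

* Single-belt, thigh-only geometry; no attempt to separate individual
  muscle contributions (the belt reads the aggregate circumference).
* The passive-deformation waveform is a qualitative stand-in; no
  quantitative description of the real passive trace is available.
* No marker-based validation of heel contacts is implemented (no rule for
  it is defined); the GRF threshold rule with debounce is the sole detector.
* Published per-condition CVs near 1 % arise from an amplitude reference
  (~130 mm) that cannot be reconstructed from the elastic-part range alone;
  the reference length is therefore a required explicit parameter, and CVs
  computed against the resting elastic length are much larger.
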