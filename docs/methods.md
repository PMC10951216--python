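# Methods

This note records the signal model, the detector conventions, the numerical
choices and the known limitations of `ppgdistort`. Everything here is a
package design decision; the code is the authority for exact constants
(`src/ppgdistort/morphology.py` documents each detector constant inline).

## 1. Analytic band-pass model

The ideal 2nd-order band-pass is

    H(s) = (w0/Q) s / (s^2 + (w0/Q) s + w0^2)

with center `w0 = 2*pi*f0` and quality factor `Q`. A band given by its edges
`(f_low, f_high)` maps to the arithmetic-midpoint convention

    f0 = (f_low + f_high) / 2,      Q = f0 / (f_high - f_low).

For `Q >= 0.5` (enforced; smaller Q makes the poles real and the closed
forms below invalid) the phase is

    phi(w) = pi/2 - arctan(x + r) - arctan(x - r),
    x = 2 Q w / w0,   r = sqrt(4 Q^2 - 1),

and the group delay `tau_g = -dphi/dw` has a closed form whose low-frequency
limit is `tau_g(0) = 1/(Q w0)`. For `f0 = 5 Hz`, `Q = 0.5` this gives
63.66 ms; the three study bands (0.1–10, 0.1–5, 0.1–2 Hz) give 61.8, 119.9
and 274.3 ms — the narrower the band, the longer the wave is held up at the
cardiac fundamental. These closed forms are verified in the tests against a
central-difference derivative of the phase (step `1e-4 rad/s`, agreement to
`1e-6 s`).

## 2. Digital filter bank

Five families — Butterworth, Bessel, Chebyshev I, Chebyshev II, elliptic —
are designed with `scipy.signal` in second-order-sections form and applied
causally (`sosfilt`, single pass; no `filtfilt`).

**Order convention.** "Order n" means the *prototype* order handed to the
scipy design routines (an order-n band-pass transformation yields 2n poles).
This matches the convention of common instrument-panel filter tools, and it
is the convention under which the qualitative study results reproduce
(order-2 designs at 0.1–2 Hz remove the dicrotic notch; the pole-count
convention would make "order 2" a first-order prototype that attenuates the
2nd cardiac harmonic by only ~30% and destroys nothing).

**Ripple defaults.** Chebyshev/elliptic designs default to 0.1 dB passband
ripple and 60 dB stopband attenuation. With a 1 dB ripple the order-2
Chebyshev I/elliptic designs distort *more* than the higher orders (the
large ripple dominates the response at low order), which inverts the
otherwise monotone order trends; 0.1 dB/60 dB are also the defaults of
widespread commercial filter tools. Both values are configurable
(`FilterSpec.passband_ripple_db`, `stopband_atten_db`).

The Bessel design uses `norm="delay"`. Stability of every designed filter
is checked (all poles strictly inside the unit circle). The digital group
delay is computed per second-order section with `scipy.signal.group_delay`
and summed; `delay_variation` summarizes its standard deviation, range and
mean over a frequency interval (default 1–8 Hz, 200 points).

## 3. Synthetic PPG generator

**Beat model.** One beat is a two-Gaussian mixture: a systolic wave
(amplitude 1, center ~0.15 s, width ~0.05 s) and a diastolic wave
(relative amplitude `r`, center ~0.45 s, width ~0.09 s). Large `r` with
separated centers yields a pronounced diastolic wave with a dicrotic notch
(Dawber class 1); small `r` with overlapping centers yields a weak shoulder
or nothing (class 2+).

**Record assembly is superposition, not concatenation.** Every beat's
mixture has full (infinite) support and the record is the sum of all beats
evaluated on the common time grid. A Gaussian mixture does not decay to
zero within one period (~3% of the systolic amplitude remains at the
boundary), so concatenating truncated beats would put a step at every beat
boundary; that step systematically drags the detected pulse foot ~12 ms
early and biases RI by several points. Superposition makes the clean signal
smooth everywhere — the spectral floor of a noise-free record above 40 Hz
is below 1e-6 of the peak power density.

**Realism knobs.** Beat-to-beat heart-rate variability (Gaussian, clipped
to 30–180 bpm), baseline drift (slow sinusoid, ~5% of the pulse
amplitude), mains harmonics (30/50 Hz at −60 dB) and broadband Gaussian
noise (−90 dB). Records are stored *raw-inverted* (pulse minima point up,
as a photodetector delivers them) on a large DC offset; the preprocessing
chain must undo both. Cohorts draw a per-record template and heart rate
(between-record SD 8 bpm, clipped to 50–110), with a configurable fraction
of class-1 records.

**Ground truth.** Fiducials are computed analytically on a 10×-oversampled
superposition using the *same* geometric rules as the detector (the
constants are imported from `morphology.py`): threshold-departure foot in
the trailing 35% of the inter-peak interval with a 2% amplitude tolerance,
notch = most prominent interior minimum within 80% of the beat, diastolic
wave present when the subsequent rise exceeds 1% of the systolic amplitude.
Recovery tests therefore measure sampling and noise error, not a
convention mismatch. The first and last beats of a record carry no truth
(their superposition context is one-sided).

## 4. Preprocessing chain

1. invert and subtract the DC estimate — a centered 1-s moving average;
2. optional reference smoothing (centered 10-sample moving average);
3. amplitude normalization to the median pulse foot / mean systolic rise
   (affine-invariant, so filter gain does not masquerade as morphology
   change).

**In-band leakage of the DC estimator.** A 1-s moving average is a sinc
filter whose first null is at 1 Hz; at a heart rate of 87 bpm
(fundamental 1.45 Hz) it still passes ~19% of the fundamental, which is
then *subtracted* from the signal. This slightly reshapes every beat and
can bias RI by several points relative to exact-offset removal. It is a
property of the measurement chain, shared by both branches of every
comparison; the parameter-recovery checks use exact offset removal on
noise-free records to characterize the detector itself.

## 5. Morphology detection

* **Beats**: local maxima with prominence ≥ 0.4× the local (rolling 2-s)
  amplitude range, separated by ≥ 0.4 s. The separation bound caps the
  detectable heart rate at 150 bpm and — deliberately — exceeds the largest
  possible systolic-to-diastolic spacing of the beat model (~0.35 s), so a
  pronounced diastolic wave can never be double-counted as a beat.
* **Pulse foot**: threshold-departure point (last sample within 2% of the
  beat amplitude above the window minimum) within the trailing 35% of the
  inter-peak interval. A plain argmin is ill-posed on causal-filtered
  signals: the high-pass sag between beats pulls the argmin ~100 ms into
  the previous beat and inflates every delta-ETc.
* **Dicrotic notch / diastolic peak**: most prominent interior minimum
  between the systolic peak and 80% of the beat period, followed by the
  first local maximum; a diastolic wave "exists" when that rise exceeds 1%
  of the systolic amplitude, and is "pronounced" (Dawber class 1) above
  10%. Classes 1–2 are eligible for RI/ETc.
* **Record indices**: S_SQI (third standardized moment, population sigma),
  HR (60 / median inter-peak interval), RI (mean of 100·A_d/A_s over
  eligible beats), ETc (mean of 1000·dT/sqrt(HR/60), ms). RI/ETc are
  reported only when ≥ 25% of the detected beats are eligible: a handful
  of "eligible" beats in an otherwise notch-free record is detection noise
  (drift wiggles mimicking a diastolic wave), and averaging them would
  present noise as morphology.

## 6. Distortion metrics and statistics

Each filter cell is compared against the unfiltered reference branch of the
same record: delta-S_SQI, delta-RI, delta-ETc (filtered minus reference;
`None` when either branch has no measurable diastolic wave) and
delta-T_peak, the mean systolic-peak delay over nearest-neighbour matched
peak pairs (pairs farther than 400 ms apart are discarded; positive =
filtered lags).
Records are trimmed of their first 2 s before comparison to exclude the
filter transient.

The Wilcoxon signed-rank test is implemented exactly: midranks for tied
|differences|, the exact permutation null via doubled-rank convolution for
n ≤ 25, and the tie-corrected normal approximation beyond. scipy's
implementation cannot compute an exact null in the presence of ties; it
serves as an oracle in the tie-free case, alongside an exhaustive 2^n
sign-flip enumeration in the tests.

## 7. Known limitations

* **Not all class-1 records lose the notch at 0.1–2 Hz.** The headline
  notch-destruction effect is demonstrated on the canonical 87-bpm record.
  Cohort members with a very large diastolic wave (ratio ~0.5), a late
  notch and a low heart rate genuinely keep a detectable notch through an
  order-2 0.1–2 Hz Butterworth — the 2nd harmonic is attenuated to ~0.52
  there, not removed. The effect is a property of the waveform population,
  not of the detector.
* **Spurious per-beat eligibility under noise.** On noisy class-2 records
  a drift/noise wiggle occasionally mimics a diastolic wave on a few beats
  (≤ ~10% in probed cohorts). The 25% record-level eligibility floor keeps
  these out of the record indices, but per-beat fiducials retain them.
* **Bessel RI distortion saturates with order.** Its maximally flat group
  delay means delta-RI barely grows from order 4 to 6; order-trend
  comparisons on small cohorts can show tie-level wobbles.
* **The generator is a two-Gaussian caricature.** It reproduces the
  morphological features the indices depend on (foot, systolic peak,
  notch, diastolic wave, class structure) and their frequency content, but
  not ectopy, respiratory amplitude modulation, motion artifacts or sensor
  saturation. Conclusions about robustness to those phenomena are out of
  scope.
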