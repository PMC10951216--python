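# ppgdistort

Quantifying the pulse-waveform distortion caused by causal IIR band-pass
filtering of photoplethysmography (PPG) signals.

## The problem

PPG devices almost universally band-pass filter the raw photodetector signal
before any morphological analysis. A causal (real-time) IIR band-pass is not
a transparent operation: its group delay varies across the cardiac band, so
different harmonics of the pulse wave arrive at different times. The visible
consequences are a delayed and reshaped systolic peak, a damped or erased
dicrotic notch, and systematic shifts in the morphology indices clinicians
actually use — the skewness signal-quality index (S_SQI), the reflection
index (RI) and the heart-rate-compensated ejection time (ETc). The effect
grows as the passband narrows or the filter order rises, and it differs
between filter families (Butterworth, Bessel, Chebyshev I/II, elliptic).

`ppgdistort` makes this distortion measurable. It provides:

* **theory** — closed-form transfer function, phase and group delay of the
  ideal 2nd-order band-pass, parameterized by the band edges
  (`f0 = (f_low + f_high)/2`, `Q = f0/(f_high - f_low)`);
* **filters** — a five-family digital IIR filter bank (second-order
  sections, causal application, per-frequency digital group delay);
* **synth** — a synthetic PPG generator: each beat is a two-Gaussian
  (systolic + diastolic) mixture, beats are superposed into a continuous
  record with beat-to-beat heart-rate variability, baseline drift, mains
  interference and broadband noise, raw-inverted polarity and a DC offset —
  together with exact analytic ground-truth fiducials for every beat;
* **preprocess** — the standard chain: inversion, 1-s moving-average DC
  estimation and removal, reference smoothing, amplitude normalization;
* **morphology** — beat detection, pulse-foot / systolic-peak /
  dicrotic-notch / diastolic-peak fiducials, Dawber class, S_SQI, RI, ETc;
* **distortion** — filtered-vs-reference deltas of all indices, systolic
  peak-shift matching, an exact Wilcoxon signed-rank test, and a full
  cohort × filter-grid experiment runner.

## Worked example

```python
import numpy as np

from ppgdistort import (
    BandSpec, FilterSpec, design_filter, generate_record,
    group_delay_analytic, invert_and_remove_dc,
)
from ppgdistort.distortion import index_deviation, match_peak_shift, process_branch

# the ideal 2nd-order band-pass predicts how much each band delays the pulse
for f_low, f_high in [(0.1, 10.0), (0.1, 5.0), (0.1, 2.0)]:
    band = BandSpec(f_low, f_high)
    tau0 = group_delay_analytic(band, np.array([1e-9]))[0]
    print(f"band {f_low}-{f_high:>4} Hz  f0={band.f0:5.2f} Hz  Q={band.q:.3f}  "
          f"low-frequency delay {1000 * tau0:6.1f} ms")

# a synthetic 60-s PPG record with a pronounced diastolic wave at 87 bpm
rec = generate_record(seed=1, hr_mean=87.0)
ac = invert_and_remove_dc(rec)          # invert + 1-s moving-average DC removal
ref = process_branch(ac, None)          # unfiltered reference branch

for family, f_high in [("butterworth", 10.0), ("butterworth", 2.0),
                       ("chebyshev2", 10.0)]:
    filt = design_filter(FilterSpec(family, 2, BandSpec(0.1, f_high)))
    res = process_branch(ac, filt)
    shift = match_peak_shift(res.peak_times, ref.peak_times)
    dev = index_deviation(res.indices, ref.indices)
    kept = res.indices.n_beats_used / res.indices.n_beats_total
    dri = "   n/a" if dev["delta_ri"] is None else f"{dev['delta_ri']:6.1f}"
    print(f"{family:>11} order 2, 0.1-{f_high:>4} Hz: peak delay {shift:6.1f} ms, "
          f"dS_SQI {dev['delta_s_sqi']:+.3f}, dRI {dri} pts, "
          f"notch kept in {kept:4.0%} of beats")
```

Output:

```
band 0.1-10.0 Hz  f0= 5.05 Hz  Q=0.510  low-frequency delay   61.8 ms
band 0.1- 5.0 Hz  f0= 2.55 Hz  Q=0.520  low-frequency delay  119.9 ms
band 0.1- 2.0 Hz  f0= 1.05 Hz  Q=0.553  low-frequency delay  274.3 ms
butterworth order 2, 0.1-10.0 Hz: peak delay   20.9 ms, dS_SQI +0.065, dRI   -2.1 pts, notch kept in  98% of beats
butterworth order 2, 0.1- 2.0 Hz: peak delay  108.9 ms, dS_SQI -0.763, dRI    n/a pts, notch kept in   2% of beats
 chebyshev2 order 2, 0.1-10.0 Hz: peak delay  280.6 ms, dS_SQI -1.450, dRI    n/a pts, notch kept in   2% of beats
```

The wide 0.1–10 Hz Butterworth delays the systolic peak by ~21 ms and
barely perturbs the indices. Narrowing the band to 0.1–2 Hz — or switching
to a Chebyshev II, whose equiripple stopband buys its flat passband with a
violent group-delay swing — destroys the dicrotic notch in ~98% of beats,
so RI is no longer measurable at all (`n/a`).

## Command-line interface

Everything is also available through the `ppgdistort` CLI:

```
ppgdistort synth --n 20 --seed 1 --out cohort/        # generate records
ppgdistort theory --f0 5 --q 0.5 --out curve.csv      # analytic delay curve
ppgdistort groupdelay --family bessel --order 4 --out gd.csv
ppgdistort filterbank --family butterworth --in cohort/rec00.csv --out filt.csv
ppgdistort indices --in cohort/rec00.csv --out idx.json
ppgdistort run-all --config config.yaml               # full experiment grid
```

`run-all` writes `per_record.csv` (long-format per-record deltas),
`summary.csv` (per-cell medians, quartiles and Wilcoxon p-values),
the resolved `config.yaml` and a `run.log`.

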