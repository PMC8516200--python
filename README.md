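# fixtof

Real-time monitoring of formalin diffusion into tissue specimens by
acoustic time-of-flight (TOF), and radial quantification of the
immunohistochemical staining it predicts.

## The problem

Formalin fixation is the dominant preanalytic variable in histology:
a specimen sectioned before formalin has diffused to its core stains
poorly, and the failure is silent until the slide is read. An
ultrasound pulse crossing the formalin bath slows measurably as
formalin displaces interstitial fluid, so the TOF differential of a
submerged specimen decays toward osmotic equilibrium and tracks
diffusion non-destructively in real time.

`fixtof` is for laboratory engineers and image-analysis scientists who
need (a) a streaming decision rule for *when a specimen has enough
formalin*, and (b) an objective, zonal readout of whether the
resulting stain is spatially adequate.

## The model

The spatially averaged, calibration-subtracted TOF signal follows a
single exponential

    TOF(t) = A · e^(−t/τ) + C

with amplitude *A* (ns), decay constant *τ* (hours) and offset *C*
(ns). The rate-of-diffusion metric is the derivative of the
amplitude-normalized curve,

    m(t) = 100 · (−1/τ) · e^(−t/τ)   [%/hr]

and the predicted completion time — when |m| slows to a threshold
slope *s* (default 7.4 %/hr, i.e. s = 0.074 per hour) — is

    t_done = −τ · ln(s·τ).

A prediction is only emitted once the streaming fit has provably
converged. After every new point the curve is refit and three
conditions checked: **past** (10 consecutive decay constants each
within 2 % of the mean of the previous 6), **present** (95 % CI of the
latest τ narrower than 0.7 h), and **future** (95 % confidence band of
the fitted TOF curve narrower than 2 ns across all times). The first
simultaneous pass *validates* the signal and latches `t_done`.

Stain adequacy is quantified radially: segment the tissue, exclude
non-staining regions, color-deconvolve hematoxylin/DAB optical
densities, call DAB positivity with a global OD threshold, bin pixels
into concentric 0.33 mm zones of edge distance, and report the
penetration depth (where positivity drops to half its edge value) and
the percent of tissue staining properly. Group contrasts use Welch's
two-sided t-test at p < 0.002.

## Worked example

```python
import numpy as np
from fixtof import simulate, monitor, tof_model

spec = simulate.SyntheticTofSpec(tau=2.5, amplitude=40, offset=5,
                                 noise_sd=0.0, position_jitter_sd=0.0)
trace = tof_model.spatial_average(simulate.simulate_tof_trace(spec))
state = monitor.run_trace(trace)
print(state.validated_at, state.predicted_done_at)
```

prints

```
1.5833333333333333 4.218498634759531
```

— on a noiseless τ = 2.5 h curve sampled every 5 minutes the monitor
validates at 1.58 h (the 16th fit, the earliest the 10/6 windowing
permits) and predicts completion at 4.22 h, the closed form
−2.5·ln(0.074·2.5).

The same flow from the shell:

```bash
fixtof simulate-tof --tau 2.5 --noise-sd 0 --out trace.csv
fixtof monitor --input trace.csv --calibration 0 --out report.json
fixtof simulate-ihc --penetration 1.0 --out tissue.tif
fixtof quantify --image tissue.tif --pixel-size 0.01 --out metrics.json
```

`metrics.json` reports `penetration_depth_mm` and
`proper_fraction_pct` for the synthetic disk, recovered from the image
alone.

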