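# Methods

## Diffusion model and units

The spatially averaged TOF differential is modelled as
`TOF(t) = A·e^(−t/τ) + C` (A, C in ns; τ in hours). Spatial averaging
takes the mean of the non-missing position readings at each time
(missing readings are skipped, never imputed) and subtracts the
formalin-only calibration reading, isolating the tissue's phase
contribution.

The completion-time formula `t_done = −τ·ln(s·τ)` is dimensionally
consistent only when the threshold slope `s` is a fraction per hour,
so the library uses fractions internally (`0.074` = 7.4 %/hr) and
treats %/hr as a display unit. This makes the slope↔completion round
trip exact: `|m(t_done)| = 100·s` to 1e−9 for any valid (τ, s). When
`s·τ ≥ 1` the specimen is already below threshold at t = 0; the
completion time is clamped to 0 and flagged (`CompletionTime.clamped`).

## Fitting

Nonlinear least squares with a deterministic initialization —
`C₀ = last value`, `A₀ = first − last`, `τ₀ = span/3` — solved by
damped least squares (trust-region reflective) with the bound τ > 0
(`scipy.optimize.curve_fit`). The parameter covariance is the
residual-variance-scaled inverse of the Gauss–Newton normal matrix at
the solution; `dof = n − 3`. A constant signal raises a
non-identifiability error before the solver runs; solver
non-convergence raises a fit-failure error carrying the
initialization and sample size. Five points are required before the
first fit (three parameters plus two degrees of freedom, the minimum
for a finite CI plus one for stability).

Confidence machinery is classical and deterministic: the τ interval
uses the t-quantile with n−3 dof and the τ variance; the band of the
fitted mean curve is the first-order (delta-method) propagation of the
full 3×3 covariance through the curve's parameter gradient. The
bootstrap appears only as a test oracle (2,000 parametric resamples,
agreement within 15 %). Condition thresholds compare *full* interval
widths with strict inequality; both conventions are configurable.
The "future" band is evaluated on a 200-point grid over
[0, 24 h] plus the asymptotic t→∞ width (which the exponential terms
leave equal to the offset-parameter width); tests confirm the outcome
is stable between 50- and 500-point grids. The band is a confidence
band for the mean curve, not a prediction band for new observations —
the monitor asks whether the *curve* is pinned down, not whether the
next point is.

## The three-condition monitor

Fits are recomputed after every new point (no wall-clock timer). The
"past" condition reads "10 consecutive decay constants within 2 % of
the average of the previous 6" as ten consecutive passing *checks*,
each comparing the current τ against the trailing six estimates
(current excluded from its own reference mean); consecutive checks may
share reference windows. This is the only reading that uses both
printed numbers, and it makes the earliest possible validation the
16th fit — a property the tests pin down. Validation latches: once
all three conditions hold, `validated_at` and `predicted_done_at` are
immutable. Traces that never satisfy all three conditions are
reported as censored, counted, and excluded from cohort means rather
than raising — mirroring real monitoring, where a decision may simply
not be reached.

Cohort evaluation replays each trace through the monitor and scores
the prediction at validation against the completion time of the fit
on the *complete* trace (the fit at the end of the experiment);
`lead_time = true_done − validated_at`.

## Synthetic TOF generator

Defaults: A = 40 ns, C = 5 ns, τ = 2.5 h, one point per 5 minutes for
8 h, 7 vertical positions 1 mm apart, additive Gaussian noise of
0.5 ns per reading (sub-nanosecond precision) plus a static zero-mean
per-position offset (sd 1 ns) modelling specimen heterogeneity along
the scan axis. Amplitude and offset scales are conventions of this
generator, chosen at the tens-of-ns scale of the instrument; the
5-minute cadence yields ~36 fits by 3 h, comfortably feeding the 10/6
windowing.

The retrospective-cohort sampler draws τ ~ U(1.5, 3.5) h,
A ~ U(20, 60) ns, C ~ U(0, 10) ns per trace. Its default keeps the
instrument geometry (7 positions averaged, so the averaged point
carries ≈ 0.19 ns noise); under these conditions validation precedes
completion by ~0.5 h on average. The acceptance cohort instead places
the full 0.5 ns on each averaged point (a single synthetic position):
under that heavier noise the 2 ns future band needs late-time data to
pin C, validation lands after completion on average, yet the mean
|predicted − true| completion error stays under 2 minutes — accuracy
and lead time decouple.

What the generator does *not* emulate: early-time departures from
single-exponential behaviour (tissue deformation, thermal
transients), drifting baselines, heteroscedastic or correlated noise,
and multi-compartment diffusion. Passing tests therefore demonstrate
the decision logic and its statistics, not robustness to
model-misspecified instruments.

## Synthetic IHC images and the radial quantifier

The image generator renders a disk of tissue on a bright background.
The disk is tessellated into cell-scale regions (nearest seed of a
seeded point process; region scale set by `cell_radius`); every
region is hematoxylin-stained and is DAB-positive with probability

    p(d) = background + (edge − background) · 2^(−d/penetration)

where `d` is edge distance, so positivity (above background) halves
every `penetration` mm — by construction the quantifier's
"penetration depth" estimates the generator parameter. Tessellation
(rather than sparse cell disks) makes the pixel-based zonal positive
fraction equal p(d) directly, which is what the zonal statistics
measure; nucleus texture and scanner noise are out of scope. Pixels
are rendered by inverse optical-density mixing of the standard
hematoxylin/DAB reference vectors; optional white holes model
non-staining tears. Default pixel size for synthetic work is 0.01
mm/px — zone statistics are unchanged at full scanner resolution but
run two orders of magnitude slower.

Quantification: Otsu segmentation on luminance (threshold recomputed
per image, hence invariant to global brightness scaling) with
largest-component selection and small-hole filling; exclusion of
near-white regions (total OD < 0.08) and sub-speck objects; color
deconvolution by least-squares projection of per-pixel OD onto the
two stain vectors, negatives clipped with a reported clip rate; exact
Euclidean distance transform scaled to mm; zones of width 0.33 mm
(`floor(d/width)`); per-zone pixel count, positive fraction at the
global DAB OD threshold (default 0.15 OD — unstated upstream, so made
explicit and configurable) and mean DAB OD. Penetration depth is the
lower boundary of the first suppressed zone (positive fraction below
half the edge value) with no sub-zone interpolation — resolution is
inherently one zone and interpolating would imply false precision;
when nothing is suppressed the full analyzed depth is returned,
flagged. The proper-staining fraction uses half of
max(edge value, maximum zone value); both values are reported so
either convention is auditable.

A caveat discovered while testing the unmixing: 8-bit quantization of
intensities propagates through the deconvolution pseudo-inverse with
roughly 3× amplification, so quantized round-trip errors reach ~6e−3
OD; the tests assert the exact per-pixel quantization bound
`|M⁺|·(0.5/(I·ln10))` rather than a flat constant, and the 1e−6 round
trip holds pre-quantization.

## Statistics

Group comparisons are pairwise Welch two-sided t-tests
(Welch–Satterthwaite dof), reported raw with the fixed p < 0.002
significance cutoff and no multiplicity correction. Identical groups
(zero pooled variance) are reported as t = 0, p = 1.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data:
a 105-trace cohort at 97 points per trace for the retrospective
evaluation (~25 s), 20-trace cohorts for monitor properties, and
300–600 px synthetic images for the imaging workflow. These sizes
were chosen so a full run completes in a few minutes on one CPU while
keeping every statistical check comfortably powered.

## Known limitations

* Single-exponential only; no Fickian PDE or multi-exponential
  modelling, no temperature dependence of sound velocity.
* The monitor never un-latches; re-validation after instrument faults
  is out of scope.
* Pixel-based (not cell-based) positivity; no nucleus segmentation,
  no cross-scanner color normalization, no whole-slide tiling.
* The stroma/hole exclusion rule is an OD heuristic; real stroma with
  appreciable hematoxylin uptake would not be excluded by it.
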