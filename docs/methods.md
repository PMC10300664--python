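# Methods

This note documents the models and procedures implemented in `batforage`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter.

## Array localization (`arrayloc`)

A planar Y-shaped array — central microphone at the origin, three outer
microphones 120° apart at 1 m (configurable) — yields three independent
time differences of arrival (TDOAs, outer minus central) per pulse.

**TDOA estimation.** Plain normalized cross-correlation of each outer
channel against the central channel, with parabolic interpolation of the
three samples around the correlation peak for sub-sample resolution. No
PHAT or other spectral weighting: echolocation pulses are high-SNR and
band-limited, where the unweighted correlator is close to optimal. The
peak correlation coefficient is kept as a per-pair quality score; pulses
with any pair below the quality floor (default 0.3) are flagged
unlocalizable but never silently dropped.

**Inversion.** The position minimizes the sum of squared TDOA residuals
via `scipy.optimize.least_squares` (trust-region reflective, bounds
`z ≥ 0`), multi-started from the best cells of a 5 m grid over a
100 × 100 × 50 m upper-half-space box. The multi-start matters: with a
~1 m baseline the hyperboloid intersection develops shallow local minima
at long range. Because the microphones are coplanar, every solution has
a mirror image below the plane with identical TDOAs; the `z ≥ 0` bound
selects the physical (airborne) branch. Note a geometric consequence:
no point at finite range is equidistant from all four microphones — a
source on the array axis gives three *equal, positive* TDOAs, not zero
TDOAs.

**Validity radius.** With exact delays the inversion is accurate to
~10⁻⁶ m; the operational error budget is set by TDOA quantization and
noise amplified by geometric dilution. The 47 m reporting gate marks the
region where sample-clock quantization (500 kHz) keeps the median
position error below the ~40 cm scale of the animal itself. The gate is
applied to *reporting* (an `in_range` flag), not to solving, so
out-of-range solutions remain available for inspection. At a 1 m arm the
*worst-case* quantized error near the horizon can exceed that bound —
the error grows monotonically with range (tested) — which is why the
flag, and not a hard cut, is the right interface.

**Derived kinematics.** Speed is the 3-point central finite difference
of position over time (`np.gradient`); altitude is the z coordinate; the
attack point of a buzz is the position of its last localized pulse, and
distance-to-attack is the 3D Euclidean distance to it.

## Pulse analysis (`callpulse`)

**Segmentation.** The Hilbert envelope (smoothed over 0.2 ms) must rise
a configurable SNR floor (default 12 dB) above the noise median;
candidate regions closer than 1 ms merge; each pulse's start/end is then
refined to the first/last envelope sample within 15 dB of that pulse's
*own* peak. Measuring each pulse against its own peak (not a global
threshold) keeps edge estimates unbiased across the ~20 dB of level
variation that range spreading imposes.

**Features.** Power spectrum of the raw pulse window (no extra taper —
the segmentation already cuts at envelope edges and the calls ramp
on/off; a window would bias sweep-edge frequencies inward). Peak
frequency is the argmax; minimum/maximum frequency are the lowest and
highest frequencies within 15 dB of the spectral peak; bandwidth is
their difference. The −15 dB criterion is the same for temporal and
spectral edges. IPI is start-to-start to the next pulse. Calls with
sweep rate (bandwidth/duration) at or below 0.60 kHz ms⁻¹ are QCF, else
FM; the boundary belongs to QCF.

**Feeding-buzz rule.** Maximal runs of consecutive IPIs below 20 ms;
runs whose boundary pulses are separated by ≤ 100 ms are fused (real
buzzes often have two sections with a brief pause); fused runs with ≥ 5
pulses are buzzes. The 100 ms parameter is interpreted as this
*merge gap*, not a cap on total buzz duration: observed buzz durations
run well past 100 ms, which rules out the cap reading. After fusion a
buzz may therefore contain one bridging interval in (20, 100] ms;
`mean_ipi_ms` averages the sub-threshold intervals only. The rule is a
pure function of timestamps, so logger event streams and
waveform-derived pulse tables give identical detections — a property the
tests exercise directly.

**Approach onset.** The approach phase (shortening IPI and duration,
rising minimum frequency before the buzz) has no standard operational
definition; ours is: the earliest pulse before the buzz from which every
IPI up to the buzz start stays below 50 % of the median IPI of the 10
preceding pulses. A train that jumps straight from search pacing into
the buzz has, by this definition, no approach onset — the detector
returns an explicit no-onset flag rather than guessing.

## Biologging (`biologging`)

GPS fixes (5 s cadence, gaps allowed) are linearly interpolated onto a
1 s grid between the first and last fix, never extrapolated; lat/lon are
interpolated directly in degrees (spans are far too small for projection
error to matter). Ground speed is the haversine distance between
consecutive *raw* fixes over elapsed time, assigned to the intervening
1 s samples — computing speed from interpolated points would launder the
interpolation into spuriously smooth velocities. Geodesy is a mean
sphere of radius 6 371 008.8 m; the spherical approximation error at
these scales is orders of magnitude below GPS noise.

Above-ground altitude is ASL minus terrain elevation, with the terrain
sampled from an ESRI ASCII DEM by bilinear interpolation between cell
centers. Negative AGL values are *retained and counted*: altitudinal GPS
error exceeds the horizontal error, and the share of negative altitudes
over a river (where true height is near zero) is itself a lower bound on
that error. Habitat is a nearest-cell lookup in a categorical raster —
categorical data must never be interpolated. Attacks are matched to the
1 s sample nearest each buzz end (ties to the earlier sample) and
inherit position, altitude and habitat from that sample.

## Statistics (`habstats`)

All three models are single-factor fixed-effects fits on one
individual's track; each result carries an explicit note that the
estimates describe within-individual patterns only.

* **Attack probability.** Binomial GLM (statsmodels IRLS) in cell-means
  coding: coefficients are per-habitat log-odds, so the saturated model
  reproduces raw frequencies exactly, which the tests verify in closed
  form. Asymptotic (Wald) CIs on the link scale, back-transformed;
  pairwise odds ratios with normal p-values. Complete separation (a
  habitat with frequency 0 or 1) raises a diagnostic error.
* **Altitude.** Gaussian with habitat-specific mean *and* variance.
  For one factor the ML solution is closed form — group means and biased
  group variances — and is cross-checked in the tests against direct
  numerical maximization of the likelihood. SE(μ̂ₕ) = √(σ̂ₕ²/nₕ);
  residual df = n − 2k (k means + k log-variances), giving df = 114 at
  the default 40-per-habitat subsample; pairwise differences use
  Welch-type SEs.
* **Speed.** One-factor OLS with pooled variance; overall one-way F;
  pairwise differences with pooled SE s√(2/n).

Wald χ² of the habitat factor is the joint test that all level
coefficients are equal (with a single factor, type II and type III
coincide). Bonferroni: p_adj = min(1, 3 · p_raw) over the three pairs.
CIs are Wald (normal/t), not profile, matching the infinite-df intervals
the binomial model reports.

**Subsampling.** Uniform without replacement, per habitat, seeded: 76
per habitat for speed, 40 for altitude. This is the anti-autocorrelation
device — a dense 1 Hz track is serially dependent, and balanced thinning
both weakens that dependence and equalizes group sizes.

**Parametric bootstrap.** The observed LR = 2(ℓ_full − ℓ_null) is
compared to B refits on data simulated from the fitted intercept-only
null; p = (1 + #{LR* ≥ LR}) / (B + 1), so the attainable minimum is
1/(B+1). Default B = 1000. The bootstrap loop uses closed-form ML
refits (per-group frequencies/means/variances), making the calibration
check (200 replicates at B = 200, Kolmogorov–Smirnov against uniform)
cheap enough to run in the test suite.

## Synthetic data (`synthio`)

The generator's defaults encode the foraging conditions the analysis
assumes:

* search-phase calls at 150–250 ms IPIs, drawn 70 % QCF
  (duration 20.9 ± 3.6 ms, bandwidth 7.78 ± 1.8 kHz, min frequency
  15.3 ± 1.5 kHz) and 30 % FM (14.5 ± 5.0 ms, 13.7 ± 3.5 kHz,
  19.0 ± 1.6 kHz);
* an 8-pulse approach phase with IPI falling geometrically 70 → 25 ms,
  duration 12 → 5 ms, minimum frequency rising;
* buzzes of 6–15 pulses at IPIs ~N(15, 7.9²) ms clipped to [5, 19.5];
* flight at ~8.2 m s⁻¹ (array scenes) and per-habitat ground speeds of
  6.1 / 6.0 / 8.8 m s⁻¹ (river/mountain/urban) in logging sessions;
* per-habitat attack rates 3.28 / 2.96 / 1.0 min⁻¹ and session
  durations 21 / 14.5 / 8 min, so a default session carries ≈ 120
  attacks split ≈ 69/43/8;
* observed above-ground altitude of −11.1 ± 13.5 / 157.7 ± 92.3 /
  77.1 ± 31.2 m per habitat. These spreads *include* GPS altitude error,
  so the generator draws intrinsic spread √(sd² − σ_gps²) and the logger
  renderer adds σ_gps = 10 m of Gaussian altitude noise back on the
  fixes; the default σ_gps reflects altitudinal error dominating the
  horizontal one.

Audio rendering: each call is a linear frequency sweep with 10 %
raised-cosine onset/offset ramps (the simplest waveform with
well-defined −15 dB edges), delayed per channel by r/c, attenuated by
spherical spreading 1/r (re 1 m), embedded in Gaussian noise at the
configured level; insertion is sample-accurate, so rendered TDOAs match
the closed form within one sample period. Speed of sound defaults to
343 m s⁻¹ (20 °C) and is configurable. Atmospheric absorption,
directional microphone response, multipath, and Doppler are *not*
modelled; the logging scenario's zigzag path is kinematically clean
(constant per-habitat speed). Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical structure,
not robustness to clutter, overlapping bats, or real-world propagation.

The terrain is an analytic surface (flat valley → rising ridge → bench)
with C¹ cosine blends between zones so that bilinear DEM sampling stays
within ~2 m of truth; the habitat raster is three latitudinal strips
aligned to cell edges. Rasters are written in geographic degrees with a
single cellsize (ESRI convention), so a cell is narrower east–west in
meters by cos(latitude); the builders account for this when sizing the
extent.

Determinism: every public generator takes a seed and is bit-reproducible
given it; renderers emit ground-truth tables (emission points, pulse
edges, phase labels, attack times) alongside the signal so detectors can
be scored exactly.

## Problem sizes used in verification

The built-in verification runs at sizes chosen to exercise the estimators
well inside their asymptotic regime while staying desk-scale: 100 seeded
pulse trains (≈ 200 implanted buzzes) for the buzz-rule check; a
200-source grid within 47 m for the exact-TDOA inversion bound; 500
replicates for parameter recovery of the three habitat models (at group
sizes 872/1263/481 for the attack model, 40 and 76 per habitat for
altitude and speed); 200 × B=200 for bootstrap calibration.

## Known limitations

* Tracks are single-bat; no call-to-individual assignment or multi-bat
  disambiguation.
* The localization solver is the generic TDOA least-squares formulation,
  not a port of any specific field system's solver; the quantized-clock
  error at the default 1 m arm exceeds 40 cm in the worst geometries near
  the 47 m edge even though the median stays far below it.
* The approach-onset rule (50 % of the 10-pulse median) is this
  package's operational definition of "distinct decrease"; alternative
  windows/fractions are parameters.
* Attack-rate denominators are exposure minutes from the track itself;
  with very short habitat exposure the rate estimate is unstable.
* The habitat models assume per-second exchangeability after balanced
  subsampling; they do not model residual autocorrelation explicitly.
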