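# batforage

Two-scale analysis of foraging in a large open-space, aerial-hawking bat
(*Nyctalus aviator*, the birdlike noctule), combining:

* **microphone-array acoustic tracking** — 3D localization of echolocating
  bats from a four-microphone Y-array, per-pulse call parameters
  (duration, minimum/peak frequency, bandwidth, inter-pulse interval),
  QCF/FM call classification, and feeding-buzz detection; and
* **acoustic-GPS biologging** — turning a tag's 5 s GPS fixes and
  pulse-onset event stream into a 1 s georeferenced track with
  above-ground altitude, ground speed, habitat type, and geolocated
  attacks, followed by habitat-stratified statistical models.

Both halves matter for conservation: large open-space bats forage at
altitudes that overlap the rotor-swept zone of wind turbines, and the
question of *where* and *how high* they hunt in each habitat is exactly
what this pipeline quantifies. The package ships a synthetic-data
generator that emulates the acoustic and movement structure of such a
foraging bout, so every stage is testable end-to-end without field data.

## Methods at the core

**Localization.** A central microphone and three outer microphones give
three time differences of arrival (TDOAs) per echolocation pulse,
estimated by normalized cross-correlation with parabolic sub-sample peak
interpolation. The source position `p` minimizes

    Σᵢ ( (‖p − mᵢ‖ − ‖p‖)/c − τᵢ )²,   i = 1..3

over the upper half-space (`z ≥ 0`; the mirror solution below the
coplanar array is discarded), by trust-region least squares multi-started
from a coarse grid. Tracks are gated at a 47 m validity radius, inside
which the range error stays below the ~40 cm wingspan of the animal.

**Feeding buzzes.** A buzz — the terminal pulse sequence of a capture
attempt — is any run of ≥ 5 pulses whose start-to-start inter-pulse
intervals (IPIs) stay below 20 ms, with sub-runs separated by ≤ 100 ms
fused into one buzz. The rule uses timestamps only, so it runs
identically on waveform-derived pulse tables and on the logger's
threshold-crossing event stream. Calls are QCF if bandwidth/duration
≤ 0.60 kHz ms⁻¹, else FM; pulse and spectral edges are taken −15 dB from
each pulse's own peak.

**Habitat models.** Per-second track samples with habitat h ∈ {river,
mountain, urban} feed three single-factor models:

* attack presence: logistic regression, `logit P(attack) = βₕ`, pairwise
  odds ratios `exp(βₐ − β_b)`;
* above-ground altitude: heteroscedastic Gaussian `y ~ N(μₕ, σₕ²)` with
  habitat-specific variance, fitted by maximum likelihood (the
  between-habitat spread differs by an order of magnitude, so a pooled
  variance would be wrong structurally);
* ground speed: one-factor OLS on balanced subsamples.

Altitude and speed fits use balanced random subsamples (40 and 76 points
per habitat) to blunt temporal autocorrelation; all pairwise contrasts
are Bonferroni-adjusted, and model-vs-null comparison is available as a
Wald χ² test or a parametric bootstrap of the likelihood-ratio statistic.
All fits are fixed-effects on one individual and say so in their output.

## Worked example

```python
from batforage import synthio, biologging, habstats

session = synthio.simulate_logging_session(seed=7)
track, attacks = biologging.build_geotrack(
    session["fixes"], session["events"], session["dem"], session["habitat_grid"])
print(habstats.summarize_habitats(track, attacks).round(2).to_string(index=False))
n_neg, pct = biologging.negative_altitude_share(track["alt_agl_m"])
print(f"negative AGL: {n_neg} of {len(track)} samples ({pct:.1f}%)")
fit = habstats.fit_attack_model(track["attack"].to_numpy(float),
                                track["habitat"].to_numpy())
print(fit.contrasts[["contrast", "odds_ratio", "p_adj"]].round(3).to_string(index=False))
```

prints

```
 habitat  attacks  attack_pct  minutes  attack_rate_per_min  agl_mean_m  agl_sd_m  speed_mean_ms  speed_sd_ms
mountain       39        32.5    14.50                 2.69      138.66     92.87           6.00         0.03
   river       69        57.5    21.00                 3.29      -14.74     13.94           6.10         0.00
   urban       12        10.0     7.93                 1.51       72.03     30.80           8.79         0.00
negative AGL: 1199 of 2606 samples (46.0%)
      contrast  odds_ratio  p_adj
mountain/river       0.810  0.915
mountain/urban       1.815  0.226
   river/urban       2.240  0.033
```

Reading it: over a simulated ~43 min bout the bat attacks mostly over the
river (69 attacks, 3.3 min⁻¹) at slightly *negative* apparent altitude —
near-surface flight seen through the tag's altitude error — while flights
over the mountain strip sit ~140 m above ground, inside the turbine
conflict zone. The river/urban odds ratio (2.24, adjusted p = 0.033) says
a river second is about twice as likely to contain an attack as an urban
one.

The same pipeline runs from the shell:

```sh
batforage all --out run1 --seed 7      # simulate + track + stats
batforage buzz --events run1/events.csv --out run1
```

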