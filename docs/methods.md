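# Methods

This note documents the models, estimators and numerical choices in
`popdecode`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic test bed
does and does not establish about real recordings.

## Stimulus design

The decoding stimulus set is the complete enumeration of 2×2 tile
patterns over three luminances (black 0.01, gray 6, white 60 Cd/m²),
P = 3⁴ = 81. Pattern ids are the base-3 encoding of the tile digits
(UL, UR, LL, LR; black = 0, gray = 1, white = 2), so id 40 is the all-gray
pattern and dictionaries are comparable across runs. The on-screen
stimulus tiles this miniature image periodically; because every analysis
target (dictionary row, decoded pattern, difference pattern) is itself a
2×2 pattern, all computations operate on the miniature image directly.

Two paradigms are generated per session, interleaved per repetition and
drawing permutations from one seeded generator (10 repetitions of both
paradigms consume 20 permutations):

* **relay** — each repetition block is one fresh permutation of all 81
  patterns shown back-to-back for 250 ms each. A 250 ms gray adaptation
  period is prepended to each block, so the first pattern of a block has
  a defined previous stimulus (gray, contrast zero); every pattern period
  then counts as one transition, 810 per 10-repetition session.
* **dictionary** — the same, with a 250 ms gray blank before every
  pattern.

Every pattern period's previous stimulus is its immediate predecessor
period. Transitions out of gray and identity transitions have a zero
(or partially zero) contrast change; the normalization convention below
makes their contribution to correlation averages exactly 0.

## Normalization (the correlation inner product)

All pattern vectors, dictionary rows and population vectors are
normalized by subtracting the mean and dividing by the Euclidean norm of
the centered vector, so the dot product of two normalized vectors is
exactly their Pearson correlation. A constant vector (no spatial
contrast) maps to the zero vector; every correlation with it is 0. The
divisor is the centered norm rather than the standard deviation — the two
differ only by a factor √n, and the norm form makes the dot-product
identity exact, which the decoder relies on. Degenerate inputs are
handled with a relative tolerance (centered norm ≤ 1e−12 × the vector's
magnitude counts as constant); non-finite input is an error.

## Dictionary decoder

The dictionary matrix RR (81 patterns × N sites) holds mean firing rates
over a configurable window after pattern onset — 0–90, 90–250 or
0–250 ms (default) — averaged across repetitions of the dictionary
paradigm. Rates (counts/window) rather than raw counts keep windows
comparable; normalization removes the overall scale anyway. Sites with
zero variance across patterns normalize to a zero row and simply
contribute nothing, rather than raising an error.

Decoding a single-trial population vector rr in one time bin (default
10 ms; any bin from 1 to 50 ms is supported): `c = R · normalize(rr)` is
the correlation of the instantaneous vector with every pattern's
template; the decoded pattern is the correlation-weighted average of the
normalized patterns, re-normalized. The max-correlation pattern id is
also reported (the simple decoding variant). All sites enter by default;
a responsiveness screen is available as a filter: a site is significant
when its mean evoked rate (across patterns and time) strictly exceeds the
blank-period baseline PSTH mean plus two of its standard deviations,
with the baseline PSTH taken over the last 100 ms of the blank periods
(the pre-onset window) and its statistics across those time bins.

The correlation trace reports, per bin, mean ± SEM (sd/√n over
transitions) of the decoded pattern's correlation with the previous,
current and difference (current − previous, computed on un-normalized
contrast codes, values in {−2…2}, then normalized) patterns.

**Crossover definition.** Before the cortical response to the new pattern
arrives, the current-pattern correlation sits at ≈ 0 while the difference
correlation is negative (the decoded image still resembles +A, and B − A
contains −A), so "current > difference" holds trivially at t ≈ 0. The
crossover is therefore defined as the first bin *after difference
dominance has been established* at which the current correlation exceeds
the difference correlation for k consecutive bins (k = 3 at 10 ms bins by
default, suppressing single-bin noise). If the difference correlation
never dominates, or never hands over, there is no crossover.

## Mutual information

Per site and time bin, single-trial spike counts across all patterns are
discretized into four equal-width intervals spanning [min, max + 1) on a
continuous axis with floor assignment — for a 0–7 range this gives
0–1, 2–3, 4–5, 6–7, and it generalizes to ranges not divisible by four
(e.g. 1–9 → edges at 1, 3.25, 5.5, 7.75). A degenerate range (all counts
equal) is defined as 0 bits, no division performed. The plug-in estimate
I = Σ P(r,s) log₂[P(r,s)/(P(r)P(s))] (0·log 0 = 0) is bias-corrected by
subtracting the mean information over random stimulus-label permutations;
the default of 20 permutations makes the correction's own error small
relative to the bias while staying cheap, and is configurable. Corrected
values can be slightly negative by construction. Previous-stimulus
information pairs each pattern label with the counts observed one 250 ms
period later (a shift of m periods is supported; transitions without a
valid shifted period are dropped). Trace averages include only sites
passing the responsiveness screen.

## Minimal encoding model

The model predicts the image sequence linearly available in a unit's
firing: each pixel's luminance-contrast time course is convolved
(causally, zero-padded history = gray screen before the session) with one
temporal response function; ON subregions add the result, OFF subregions
subtract it (an OFF region is the same kernel inverted). There is no
spatiotemporal interaction (no velocity selectivity) and no nonlinearity
between this drive and the "encoded image" — it is deliberately the
simplest model that produces the difference-then-current representation.

**Default kernel.** A difference of two gamma-shaped lobes, sampled at
1 ms: positive lobe peaking at 50 ms (shape 3), negative lobe peaking at
85 ms (shape 8), with the negative lobe's integral 95% of the positive
lobe's. The kernel is peak-normalized. The shape is a configuration, not
a fitted constant: the lobe timings and the near-cancelling (but slightly
positive) net integral were chosen so the model reproduces the reported
temporal anatomy of the phenomenon — a firing-rate peak ~50 ms after a
transition, early dominance of the difference-pattern correlation, a
hand-over to the current pattern around 100–150 ms, and a small sustained
representation of a constant stimulus (a perfectly balanced kernel would
encode only the difference image and could never hand over). The net
integral also controls the trade-off visible in the orientation test: the
larger it is, the more the unchanged stimulus component competes with the
transient difference response.

For a transition A→B the encoded image is (I − K(t))·A + K(t)·B with K
the kernel's running integral and I its total; the model correlation
trace averages the normalized encoded image's correlation with A, B and
B − A over all 81 × 81 ordered pairs (identity pairs contribute 0 to the
difference average).

**Reverse correlation.** The kernel is estimated from white-noise
stimulation as the spike-count-weighted average of the stimulus at lags
0–200 ms (default; 8.3 ms frames), per pixel, averaged over the unit's
driving pixels with OFF pixels sign-flipped, and normalized to unit peak.
Zero spikes is an error (kernel unestimable). On a synthetic
rectified-linear Poisson unit with a known kernel, 10⁵ frames recover the
kernel with correlation ≈ 0.999; recovery degrades gracefully at smaller
sample sizes (STA noise ∝ 1/√spikes).

## Synthetic population

Sixteen units (one simulated laminar probe) with non-negative ON and OFF
weights over the four tiles: signed uniform draws in [−1, 1] with
magnitudes < 0.15 zeroed (sparse receptive fields), coverage of all four
tiles enforced. Rate mapping: rate(t) = baseline + gain · max(0,
drive(t − latency)), Poisson counts per bin, independent across bins and
sites; a noiseless mode returns exact expected counts for oracle tests.
The kernel is rescaled so a full-contrast luminance step yields unit peak
drive, making gain the peak evoked rate of a preferred transition.
Defaults: gain ~ U(20, 60) spikes/s, baseline ~ U(2, 10) spikes/s
(order-of-magnitude multiunit values for early visual cortex; the true
distributions are unknown and both are exposed in the configuration),
latency 25 ms, bin 10 ms (1–50 ms supported).

What the generator emulates: transition-locked transients, ON/OFF tile
selectivity, rate-dependent Poisson variability, adaptation-like
difference coding inherited from the biphasic kernel. What it does not:
spike-sorting artifacts, inter-site correlations beyond shared stimulus
drive, laminar structure, complex cells in the decoding population,
eye movements, slow nonstationarities. Passing tests on this generator
establish the *estimators'* correctness and the internal consistency of
the difference-image account, not claims about any particular dataset.

## Orientation analysis

Preference is the phase of the second circular harmonic of the rate–
orientation function: pref = ½·arg Σ r(θ)e^{2iθ}, reported in [0, 180).
On the uniform 16-orientation grid this equals a least-squares cosine
(180° period) phase fit, is deterministic, and is invariant to additive
offsets and multiplicative scaling; an all-equal (or vanishing-harmonic)
tuning curve is flagged undefined (NaN). The shift between two
preferences is wrapped into [0°, 90°].

The model test renders the 5/35 Cd/m² square-wave grating, the fixed
0/10/10/60 Cd/m² checker and the 20 Cd/m² background on a 64×64 pixel
grid (8-pixel tiles) and simulates a grating-matched stripe
receptive-field unit through the minimal model, averaging its response
25–90 ms after grating onset. Two rendering/readout choices matter:

* **Center-symmetric rendering.** Tile boundaries follow the sign of a
  cosine in the rotated frame, so every stimulus is symmetric under
  reflection about its stripe axes and under 180° rotation about the
  rotation pivot. This makes the checker→grating transition geometrically
  identical at all orientations and forces the fitted preference of the
  checker-preceded condition onto the exact orthogonal orientation in the
  noiseless model (the worked example — dark-stripe column mean 5 Cd/m²
  before and after the transition — holds to machine precision). With
  corner-anchored tiles the broken symmetry biases the fit by several
  degrees.
* **Phase-invariant readout.** The default unit response is the energy
  |drive| (complex-cell-like). A half-wave-rectified simple cell's early
  response to the difference image depends on its receptive-field phase —
  anti-phase units are silenced — whereas the orthogonal-shift phenomenon
  is not phase-specific; the energy readout captures the phase-insensitive
  population-level effect without modeling a phase distribution. A
  "simple" (rectified) readout remains available.

Noiseless, the blank→grating preference equals the unit's receptive-field
orientation and the checker→grating preference is orthogonal: shift = 90°
exactly for units on the grid's symmetry axes (0°, 45°, 90°, 135°), and
within ~1° elsewhere (pixel-grid reflection residuals). With Poisson
spiking (10 repeats, gain 40, baseline 2 spikes/s) a 17-unit population
averages ~80–88° with a few degrees' spread: the sustained representation
of the unchanged grating-aligned component (net kernel integral > 0)
pulls some units' fits slightly off orthogonal, which is the model's
honest behavior, not an estimator artifact.

## Pipeline, determinism, problem sizes

`run_pipeline` executes stimulus → simulation → dictionary → decoding →
information → orientation, writing every table as CSV and a JSON report
whose every number is traceable to a table. One master seed spawns
independent sub-seeds (all < 2³¹) for schedule permutations, population
draws, the two paradigms' Poisson noise, information shuffles, and the
noisy orientation population; identical configurations produce
byte-identical tables. The default run is the full study layout — 81
patterns, 10 repetitions, 810 transitions, 16 sites, 10 ms bins — and
completes in a few seconds; the test suite runs a mixture of this layout
and smaller schedules and finishes in well under a minute, with the
largest single computation the 10⁵-frame reverse-correlation recovery.

## Known limitations

* The decoder assumes a monotonic rate–luminance-contrast relation
  (simple-cell-like sites); complex-cell-dominated populations would
  violate it, and the generator does not model them.
* The 4-interval count discretization caps information at 2 bits and is
  biased for very low rates even after shuffle correction.
* The crossover time depends on the kernel's negative lobe, which real
  data would have to constrain by reverse correlation; the default is a
  documented configuration, not a measurement.
* Tile-level (4-pixel) receptive fields are sufficient for the periodic
  decoding stimulus but cannot represent position within a tile; the
  orientation test uses the pixel grid instead.
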