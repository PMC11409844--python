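# Methods

## The model

`cardioscore` models a performing musician's beat-to-beat heart (RR)
intervals as a linear function of what the ensemble is playing.  All
signals are expressed in *score time* — the piece's half-beat
(eighth-note) lattice, L = 848 samples for the Schubert piano-trio
movement the package is built around — so that the nine rehearsal
performances become directly comparable.  For each musician the
normalized score-time RR response y is modeled as

    y_pt = beta_0 + x_t' beta + u_p + eps_pt,
    u_p ~ N(0, sigma_u^2),   eps_pt ~ N(0, sigma^2),

with performance p = 1..9 as a random intercept and t = 1..L.  Three
nested fixed-effect sets are fitted per musician:

* **Set 1** — loudness and tempo of the ensemble recording;
* **Set 2** — Set 1 plus the musician's note density and the six
  Interpretation-Map terms (melody, dialogue, significant
  accompaniment, accompaniment, climax, moment of concern), each
  encoded as a Gaussian-kernel signal;
* **Set 3** — Set 2 plus the starting factor.

### Predictors

**Tempo** comes from the annotated half-beat onset times: the local
inter-half-beat interval is estimated by central differences (one-sided
at the endpoints) and reported as quarter-note BPM, `60 / (2 dt)`, so
the piece's notated ~88 BPM appears on its natural scale.  An
eighth-note-pulse variant is available.

**Loudness** is an energy-based sone-like signal: frame RMS → dB level
→ `2**((level - 40)/10)`, so ~10 dB corresponds to a doubling.  This is
a deliberate simplification of a psychoacoustic loudness model (no
Bark-band analysis or ear transfer functions); because every
performance's loudness is min-max normalized before entering the model,
only the curve's shape matters, and a precomputed-loudness CSV path is
provided as a first-class alternative frontend.  Loudness is smoothed
with a zero-phase (forward-backward) Butterworth low-pass, order 3,
Wn = 0.125 of the half-beat Nyquist rate; zero-phase application avoids
introducing lag between loudness and the RR response, and the DC gain
is exactly 1.  Filtering precedes normalization.

**Note density** counts each musician's note onsets in a centered
4-half-beat (one-bar) window, divided by the clipped window length; it
is left on its natural notes-per-half-beat scale.

**Interpretation-Map terms.**  Annotations are inclusive bar spans per
category; bar n occupies half-beats (n-1)*4+1 .. n*4, a convention
fixed by the piece's printed landmarks (bar 67 ↔ half-beat 268).  Each
category becomes a binary vector marking every annotated half-beat,
then a kernel signal: each 1 at position i contributes a discrete
Gaussian centered at i + 16 (four bars ahead) with SD 8 (two bars),
normalized to unit mass on its ±6 SD support *before* edge truncation;
truncated mass is reported, not redistributed.  The forward offset
encodes a delayed, smeared physiological response to the annotated
event; the offset and SD are configurable (including negative,
anticipatory offsets).  Melodic interest and melodic interaction are
pooled into a single Melody term; return/repose is parsed but excluded
from default designs because of its low occurrence.

**Starting factor.**  The onset-of-playing response is a piecewise
power law on the first t_end = 80 half-beats (20 bars):
`f(t) = t**(b1 m(t) + b2 a(t))` for t in 1..80 and 0 after, where m/a
indicate melody/accompaniment roles read off the musician's own map
restricted to the opening.  Defaults b1 = -0.2364 (opening-melody role)
and b2 = -0.0871 (accompaniment role) are means of per-performance
least-squares fits of t^b to opening score-time RR values; the fitting
routine (`fit_exponent`) works on the raw scale by default (log-log
offered), because normalized RR values near zero make the log map
unstable.  The lattice starts at t = 1 since 0^b diverges for negative
exponents.  t_end is configurable but has no piece-independent rule —
it is tailored to this movement's calm 20-bar opening.

### Estimation and inference

Estimation is maximum likelihood (not REML: AIC comparisons across
fixed-effect structures require ML).  For a single random intercept the
likelihood profiles analytically: given the variance ratio
lambda = sigma_u^2/sigma^2, the GLS coefficients and both variances
have closed forms via the Woodbury identity, leaving a 1-D bounded
optimization over log lambda (with lambda = 0 evaluated explicitly so
the no-random-effect boundary is exact).  This makes a full refit cost
microseconds-to-milliseconds, which the bootstrap and the calibration
studies depend on; the fitter is validated against an independent
general-purpose mixed-model implementation in the test suite (log
likelihood and coefficients agree to ~1e-6).

Inference is by stratified row bootstrap: rows are resampled with
replacement within each performance (preserving group sizes), the model
refit, and 2.5/97.5 percentiles of the refitted coefficients taken as
the 95% CI.  P-values re-center the bootstrap coefficient distribution
at zero — the no-effect null — and measure the two-tailed exceedance of
the observed estimate, p = 2·min(tails) with the (k+1)/(B+1)
correction, so p can never be exactly 0 and its resolution is
2/(B+1).  Resampling whole performances instead of rows is available
but statistically coarse with only nine groups.  Backward stepwise
elimination repeatedly removes the single term whose removal most
lowers AIC (AIC = -2 logLik + 2(k+2), counting fixed effects plus two
variance parameters), stopping at a fixed point; near-ties are broken
by dropping the higher-VIF term so the procedure is deterministic.
Eliminated terms are reported as "non-sign." in output tables.
Stepwise runs before the bootstrap; the bootstrap then covers the
reduced model.

Diagnostics: VIF_j = 1/(1 - R²_j) from OLS of predictor j on the
others; Cohen's f² = (R²_full - R²_without_term)/(1 - R²_full); the
mixed-model R² is not unique, so both a marginal (fixed-effects-only
squared correlation) and a conditional (fixed + predicted random
intercepts) flavour are always reported, with the marginal one used for
f².  Predictor correlation matrices (Pearson r with two-tailed p) flag
|r| ≥ 0.5 pairs.

## The synthetic-data generator

No public recordings of the study setting exist, so validation rests on
simulation.  The generator fabricates a 212-bar piece (sections of
4-12 bars with rotating melody leadership, two climax sections near
30% and 72% of the piece with crescendos leading in, sparse moments of
concern, a calm 20-bar opening with the cello leading over piano
accompaniment and the violin silent), per-musician note lists and
Interpretation Maps, and nine performances' beat times (base ~88 BPM
with a smooth tempo curve, ±2% per-performance tempo, 1% half-beat
timing jitter) and loudness curves.

The response is generated on the grid as exactly y = X beta + u + eps,
where X is built from those fixtures *by the public pipeline modules* —
a design-construction bug therefore breaks the recovery tests by
construction.  True coefficients default to the reference Model-Set-3
columns per musician (terms eliminated in the reference fits carry 0);
the random-intercept SD is 0.02; the noise SD defaults to the SD of the
fixed-effect signal itself, computed analytically from the realized
design, which places the fixed effects at roughly half the response
variance — the regime of the reference fits — without tuning toward any
R² value.  The grid response is then mapped to milliseconds by a fixed
affine back-map (700 + 200·y ms) and emitted as a beat-to-beat series
whose R-peak clock advances by the local interval; optional ectopic
beats halve an interval and push the remainder onto the next beat
(premature beat plus compensatory pause).  An optional AR(1) noise flag
exists purely to stress-test beyond the model's own iid assumption.

What the generator does *not* emulate: respiratory sinus arrhythmia and
other structured HRV spectra, audio (loudness fixtures are generated as
signals directly), inter-annotator disagreement, or any nonlinearity in
the music-to-RR mapping.  Passing recovery tests therefore shows that
the pipeline is a correct and well-calibrated implementation of the
model, not that the model is true of real performances.

### Scale bookkeeping in recovery experiments

The pipeline min-max normalizes each performance's RR series by its own
realized range, so fitted coefficients live on a per-run,
per-performance scale.  Recovery experiments invert this before
fitting, converting each performance's normalized response back to
generator units from the recorded normalization parameters and the
generator's fixed back-map constants.  This is unit bookkeeping from
run metadata — it never touches the true coefficients — and it is
exact, so bootstrap CIs retain their nominal meaning against the
generating values.

Two known, small systematic effects remain.  The R-peak clock samples
the wall-clock response more coarsely (~0.7-0.9 s) than the half-beat
grid (~0.34 s), so resampling back to the grid low-pass filters the
response; smooth predictors are essentially unaffected, but the tempo
coefficient is attenuated by the annotation jitter's high-frequency
content (observed ≈ +0.008 on a true -0.143).  The ectopic filter's
~1% false-removal rate on strongly noisy series has no measurable
effect after resampling.

## Numerical choices and degenerate inputs

* Normalization of degenerate (zero-range / zero-SD) input raises
  rather than returning zeros.
* Ectopic removal computes all running medians on the original series
  in one pass (window of 5 surrounding beats, 20% relative threshold,
  both configurable); removal is idempotent on physiological series.
* Rank-deficient fixed-effect matrices raise an error naming the
  collinear columns; constant predictor columns are reported the same
  way.  The fixture generator repairs the rare rank deficiencies that
  short synthetic pieces can produce (one category's spans tiling a
  union of others') by shifting a span boundary one bar.
* Gaussian kernels are evaluated on a ±6 SD support (<1e-8 mass
  beyond); score-time resampling clamps, never extrapolates.
* Stepwise AIC ties within 1e-9 are broken by VIF; every stochastic
  routine takes an explicit seed, which is recorded in output metadata.
* Cohen's f² is applied exactly as defined; with GLS coefficients and a
  correlation-based R² the nested-model R² difference can be slightly
  negative in finite samples, and such values are reported as-is rather
  than clamped to zero.

## Problem sizes

Recovery experiments use the full study geometry (9 performances ×
848 samples) with 100 replicates per musician.  The statistical
calibration studies (bootstrap type-I error at nominal 5%, CI coverage)
use reduced designs — 5-6 groups of 30-40 rows, B = 100-200, 300-500
replicates — chosen so the whole validation battery runs on a single
CPU in minutes while keeping Monte-Carlo error well below the asserted
bounds.

## Known limitations

* The loudness frontend is an energy surrogate; absolute sone values
  are not comparable to psychoacoustic toolchains (normalization makes
  the models invariant to this, but exported raw loudness is
  approximate and flagged as such).
* The AIC backward-stepwise rule retains a truly null term with
  asymptotic probability P(chi2_1 >= 2) ≈ 0.16; this is a property of
  AIC itself, not of the implementation.
* Whether the reference analysis normalized per performance or pooled
  per performer, and min-max or z-score, is not documented; both are
  implemented (per-performance min-max as default) and recorded in
  output metadata, without claiming the original choice.
* The starting factor's 80-half-beat extent is specific to this piece's
  opening; applying the pipeline to other repertoire requires
  re-tailoring t_end and refitting the exponents.
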