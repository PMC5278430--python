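# Methods

This note documents the models implemented in `echowing`, the numerical
choices behind them, and what the synthetic-data generators do and do
not emulate.

## The measurement model

### Reverberation-chamber absorption

A reverberation chamber measures random-incidence absorption by
comparing decay rates.  When a continuous ultrasonic excitation stops,
the sound level in a diffuse field decays linearly in dB; the
reverberation time `T60` is the time for a 60 dB drop.  For the empty
chamber the Sabine relation with an air-attenuation correction gives
the average surface absorption factor

    alpha_0 = 55.25 V / (c S T0) - 4 m1 V / S

with chamber volume `V` (m^3), interior surface `S` (m^2), speed of
sound `c` (m/s), and the air volume absorption coefficient `m1` (1/m).
Introducing an absorbent sample of planform area `S_w` shortens the
reverberation time from `T0` to `T1`; because the air term is common to
both measurements it cancels in the difference, and the sample
absorption factor is

    alpha_w = 55.25 V / (c S_w) * (1/T1 - 1/T0).

`m1` is the classical (Stokes–Kirchhoff) thermoviscous coefficient

    m(f) = (4 pi^2 f^2 / (rho c^3)) [ (4/3) mu + (gamma - 1) k / Cp ],

averaged in closed form over each third-octave band (the f^2 law makes
the band average `C (fh^3 - fl^3) / (3 (fh - fl))`).  Molecular
relaxation is deliberately excluded: over the centimetre-scale path
lengths of a bench-top chamber it is a negligible correction to the
decay, while the free-field propagation model used for detection
distances (below) includes it in full.

Absorption factors are reported raw, never clamped to [0, 1].
Measurement noise routinely produces values slightly outside the
physical range, and clamping would bias every spatial or per-set
average; a warning is logged instead.

### Analysis bands

Analyses run on preferred-centre 1/3-octave bands, base-2 convention
(`fh/fl = 2^(1/3)`, edges `fc * 2^(+-1/6)`).  The ultrasonic default is
the 8 preferred centres 20, 25, 31.5, 40, 50, 63, 80, 100 kHz, which is
what a balanced 8-level within-subject design requires.  A nine-band
variant (prepending 16 kHz) is selectable for workflows that count nine
consecutive bands ending at 100 kHz; no ninth *preferred* centre exists
strictly inside 20–100 kHz.

### T60 from a steady-state decay

Per band and microphone position:

1. **Bandpass.** Kaiser-window linear-phase FIR, passband `[fl, fh]`,
   stopband attenuation >= 80 dB.  The transition width defaults to 10%
   of the lower band edge; cutoffs are widened by half the transition
   so the nominal band sits inside the flat passband.  Filtering is
   forward-only with the integer group delay `(ntaps-1)/2` removed, so
   the recorded sound-offset time stays aligned and the decay remains
   causal.
2. **Envelope.** Magnitude of the analytic signal (Hilbert transform),
   then a centred moving average of 625 samples — 1 ms at the 625 kHz
   sampling rate the hardware chain uses.
3. **Noise-crossing time `tau_N`.** Iterative decay-line/noise-floor
   intersection: the floor is first estimated from the last 10% of the
   record; a line is regressed on the contiguous decay segment between
   the offset level and 5 dB above the floor; the line–floor
   intersection updates `tau_N`, and the floor is re-estimated beyond
   the crossing plus a safety interval (up to 5 iterations).  Late
   noise excursions are excluded from the fit because their time
   leverage would destroy the slope.  Conventions: a record whose tail
   is still decaying (no stationary floor) returns the record end; a
   record whose offset level is within 10 dB of the floor raises a
   "no decay" error.
4. **Schroeder integration.** Backward integration of the *squared*
   smoothed envelope between `tau_off` and `tau_N`, normalised to 0 dB
   at the offset.  Reverberation is an energy-decay concept, so the
   energy form is the default; an amplitude variant is available
   (`square=False`) since a magnitude envelope can also be integrated
   directly, and on an exponential decay the two differ only by a
   factor of two in the pre-log domain.
5. **Regression.** Least-squares line `L'(t) = A t + B` (time origin at
   the offset) fitted between 0 dB and `max(L(tau_N), -45 dB)`, then
   `T60 = -(60 + B)/A`.  The -45 dB floor was chosen to use as much of
   the decay as possible — a single band-limited decay realisation has
   few independent envelope samples (bandwidth x duration), so a wider
   fit range materially reduces estimator variance — while staying
   above the truncation- and noise-bent tail.  This presumes decays
   that span at least ~50 dB above the noise floor; noisier records
   fall back to the usable part of the curve.
6. **Spatial averaging.** The per-band reverberation time is the
   arithmetic mean of per-position T60 estimates (averaging T, not
   1/T).  Positions where estimation fails are excluded with a logged
   warning; the measurement errors out only if all fail.

### Wing planform area

Specimen photographs are modelled as dark wings on a white background
of known area `S_b`.  The image (colour collapsed by Rec. 601 luminance
weights) is smoothed with an edge-preserving bilateral filter (spatial
sigma 3 px, range sigma 10% of the intensity range — values chosen to
suppress sensor-like noise without moving wing edges), binarised by
two-class k-means++ on pixel intensities (5 restarts, best inertia,
deterministic for a fixed seed), and the cluster with the lower mean
intensity is labelled wing (flag-overridable).  The area is the pixel
fraction `S_w = (N_w / N) S_b`.  A constant image has no second cluster
and raises a "no contrast" error rather than returning an arbitrary
split.

### Detection distances

At the maximum detection distance the sonar equation balances detection
threshold, source level, two-way transmission loss
`2 (20 log10 r + lam r)` and target strength.  For two targets that are
identical except for wing absorption, the reflected-intensity ratio
`1 - alpha` is the only differing term; subtracting the two equations
leaves

    40 log10 r1 + 2 lam r1 - 10 log10(1 - alpha1)
        = 40 log10 r2 + 2 lam r2 - 10 log10(1 - alpha2),

solved in closed form on the principal branch of the Lambert W function
(`r1 = W(a e^b)/a` with `a = lam ln10 / 20`; the argument is positive
so exactly one real solution exists).  For `lam r2 < 1e-12` the
zero-attenuation limit `r1 = r2 ((1-alpha1)/(1-alpha2))^(1/4)` is used
instead, because the `W/a` form loses precision as `a -> 0`.  The
solution satisfies the defining equality to better than 1e-9 dB, and an
independent bisection root agrees to 1e-9 m.

The atmospheric attenuation factor `lam` (dB/m) is computed from the
standard humid-air absorption model (classical term plus O2 and N2
vibrational relaxation, the ISO 9613-1 formulation) as a function of
frequency, temperature, relative humidity and pressure.  A formula
implementation is reproducible where a tabulated source is not; the
test suite checks it against an independently coded arrangement of the
published equations.  Inputs are restricted to 1 kHz–1 MHz — the model
is used only at bat-sonar frequencies.

### Repeated-measures statistics

The measured table is a balanced split-plot (subject-by-treatment)
design: each wing set is a subject, preparation (or preparation group)
is the between-subjects factor, the analysis band is the within-subject
factor.  The battery:

* **Between-subjects ANOVA** — one-way ANOVA on each subject's marginal
  mean across bands; df = (g-1, N-g).  With the study design
  (9 preparations x 6 sets, 8 bands) this is (8, 45), and (2, 51) for
  the 3 preparation groups.
* **Sphericity** — Mauchly's W on the pooled within-group covariance of
  the band measures projected onto orthonormal contrasts, chi-square
  approximation with the pooled error df `N-g`; Greenhouse–Geisser
  epsilon from the same eigenstructure, clipped to [1/(k-1), 1].  The
  pooled within-group covariance (not the total covariance across all
  subjects) is the error covariance of the split-plot model; a pooled
  estimator that ignored the between factor would absorb group mean
  differences into apparent non-sphericity.
* **Within-subject ANOVA** — band main effect (k-1, (N-g)(k-1)) and
  between x band interaction ((g-1)(k-1), (N-g)(k-1)) against the
  subject-by-band residual; (7, 315) and (56, 315) for the preparation
  design, (7, 357) and (14, 357) for the group design.  Under the
  Greenhouse–Geisser correction p-values use epsilon-scaled,
  non-integer degrees of freedom directly in the F distribution.
* **Tukey–Kramer** — studentized-range pairwise comparisons with the
  Kramer adjustment for unequal n, either on marginal means or per band
  with each band's own one-way error term.  Per-band comparisons carry
  no additional multiplicity correction across bands; each band is
  reported at the usual 0.05/0.01/0.001 tiers.

The implementation uses the balanced closed-form decompositions; the
test suite cross-checks every statistic against independent
implementations (pingouin's mixed ANOVA and sphericity, statsmodels'
Tukey HSD, scipy's one-way ANOVA).

## Synthetic data: what it emulates, what it does not

**Decay recordings.** Gaussian noise band-limited with a Butterworth
filter (a different family from the analysis FIR, so generation and
analysis share no code path), multiplied after `tau_off` by
`exp(-3 ln10 (t - tau_off)/T60)` — an energy decay of exactly
60/T60 dB/s — plus an independent band-limited stationary noise floor
at a prescribed level below the steady state.  Paired chamber sets
invert the Sabine equations at prescribed `alpha0`/`alpha_w` to get the
nominal `T0`/`T1` and jitter each microphone position's T by a uniform
±2%, standing in for residual non-diffuseness of a real chamber.
Defaults mirror the hardware chain: 625 kHz sampling, 27 empty-chamber
positions, 4 positions per wing set, 6 sets per treatment.  Not
emulated: room modes, position-dependent coloration, transducer and
microphone responses, early non-exponential decay.  Passing round-trip
tests therefore shows the estimation chain is correct and unbiased
under ideal diffuse-field statistics, not that a physical chamber meets
those statistics.

**Wing images.** Non-overlapping ellipse unions at a dark grey level on
white, with additive Gaussian noise as a fraction of the contrast, and
the exact rendered pixel count as truth.  Real wings have translucent
margins, scale texture and shadows; only the pixel-count arithmetic and
the two-class separability are exercised.

**Absorption tables.** `alpha = mean(preparation, band) + b_subject +
eps`, with `b ~ N(0, 0.03^2)` shared across a subject's bands and
`eps ~ N(0, 0.05^2)` per record — magnitudes consistent with the
confidence intervals visible in published wing-absorption spectra.  The
default mean curves peak at 20–25 kHz, near 0.4 for chalcosiines and
0.6 for saturniids, with the male saturniids declining most steeply.
The subject effect induces a compound-symmetric within-subject
covariance, so the null-calibration tests run under sphericity; real
spectra are smoother across neighbouring bands than this model.

## Problem sizes and tolerances in the test suite

Round-trip tolerances are 5% (T60 recovery as a median over a
10–50 ms x (-50..-70 dB) grid, 20 seeds per cell; absorption factors
0.1–0.6 as medians over 10–20 seeds at the study's measurement volume),
2% for image areas, 1e-9 m for the Lambert-W/bisection agreement, and
exact df structure for the statistics.  The wing-set round trip fixes
the empty-chamber absorption at 0.1: a usable reverberation chamber is
by construction weakly absorbing (long `T0`), and the difference method
loses sensitivity quadratically as `T0` shrinks — with `alpha_0 = 0.6`
the chamber's own 7.6 ms reverberation time leaves a wing-induced
change of well under a millisecond, below what ±2% spatial jitter over
4 positions can resolve.  This sensitivity limit is a property of the
method, and the synthetic fixtures are sized to stay on the usable side
of it, as the physical design of low-absorption chambers does.

The fixture chamber is a 20 cm Perspex cube (`V = 0.008 m^3`,
`S = 0.28 m^2` including diffuser relief) with wing sets covering up to
half its floor (`S_w = 0.02 m^2`), and air properties default to
standard 20 °C values.

## Known limitations

* Steady-state decay only; no impulse-response (MLS/sweep) methods.
* The Sabine difference form assumes identical air conditions for the
  paired measurements and no coverage correction for the floor area the
  sample occupies.
* The classical `m1` underestimates total air absorption at ultrasonic
  frequencies (no relaxation term); inside a small chamber the `4 m1 V`
  term is a ~1% correction, but the same coefficient should not be used
  for free-field propagation — the detection model uses the full
  humid-air formulation instead.
* T60 estimation assumes a single exponential decay at least ~50 dB
  above the noise floor; double-slope decays are fitted as one line.
* The statistics assume a balanced design; only Tukey–Kramer handles
  unequal group sizes.
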