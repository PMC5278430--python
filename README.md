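# echowing

Ultrasound absorption of moth wings, measured the reverberation-chamber
way — a Python library for the complete analysis pipeline behind
comparative studies of anti-bat acoustic camouflage.

Nocturnal moths under echolocating-bat predation carry wing scales that
absorb a large fraction of an incident ultrasonic cry, dimming the echo
the bat receives.  Quantifying that absorbance takes four linked
analyses, all implemented here:

1. **Reverberation-time estimation** (`echowing.reverb`): a steady-state
   ultrasonic excitation inside a small reverberation chamber is switched
   off and the recorded decay is reduced to a T60 per 1/3-octave band —
   Kaiser-window bandpass (>= 80 dB stopband), Hilbert envelope with 1 ms
   smoothing, iterative noise-crossing detection, Schroeder backward
   integration, and linear extrapolation to -60 dB.
2. **Absorption factors** (`echowing.absorption`): Sabine-type
   conversion of spatially averaged reverberation times, with a
   band-averaged classical air-attenuation correction `m1`:
   `alpha_0 = 55.25 V/(c S T0) - 4 m1 V/S` for the empty chamber and
   `alpha_w = 55.25 V/(c S_w) (1/T1 - 1/T0)` for an introduced wing set.
3. **Wing planform area** (`echowing.wing_area`): bilateral smoothing +
   two-class k-means++ binarisation of a top-down photograph on a white
   background of known area; `S_w = (N_w/N) S_b`.
4. **Detection distances** (`echowing.detection`): the sonar-equation
   comparison of two targets differing only in wing absorption, solved
   in closed form with the Lambert W function, with humid-air
   atmospheric attenuation (ISO 9613-1 form).
5. **Statistics** (`echowing.stats`): the repeated-measures battery for
   a preparations x sets x bands design — between-subjects ANOVA on
   marginal means, Mauchly sphericity, Greenhouse–Geisser-corrected
   within-subject ANOVA, and Tukey–Kramer pairwise comparisons overall
   or per band.

Because chamber recordings and specimens are laboratory artefacts, the
package ships a first-class synthetic-data module
(`echowing.synthetic`) that generates every input with known ground
truth: band-limited exponential decays with prescribed T60 and noise
floor, paired empty/wings recording sets obtained by inverting the
Sabine equations, wing-silhouette images with exact pixel counts, and
balanced 9-preparation x 6-set x 8-band absorption tables.

## Worked example

```bash
python examples/absorption_roundtrip.py
```

```
T0 (empty, 27 positions): 45.81 ms (true 45.41 ms)
T1 (wings, 4 positions): 33.51 ms (true 33.57 ms)
empty-chamber alpha0: 0.099  (true 0.100)
wing-set alpha_w    : 0.516  (true 0.500)
```

A synthetic 20 cm chamber with empty-chamber absorption 0.1 receives a
wing set of absorption 0.5 covering half its floor.  Reverberation
times estimated from 27 (empty) and 4 (wings) microphone positions
shorten from ~45 to ~34 ms; the Sabine equations convert the pair back
to absorption factors within a few percent of the generating truth —
the residual reflects per-position spatial jitter and single-decay
realisation noise, exactly the error sources a physical chamber has.

`python examples/stats_battery.py` runs the full statistical battery on
a synthetic 9-preparation table (between-subjects F(8,45), Mauchly,
GG-corrected F(7,315) and F(56,315), Tukey–Kramer), and
`python examples/detection_distance.py` prints the percentage
detection-distance reduction per band for a more- vs less-absorbent
target pair.

See `docs/methods.md` for the models, defaults and their rationale.

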