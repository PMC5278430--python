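"""Estimate the reverberation time of a synthetic steady-state decay.

A band-limited noise burst with a known T60 of 25 ms and a -60 dB noise
floor is synthesized, then pushed through the full analysis chain:
Kaiser bandpass, Hilbert envelope, 1 ms smoothing, noise-crossing
detection, Schroeder backward integration and linear regression.
"""

from echowing import Band, recording_t60
from echowing.synthetic import DecaySpec, gen_decay_recording

band = Band.from_centre(20_000.0)
spec = DecaySpec(band=band, t60_true=0.025, steady_dur=0.015,
                 record_dur=0.25, noise_floor_db=-60.0, seed=1)
rec = gen_decay_recording(spec, fs=625_000.0)

t60, tau_n, slope = recording_t60(rec, band)
print(f"true T60          : {spec.t60_true * 1e3:.2f} ms")
print(f"estimated T60     : {t60 * 1e3:.2f} ms")
print(f"noise-crossing    : {tau_n * 1e3:.1f} ms after recording start")
print(f"Schroeder slope   : {slope:.0f} dB/s")
print("The estimate should sit within a few percent of the true value;")
print("the slope times T60 is -60 dB by construction of the decay.")
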