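"""Brightness-adjusted photobleaching half-time of a simulated decay.

Simulates a mono-exponential bleaching trace, puts it on the standard
1,000 photons/s/molecule scale using StayGold's photophysics, and reports the
half-time.  The normalized half-time equals scale_factor * ln2 / k: brighter
fluorophores burn through their photon budget faster, so the same raw decay
corresponds to a longer standardized half-time.
"""

import math

import fp_photodyn as fp

spectra = fp.load_reference_spectra()
sp = spectra["StayGold"]

k = 0.005  # raw bleaching rate, 1/s
trace, truth = fp.simulate_bleach_trace(k=k, noise_cv=0.0, n_points=2400, dt=1.0)
curve = fp.normalize_trace(trace, sp)
result = fp.half_time(curve)

print(f"fluorophore:          {sp.name}")
print(f"initial emission rate {fp.initial_emission_rate(sp, 5.6, 488.0):.0f} photons/s/molecule")
print(f"time-axis scale:      {curve.scale_factor:.3f}")
print(f"raw half-life ln2/k:  {math.log(2) / k:.1f} s")
print(f"normalized t1/2:      {result.t_half:.1f} s (expected {curve.scale_factor * math.log(2) / k:.1f})")
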