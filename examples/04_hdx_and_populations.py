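"""HDX exchange times -> unfolding rates; peak volumes -> populations.

Fits single-exponential decays to synthetic imino-proton HDX series on the
sparse experimental grid (10 min ... 24 h) to fix the unfolding rates k4
and k5, then estimates the G4(I)/G4(II) population split from reporter
peak volumes at the 5fC4 regime.
"""

from quadkin import (
    NoiseSpec,
    estimate_populations,
    gen_hdx_series,
    gen_peak_table,
    hdx_exchange_time,
    unfolding_rate_from_hdx,
)

for label, tau_true in (("G4(I) middle tetrad", 25.0), ("G4(II) middle tetrad", 3800.0)):
    series = gen_hdx_series(tau_true, noise=NoiseSpec(0.02, seed=2))
    fit = hdx_exchange_time(series)
    rate = unfolding_rate_from_hdx(fit)
    print(f"{label:22s} tau = {fit.tau:7.0f} min  ->  k_unfold = {rate:.2e} min^-1")

table = gen_peak_table(0.85, noise=NoiseSpec(0.05, seed=2))
est = estimate_populations(table)
print(f"\n5fC4 peak volumes (G16, G18): G4(I) fraction = {est.fraction_g4i:.2f} "
      f"(dispersion {est.dispersion:.3f})")
print()
print("Exchange only counts unfolding, so 1/tau gives k4 (~0.04 min^-1) and")
print("k5 (~2.6e-4 min^-1).  The ~0.85 G4(I) fraction matches the dominant")
print("intermediate fold that 5-formylcytosine stabilizes.")
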