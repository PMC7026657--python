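"""Melting temperatures by the first-derivative rule.

Generates sloped sigmoidal CD melting curves at the published midpoints of
WT22m (73.0 C) and its T4 substitution (69.2 C), then locates Tm as the
extremum of the first derivative of the baseline-subtracted signal.
"""

from quadkin import NoiseSpec, estimate_tm, gen_melting_curve, get_variant

for name in ("WT22m", "WT22m-T4"):
    tm_true = get_variant(name).tm_expected
    curve = gen_melting_curve(tm_true, noise=NoiseSpec(sigma_rel=0.01, seed=3))
    tm, err = estimate_tm(curve)
    print(f"{name:10s} true Tm {tm_true:5.1f} C  ->  estimated {tm:5.2f} +/- {err:.2f} C")

print()
print("The ~4 C drop on replacing C4 with T reflects the lost stabilization")
print("of the G4(II) fold; the derivative estimator recovers each midpoint")
print("to a fraction of the 1-C temperature grid.")
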