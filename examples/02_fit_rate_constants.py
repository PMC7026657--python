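"""Constrained dual-wavelength global fit of the folding rates k2, k3.

Generates noisy 265-nm and 295-nm kinetic traces from the published WT22m
regime, fixes k1, k4, k5 at their measured values and fits k2, k3 jointly.
Illustrates the key identifiability caveat: on a 1-min grid the unfolded
ensemble is quasi-steady, so the branch ratio k3/k2 is pinned down sharply
while the absolute scale of k2 and k3 is nearly flat.
"""

from quadkin import NoiseSpec, fit_kinetics, gen_cd_traces, get_variant

k_true = get_variant("WT22m").rates
traces = gen_cd_traces(k_true, noise=NoiseSpec(sigma_rel=0.02, seed=1))

result = fit_kinetics(
    list(traces),
    fixed={"k1": k_true.k1, "k4": k_true.k4, "k5": k_true.k5},
)

print(f"true  k2 = {k_true.k2:8.1f}  k3 = {k_true.k3:7.2f}  "
      f"ratio k3/k2 = {k_true.k3 / k_true.k2:.4f}")
print(f"fitted k2 = {result.k.k2:8.3g}  k3 = {result.k.k3:7.3g}  "
      f"ratio k3/k2 = {result.ratio_k3_k2:.4f} +/- {result.ratio_stderr:.4f}")
print(f"scale flagged uninformative: {result.uninformative}")
print()
print("The fitted ratio reproduces the true branch partition to ~1%, which")
print("is what fixes the equilibrium G4(I)/G4(II) split; the absolute k2")
print("is not constrained by these traces (see docs/methods.md).")
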