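# Methods

## The four-state model

States are ordered (A, B, D, C) = (Hp, G4(I), U, G4(II)) everywhere in the
package (`quadkin.kinetics.STATE_ORDER`).  The wiring is

* A → B at k1 (hairpin unfolding is rate-limiting for G4(I) appearance;
  the brief unfolded stretch between Hp and G4(I) is coarse-grained away),
* B ⇄ D at k4 (unfold) / k2 (refold),
* D ⇄ C at k3 (fold) / k5 (unfold),

with no edge back into A: the hairpin imino signals vanish after K⁺
addition, so hairpin reformation is negligible.  U is a single well-mixed
lumped state for all intermediate/unfolded species; it carries no internal
structure.  All rates are min⁻¹, all times minutes, because every measured
time constant in this system (4 min arising, 25/3800 min HDX, ~250 min
interconversion) is naturally expressed in minutes.

The generator M (columns sum to zero, off-diagonal (j,i) = rate i→j) is
solved exactly: x(t) = V e^{Λt} V⁻¹ x0.  If the eigenvector matrix is
ill-conditioned (condition number > 1e12, i.e. a near-defective generator)
the propagation falls back to `scipy.linalg.expm` per time point with a
warning.  Structurally repeated zero eigenvalues (e.g. only one edge
active) are benign and do not trigger the fallback.  Populations within
−1e−9 of zero are clipped to zero.  The default initial condition is pure
hairpin (1, 0, 0, 0) at the moment of K⁺ addition; it is overridable.

Equilibrium of the B/D/C subsystem follows from detailed balance on the
two reversible edges: B : D : C = (k2/k4) : 1 : (k3/k5), normalized.  The
slow relaxation time is 1/λ_slow where λ_slow is the smaller root of
λ² − λ(k2+k3+k4+k5) + (k4k3 + k4k5 + k2k5) = 0, computed in the
cancellation-free form 2p/(s+√(s²−4p)) because the two roots differ by four
orders of magnitude in the published regime.

## Fitting protocol

**Exponential fits.**  `fit_exponential` fits offset ± amplitude·e^{−t/τ}
by multi-start nonlinear least squares (four τ starts spanning the sampling
window; τ on a log scale).  For decays, a 2-parameter decay-to-zero model
and a 3-parameter decay-to-floor model are both fitted and the floor is
kept only when an F-test at α = 0.01 favors it.  Rationale: the HDX floor
(residual protonation/peak overlap) is real and must not bias τ when the
data show it, but on the sparse 5-point HDX grid spanning only ~0.4·τ for
the slow G4(II) proton, a free offset is nearly collinear with the decay
and destroys the τ estimate (median error ~90% with the offset always
free, ~5% with the F-test gate, at 2% noise).

**Global CD fit.**  `fit_kinetics` fits k2, k3 to the 265-nm and
290/295-nm traces jointly with k1, k4, k5 fixed (returned bit-exactly).
Each trace is normalized to unit maximum absolute signal so neither
channel dominates; points are equally weighted within a trace.  At each
trial (log k2, log k3) the linear parameters per channel — baseline, c_B,
c_C — are solved by linear least squares (variable projection); Hp and U
coefficients default to zero but the design can be extended.  The log
parameterization enforces positivity and tames the ~10× scale difference
between k2 and k3.  Optimization: a 5×5 log-spaced start grid over
k2 ∈ [10, 2000], k3 ∈ [1, 500] is screened by residual norm, the best 3
starts are polished by trust-region least squares (hard log-bounds at
[1e−6, 1e8] keep trial steps finite), and the result is refined by a
nested profile search — an outer scan-plus-Brent over log k2 with the
ratio log k3 − log k2 re-optimized by a bounded 1-D search at every trial
— because the least-squares surface is a long curved valley (next section)
in which plain quadratic steps stall.  Standard errors come from the
Jacobian covariance of the projected residual at the optimum;
`ratio_k3_k2` and its delta-method standard error are reported alongside
k2 and k3, and a flat scale direction (log-scale stderr > 1) sets the
`uninformative` flag.

### Identifiability of k2 and k3

Under the published WT22m regime (k2+k3 ≈ 583 min⁻¹) the unfolded ensemble
relaxes in ~0.1 min and holds ~1e−5 of the population, so on any practical
CD sampling grid U is quasi-steady.  In that limit the observable dynamics
depend on the folding rates only through the branch ratio r = k3/k2: the
effective B→C and C→B rates are k4·r/(1+r) and k5/(1+r), and the
equilibrium B/C ratio is (k2k5)/(k3k4) = (k5/k4)/r.  Numerically, scaling
(k2, k3) by 10 at fixed r changes the noiseless traces by < 5×10⁻⁴ of the
signal amplitude, and with the ratio re-optimized the residual is flat to
machine precision from k2 ≈ 10 up to 10⁸.  Consequences, verified by the
test suite:

* the branch ratio, the equilibrium partition and the slow relaxation time
  are recovered to ~1% (noiseless) and a few percent (2% noise);
* the absolute scale of k2 and k3 is not recoverable from these traces —
  under noise the maximum-likelihood scale wanders over orders of
  magnitude (typically collapsing low, where the model gains transient
  shape freedom to absorb noise), and the formal 1-σ coverage of k2 is far
  from nominal;
* absolute recovery works exactly when the scale is physically resolvable,
  i.e. when the fast relaxation 1/(k2+k3) spans several grid steps
  (demonstrated at k2+k3 ≈ 0.9 min⁻¹ in the tests).

The package therefore treats the ratio as the primary fitted quantity and
reports the absolute rates with the `uninformative` flag when the scale
direction is flat.

**Uncertainties.**  Jacobian-covariance standard errors are the default;
`fit_exponential` additionally reports τ·SE(log τ).  No bootstrap is run
by default; the residual structure is white by construction in the
synthetic setting.

## Auxiliary estimators

**Tm.**  A line fitted to the coolest and hottest 10% of points is
subtracted; the first derivative is taken with a Savitzky–Golay filter
(window 7, order 2 — a 1 °C grid with experimental-scale noise makes raw
differencing unusable; both exposed as arguments); Tm is the vertex of a
quadratic fitted to |derivative| over ±6 grid points around its extremum.
The wide vertex window averages derivative noise: at 1% noise the
estimator stays within ±0.43 °C of the generator midpoint across 400
seeded draws, versus ~±1.3 °C with a 3-point vertex.  Using |derivative|
makes the rule channel-agnostic (signal may rise or fall on melting); the
reported uncertainty is the delta-method vertex error floored at half the
grid step.  A curve whose baseline-subtracted span is within 5× the local
noise (estimated from second differences) raises a no-transition error.

**Populations.**  fraction_G4(I) = V_I/(V_I+V_II) per reporter residue
(G16 and G18 by default — the two imino peaks resolved for both
conformers), averaged over reporters; the max−min spread above 0.15 flags
discordant reporters (with only two reporters and no published concordance
criterion, a warning rather than an error).

**HDX.**  `hdx_exchange_time` delegates to the decay exponential fit and
rejects series that rise overall; `unfolding_rate_from_hdx` returns 1/τ,
which is how k4 and k5 are fixed (exchange counts unfolding only, not the
~10×-slower net interconversion).

## Synthetic data

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`; every generator/estimator pair round-trips
exactly without noise.

* **CD traces**: forward model (default grid 1…600 min at 1-min steps,
  matching the fitted experimental window) plus additive Gaussian noise
  with σ = 0.02 × max|signal| per channel.  The 2% default is an
  assumption — no noise magnitude is published — chosen as typical of
  smoothed CD kinetic traces.  Default response: 265 nm = (c_B, c_C) =
  (1.0, 0.2), 295 nm = (0.1, 1.0); the minor cross-terms encode the
  secondary bands each fold shows at the other wavelength.
* **Melting curves**: θ(T) = 1/(1+e^{(T−tm)/width}) mixed between sloping
  folded/unfolded baselines on a 10–95 °C, 1 °C grid (a 1 °C/min ramp
  sampled each minute), width 3 °C, 1% noise.  A logistic rather than a
  van't Hoff two-state form: only the derivative-extremum location matters
  to the estimator, and the logistic places the truth exactly at tm.
* **HDX series**: floor + v0·e^{−t/τ} on the experimental grid
  (10, 30, 60, 120, 1440 min) with multiplicative noise.
* **Peak tables**: volumes (f·V, (1−f)·V) per reporter with independent
  multiplicative noise.
* **Variants**: the nine published 22-mers with their single substitutions
  or cytosine modifications, melting temperatures, NMR G4(I) populations
  and (where fitted) kinetic regimes.  Modified cytosines map to parameter
  lookups only; no chemistry is modelled.

What the generators do **not** emulate: baseline drift and instrument
response of real CD kinetics, correlated noise, peak overlap and phasing
errors in NMR integrals, concentration effects, or temperature dependence
of the rate constants.  Passing tests therefore demonstrate estimator
correctness under the stated statistical model, not robustness to every
instrumental artifact.

## Problem sizes and determinism

Default problem sizes — 600-point dual traces, 86-point melting curves,
5-point HDX series, 100-replicate oracle comparisons and 200-replicate
recovery/calibration studies — are chosen so the full suite and the
acceptance script each run in minutes on one core while keeping Monte
Carlo error well below the tolerances being checked.  All stochastic
stages take explicit integer seeds; the pipeline spawns per-stage seeds
from a master seed via `numpy.random.SeedSequence` and records them in its
report, which is byte-identical for identical (config, seed).

## Known limitations

* The kinetic scheme is fixed; no model selection over alternative wirings.
* No stochastic (single-molecule) simulation; populations are deterministic
  ensemble fractions.
* The CD-signature rule is a qualitative three-way label from tetrad
  hydrogen-bonding directionality, not a spectrum calculation.
* Melting curves yield Tm only; no ΔH/ΔS extraction.
* Single-exponential HDX only; overlapping imino peaks are out of scope.
* The 290 nm vs 295 nm channel labels are treated as the same
  G4(II)-reporting channel and stored verbatim.
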