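"""Synthetic inputs with the statistical structure the estimators assume.

Every stage of the analysis can be exercised without instrument data:
dual-wavelength CD kinetic traces are generated from the four-state model
plus additive Gaussian noise, melting curves as two-state sigmoids over
sloping baselines, HDX series as single-exponential decays, and peak-volume
tables at a chosen conformer ratio.  All generators are pure functions of
(parameters, seed).

The built-in sequence variants carry the published WNT1-promoter 22-mer
family (WT22m and its single-position substitutions and cytosine
modifications) together with their melting temperatures and, where
measured, their kinetic regimes and NMR-derived G4(I) populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import PURE_HAIRPIN, RateConstants, solve_populations
from .nmr import HDXSeries, MeltingCurve, PeakVolumeTable
from .observables import CDCoefficients, CDTrace, cd_signal

__all__ = [
    "SequenceVariant",
    "NoiseSpec",
    "builtin_variants",
    "get_variant",
    "gen_cd_traces",
    "gen_melting_curve",
    "gen_hdx_series",
    "gen_peak_table",
    "DEFAULT_COEFF_265",
    "DEFAULT_COEFF_295",
    "HDX_DEFAULT_GRID",
]

#: Default relative noise on CD kinetic traces (fraction of max amplitude).
DEFAULT_SIGMA_REL = 0.02

#: HDX sampling grid in minutes: 10 min, 30 min, 1 h, 2 h, 24 h.
HDX_DEFAULT_GRID = (10.0, 30.0, 60.0, 120.0, 1440.0)

#: Default linear CD response per channel.  The 265-nm channel reports
#: G4(I) with a minor G4(II) shoulder; the 295-nm channel the reverse.
DEFAULT_COEFF_265 = CDCoefficients(wavelength=265.0, c_b=1.0, c_c=0.2)
DEFAULT_COEFF_295 = CDCoefficients(wavelength=295.0, c_b=0.1, c_c=1.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise level (s.d. as a fraction of max amplitude) and seed."""

    sigma_rel: float = DEFAULT_SIGMA_REL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SequenceVariant:
    """One member of the WT22m family.

    ``sequence`` is the plain 5'->3' base string; ``modifications`` maps
    1-based positions to modified-cytosine codes (5mC, 5hmC, 5fC, 5caC).
    ``tm_expected`` is the published melting temperature where measured,
    ``rates`` the published kinetic regime where the transition was fitted,
    and ``population_g4i`` the NMR-estimated equilibrium G4(I) fraction.
    """

    name: str
    sequence: str
    modifications: dict[int, str] = field(default_factory=dict)
    tm_expected: float | None = None
    rates: RateConstants | None = None
    population_g4i: float | None = None

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence must be over {A, C, G, T}")
        for pos, code in self.modifications.items():
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside sequence")
            if code not in {"5mC", "5hmC", "5fC", "5caC"}:
                raise ValueError(f"unknown modification code {code}")
            if self.sequence[pos - 1] != "C":
                raise ValueError(f"modification at position {pos} must sit on a C")


_WT22M = "GGGCCACCGGGCAGTGGGCGGG"


def _sub(pos: int, base: str) -> str:
    return _WT22M[: pos - 1] + base + _WT22M[pos:]


def builtin_variants() -> list[SequenceVariant]:
    """The published WT22m variant family with Tm, kinetics and populations."""
    return [
        SequenceVariant(
            "WT22m", _WT22M, tm_expected=73.0,
            rates=RateConstants(0.23, 533.0, 50.0, 0.037, 2.7e-4),
            population_g4i=0.10,
        ),
        SequenceVariant("WT22m-T4", _sub(4, "T"), tm_expected=69.2, population_g4i=1.0),
        SequenceVariant("WT22m-T5", _sub(5, "T")),
        SequenceVariant("WT22m-T7", _sub(7, "T")),
        SequenceVariant("WT22m-T8", _sub(8, "T")),
        SequenceVariant(
            "WT22m-5mC4", _WT22M, modifications={4: "5mC"}, tm_expected=73.0,
            rates=RateConstants(0.12, 1173.0, 147.0, 0.029, 1.7e-4),
            population_g4i=0.20,
        ),
        SequenceVariant(
            "WT22m-5hmC4", _WT22M, modifications={4: "5hmC"}, tm_expected=69.5,
            population_g4i=0.65,
        ),
        SequenceVariant(
            "WT22m-5fC4", _WT22M, modifications={4: "5fC"}, tm_expected=69.5,
            rates=RateConstants(0.58, 653.0, 73.0, 0.027, 0.023),
            population_g4i=0.85,
        ),
        SequenceVariant(
            "WT22m-5caC4", _WT22M, modifications={4: "5caC"}, tm_expected=69.5,
            population_g4i=0.70,
        ),
    ]


def get_variant(name: str) -> SequenceVariant:
    for v in builtin_variants():
        if v.name == name:
            return v
    raise KeyError(f"unknown variant {name!r}")


def gen_cd_traces(
    k: RateConstants,
    coeff265: CDCoefficients = DEFAULT_COEFF_265,
    coeff295: CDCoefficients = DEFAULT_COEFF_295,
    grid=None,
    noise: NoiseSpec = NoiseSpec(),
    x0=PURE_HAIRPIN,
) -> tuple[CDTrace, CDTrace]:
    """Dual-wavelength CD kinetic traces from the four-state forward model.

    Default grid: 1-min spacing out to 600 min.  Additive Gaussian noise
    with s.d. = sigma_rel * max|signal| per channel, one seeded generator
    for both channels (deterministic given the seed).
    """
    if grid is None:
        grid = np.arange(1.0, 601.0)
    grid = np.asarray(grid, dtype=float)
    traj = solve_populations(k, x0, grid)
    rng = noise.rng()
    out = []
    for coeff in (coeff265, coeff295):
        tr = cd_signal(traj, coeff)
        sigma = noise.sigma_rel * np.max(np.abs(tr.signal))
        if sigma > 0:
            tr.signal = tr.signal + rng.normal(0.0, sigma, tr.signal.size)
        out.append(tr)
    return out[0], out[1]


def gen_melting_curve(
    tm: float,
    width: float = 3.0,
    folded_baseline: tuple[float, float] = (1.0, -0.002),
    unfolded_baseline: tuple[float, float] = (0.05, -0.0005),
    grid=None,
    noise: NoiseSpec = NoiseSpec(sigma_rel=0.01),
    wavelength: float = 295.0,
) -> MeltingCurve:
    """Two-state sigmoidal melting curve with sloping baselines.

    The folded fraction is theta(T) = 1/(1+exp((T-tm)/width)); the signal
    mixes folded and unfolded linear baselines (each an (offset, slope)
    pair) through theta, so the derivative extremum of the noiseless,
    baseline-subtracted curve sits at ``tm``.  Default grid 10-95 degC in
    1-degC steps, matching a 1 degC/min ramp sampled each minute.
    """
    if not 10.0 < tm < 95.0:
        raise ValueError("tm must lie inside the 10-95 degC window")
    if width <= 0:
        raise ValueError("width must be positive")
    if grid is None:
        grid = np.arange(10.0, 96.0)
    temp = np.asarray(grid, dtype=float)
    theta = 1.0 / (1.0 + np.exp((temp - tm) / width))
    fold = folded_baseline[0] + folded_baseline[1] * temp
    unfold = unfolded_baseline[0] + unfolded_baseline[1] * temp
    signal = theta * fold + (1.0 - theta) * unfold
    sigma = noise.sigma_rel * (signal.max() - signal.min())
    if sigma > 0:
        signal = signal + noise.rng().normal(0.0, sigma, signal.size)
    return MeltingCurve(temperatures=temp, ellipticity=signal, wavelength=wavelength)


def gen_hdx_series(
    tau: float,
    grid=HDX_DEFAULT_GRID,
    v0: float = 1.0,
    floor: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
    residue: str = "G21",
) -> HDXSeries:
    """Imino-proton HDX decay: floor + v0*exp(-t/tau), multiplicative noise."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = np.asarray(grid, dtype=float)
    v = floor + v0 * np.exp(-t / tau)
    if noise.sigma_rel > 0:
        v = v * (1.0 + noise.rng().normal(0.0, noise.sigma_rel, v.size))
    return HDXSeries(residue=residue, times=t, volumes=np.clip(v, 0.0, None))


def gen_peak_table(
    fraction_g4i: float,
    residues: tuple[str, ...] = ("G16", "G18"),
    total_volume: float = 100.0,
    noise: NoiseSpec = NoiseSpec(sigma_rel=0.0),
) -> PeakVolumeTable:
    """Reporter peak volumes at a given conformer ratio.

    Each residue gets volumes (f*V, (1-f)*V) with independent multiplicative
    noise on the two peaks; the noiseless table round-trips the fraction
    exactly through ``estimate_populations``.
    """
    if not 0.0 <= fraction_g4i <= 1.0:
        raise ValueError("fraction_g4i must be in [0, 1]")
    n = len(residues)
    vi = np.full(n, fraction_g4i * total_volume)
    vii = np.full(n, (1.0 - fraction_g4i) * total_volume)
    if noise.sigma_rel > 0:
        rng = noise.rng()
        vi = np.clip(vi * (1.0 + rng.normal(0.0, noise.sigma_rel, n)), 0.0, None)
        vii = np.clip(vii * (1.0 + rng.normal(0.0, noise.sigma_rel, n)), 0.0, None)
    return PeakVolumeTable(residues=tuple(residues), vol_g4i=vi, vol_g4ii=vii)
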