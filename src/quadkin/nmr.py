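"""HDX exchange times, conformer populations, and CD-melting Tm.

Three estimators that turn the auxiliary measurements into numbers the
kinetic model consumes:

* ``hdx_exchange_time`` — single-exponential decay of an imino-proton peak
  volume after dissolution in D2O; the time constant is the hydrogen-bond
  opening (unfolding) time, because exchange only counts unfolding, not
  refolding.  ``unfolding_rate_from_hdx`` inverts it into k4 or k5.
* ``estimate_populations`` — G4(I)/G4(II) fractions from the peak volumes of
  reporter imino protons (G16 and G18 by default), one resolved peak per
  conformer.
* ``estimate_tm`` — melting temperature from a CD melting curve, defined as
  the extremum of the first derivative of the baseline-subtracted signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .estimation import ExponentialFit, fit_exponential, time_to_rate

__all__ = [
    "HDXSeries",
    "PeakVolumeTable",
    "MeltingCurve",
    "PopulationEstimate",
    "hdx_exchange_time",
    "unfolding_rate_from_hdx",
    "estimate_populations",
    "estimate_tm",
    "NoTransitionError",
]

#: Reporter residues whose imino peaks are resolved for both conformers.
DEFAULT_REPORTERS = ("G16", "G18")

#: Spread across reporters above which the estimate is flagged discordant.
DISPERSION_WARN_THRESHOLD = 0.15


class NoTransitionError(ValueError):
    """Melting curve shows no resolvable transition."""


@dataclass
class HDXSeries:
    """Peak volumes of one residue's imino proton vs time in D2O (minutes)."""

    residue: str
    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and increasing")
        if self.volumes.shape != self.times.shape:
            raise ValueError("volumes and times must have equal length")
        if np.any(self.volumes < 0):
            raise ValueError("peak volumes must be non-negative")


@dataclass
class PeakVolumeTable:
    """Rows of (residue, volume in the G4(I) form, volume in the G4(II) form)."""

    residues: tuple[str, ...]
    vol_g4i: np.ndarray
    vol_g4ii: np.ndarray

    def __post_init__(self) -> None:
        self.vol_g4i = np.asarray(self.vol_g4i, dtype=float)
        self.vol_g4ii = np.asarray(self.vol_g4ii, dtype=float)
        n = len(self.residues)
        if self.vol_g4i.shape != (n,) or self.vol_g4ii.shape != (n,):
            raise ValueError("volume arrays must match the residue list")
        if np.any(self.vol_g4i < 0) or np.any(self.vol_g4ii < 0):
            raise ValueError("volumes must be non-negative")
        if not np.any(self.vol_g4i + self.vol_g4ii > 0):
            raise ValueError("at least one residue must have positive total volume")


@dataclass
class MeltingCurve:
    """CD ellipticity vs temperature, nominally 10-95 degC at 1 degC/min."""

    temperatures: np.ndarray
    ellipticity: np.ndarray
    wavelength: float = 295.0

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.temperatures.size < 20:
            raise ValueError("melting curve needs at least 20 points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be increasing")
        if self.ellipticity.shape != self.temperatures.shape:
            raise ValueError("ellipticity and temperatures must have equal length")


@dataclass
class PopulationEstimate:
    """G4(I)/G4(II) fractions averaged over reporter residues."""

    fraction_g4i: float
    fraction_g4ii: float
    per_residue_fractions: dict[str, float]
    dispersion: float
    discordant: bool = False


def hdx_exchange_time(series: HDXSeries) -> ExponentialFit:
    """Exchange time of one imino proton from its volume decay in D2O.

    A constant offset is included to absorb residual protonation or peak
    overlap.  A series whose volumes rise overall cannot be exchange decay
    and is rejected.
    """
    if series.times.size < 4:
        raise ValueError("need at least 4 HDX time points")
    if series.volumes[-1] > series.volumes[0]:
        raise ValueError(
            f"HDX series for {series.residue} rises; exchange volumes cannot grow"
        )
    return fit_exponential((series.times, series.volumes), direction="decay")


def unfolding_rate_from_hdx(fit: ExponentialFit) -> float:
    """Unfolding rate k = 1/tau_HDX (min^-1): exchange counts only unfolding.

    This is how the quadruplex unfolding rates are fixed: the G4(I)
    middle-tetrad exchange time gives k4, the G4(II) one gives k5.
    """
    if fit.direction != "decay":
        raise ValueError("HDX rate requires a decay fit")
    return time_to_rate(fit.tau)


def estimate_populations(
    table: PeakVolumeTable, reporters: tuple[str, ...] = DEFAULT_REPORTERS
) -> PopulationEstimate:
    """Conformer populations from reporter imino-proton peak volumes.

    Per residue, fraction_G4(I) = V_I / (V_I + V_II); the overall estimate is
    the mean over reporters and the dispersion is their max-min spread.  A
    spread above ``DISPERSION_WARN_THRESHOLD`` flags discordant reporters.
    """
    fractions: dict[str, float] = {}
    for res in reporters:
        try:
            i = table.residues.index(res)
        except ValueError:
            raise ValueError(f"reporter residue {res} not in table") from None
        total = table.vol_g4i[i] + table.vol_g4ii[i]
        if total <= 0:
            raise ValueError(f"reporter residue {res} has zero total volume")
        fractions[res] = float(table.vol_g4i[i] / total)

    vals = np.array(list(fractions.values()))
    mean = float(vals.mean())
    disp = float(vals.max() - vals.min())
    discordant = disp > DISPERSION_WARN_THRESHOLD
    if discordant:
        warnings.warn(
            f"reporter fractions disagree by {disp:.2f} "
            f"(> {DISPERSION_WARN_THRESHOLD}): {fractions}",
            UserWarning,
            stacklevel=2,
        )
    return PopulationEstimate(
        fraction_g4i=mean,
        fraction_g4ii=1.0 - mean,
        per_residue_fractions=fractions,
        dispersion=disp,
        discordant=discordant,
    )


def estimate_tm(
    curve: MeltingCurve,
    smooth_window: int = 7,
    smooth_order: int = 2,
    baseline_fraction: float = 0.1,
    vertex_halfwidth: int = 6,
) -> tuple[float, float]:
    """Melting temperature as the first-derivative extremum, with uncertainty.

    Procedure: fit a straight line to the coolest and hottest
    ``baseline_fraction`` of points and subtract it; take the smoothed first
    derivative with a Savitzky-Golay filter (window ``smooth_window``
    points, order ``smooth_order``); locate the extremum of |derivative|
    (the sign depends on whether the channel loses or gains signal on
    melting) and refine it as the vertex of a quadratic fitted to the
    derivative over ``vertex_halfwidth`` grid points on each side.  The
    wide vertex fit averages derivative noise; half-width 6 on a 1-degC
    grid spans roughly one transition width.  Returns ``(tm, uncertainty)``
    with the uncertainty no tighter than half the grid step.

    Raises ``NoTransitionError`` when the signal change is indistinguishable
    from local noise (no sigmoidal transition).
    """
    temp = curve.temperatures
    sig = curve.ellipticity
    n = temp.size
    n_edge = max(int(round(baseline_fraction * n)), 2)

    edge_t = np.concatenate([temp[:n_edge], temp[-n_edge:]])
    edge_s = np.concatenate([sig[:n_edge], sig[-n_edge:]])
    slope, intercept = np.polyfit(edge_t, edge_s, 1)
    corrected = sig - (slope * temp + intercept)

    # Noise scale from second differences (transition-insensitive).
    noise = np.median(np.abs(np.diff(corrected, 2))) / np.sqrt(6) * 1.4826
    span = corrected.max() - corrected.min()
    if span <= 5 * max(noise, 1e-12 * max(abs(sig).max(), 1.0)):
        raise NoTransitionError(
            "signal range is within 5x the local noise; no melting transition"
        )

    window = min(smooth_window, n if n % 2 else n - 1)
    step = float(np.median(np.diff(temp)))
    deriv = savgol_filter(
        corrected, window_length=window, polyorder=smooth_order, deriv=1, delta=step
    )

    idx = int(np.argmax(np.abs(deriv)))
    if idx == 0 or idx == n - 1:
        raise NoTransitionError("derivative extremum sits on the grid edge")

    lo, hi = max(idx - vertex_halfwidth, 0), min(idx + vertex_halfwidth + 1, n)
    tw, dw = temp[lo:hi], np.abs(deriv)[lo:hi]
    (a, b, c0), cov = np.polyfit(tw, dw, 2, cov="unscaled")
    resid = dw - np.polyval([a, b, c0], tw)
    dof = max(tw.size - 3, 1)
    cov = cov * float(resid @ resid) / dof
    tm = float(temp[idx])
    vertex_err = np.inf
    if a < 0:
        vertex = float(-b / (2 * a))
        if tw[0] <= vertex <= tw[-1]:
            tm = vertex
        # delta-method variance of the vertex -b/(2a)
        dv = np.array([b / (2 * a * a), -1.0 / (2 * a)])
        vertex_err = float(np.sqrt(max(dv @ cov[:2, :2] @ dv, 0.0)))
    uncertainty = max(step / 2, min(vertex_err, 5 * step))
    return tm, uncertainty
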