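"""Map state populations to measurable signals.

CD kinetic traces are modelled as a linear response over the four species:
each species contributes its molar ellipticity coefficient times its
population, plus an instrument baseline.  The qualitative CD-signature rule
for quadruplex topologies (uniform tetrad hydrogen-bonding directionality
gives a dominant 265-nm band; mixed stacking interfaces add 295-nm
character) is encoded as a three-way classifier.  A trapezoidal peak
integrator supports peak-volume work on 1-D spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .kinetics import StateTrajectory

__all__ = [
    "CDCoefficients",
    "CDTrace",
    "FoldTopology",
    "cd_signal",
    "predict_cd_signature",
    "integrate_peak",
]

#: Wavelengths used in the dual-channel kinetics/melting experiments.
STANDARD_WAVELENGTHS = (265.0, 290.0, 295.0)


@dataclass(frozen=True)
class CDCoefficients:
    """Per-species CD response at one wavelength.

    ``c_a``..``c_d`` are ellipticity per unit population of Hp, G4(I),
    G4(II) and U respectively; ``baseline`` is the population-independent
    offset.  290 nm and 295 nm are both accepted labels for the
    G4(II)-reporting channel.  Hairpin and unfolded-ensemble coefficients
    default to zero but are fittable.
    """

    wavelength: float
    c_a: float = 0.0
    c_b: float = 0.0
    c_c: float = 0.0
    c_d: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength not in STANDARD_WAVELENGTHS:
            warnings.warn(
                f"wavelength {self.wavelength} nm is outside the standard "
                f"channels {STANDARD_WAVELENGTHS}",
                UserWarning,
                stacklevel=3,
            )


@dataclass
class CDTrace:
    """A CD kinetic trace: ellipticity vs time at one wavelength."""

    wavelength: float
    times: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.signal.shape != self.times.shape:
            raise ValueError("signal and times must have equal length")


@dataclass(frozen=True)
class FoldTopology:
    """Qualitative description of a quadruplex fold.

    ``tetrad_directionalities`` lists the hydrogen-bonding directionality of
    each tetrad layer ("clockwise"/"counterclockwise"); ``glycosidic_states``
    optionally lists syn/anti per core guanine (4 per layer).
    """

    name: str
    tetrad_directionalities: tuple[str, ...]
    glycosidic_states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        allowed = {"clockwise", "counterclockwise"}
        if any(d not in allowed for d in self.tetrad_directionalities):
            raise ValueError("directionalities must be 'clockwise' or 'counterclockwise'")
        if self.glycosidic_states:
            if len(self.glycosidic_states) != 4 * len(self.tetrad_directionalities):
                raise ValueError("need exactly 4 glycosidic states per tetrad layer")
            if any(g not in {"syn", "anti"} for g in self.glycosidic_states):
                raise ValueError("glycosidic states must be 'syn' or 'anti'")


def cd_signal(traj: StateTrajectory, coeff: CDCoefficients) -> CDTrace:
    """Project a trajectory onto one CD channel.

    signal(t) = baseline + c_a*A(t) + c_b*B(t) + c_c*C(t) + c_d*D(t).
    """
    sig = (
        coeff.baseline
        + coeff.c_a * traj.A
        + coeff.c_b * traj.B
        + coeff.c_c * traj.C
        + coeff.c_d * traj.D
    )
    return CDTrace(wavelength=coeff.wavelength, times=traj.times.copy(), signal=sig)


def predict_cd_signature(topo: FoldTopology) -> str:
    """Classify the expected CD signature of a fold.

    All tetrad layers sharing one hydrogen-bonding directionality means all
    stacking interfaces are of the parallel (head-to-tail) kind, producing a
    dominant 265-nm band.  A fold whose layers mix directionalities has both
    kinds of stacking interface when layers of each directionality are
    adjacent somewhere, giving mixed 265+295 character; if every interface
    is heteropolar the 295-nm band dominates.
    """
    dirs = topo.tetrad_directionalities
    if len(dirs) < 2:
        raise ValueError("a quadruplex needs at least 2 tetrad layers")
    interfaces = [a == b for a, b in zip(dirs, dirs[1:])]
    if all(interfaces):
        return "265-dominant"
    if any(interfaces):
        return "mixed 265+295"
    return "295-dominant"


def integrate_peak(
    ppm: Sequence[float], intensity: Sequence[float], window: tuple[float, float]
) -> float:
    """Trapezoidal peak volume of a 1-D spectrum over a ppm window.

    The grid must be strictly monotone (either direction; NMR axes usually
    run downfield-to-upfield) and the window must overlap it with at least
    two points.
    """
    ppm = np.asarray(ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if ppm.shape != intensity.shape or ppm.ndim != 1:
        raise ValueError("ppm and intensity must be equal-length 1-D arrays")
    d = np.diff(ppm)
    if np.all(d > 0):
        pass
    elif np.all(d < 0):
        ppm, intensity = ppm[::-1], intensity[::-1]
    else:
        raise ValueError("ppm grid must be strictly monotone")
    lo, hi = min(window), max(window)
    mask = (ppm >= lo) & (ppm <= hi)
    if mask.sum() < 2:
        raise ValueError(f"window {window} selects fewer than 2 grid points")
    return float(np.trapezoid(intensity[mask], ppm[mask]))
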