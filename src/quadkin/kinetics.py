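"""Four-state kinetic model of the hairpin-to-quadruplex transition.

The WNT1-promoter sequence WT22m folds from a hairpin (Hp) into an
intermediate quadruplex G4(I) and finally into a hybrid quadruplex G4(II)
after K+ addition.  The interconversion between the two quadruplexes goes
through a lumped ensemble of unfolded intermediates, U.  The scheme is a
linear first-order network:

    Hp --k1--> G4(I) <--k2/k4--> U <--k3/k5--> G4(II)

with no return into the hairpin (its imino signals vanish after K+
addition, so the reverse step is negligible).  State populations are
written (A, B, D, C) = (Hp, G4(I), U, G4(II)); this ordering is the single
source of truth for every array in the package (see ``STATE_ORDER``).

All rates are in min^-1 and all times in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eig, expm

__all__ = [
    "STATE_ORDER",
    "RateConstants",
    "StateTrajectory",
    "rate_matrix",
    "solve_populations",
    "equilibrium_populations",
    "slow_relaxation_time",
]

#: Fixed state ordering used by every matrix and trajectory in the package:
#: A = hairpin, B = G4(I), D = unfolded ensemble, C = G4(II).
STATE_ORDER = ("A_hp", "B_g4i", "D_u", "C_g4ii")

#: Default initial condition: pure hairpin at the moment of K+ addition.
PURE_HAIRPIN = np.array([1.0, 0.0, 0.0, 0.0])

# Threshold controlling the fallback from eigendecomposition to the matrix
# exponential: the eigenvector basis is unusable when its condition number
# exceeds 1/_DEGENERACY_TOL (near-defective generator).
_DEGENERACY_TOL = 1e-12


@dataclass(frozen=True)
class RateConstants:
    """First-order rate constants of the four-state scheme, in min^-1.

    k1 : Hp -> G4(I)    (hairpin unfolding feeds the intermediate quadruplex)
    k2 : U  -> G4(I)    (refolding of the ensemble into G4(I))
    k3 : U  -> G4(II)   (folding of the ensemble into G4(II))
    k4 : G4(I)  -> U    (unfolding of G4(I))
    k5 : G4(II) -> U    (unfolding of G4(II))
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k5"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4, self.k5])


@dataclass
class StateTrajectory:
    """Populations of (Hp, G4(I), U, G4(II)) on a time grid.

    ``states`` has shape (len(times), 4) in the ``STATE_ORDER`` ordering.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D sequence")
        if self.states.shape != (self.times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")

    @property
    def A(self) -> np.ndarray:  # noqa: N802 - field names follow the model symbols
        return self.states[:, 0]

    @property
    def B(self) -> np.ndarray:  # noqa: N802
        return self.states[:, 1]

    @property
    def D(self) -> np.ndarray:  # noqa: N802
        return self.states[:, 2]

    @property
    def C(self) -> np.ndarray:  # noqa: N802
        return self.states[:, 3]


def rate_matrix(k: RateConstants) -> np.ndarray:
    """Build the 4x4 generator matrix M with dx/dt = M x, states (A, B, D, C).

    Off-diagonal entry (j, i) is the rate of the i -> j step; each column
    sums to zero (probability conservation).  No state feeds back into the
    hairpin, so row A has no positive entries.
    """
    m = np.zeros((4, 4))
    # A -> B
    m[0, 0] -= k.k1
    m[1, 0] += k.k1
    # B -> D and D -> B
    m[1, 1] -= k.k4
    m[2, 1] += k.k4
    m[2, 2] -= k.k2
    m[1, 2] += k.k2
    # D -> C and C -> D
    m[2, 2] -= k.k3
    m[3, 2] += k.k3
    m[3, 3] -= k.k5
    m[2, 3] += k.k5
    return m


def _validate_x0(x0: Sequence[float]) -> np.ndarray:
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (4,):
        raise ValueError("x0 must have 4 components (A, B, D, C)")
    if np.any(x0 < -1e-9):
        raise ValueError("initial populations must be non-negative")
    return x0


def solve_populations(
    k: RateConstants,
    x0: Sequence[float] = PURE_HAIRPIN,
    times: Sequence[float] = (),
) -> StateTrajectory:
    """Exact state populations x(t) = exp(M t) x0 on the requested grid.

    The generator of a linear first-order network is solved by
    eigendecomposition, which is exact up to round-off.  If the spectrum is
    near-defective (eigenvector matrix condition number above ``1e12``) the
    scaling-and-squaring matrix exponential is used instead and a warning is
    emitted.
    """
    x0 = _validate_x0(x0)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")

    m = rate_matrix(k)
    states = _propagate(m, x0, times)
    # Clip round-off-level negatives so downstream invariants hold.
    states[(states < 0) & (states > -1e-9)] = 0.0
    return StateTrajectory(times=times, states=states)


def _propagate(m: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    lam, vecs = eig(m)
    # Repeated eigenvalues only break the eigenvector basis when the matrix
    # is defective, which shows up as an ill-conditioned eigenvector matrix
    # (structurally repeated zeros, e.g. a single active edge, stay benign).
    degenerate = np.linalg.cond(vecs) > 1.0 / _DEGENERACY_TOL
    if not degenerate:
        try:
            coef = np.linalg.solve(vecs, x0.astype(complex))
        except np.linalg.LinAlgError:
            degenerate = True
    if degenerate:
        warnings.warn(
            "near-degenerate generator spectrum; falling back to matrix exponential",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.stack([expm(m * t) @ x0 for t in times])
    out = np.real(vecs @ (coef[:, None] * np.exp(np.outer(lam, times))))
    return out.T


def equilibrium_populations(k: RateConstants) -> tuple[float, float, float]:
    """Detailed-balance equilibrium fractions (B, D, C) of the G4(I)/U/G4(II)
    subsystem, normalized to sum 1 (the hairpin drains irreversibly, A -> 0).

    Detailed balance on the two reversible edges gives B*k4 = D*k2 and
    C*k5 = D*k3, i.e. B : D : C = (k2/k4) : 1 : (k3/k5).
    """
    if min(k.k2, k.k3, k.k4, k.k5) <= 0:
        raise ValueError("equilibrium requires k2, k3, k4, k5 all > 0")
    b, d, c = k.k2 / k.k4, 1.0, k.k3 / k.k5
    total = b + d + c
    return b / total, d / total, c / total


def slow_relaxation_time(k: RateConstants) -> float:
    """Slow relaxation time (min) of the G4(I) <-> U <-> G4(II) subsystem.

    The 3-state sub-generator (hairpin excluded: it only feeds in) has
    eigenvalues 0 and the two roots of

        lam^2 - lam*(k2+k3+k4+k5) + (k4*k3 + k4*k5 + k2*k5) = 0.

    Returns 1/|lam_slow| for the smaller-magnitude nonzero root.  This is the
    time constant of the slow interconversion between the two quadruplexes.
    """
    if max(k.k2, k.k3, k.k4, k.k5) <= 0:
        raise ValueError("relaxation time requires at least one of k2..k5 > 0")
    s = k.k2 + k.k3 + k.k4 + k.k5
    p = k.k4 * k.k3 + k.k4 * k.k5 + k.k2 * k.k5
    if p <= 0:
        # The subsystem has an absorbing direction; no finite slow relaxation.
        raise ValueError("slow relaxation undefined: product term of the characteristic "
                         "quadratic vanishes (no exchange closes the loop)")
    disc = max(s * s - 4.0 * p, 0.0)
    # Stable form of the smaller quadratic root (avoids cancellation when
    # the fast and slow modes are orders of magnitude apart, as in Table-2
    # style rate sets where k2 >> k4).
    lam_slow = 2.0 * p / (s + np.sqrt(disc))
    if lam_slow <= 0:
        raise ValueError("nonzero eigenvalues vanished; relaxation time undefined")
    return 1.0 / lam_slow
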