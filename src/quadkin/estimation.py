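"""Fitting protocol for the four-state transition.

The protocol mirrors how the rate constants are determined experimentally:

1. the hairpin-unfolding rate k1 comes from a single-exponential fit to the
   first ~20 min of the rising 265-nm CD signal (``fit_exponential`` +
   ``time_to_rate``);
2. the quadruplex unfolding rates k4 and k5 come from HDX exchange times of
   the middle-tetrad imino protons (same exponential machinery, decay
   direction);
3. with k1, k4, k5 fixed, the folding rates k2 (U -> G4(I)) and k3
   (U -> G4(II)) are obtained by a constrained global fit of the four-state
   model to the 265-nm and 290/295-nm kinetic traces jointly
   (``fit_kinetics``).

The global fit is separable: at any trial (k2, k3) the species CD
coefficients enter linearly, so they are solved by linear least squares at
each step (variable projection) and only log k2, log k3 are iterated
nonlinearly.  Fitting on the log scale enforces positivity and tames the
order-of-magnitude gap between the folding and unfolding constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares, minimize_scalar
from scipy.stats import f as f_dist

from .kinetics import PURE_HAIRPIN, RateConstants, solve_populations
from .observables import CDCoefficients, CDTrace

__all__ = [
    "ExponentialFit",
    "KineticFitResult",
    "fit_exponential",
    "time_to_rate",
    "fit_kinetics",
    "FitFailure",
]


class FitFailure(RuntimeError):
    """Raised when a fit fails to converge after multi-start."""


@dataclass(frozen=True)
class ExponentialFit:
    """Result of a single-exponential fit.

    decay:  y(t) = offset + amplitude * exp(-t/tau)
    rise:   y(t) = offset - amplitude * exp(-t/tau)

    ``tau`` is the time constant in minutes, ``tau_stderr`` its standard
    error from the fit covariance.
    """

    tau: float
    amplitude: float
    offset: float
    direction: str
    tau_stderr: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not np.isfinite(self.tau_stderr):
            raise ValueError("tau_stderr must be finite")
        if self.direction not in ("rise", "decay"):
            raise ValueError("direction must be 'rise' or 'decay'")


@dataclass
class KineticFitResult:
    """Constrained global fit of the four-state model to two CD traces.

    ``k`` carries the full rate set: k1, k4, k5 are exactly the supplied
    fixed values, k2 and k3 are fitted.  ``coefficients`` holds the fitted
    linear CD response per wavelength channel.
    """

    k: RateConstants
    coefficients: tuple[CDCoefficients, CDCoefficients]
    k2_stderr: float
    k3_stderr: float
    residual_norm: float
    n_points: int
    fixed: tuple[str, ...] = ("k1", "k4", "k5")
    uninformative: bool = False
    #: Branch ratio k3/k2 of the unfolded ensemble's folding partition.
    #: When the ensemble is quasi-steady this ratio is the combination the
    #: traces actually pin down, even when k2 and k3 individually are flat.
    ratio_k3_k2: float = float("nan")
    ratio_stderr: float = float("nan")


def _extract_series(trace, t_max=None) -> tuple[np.ndarray, np.ndarray]:
    """Pull (t, y) out of a CDTrace, an HDX-like object, or a pair of arrays."""
    if hasattr(trace, "signal"):
        t, y = np.asarray(trace.times, float), np.asarray(trace.signal, float)
    elif hasattr(trace, "volumes"):
        t, y = np.asarray(trace.times, float), np.asarray(trace.volumes, float)
    else:
        t, y = (np.asarray(a, dtype=float) for a in trace)
    if t_max is not None:
        keep = t <= t_max
        t, y = t[keep], y[keep]
    return t, y


def fit_exponential(trace, direction: str, t_max: float | None = None) -> ExponentialFit:
    """Least-squares single-exponential fit of a rising or decaying series.

    ``t_max`` restricts the fit window (the arising-time protocol fits the
    first 20 min only, where the slow G4(I)->G4(II) conversion has not yet
    set in).  Multi-start over the time constant guards against local
    minima; failure to converge from every start raises ``FitFailure``.
    """
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise' or 'decay'")
    t, y = _extract_series(trace, t_max)
    if t.size < 5:
        raise ValueError(f"need at least 5 points to fit, have {t.size}")

    sign = -1.0 if direction == "rise" else 1.0

    def model3(tt, log_tau, amplitude, offset):
        return offset + sign * amplitude * np.exp(-tt / np.exp(log_tau))

    def model2(tt, log_tau, amplitude):
        return sign * amplitude * np.exp(-tt / np.exp(log_tau))

    span = float(y.max() - y.min())
    amp0 = max(span, 1e-12)
    off0 = float(y.max() if direction == "rise" else y.min())
    # Start tau at a few scales spanning the sampling window.
    t_scale = max(t.max() - t.min(), 1e-6)
    starts = t_scale * np.array([0.05, 0.2, 1.0, 5.0])

    def multistart(model, p0_tail):
        best = None
        errors: list[str] = []
        for tau0 in starts:
            try:
                popt, pcov = curve_fit(
                    model, t, y, p0=[np.log(tau0), *p0_tail], maxfev=20000
                )
            except (RuntimeError, ValueError) as exc:  # no convergence here
                errors.append(str(exc))
                continue
            ssr = float(np.sum((model(t, *popt) - y) ** 2))
            if best is None or ssr < best[0]:
                best = (ssr, popt, pcov)
        return best, errors

    best3, errors = multistart(model3, (amp0, off0))
    popt, pcov, offset = None, None, 0.0
    if direction == "decay":
        # A free offset (residual protonation / peak overlap floor) is kept
        # only when it significantly improves the fit (F-test, alpha=0.01):
        # on sparse grids spanning a fraction of tau the offset and the slow
        # decay are nearly collinear and the 3-parameter fit is unstable.
        best2, errors2 = multistart(model2, (amp0,))
        errors += errors2
        use3 = False
        if best3 is not None and best2 is not None:
            ssr3, ssr2 = best3[0], best2[0]
            dof3 = t.size - 3
            if dof3 > 0 and ssr3 > 0:
                fstat = (ssr2 - ssr3) / (ssr3 / dof3)
                use3 = fstat > f_dist.ppf(0.99, 1, dof3)
            elif ssr3 < ssr2 * 1e-6:  # essentially perfect 3-parameter fit
                use3 = True
        elif best3 is not None:
            use3 = True
        if use3:
            _, popt, pcov = best3
            offset = float(popt[2])
        elif best2 is not None:
            _, popt, pcov = best2
    elif best3 is not None:
        _, popt, pcov = best3
        offset = float(popt[2])
    if popt is None:
        raise FitFailure(
            "single-exponential fit failed from all starts: " + "; ".join(errors)
        )
    tau = float(np.exp(popt[0]))
    var = float(pcov[0, 0])
    # A numerically perfect fit has no residual scatter to estimate a
    # covariance from; report zero uncertainty rather than inf.
    log_tau_err = np.sqrt(var) if np.isfinite(var) and var > 0 else 0.0
    return ExponentialFit(
        tau=tau,
        amplitude=float(popt[1]),
        offset=offset,
        direction=direction,
        tau_stderr=tau * log_tau_err,
    )


def time_to_rate(tau: float) -> float:
    """Convert a measured time constant (min) to a first-order rate (min^-1)."""
    if tau <= 0:
        raise ValueError(f"time constant must be positive, got {tau}")
    return 1.0 / tau


# ---------------------------------------------------------------------------
# Constrained dual-wavelength global fit
# ---------------------------------------------------------------------------

def _refine_sloppy_valley(objective, sol):
    """Nested profile refinement over the (scale, ratio) valley of (k2, k3).

    When the unfolded ensemble is quasi-steady the traces constrain the
    branch ratio k3/k2 sharply but the absolute scale only weakly, so the
    least-squares surface is a long curved valley in which local
    quadratic steps stall.  The refinement profiles the objective over
    log k2 (the scale proxy) with the ratio re-optimized by a bounded 1-D
    search at every trial scale, then polishes the best point with a final
    least-squares run.
    """

    def ssr(x):
        return float(np.sum(objective(x) ** 2))

    x = sol.x.copy()
    log_r0 = x[1] - x[0]

    def profiled(log_k2, span=2.0):
        inner = minimize_scalar(
            lambda lr: ssr(np.array([log_k2, log_k2 + lr])),
            bounds=(log_r0 - span, log_r0 + span),
            method="bounded",
            options={"xatol": 1e-9},
        )
        return inner.fun, inner.x

    # The profile over the scale can hold a narrow dip (resolvable fast
    # phase) on top of a flat quasi-steady-state plateau, so scan a coarse
    # log grid first and then polish the best bracket with Brent.
    scan = np.linspace(np.log(1e-4), np.log(1e6), 41)
    scan_f = [profiled(lk2)[0] for lk2 in scan]
    i_best = int(np.argmin(scan_f))
    lo = scan[max(i_best - 1, 0)]
    hi = scan[min(i_best + 1, len(scan) - 1)]
    outer = minimize_scalar(
        lambda lk2: profiled(lk2)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    fx, best_x = ssr(x), x
    if outer.fun < fx:
        _, lr = profiled(outer.x)
        best_x = np.array([outer.x, outer.x + lr])
    polished = least_squares(
        objective, best_x, method="trf",
        bounds=(_LOG_RATE_BOUNDS[0], _LOG_RATE_BOUNDS[1]),
        xtol=1e-14, ftol=1e-14,
    )
    return polished if polished.cost <= sol.cost else sol

def _design_columns(k: RateConstants, times: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Columns [1, B(t), C(t)] of the linear response model at given rates."""
    traj = solve_populations(k, x0, times)
    return np.column_stack([np.ones_like(times), traj.B, traj.C])


# Hard box for the free rates on the log scale; keeps trial steps finite
# and far wider than any physically plausible folding rate.
_LOG_RATE_BOUNDS = (np.log(1e-6), np.log(1e8))


def _projected_residuals(
    log_k23: np.ndarray,
    fixed: dict[str, float],
    data: list[tuple[np.ndarray, np.ndarray, float]],
    x0: np.ndarray,
) -> tuple[np.ndarray, list[np.ndarray]]:
    log_k23 = np.clip(log_k23, *_LOG_RATE_BOUNDS)
    k2, k3 = np.exp(log_k23)
    k = RateConstants(k1=fixed["k1"], k2=k2, k3=k3, k4=fixed["k4"], k5=fixed["k5"])
    residuals, coefs = [], []
    for t, y, w in data:
        design = _design_columns(k, t, x0)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        residuals.append(w * (design @ beta - y))
        coefs.append(beta)
    return np.concatenate(residuals), coefs


def fit_kinetics(
    traces: Sequence[CDTrace],
    fixed: dict[str, float],
    init_guess: tuple[float, float] | None = None,
    x0: Sequence[float] = PURE_HAIRPIN,
    n_polish: int = 3,
) -> KineticFitResult:
    """Joint fit of k2, k3 to the G4(I)- and G4(II)-channel kinetic traces.

    Parameters
    ----------
    traces
        Two CDTrace objects: the 265-nm channel (G4(I) growth and decay) and
        the 290/295-nm channel (G4(II) growth).
    fixed
        ``{"k1": ..., "k4": ..., "k5": ...}`` rates fixed from the arising
        time and HDX measurements; returned bit-exactly.
    init_guess
        Optional (k2, k3) starting point; otherwise a 5x5 log-spaced start
        grid is screened and the best starts polished.
    x0
        Initial populations, default pure hairpin.
    n_polish
        Number of screened starts to polish with the full optimizer.

    Each trace is normalized to unit maximum absolute signal so neither
    wavelength dominates the joint residual; the per-species coefficients
    (baseline, c_B, c_C per channel) are solved linearly at each (k2, k3)
    trial.  Standard errors come from the Jacobian covariance of the full
    parameter vector at the optimum.
    """
    if len(traces) != 2:
        raise ValueError("fit_kinetics expects exactly two traces")
    for name in ("k1", "k4", "k5"):
        if name not in fixed or fixed[name] <= 0:
            raise ValueError(f"fixed rate {name} must be supplied and > 0")
    x0 = np.asarray(x0, dtype=float)

    data = []
    for tr in traces:
        t, y = np.asarray(tr.times, float), np.asarray(tr.signal, float)
        scale = np.max(np.abs(y))
        w = 1.0 / scale if scale > 0 else 1.0
        data.append((t, y, w))

    def objective(log_k23):
        return _projected_residuals(log_k23, fixed, data, x0)[0]

    if init_guess is not None:
        starts = [np.log(np.asarray(init_guess, float))]
    else:
        k2_grid = np.log(np.geomspace(10.0, 2000.0, 5))
        k3_grid = np.log(np.geomspace(1.0, 500.0, 5))
        grid = [np.array([a, b]) for a in k2_grid for b in k3_grid]
        # Screen the grid by residual norm, then polish the best few starts.
        scores = [float(np.sum(objective(g) ** 2)) for g in grid]
        order = np.argsort(scores)
        starts = [grid[i] for i in order[: max(n_polish, 1)]]

    best = None
    for s in starts:
        sol = least_squares(
            objective, s, method="trf",
            bounds=(_LOG_RATE_BOUNDS[0], _LOG_RATE_BOUNDS[1]),
            xtol=1e-12, ftol=1e-12,
        )
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    assert best is not None
    best = _refine_sloppy_valley(objective, best)

    k2, k3 = np.exp(best.x)
    k_full = RateConstants(k1=fixed["k1"], k2=k2, k3=k3, k4=fixed["k4"], k5=fixed["k5"])
    _, coefs = _projected_residuals(best.x, fixed, data, x0)

    n_points = sum(t.size for t, _, _ in data)
    n_params = 2 + sum(len(b) for b in coefs)
    dof = max(n_points - n_params, 1)
    s2 = 2.0 * best.cost / dof

    jtj = best.jac.T @ best.jac
    uninformative = False
    ratio = k3 / k2
    try:
        cov_log = s2 * np.linalg.inv(jtj)
        log_err = np.sqrt(np.maximum(np.diag(cov_log), 0.0))
        var_log_ratio = max(cov_log[0, 0] + cov_log[1, 1] - 2 * cov_log[0, 1], 0.0)
        ratio_stderr = ratio * float(np.sqrt(var_log_ratio))
    except np.linalg.LinAlgError:
        uninformative = True
        log_err = np.array([np.inf, np.inf])
        ratio_stderr = float("inf")
    # Flat directions in (log k2, log k3) mean the traces do not constrain
    # the folding branch ratio; flag rather than fail.
    if np.any(log_err > 1.0):
        uninformative = True
        warnings.warn(
            "traces are weakly informative for k2/k3; standard errors are wide",
            UserWarning,
            stacklevel=2,
        )

    wl = [tr.wavelength for tr in traces]
    coefficients = tuple(
        CDCoefficients(wavelength=w, baseline=float(b[0]), c_b=float(b[1]), c_c=float(b[2]))
        for w, b in zip(wl, coefs)
    )
    return KineticFitResult(
        k=k_full,
        coefficients=coefficients,  # type: ignore[arg-type]
        k2_stderr=float(k2 * log_err[0]),
        k3_stderr=float(k3 * log_err[1]),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_points=n_points,
        uninformative=uninformative,
        ratio_k3_k2=float(ratio),
        ratio_stderr=float(ratio_stderr),
    )
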