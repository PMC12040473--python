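"""Time-domain simulation and limit-cycle characterization.

The linear analysis predicts whether a perturbed steady state spirals
outwards; the nonlinear simulation confirms whether the growing oscillation
saturates into a limit cycle.  Integration is stiff-capable (BDF with the
analytic Jacobian); chemostat amounts are held exactly constant because they
are not part of the integrated state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .errors import BondoscError, ConvergenceError, DomainError
from .network import Network

__all__ = [
    "Trajectory",
    "LimitCycleStats",
    "integrate_nonlinear",
    "integrate_linear",
    "limit_cycle_stats",
]

#: default number of fixed output-grid samples
N_SAMPLES = 1000


@dataclass
class Trajectory:
    """Time series of dynamic-species amounts.

    ``states`` has one row per time point and one column per dynamic
    species (in state-vector order).  ``time_unit`` is carried as metadata
    and never converted implicitly.
    """

    times: np.ndarray
    states: np.ndarray
    species: tuple
    kind: str  # "nonlinear" | "linear"
    time_unit: str = "s"

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]


@dataclass
class LimitCycleStats:
    """Period/amplitude summary of the late-time behaviour of a trajectory."""

    detected: bool
    period: float
    amplitude: dict
    transient_end: int


def integrate_nonlinear(network: Network, x0=None, t_end: float = 10.0,
                        rtol: float = 1e-8, atol: float = 1e-11,
                        n_samples: int = N_SAMPLES,
                        allow_negative: bool = False) -> Trajectory:
    """Integrate the closed-loop mass-action ODE from ``x0``.

    Sampling is on a fixed output grid for reproducible exports; the
    integrator's internal steps remain adaptive.  Negative excursions of the
    state raise a diagnostic rather than being clipped silently.
    """
    if not (t_end > 0):
        raise ValueError("t_end must be > 0")
    x_full = network.state_vector(x0)
    x_dyn0 = network.dynamic_part(x_full)

    def rhs(t, y):
        return network.rhs_dynamic(y, x_full)

    def jac(t, y):
        return network.jacobian_dynamic(network.full_from_dynamic(y, x_full))

    t_eval = np.linspace(0.0, float(t_end), n_samples)
    sol = solve_ivp(rhs, (0.0, float(t_end)), x_dyn0, method="BDF", jac=jac,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise ConvergenceError(
            f"nonlinear integration failed at t={sol.t[-1] if sol.t.size else 0}: "
            f"{sol.message}"
        )
    states = sol.y.T
    if not allow_negative and np.min(states) < -10 * atol:
        t_bad = sol.t[np.argmax(np.any(states < -10 * atol, axis=1))]
        raise DomainError(
            f"state went negative at t={t_bad:.6g} "
            f"(min {np.min(states):.3e}); the model is being driven outside "
            "its physical domain"
        )
    return Trajectory(times=sol.t, states=states,
                      species=network.dynamic_species, kind="nonlinear")


def integrate_linear(ss, dx0, t_end: float, n_samples: int = N_SAMPLES,
                     species=None) -> Trajectory:
    """Exact solution of the linearized autonomous system dx = A x.

    ``ss`` may be a :class:`~bondosc.linearize.StateSpaceModel` or a plain
    Jacobian matrix.  The solution is the matrix exponential applied to the
    initial perturbation, evaluated by eigendecomposition.
    """
    A = np.asarray(getattr(ss, "A", ss), float)
    dx0 = np.asarray(dx0, float)
    if A.shape[0] != dx0.size:
        raise ValueError("initial perturbation dimension mismatch")
    times = np.linspace(0.0, float(t_end), n_samples)
    try:
        vals, vecs = np.linalg.eig(A)
        c = np.linalg.solve(vecs, dx0.astype(complex))
        states = np.real((vecs @ (c[:, None] * np.exp(
            np.outer(vals, times)))).T)
    except np.linalg.LinAlgError:  # defective A: fall back to expm steps
        states = np.array([scipy.linalg.expm(A * t) @ dx0 for t in times])
    labels = tuple(species) if species is not None else \
        tuple(getattr(ss, "state_labels", ()) or
              tuple(f"x{i}" for i in range(A.shape[0])))
    return Trajectory(times=times, states=states, species=labels, kind="linear")


def limit_cycle_stats(traj: Trajectory, species: str,
                      min_periods: int = 10,
                      amplitude_rtol: float = 0.01) -> LimitCycleStats:
    """Detect and characterize a limit cycle in the late part of a trajectory.

    The period is estimated from the peaks of the mean-removed signal over
    the last ~40% of the trajectory; a cycle is ``detected`` only when at
    least ``min_periods`` putative periods fit in the trajectory and the
    peak-to-peak amplitude is stationary within ``amplitude_rtol`` over the
    last three periods.
    """
    y = traj.column(species)
    t = traj.times
    tail_start = int(0.6 * len(t))
    y_tail = y[tail_start:] - np.mean(y[tail_start:])
    t_tail = t[tail_start:]
    span = np.max(y_tail) - np.min(y_tail)
    if span <= 0:
        return LimitCycleStats(False, 0.0, {}, tail_start)
    peaks, _ = find_peaks(y_tail, prominence=0.1 * span)
    if peaks.size >= 2:
        period = float(np.median(np.diff(t_tail[peaks])))
        n_fit = (t[-1] - t[0]) / period if period > 0 else np.inf
        if n_fit < min_periods:
            raise BondoscError(
                f"trajectory too short for limit-cycle statistics: spans "
                f"{n_fit:.1f} putative periods, need >= {min_periods}"
            )
    if peaks.size < 4:
        return LimitCycleStats(False, 0.0, {}, tail_start)
    period = float(np.median(np.diff(t_tail[peaks])))
    if period <= 0:
        return LimitCycleStats(False, 0.0, {}, tail_start)
    # amplitude stationarity over the last three periods
    t_end = t_tail[-1]
    windows = []
    for k in range(3):
        lo, hi = t_end - (k + 1) * period, t_end - k * period
        mask = (t_tail >= lo) & (t_tail <= hi)
        if np.count_nonzero(mask) < 5:
            return LimitCycleStats(False, period, {}, tail_start)
        windows.append(np.max(y_tail[mask]) - np.min(y_tail[mask]))
    stationary = (np.max(windows) - np.min(windows)) <= \
        amplitude_rtol * np.mean(windows)
    amplitudes = {}
    last3 = t_tail >= t_end - 3 * period
    for name in traj.species:
        col = traj.column(name)[tail_start:][last3]
        amplitudes[name] = float(np.max(col) - np.min(col))
    return LimitCycleStats(
        detected=bool(stationary),
        period=period,
        amplitude=amplitudes,
        transient_end=tail_start,
    )


def perturbed_initial_state(network: Network, steady_amounts,
                            species: str, rel: float = 1e-3) -> dict:
    """Steady state with one species perturbed by a relative amount."""
    x = dict(steady_amounts)
    x[species] = x[species] * (1.0 + rel)
    return x
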