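"""Frequency-response analysis of the loop gain.

The loop gain L(s) = L0(s)/s is evaluated on the imaginary axis; the gain
crossover is the frequency where |L(jw)| = 1 and the phase margin is
180 deg + the phase of L at that frequency.  A negative phase margin
indicates closed-loop instability, and a complex right-half-plane pole pair
of 1 + L = 0 indicates that the instability is oscillatory — the linear
signature of a limit cycle.  The open loop is assumed stable (the
loop-breaking construction guarantees this for the built-in fixtures), so
no Nyquist encirclement counting is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from .errors import BondoscError
from .linearize import RationalTransferFunction, split_loop
from .steady import solve_closed_loop

__all__ = [
    "MarginReport",
    "RootLocusResult",
    "frequency_response",
    "gain_crossover",
    "phase_margin",
    "closed_loop_poles",
    "root_locus",
    "phase_margin_grid",
    "analyze_loop",
]

#: frequency grid design: points per sweep, decades beyond extreme roots
GRID_POINTS = 400
GRID_DECADES_BEYOND = 2
OMEGA_MIN = 1e-6


@dataclass
class MarginReport:
    """Gain-crossover frequencies, phase margin and stability verdict.

    ``phase_margin`` is the minimum-margin crossover's value in degrees
    (None when there is no crossover); ``verdict`` is one of ``stable``,
    ``unstable-oscillatory``, ``unstable-monotone`` or ``no-crossover`` and
    is cross-checked against the closed-loop poles.
    """

    crossover_frequencies: list
    phase_margin: Optional[float]
    evaluated_at: Optional[float]
    verdict: str
    all_margins: list = field(default_factory=list)
    closed_loop_poles: np.ndarray = field(
        default_factory=lambda: np.zeros(0, complex))


@dataclass
class RootLocusResult:
    """Closed-loop pole branches as the loop gain k varies."""

    gain_grid: np.ndarray
    branches: np.ndarray  # (n_gains, n_poles), continuity-matched
    open_loop_poles: np.ndarray
    open_loop_zeros: np.ndarray


def frequency_response(tf: RationalTransferFunction, omegas) -> np.ndarray:
    """Exact rational evaluation of ``tf`` at s = j*omega.

    Raises if any requested frequency coincides with an imaginary-axis pole
    (a singular point of the response).
    """
    om = np.atleast_1d(np.asarray(omegas, float))
    if np.any(om <= 0):
        raise ValueError("frequencies must be positive")
    for p in tf.poles:
        if abs(p.real) < 1e-300:
            hits = np.isclose(om, abs(p.imag), rtol=1e-12, atol=0.0)
            if p.imag != 0 and np.any(hits):
                raise BondoscError(
                    f"frequency {abs(p.imag)} coincides with an imaginary-axis "
                    "pole (singular point)")
    return tf.frequency_response(om)


def _default_grid(tf: RationalTransferFunction, n: int = GRID_POINTS):
    roots = np.concatenate([tf.zeros, tf.poles])
    mags = np.abs(roots[np.abs(roots) > 0]) if roots.size else np.array([1.0])
    if mags.size == 0:
        mags = np.array([1.0])
    lo = max(OMEGA_MIN, 10.0 ** (np.log10(mags.min()) - GRID_DECADES_BEYOND))
    hi = 10.0 ** (np.log10(mags.max()) + GRID_DECADES_BEYOND)
    if hi <= lo:
        hi = lo * 1e4
    return np.geomspace(lo, hi, n)


def gain_crossover(L: RationalTransferFunction, grid=None) -> list:
    """All frequencies where |L(jw)| crosses unity.

    Sign changes of log|L| on a log-spaced grid are refined by bisection to
    relative 1e-6; an empty list is a valid outcome.
    """
    if L.gain == 0.0:
        return []
    om = _default_grid(L) if grid is None else np.asarray(grid, float)
    logmag = np.log10(L.gain_mag(om))
    crossings = []
    for i in range(len(om) - 1):
        a, b = logmag[i], logmag[i + 1]
        if a == 0.0:
            crossings.append(om[i])
        elif a * b < 0:
            wc = brentq(lambda w: np.log10(abs(L(1j * w))), om[i], om[i + 1],
                        rtol=1e-12)
            crossings.append(wc)
    if logmag[-1] == 0.0:
        crossings.append(om[-1])
    return sorted(crossings)


def _wrap_180(theta: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = (theta + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def closed_loop_poles(L: RationalTransferFunction, k: float = 1.0) -> np.ndarray:
    """Roots of denominator(L) + k * numerator(L) = 0."""
    if k <= 0:
        raise ValueError("gain k must be > 0")
    num, den = L.num_den()
    if den.size == 1 and abs(den[0]) < 1e-300:
        raise BondoscError("degenerate denominator")
    n = max(num.size, den.size)
    poly = np.zeros(n)
    poly[n - den.size:] += den
    poly[n - num.size:] += k * num
    if abs(poly[0]) < 1e-300 * max(1.0, np.max(np.abs(poly))):
        raise BondoscError("degenerate leading coefficient in 1 + kL")
    return np.roots(poly)


def _verdict_from_poles(poles: np.ndarray) -> str:
    if poles.size == 0:
        return "stable"
    scale = 1.0 + np.max(np.abs(poles))
    tol = 1e-6 * scale
    rhp = poles[poles.real > tol]
    if rhp.size == 0:
        return "stable"
    if np.any(np.abs(rhp.imag) > tol):
        return "unstable-oscillatory"
    return "unstable-monotone"


def phase_margin(L: RationalTransferFunction, grid=None) -> MarginReport:
    """Phase margin of the loop gain at its gain crossover(s).

    With multiple crossovers, every margin is listed and the minimum
    (most critical) one is reported.  The stability verdict comes from the
    closed-loop poles, so the report stays meaningful even when the
    crossover structure is degenerate.
    """
    crossings = gain_crossover(L, grid=grid)
    poles_cl = closed_loop_poles(L, 1.0)
    if not crossings:
        return MarginReport(
            crossover_frequencies=[], phase_margin=None, evaluated_at=None,
            verdict="no-crossover", all_margins=[],
            closed_loop_poles=poles_cl)
    margins = [
        _wrap_180(180.0 + float(L.phase_deg(wc)[0])) for wc in crossings
    ]
    i_min = int(np.argmin(margins))
    return MarginReport(
        crossover_frequencies=list(crossings),
        phase_margin=margins[i_min],
        evaluated_at=crossings[i_min],
        verdict=_verdict_from_poles(poles_cl),
        all_margins=margins,
        closed_loop_poles=poles_cl,
    )


def root_locus(L: RationalTransferFunction, gain_grid=None) -> RootLocusResult:
    """Track the roots of 1 + k L(s) = 0 over a grid of gains.

    Branches are matched between consecutive gains by nearest-neighbour
    assignment (ties broken lexicographically on the real part); at small
    gain the branches start at the open-loop poles and at large gain they
    approach the finite zeros or diverge.
    """
    if gain_grid is None:
        gain_grid = np.geomspace(1e-3, 1e3, 500)
    gain_grid = np.asarray(gain_grid, float)
    if np.any(gain_grid <= 0) or np.any(np.diff(gain_grid) <= 0):
        raise ValueError("gain grid must be positive and sorted")
    n_poles = L.poles.size
    branches = np.zeros((gain_grid.size, n_poles), complex)
    prev = np.sort_complex(np.asarray(L.poles, complex))
    for i, k in enumerate(gain_grid):
        roots = closed_loop_poles(L, k)
        assigned = np.zeros(n_poles, complex)
        remaining = list(roots)
        order = sorted(range(n_poles), key=lambda j: (prev[j].real, prev[j].imag))
        for j in order:
            d = [abs(r - prev[j]) for r in remaining]
            m = int(np.argmin(d))
            assigned[j] = remaining.pop(m)
        branches[i] = assigned
        prev = assigned
    return RootLocusResult(
        gain_grid=gain_grid,
        branches=branches,
        open_loop_poles=np.asarray(L.poles, complex),
        open_loop_zeros=np.asarray(L.zeros, complex),
    )


@dataclass
class GridCell:
    """Phase-margin summary of one parameter-sweep cell."""

    params: tuple
    theta_pm: Optional[float]
    omega_c: Optional[float]
    verdict: str
    failed: bool = False
    error: str = ""


def analyze_loop(network, loop, steady=None) -> MarginReport:
    """Steady state (if not given) + split-loop linearization + margins."""
    if steady is None:
        steady = solve_closed_loop(network, loop)
    decomp = split_loop(network, loop, steady)
    return phase_margin(decomp.L)


def phase_margin_grid(builder: Callable, axis1, axis2) -> list:
    """Phase margin over a two-parameter grid.

    ``builder(p1, p2)`` must return a valid ``(Network, LoopSpec)`` fixture
    for every grid point; the steady state is re-solved per point.  Cells
    where the solve fails are flagged, not dropped.
    """
    cells = []
    for p1 in np.atleast_1d(axis1):
        for p2 in np.atleast_1d(axis2):
            try:
                net, loop = builder(p1, p2)
                report = analyze_loop(net, loop)
                cells.append(GridCell(
                    params=(float(p1), float(p2)),
                    theta_pm=report.phase_margin,
                    omega_c=report.evaluated_at,
                    verdict=report.verdict,
                ))
            except BondoscError as exc:
                cells.append(GridCell(
                    params=(float(p1), float(p2)), theta_pm=None, omega_c=None,
                    verdict="failed", failed=True, error=str(exc),
                ))
    return cells
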