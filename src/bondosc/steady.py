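"""Loop-broken steady-state computation.

Closed-loop equilibria of feedback oscillators are typically unstable, so
they cannot be found by simulating the closed loop.  The loop is therefore
broken by clamping the product species as a chemostat at a trial amount
``xP``: the remaining (open-loop, stable) network is relaxed to its steady
state, the net product flux at that state is evaluated, and a scalar root
finder locates the ``xP`` at which the net product flux vanishes.  The
resulting state is a genuine equilibrium of the closed-loop ODE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .errors import ConvergenceError, RootFindingError
from .network import LoopSpec, Network

__all__ = [
    "SteadyState",
    "relax_open_loop",
    "product_flux_residual",
    "solve_closed_loop",
]

#: default relaxation residual tolerance scale factor
RELAX_TOL = 1e-10
#: default scalar root tolerance on the product amount
ROOT_XTOL = 1e-12


@dataclass
class SteadyState:
    """A closed-loop equilibrium found by the loop-breaking procedure."""

    amounts: dict
    product_flux: float
    residual: float
    converged: bool

    def vector(self, network: Network) -> np.ndarray:
        return network.state_vector(self.amounts)


def _net_product_flux(network: Network, loop: LoopSpec, x_full: np.ndarray) -> float:
    """Net flux into the product summed over all of its reactions."""
    v = network.flux_values(x_full)
    total = 0.0
    for j, r in enumerate(network.reactions):
        w = r.net_stoichiometry(loop.product)
        if w:
            total += w * v[j]
    return total


def relax_open_loop(network: Network, loop: LoopSpec, xP: float,
                    x0=None, horizon: float = 100.0, tol: float = None,
                    max_doublings: int = 12) -> dict:
    """Relax the open loop (product clamped at ``xP``) to a steady state.

    Integrates the clamped network from ``x0`` (default: declared amounts)
    with a stiff solver, doubling the horizon until the residual
    ``max |dx/dt|`` over the remaining dynamic species falls below ``tol``.
    Conserved totals of ``x0`` are preserved by the integration.  Returns the
    relaxed state as a dict over all species (including the clamped product).
    """
    if not (xP > 0):
        raise ValueError(f"clamped product amount must be > 0 (got {xP})")
    clamped = network.with_chemostats({loop.product: xP})
    x_full = clamped.state_vector(x0)
    x_full[clamped.species_index(loop.product)] = xP
    x_dyn = clamped.dynamic_part(x_full)
    if x_dyn.size == 0:
        return clamped.state_dict(x_full)

    def rhs(t, y):
        return clamped.rhs_dynamic(y, x_full)

    def jac(t, y):
        return clamped.jacobian_dynamic(clamped.full_from_dynamic(y, x_full))

    def eff_tol(y):
        # residuals are differences of one-way fluxes; scale the tolerance
        # by the largest of those so it stays meaningful when the relaxed
        # state visits large amounts
        scale = clamped.flux_scale(clamped.full_from_dynamic(y, x_full))
        base = RELAX_TOL if tol is None else tol
        return base * max(1.0, scale) if tol is None else tol

    def is_open_loop_attractor(y):
        """Accept a candidate only if it is the stable open-loop state."""
        if np.any(y < 0):
            return False
        eigs = np.linalg.eigvals(
            clamped.jacobian_dynamic(clamped.full_from_dynamic(y, x_full)))
        scale = 1.0 + (np.max(np.abs(eigs)) if eigs.size else 0.0)
        # conserved-moiety modes contribute exact zeros; anything clearly
        # positive means Newton found an unstable root, not the attractor
        return bool(np.max(eigs.real, initial=-np.inf) < 1e-6 * scale)

    # fast path: the open loop is stable by assumption, so a Newton solve
    # seeded at x0 that lands on a non-negative state with a Hurwitz
    # Jacobian (moiety zero modes aside) is the relaxation fixed point;
    # otherwise integrate (doubling the horizon) and polish.
    candidate = _newton_polish(clamped, x_dyn, x_full)
    if float(np.max(np.abs(rhs(0.0, candidate)))) <= eff_tol(candidate) \
            and is_open_loop_attractor(candidate):
        x_dyn = candidate
        residual = float(np.max(np.abs(rhs(0.0, x_dyn))))
    else:
        coarse_tol = 1e-6 * max(1.0, float(np.max(x_full)))
        t_chunk = float(horizon)
        residual = float(np.max(np.abs(rhs(0.0, x_dyn))))
        for _ in range(max_doublings):
            if residual <= max(coarse_tol, eff_tol(x_dyn)):
                break
            sol = solve_ivp(rhs, (0.0, t_chunk), x_dyn, method="BDF", jac=jac,
                            rtol=1e-8, atol=1e-10)
            if not sol.success:
                raise ConvergenceError(
                    f"open-loop relaxation integrator failed: {sol.message}",
                    residual=residual,
                )
            x_dyn = sol.y[:, -1]
            residual = float(np.max(np.abs(rhs(0.0, x_dyn))))
            t_chunk *= 2.0
        if residual > eff_tol(x_dyn):
            x_dyn = _newton_polish(clamped, x_dyn, x_full)
            residual = float(np.max(np.abs(rhs(0.0, x_dyn))))
    if residual > eff_tol(x_dyn):
        raise ConvergenceError(
            f"open-loop relaxation did not reach steady state "
            f"(residual {residual:.3e} > tol {eff_tol(x_dyn):.3e})",
            residual=residual,
        )
    return clamped.state_dict(clamped.full_from_dynamic(x_dyn, x_full))


def _newton_polish(clamped: Network, x_dyn: np.ndarray,
                   x_full: np.ndarray) -> np.ndarray:
    """Polish a relaxed state to machine-precision steady state.

    Solves dx/dt = 0 with redundant rows replaced by the conserved-moiety
    totals of the relaxed state.
    """
    G = clamped.conserved_moieties()
    if G.size:
        totals = G @ x_dyn
        Q, _ = np.linalg.qr(G.T, mode="complete")
        P = Q[:, G.shape[0]:]

        def fun(y):
            r = clamped.rhs_dynamic(y, x_full)
            return np.concatenate([P.T @ r, G @ y - totals])

        def jac(y):
            J = clamped.jacobian_dynamic(clamped.full_from_dynamic(y, x_full))
            return np.vstack([P.T @ J, G])
    else:
        def fun(y):
            return clamped.rhs_dynamic(y, x_full)

        def jac(y):
            return clamped.jacobian_dynamic(clamped.full_from_dynamic(y, x_full))

    # judge by the achieved residual, not the solver's status flag (MINPACK
    # sometimes reports "not making good progress" after converging)
    sol = root(fun, x_dyn, jac=jac, method="hybr", tol=1e-14)
    if np.all(sol.x >= 0) and \
            np.max(np.abs(fun(sol.x))) < np.max(np.abs(fun(x_dyn))):
        return sol.x
    return x_dyn


def solve_open_loop_algebraic(network: Network, loop: LoopSpec, xP: float,
                              x0=None) -> dict:
    """Direct algebraic solve of the clamped steady state (cross-check oracle).

    Solves dx/dt = 0 for the clamped network, replacing redundant rows by
    conserved-moiety total constraints taken from the initial condition.
    """
    clamped = network.with_chemostats({loop.product: xP})
    x_full = clamped.state_vector(x0)
    x_full[clamped.species_index(loop.product)] = xP
    x_dyn0 = clamped.dynamic_part(x_full)
    if x_dyn0.size == 0:
        return clamped.state_dict(x_full)
    G = clamped.conserved_moieties()
    totals = G @ x_dyn0 if G.size else np.zeros(0)

    if G.size:
        # square system: project the RHS onto the orthogonal complement of
        # the moiety rows (where it is redundant) and append the totals
        Q, _ = np.linalg.qr(G.T, mode="complete")
        P = Q[:, G.shape[0]:]

        def fun(y):
            r = clamped.rhs_dynamic(y, x_full)
            return np.concatenate([P.T @ r, G @ y - totals])

        def jac(y):
            J = clamped.jacobian_dynamic(clamped.full_from_dynamic(y, x_full))
            return np.vstack([P.T @ J, G])
    else:
        def fun(y):
            return clamped.rhs_dynamic(y, x_full)

        def jac(y):
            return clamped.jacobian_dynamic(clamped.full_from_dynamic(y, x_full))

    # Levenberg-Marquardt copes with the wildly different flux scales that
    # defeat a plain trust-region Newton far from the solution
    sol = root(fun, x_dyn0, jac=jac, method="lm",
               options={"xtol": 1e-15, "ftol": 1e-15, "maxiter": 20000})
    scale = max(1.0, clamped.flux_scale(clamped.full_from_dynamic(sol.x, x_full)))
    if np.max(np.abs(fun(sol.x))) > 1e-8 * scale or np.any(sol.x < -1e-12):
        raise ConvergenceError(f"algebraic open-loop solve failed: {sol.message}")
    return clamped.state_dict(clamped.full_from_dynamic(np.abs(sol.x), x_full))


def product_flux_residual(network: Network, loop: LoopSpec, xP: float,
                          x0=None, **relax_kwargs) -> float:
    """Net product flux at the relaxed open-loop state for clamped ``xP``."""
    state = relax_open_loop(network, loop, xP, x0=x0, **relax_kwargs)
    return _net_product_flux(network, loop, network.state_vector(state))


def solve_closed_loop(network: Network, loop: LoopSpec, bracket=None,
                      x0=None, grid_points: int = 25, xtol: float = ROOT_XTOL,
                      relax_tol: float = None) -> SteadyState:
    """Find the closed-loop steady state by scalar root finding on ``xP``.

    The residual is the net product flux of the relaxed open loop.  If no
    bracket is supplied, a geometric grid over ``[1e-3, 1e3] * xP0`` (the
    declared product amount) is scanned and the first sign change is taken;
    additional sign changes are reported as a warning.
    """
    loop.validate(network)
    xP0 = network.species[network.species_index(loop.product)].amount
    if xP0 <= 0:
        xP0 = 1.0
    cache = {}
    warm = {"state": x0}

    def residual(xP):
        if xP not in cache:
            state = relax_open_loop(network, loop, xP, x0=warm["state"],
                                    tol=relax_tol)
            warm["state"] = state
            cache[xP] = _net_product_flux(network, loop,
                                          network.state_vector(state))
        return cache[xP]

    xP_star = None
    if bracket is None:
        grid = xP0 * np.geomspace(1e-3, 1e3, grid_points)
        vals = [residual(g) for g in grid]
        exact = [g for g, v in zip(grid, vals) if v == 0.0]
        if exact:
            # a grid point is already the root (exactly balanced fluxes)
            xP_star = min(exact, key=lambda g: abs(np.log(g / xP0)))
        brackets = [
            (grid[i], grid[i + 1]) for i in range(len(grid) - 1)
            if np.sign(vals[i]) * np.sign(vals[i + 1]) < 0
        ]
        if not brackets and xP_star is None:
            raise RootFindingError(
                "no sign change of the net product flux on the default "
                f"geometric grid [{grid[0]:.3e}, {grid[-1]:.3e}]"
            )
        if len(brackets) > 1:
            warnings.warn(
                f"multiple product-flux sign changes found: {brackets}; "
                "taking the one nearest the declared product amount",
                stacklevel=2)
        if xP_star is None:
            # with several admissible roots, continue the branch anchored at
            # the declared product amount (nearest bracket on the log axis)
            lo, hi = min(brackets, key=lambda b: abs(
                0.5 * (np.log(b[0]) + np.log(b[1])) - np.log(xP0)))
    else:
        lo, hi = bracket
        if np.sign(residual(lo)) * np.sign(residual(hi)) > 0:
            raise RootFindingError(
                f"net product flux does not change sign over bracket "
                f"({lo:.6g}, {hi:.6g})"
            )
    if xP_star is None:
        xP_star = brentq(residual, lo, hi, xtol=xtol, rtol=8.9e-16)
    state = relax_open_loop(network, loop, xP_star, x0=x0, tol=relax_tol)
    x_full = network.state_vector(state)
    fP = _net_product_flux(network, loop, x_full)
    res = float(np.max(np.abs(network.state_derivative(x_full))))
    tol_eff = (relax_tol if relax_tol is not None
               else RELAX_TOL * max(1.0, network.flux_scale(x_full)))
    converged = res <= 10 * tol_eff and abs(fP) <= 10 * tol_eff
    return SteadyState(
        amounts=network.state_dict(x_full),
        product_flux=float(fP),
        residual=res,
        converged=bool(converged),
    )
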