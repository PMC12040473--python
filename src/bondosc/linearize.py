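"""Linearization about the loop-broken steady state.

The feedback loop carries both an effort-like variable (the product amount)
and a flow (the product flux).  Splitting the loop duplicates the product
into a feedback-side chemostat port Pf (substituted into the declared
feedback reactions) and an output-side chemostat port Po (all remaining
product reactions).  Linearizing the split network about the steady state
yields a two-input/two-output state-space model whose elements are the four
transfer functions

    [f_f]   [g11 g12] [x_f]
    [f_o] = [g21 g22] [x_o]

interpreted as an amplifier: g21 forward gain (the *active* feedback), g12
reverse gain, g11 input admittance, g22 output admittance (the passive
parts, i.e. retroactivity).  The single-port loop transfer function is
L0 = -(g11+g12+g21+g22); appending the product's integrator gives the loop
gain L = L0/s, decomposed as L = Lact + Lpas with Lact = -g21/s.

All Jacobians are analytic (mass action has closed-form derivatives); finite
differences are used only as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import BondoscError, ModelValidationError
from .network import LoopSpec, Network, Reaction, Species
from .steady import SteadyState

__all__ = [
    "StateSpaceModel",
    "RationalTransferFunction",
    "LoopDecomposition",
    "linearize",
    "split_loop",
    "loop_gains",
    "minimal_realization",
    "balanced_reduction",
    "closed_loop_jacobian",
]

#: relative tolerance for pruning cancelling pole/zero pairs after extraction
PRUNE_TOL = 1e-8


# --------------------------------------------------------------------------
# state-space container
# --------------------------------------------------------------------------
@dataclass
class StateSpaceModel:
    """A linear time-invariant model dx = Ax + Bu, y = Cx + Du."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    state_labels: tuple = ()
    input_labels: tuple = ()
    output_labels: tuple = ()

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, float))
        self.B = np.atleast_2d(np.asarray(self.B, float))
        self.C = np.atleast_2d(np.asarray(self.C, float))
        self.D = np.atleast_2d(np.asarray(self.D, float))
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ModelValidationError("A must be square")
        if self.B.shape[0] != n or self.C.shape[1] != n:
            raise ModelValidationError("B/C dimensions inconsistent with A")
        if self.D.shape != (self.C.shape[0], self.B.shape[1]):
            raise ModelValidationError("D dimensions inconsistent with B/C")
        for labels, count, what in (
            (self.state_labels, n, "state"),
            (self.input_labels, self.B.shape[1], "input"),
            (self.output_labels, self.C.shape[0], "output"),
        ):
            if labels and len(labels) != count:
                raise ModelValidationError(f"{what} labels length mismatch")
            if labels and len(set(labels)) != len(labels):
                raise ModelValidationError(f"duplicate {what} labels")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    def transfer(self, s: complex) -> np.ndarray:
        """Evaluate the transfer matrix C (sI - A)^-1 B + D."""
        n = self.n_states
        if n == 0:
            return self.D.astype(complex)
        X = np.linalg.solve(s * np.eye(n) - self.A, self.B)
        return self.C @ X + self.D

    def frequency_response(self, omegas) -> np.ndarray:
        """Transfer matrix evaluated at s = j*omega for each omega."""
        return np.array([self.transfer(1j * w) for w in np.atleast_1d(omegas)])


# --------------------------------------------------------------------------
# rational transfer functions in zero-pole-gain form
# --------------------------------------------------------------------------
def _pair_conjugates(roots: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Coerce near-conjugate root sets to exact conjugate pairs."""
    roots = np.asarray(roots, complex)
    if roots.size == 0:
        return roots
    scale = 1.0 + np.abs(roots)
    real_mask = np.abs(roots.imag) <= tol * scale
    reals = roots[real_mask].real
    cplx = roots[~real_mask]
    pos = sorted(cplx[cplx.imag > 0], key=lambda z: (z.real, z.imag))
    neg = sorted(cplx[cplx.imag < 0], key=lambda z: (z.real, -z.imag))
    paired = []
    for p in pos:
        if neg:
            # match with nearest conjugate candidate
            k = int(np.argmin([abs(np.conj(p) - q) for q in neg]))
            q = neg.pop(k)
            z = 0.5 * (p + np.conj(q))
            paired.extend([z, np.conj(z)])
        else:
            paired.extend([p, np.conj(p)])
    for q in neg:  # unmatched negatives
        paired.extend([np.conj(q), q])
    out = np.concatenate([reals.astype(complex), np.array(paired, complex)]) \
        if paired else reals.astype(complex)
    return np.sort_complex(out)


@dataclass
class RationalTransferFunction:
    """A SISO rational transfer function in zero-pole-gain form.

    G(s) = gain * prod(s - z) / prod(s - p).  Complex zeros and poles occur
    in conjugate pairs; an identically-zero transfer function is represented
    by gain 0 with empty zero/pole sets.
    """

    zeros: np.ndarray = field(default_factory=lambda: np.zeros(0, complex))
    poles: np.ndarray = field(default_factory=lambda: np.zeros(0, complex))
    gain: float = 0.0

    def __post_init__(self):
        self.zeros = _pair_conjugates(np.atleast_1d(np.asarray(self.zeros, complex)))
        self.poles = _pair_conjugates(np.atleast_1d(np.asarray(self.poles, complex)))
        self.gain = float(self.gain)
        if not np.isfinite(self.gain):
            raise ModelValidationError("transfer-function gain must be finite")
        if self.gain == 0.0:
            self.zeros = np.zeros(0, complex)
            self.poles = np.zeros(0, complex)

    # ------------------------------------------------------------ evaluation
    def __call__(self, s) -> complex:
        s = complex(s)
        num = self.gain * np.prod(s - self.zeros) if self.zeros.size else self.gain
        den = np.prod(s - self.poles) if self.poles.size else 1.0
        return num / den

    def frequency_response(self, omegas) -> np.ndarray:
        """Exact rational evaluation at s = j*omega."""
        om = np.atleast_1d(np.asarray(omegas, float))
        s = 1j * om
        num = np.full(om.shape, self.gain, complex)
        for z in self.zeros:
            num *= s - z
        den = np.ones(om.shape, complex)
        for p in self.poles:
            den *= s - p
        return num / den

    @staticmethod
    def _factor_angle(s: np.ndarray, root: complex) -> np.ndarray:
        """Angle of (s - root) on a branch continuous along the jw axis.

        For a left-half-plane root, (jw - root) stays in the right half of
        the complex plane and the principal angle is continuous.  For a
        right-half-plane root the locus lives in the left half, where the
        principal angle crosses its +-180 deg cut; evaluating the reflected
        factor (root - s), which stays in the right half, and shifting by
        180 deg gives the continuous branch.
        """
        if root.real > 0:
            return np.angle(root - s) + np.pi
        return np.angle(s - root)

    def phase_deg(self, omegas) -> np.ndarray:
        """Continuous phase in degrees, summed factor by factor.

        Each root contributes a branch-continuous angle, so no unwrapping
        step (and none of its grid-resolution pitfalls) is needed.
        """
        om = np.atleast_1d(np.asarray(omegas, float))
        s = 1j * om
        ph = np.zeros(om.shape)
        for z in self.zeros:
            ph += self._factor_angle(s, z)
        for p in self.poles:
            ph -= self._factor_angle(s, p)
        if self.gain < 0:
            ph += np.pi
        return np.degrees(ph)

    def gain_mag(self, omegas) -> np.ndarray:
        return np.abs(self.frequency_response(omegas))

    # --------------------------------------------------------- polynomial view
    def num_den(self):
        """Numerator/denominator coefficient sequences (descending powers)."""
        num = self.gain * np.real(np.poly(self.zeros)) if self.zeros.size \
            else np.array([self.gain])
        den = np.real(np.poly(self.poles)) if self.poles.size \
            else np.array([1.0])
        return num, den

    # ------------------------------------------------------------- arithmetic
    def __neg__(self):
        return RationalTransferFunction(self.zeros, self.poles, -self.gain)

    def __add__(self, other):
        if not isinstance(other, RationalTransferFunction):
            return NotImplemented
        if self.gain == 0.0:
            return RationalTransferFunction(other.zeros, other.poles, other.gain)
        if other.gain == 0.0:
            return RationalTransferFunction(self.zeros, self.poles, self.gain)
        n1, d1 = self.num_den()
        n2, d2 = other.num_den()
        num = np.polyadd(np.polymul(n1, d2), np.polymul(n2, d1))
        den = np.polymul(d1, d2)
        return _from_num_den(num, den, prune=PRUNE_TOL)

    def __sub__(self, other):
        return self.__add__(-other)

    def __mul__(self, other):
        if isinstance(other, RationalTransferFunction):
            out = RationalTransferFunction(
                np.concatenate([self.zeros, other.zeros]),
                np.concatenate([self.poles, other.poles]),
                self.gain * other.gain,
            )
            return minimal_realization(out, tol=PRUNE_TOL)
        return RationalTransferFunction(self.zeros, self.poles,
                                        self.gain * float(other))

    __rmul__ = __mul__

    def over_s(self):
        """Append the product integrator: G(s) -> G(s)/s."""
        if self.gain == 0.0:
            return RationalTransferFunction([], [], 0.0)
        return RationalTransferFunction(
            self.zeros, np.concatenate([self.poles, [0.0]]), self.gain)

    @property
    def order(self) -> int:
        return self.poles.size

    def __repr__(self):
        return (f"RationalTransferFunction(zeros={np.round(self.zeros, 6)}, "
                f"poles={np.round(self.poles, 6)}, gain={self.gain:.6g})")


def _from_num_den(num, den, prune: float = 0.0) -> RationalTransferFunction:
    num = np.trim_zeros(np.atleast_1d(np.asarray(num, float)), "f")
    den = np.trim_zeros(np.atleast_1d(np.asarray(den, float)), "f")
    if num.size == 0:
        return RationalTransferFunction([], [], 0.0)
    if den.size == 0:
        raise ModelValidationError("zero denominator polynomial")
    zeros = np.roots(num) if num.size > 1 else np.zeros(0)
    poles = np.roots(den) if den.size > 1 else np.zeros(0)
    gain = num[0] / den[0]
    tf = RationalTransferFunction(zeros, poles, gain)
    return minimal_realization(tf, tol=prune) if prune else tf


def ss_to_zpk(ss: StateSpaceModel, input_index: int = 0, output_index: int = 0,
              prune_tol: float = PRUNE_TOL) -> RationalTransferFunction:
    """Extract a SISO zero-pole-gain transfer function from a state space.

    Poles are the eigenvalues of A; zeros are the finite generalized
    eigenvalues of the Rosenbrock pencil; the gain is fixed by evaluating the
    transfer function at a real point away from all roots.  Cancelling
    pole/zero pairs (uncontrollable/unobservable modes) are pruned.
    """
    A = ss.A
    b = ss.B[:, [input_index]]
    c = ss.C[[output_index], :]
    d = ss.D[output_index, input_index]
    n = A.shape[0]
    if n == 0:
        return RationalTransferFunction([], [], float(d))
    poles = np.linalg.eigvals(A)
    # identically-zero channel: b or c structurally zero
    if (not np.any(b) or not np.any(c)) and d == 0.0:
        return RationalTransferFunction([], [], 0.0)
    M = np.block([[A, b], [c, np.array([[d]])]])
    N = np.diag(np.concatenate([np.ones(n), [0.0]]))
    w = scipy.linalg.eigvals(M, N)
    zeros = w[np.isfinite(w)]
    # large spurious generalized eigenvalues stand in for zeros at infinity
    scale = 1.0 + np.max(np.abs(poles))
    zeros = zeros[np.abs(zeros) < 1e9 * scale]
    tf = RationalTransferFunction(zeros, poles, 1.0)
    tf = minimal_realization(tf, tol=prune_tol)
    # calibrate the gain at real evaluation points clear of all roots
    roots = np.concatenate([tf.zeros, tf.poles])
    rmax = np.max(np.abs(roots)) if roots.size else 1.0
    gains = []
    for mult in (2.3, 3.7, 5.1):
        s0 = mult * (1.0 + rmax)
        ref = complex(ss.transfer(s0)[output_index, input_index])
        raw = tf(s0)
        if abs(raw) > 0:
            gains.append((ref / raw).real)
    if not gains:
        return RationalTransferFunction([], [], 0.0)
    gain = float(np.median(gains))
    if abs(gain) < 1e-300:
        return RationalTransferFunction([], [], 0.0)
    return RationalTransferFunction(tf.zeros, tf.poles, gain)


def minimal_realization(tf, tol: float = 1e-7):
    """Remove near-cancelling pole/zero pairs.

    Pairs whose distance is at most ``tol`` relative to their magnitude are
    cancelled greedily, closest pair first.  Accepts a zero-pole-gain
    transfer function or a SISO :class:`StateSpaceModel` (returned as a
    reduced model of the same kind).
    """
    if tol is None or tol <= 0:
        raise ValueError("minimal_realization tolerance must be > 0")
    if isinstance(tf, StateSpaceModel):
        if tf.B.shape[1] != 1 or tf.C.shape[0] != 1:
            raise ModelValidationError(
                "minimal_realization of a state space requires a SISO model")
        zpk = ss_to_zpk(tf, prune_tol=tol)
        return zpk_to_ss(zpk)
    zeros = list(tf.zeros)
    poles = list(tf.poles)
    changed = True
    while changed and zeros and poles:
        changed = False
        best = None
        for i, z in enumerate(zeros):
            for j, p in enumerate(poles):
                d = abs(z - p)
                if d <= tol * max(1.0, abs(p), abs(z)):
                    if best is None or d < best[0]:
                        best = (d, i, j)
        if best is not None:
            _, i, j = best
            zeros.pop(i)
            poles.pop(j)
            changed = True
    return RationalTransferFunction(np.array(zeros), np.array(poles), tf.gain)


def zpk_to_ss(tf: RationalTransferFunction) -> StateSpaceModel:
    """Controllable-canonical state-space realization of a SISO zpk model."""
    num, den = tf.num_den()
    if den.size == 1:
        return StateSpaceModel(np.zeros((0, 0)), np.zeros((0, 1)),
                               np.zeros((1, 0)), np.array([[num[0] / den[0]]]))
    import scipy.signal

    A, B, C, D = scipy.signal.tf2ss(num, den)
    return StateSpaceModel(A, B, C, D)


# --------------------------------------------------------------------------
# split-loop linearization
# --------------------------------------------------------------------------
@dataclass
class LoopDecomposition:
    """The split-loop two-port and the derived loop-gain transfer functions."""

    g11: RationalTransferFunction
    g12: RationalTransferFunction
    g21: RationalTransferFunction
    g22: RationalTransferFunction
    L0: RationalTransferFunction
    L: RationalTransferFunction
    Lact: RationalTransferFunction
    Lpas: RationalTransferFunction
    two_port: StateSpaceModel = None


def _substitute_species(reaction: Reaction, old: str, new: str) -> Reaction:
    def sub(side):
        return {new if sp == old else sp: s for sp, s in side.items()}

    return Reaction(reaction.name, reaction.kappa,
                    sub(reaction.reactants), sub(reaction.products))


def split_product_network(network: Network, loop: LoopSpec, xP: float):
    """Duplicate the product into feedback/output chemostat ports.

    Returns the split network plus the names of the two port species.  Both
    ports inherit the product's thermodynamic constant and are clamped at
    the steady-state amount ``xP``.
    """
    loop.require_two_sides(network)
    prod = loop.product
    p_spec = network.species[network.species_index(prod)]
    fb = set(loop.feedback_reactions)
    species = [s for s in network.species if s.name != prod]
    species.append(Species(prod + "__f", p_spec.K, xP, is_chemostat=True))
    species.append(Species(prod + "__o", p_spec.K, xP, is_chemostat=True))
    reactions = []
    for r in network.reactions:
        if prod in r.species:
            port = prod + "__f" if r.name in fb else prod + "__o"
            reactions.append(_substitute_species(r, prod, port))
        else:
            reactions.append(r)
    return Network(species, reactions, network.RT), prod + "__f", prod + "__o"


def linearize(network: Network, loop: LoopSpec, steady: SteadyState,
              require_converged: bool = True) -> StateSpaceModel:
    """Two-port linearization of the split loop about the steady state.

    Inputs are the clamped port amounts (x_f, x_o); outputs are the net port
    flows (f_f, f_o) of the product through the feedback-side and
    output-side reactions.  A is the analytic Jacobian of the mass-action
    RHS at the steady state; B the sensitivities to the port amounts; C/D
    the flow read-outs and direct flux sensitivities.
    """
    if require_converged and not steady.converged:
        raise BondoscError(
            "linearization requires a converged steady state "
            f"(residual {steady.residual:.3e})"
        )
    xP = steady.amounts[loop.product]
    split, pf, po = split_product_network(network, loop, xP)
    x_full = split.state_vector(
        {**{k: v for k, v in steady.amounts.items() if k != loop.product},
         pf: xP, po: xP})
    dyn_idx = split._dyn
    i_pf = split.species_index(pf)
    i_po = split.species_index(po)
    Jf = split.flux_jacobian(x_full)
    S_dyn = split.stoichiometric_matrix[dyn_idx]
    A = S_dyn @ Jf[:, dyn_idx]
    B = S_dyn @ Jf[:, [i_pf, i_po]]
    # port flow read-outs: net product flux through each reaction side
    rows = []
    for alias, rnames in ((pf, loop.feedback_reactions),
                          (po, loop.output_reactions(network))):
        w = np.zeros(len(split.reactions))
        for rn in rnames:
            j = split.reaction_names.index(rn)
            w[j] = split.reactions[j].net_stoichiometry(alias)
        rows.append(w)
    W = np.array(rows)
    C = W @ Jf[:, dyn_idx]
    D = W @ Jf[:, [i_pf, i_po]]
    return StateSpaceModel(
        A, B, C, D,
        state_labels=split.dynamic_species,
        input_labels=("x_f", "x_o"),
        output_labels=("f_f", "f_o"),
    )


def single_port_l0(network: Network, loop: LoopSpec,
                   steady: SteadyState) -> RationalTransferFunction:
    """L0 computed directly from the unsplit single-port configuration.

    The product is clamped as one chemostat; L0 is minus the transfer
    function from its amount to the total net product flux.  Used as the
    independent check of the split-loop sum identity.
    """
    xP = steady.amounts[loop.product]
    clamped = network.with_chemostats({loop.product: xP})
    x_full = clamped.state_vector(steady.amounts)
    dyn_idx = clamped._dyn
    iP = clamped.species_index(loop.product)
    Jf = clamped.flux_jacobian(x_full)
    S_dyn = clamped.stoichiometric_matrix[dyn_idx]
    A = S_dyn @ Jf[:, dyn_idx]
    B = S_dyn @ Jf[:, [iP]]
    w = np.array([r.net_stoichiometry(loop.product) for r in clamped.reactions],
                 float)
    C = -(w @ Jf[:, dyn_idx])[None, :]
    D = -np.array([[w @ Jf[:, iP]]])
    ss = StateSpaceModel(A, B, C, D, state_labels=clamped.dynamic_species)
    return ss_to_zpk(ss)


def split_loop(network: Network, loop: LoopSpec,
               steady: SteadyState) -> LoopDecomposition:
    """Split-loop decomposition: two-port elements plus L0, L, Lact, Lpas."""
    ss = linearize(network, loop, steady)
    g11 = ss_to_zpk(ss, 0, 0)
    g12 = ss_to_zpk(ss, 1, 0)
    g21 = ss_to_zpk(ss, 0, 1)
    g22 = ss_to_zpk(ss, 1, 1)
    # L0 from the same two-port model with both ports driven together and
    # the total flow negated: exactly -(g11+g12+g21+g22) without polynomial
    # round-trips.
    B_sum = ss.B.sum(axis=1, keepdims=True)
    C_sum = -ss.C.sum(axis=0, keepdims=True)
    D_sum = -np.array([[ss.D.sum()]])
    L0 = ss_to_zpk(StateSpaceModel(ss.A, B_sum, C_sum, D_sum))
    L = L0.over_s()
    Lact_0 = ss_to_zpk(StateSpaceModel(ss.A, ss.B[:, [0]], -ss.C[[1], :],
                                       -ss.D[[1], [0]][None]))
    Lact = Lact_0.over_s()
    # L0pas = -(g11 + g12 + g22): two copies of the dynamics, one driven by
    # both ports and read at the feedback flow, one driven by the output
    # port and read at the output flow.
    n = ss.A.shape[0]
    Az = np.zeros((n, n))
    A2 = np.block([[ss.A, Az], [Az, ss.A]])
    B2 = np.vstack([B_sum, ss.B[:, [1]]])
    C2 = np.hstack([-ss.C[[0], :], -ss.C[[1], :]])
    D2 = -np.array([[ss.D[0, 0] + ss.D[0, 1] + ss.D[1, 1]]])
    Lpas = ss_to_zpk(StateSpaceModel(A2, B2, C2, D2)).over_s()
    return LoopDecomposition(g11=g11, g12=g12, g21=g21, g22=g22,
                             L0=L0, L=L, Lact=Lact, Lpas=Lpas, two_port=ss)


def loop_gains(decomp: LoopDecomposition):
    """(L, Lact, Lpas) with the integrator appended exactly."""
    return decomp.L, decomp.Lact, decomp.Lpas


def closed_loop_jacobian(network: Network, steady: SteadyState) -> np.ndarray:
    """Jacobian of the full closed-loop RHS at the steady state.

    Its eigenvalues are the closed-loop poles (up to modes cancelled in the
    loop-gain transfer function); used as the eigenvalue oracle for
    1 + L = 0.
    """
    x_full = network.state_vector(steady.amounts)
    return network.jacobian_dynamic(x_full)


# --------------------------------------------------------------------------
# balanced order reduction
# --------------------------------------------------------------------------
def _gramian_factor(A, X):
    """Square-root factor of a (possibly semidefinite) Gramian."""
    W = scipy.linalg.solve_continuous_lyapunov(A, -X)
    W = 0.5 * (W + W.T)
    vals, vecs = np.linalg.eigh(W)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def balanced_reduction(ss: StateSpaceModel, order: int):
    """Balanced truncation of an asymptotically stable state-space model.

    Returns ``(reduced_model, discarded_hankel_singular_values)``.  The
    classical bound guarantees a peak frequency-response error of at most
    twice the sum of the discarded Hankel singular values.
    """
    n = ss.n_states
    if not (1 <= order <= n):
        raise ValueError(f"order must be in [1, {n}] (got {order})")
    eigs = np.linalg.eigvals(ss.A)
    if np.any(eigs.real >= 0):
        raise BondoscError(
            "balanced reduction requires an asymptotically stable model; "
            f"max Re(eig) = {np.max(eigs.real):.3e}"
        )
    Lc = _gramian_factor(ss.A, ss.B @ ss.B.T)
    Lo = _gramian_factor(ss.A.T, ss.C.T @ ss.C)
    U, hsv, Vt = np.linalg.svd(Lo.T @ Lc)
    k = order
    pos = hsv > 1e-14 * (hsv[0] if hsv.size else 1.0)
    k = min(k, int(np.count_nonzero(pos)))
    s_inv_sqrt = 1.0 / np.sqrt(hsv[:k])
    T = Lc @ Vt[:k].T * s_inv_sqrt
    Tinv = (U[:, :k] * s_inv_sqrt).T @ Lo.T
    Ar = Tinv @ ss.A @ T
    Br = Tinv @ ss.B
    Cr = ss.C @ T
    reduced = StateSpaceModel(Ar, Br, Cr, ss.D.copy(),
                              input_labels=ss.input_labels,
                              output_labels=ss.output_labels)
    return reduced, hsv[k:]


# --------------------------------------------------------------------------
# finite-difference oracle (kept here for reuse by tests)
# --------------------------------------------------------------------------
def finite_difference_jacobian(fun, x, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite differences of ``fun`` at ``x`` (test oracle)."""
    x = np.asarray(x, float)
    f0 = np.asarray(fun(x), float)
    J = np.zeros((f0.size, x.size))
    for i in range(x.size):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (np.asarray(fun(xp), float) - np.asarray(fun(xm), float)) / (2 * h)
    return J
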