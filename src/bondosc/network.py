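"""Energy-based mass-action reaction networks.

A network is a set of species stores and mass-action reaction elements in the
bond-graph (thermodynamic) parameterization: each species carries a
thermodynamic constant ``K`` and an amount ``x``; its chemical potential is
``phi = RT ln(K x)`` and the net flux of a reaction is

    v_r = kappa_r * ( prod_reactants (K_i x_i)^s_i - prod_products (K_j x_j)^s_j )

so that the flux vanishes exactly at thermodynamic equilibrium of the
reaction.  Species flagged as *chemostats* have their amount held constant by
an implicit external flow; they parameterize the open-system boundary and are
also used to break feedback loops.

The state vector of the dynamical system is the vector of amounts of the
*dynamic* (non-chemostat) species in declaration order; this ordering is
stable and is relied upon by the linearization machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy

from .errors import DomainError, ModelValidationError

__all__ = [
    "Species",
    "Reaction",
    "Network",
    "FluxVector",
    "LoopSpec",
]


@dataclass(frozen=True)
class Species:
    """A species store with thermodynamic constant K and amount x.

    ``K`` is the (normalized, per-amount) thermodynamic constant relating the
    amount to the chemical potential; ``amount`` is the normalized amount of
    substance.  A chemostat's amount is held constant under every simulation
    and steady-state operation.
    """

    name: str
    K: float = 1.0
    amount: float = 1.0
    is_chemostat: bool = False

    def __post_init__(self):
        errs = []
        if not self.name or not isinstance(self.name, str):
            errs.append("species name must be a nonempty string")
        if not (self.K > 0):
            errs.append(f"species {self.name!r}: K must be > 0 (got {self.K})")
        if not (self.amount >= 0):
            errs.append(
                f"species {self.name!r}: amount must be >= 0 (got {self.amount})"
            )
        if errs:
            raise ModelValidationError(errs)


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction element with rate constant kappa.

    Stoichiometries are positive integers; a species may appear on both sides
    (a catalyst).  Cooperativity enters as stoichiometric multiplicity of the
    catalytic species, which raises its activity to the corresponding power in
    the flux.
    """

    name: str
    kappa: float
    reactants: Mapping[str, int] = field(default_factory=dict)
    products: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        errs = []
        if not self.name or not isinstance(self.name, str):
            errs.append("reaction name must be a nonempty string")
        if not (self.kappa > 0):
            errs.append(f"reaction {self.name!r}: kappa must be > 0 (got {self.kappa})")
        for side, label in ((self.reactants, "reactants"), (self.products, "products")):
            if not side:
                errs.append(f"reaction {self.name!r}: {label} side is empty")
            for sp, s in side.items():
                if not (isinstance(s, (int, np.integer)) and s > 0):
                    errs.append(
                        f"reaction {self.name!r}: stoichiometry of {sp!r} must be a "
                        f"positive integer (got {s!r})"
                    )
        if errs:
            raise ModelValidationError(errs)
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))

    def net_stoichiometry(self, species_name: str) -> int:
        """Net production of ``species_name`` per unit forward flux."""
        return self.products.get(species_name, 0) - self.reactants.get(species_name, 0)

    @property
    def species(self) -> set:
        return set(self.reactants) | set(self.products)


@dataclass
class FluxVector:
    """Per-reaction net fluxes (normalized amount per unit time)."""

    reactions: tuple
    values: np.ndarray

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.reactions.index(name)])

    def as_dict(self) -> dict:
        return {r: float(v) for r, v in zip(self.reactions, self.values)}


class Network:
    """An executable energy-based reaction network.

    Parameters
    ----------
    species:
        Ordered collection of :class:`Species`; names must be unique.  The
        state-vector ordering of the dynamical system is the declaration
        order of the dynamic (non-chemostat) species.
    reactions:
        Ordered collection of :class:`Reaction`; every referenced species
        must be declared.
    RT:
        Normalized energy unit; enters only the reported chemical potentials
        (linearization is carried out in amounts, not potentials).
    """

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction],
                 RT: float = 1.0):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.RT = float(RT)
        self._validate()
        self._index = {s.name: i for i, s in enumerate(self.species)}
        self._r_index = {r.name: i for i, r in enumerate(self.reactions)}
        ns, nr = len(self.species), len(self.reactions)
        # exponent matrices (reactions x species) and net stoichiometry
        self._Ar = np.zeros((nr, ns))
        self._Ap = np.zeros((nr, ns))
        for j, r in enumerate(self.reactions):
            for sp, s in r.reactants.items():
                self._Ar[j, self._index[sp]] = s
            for sp, s in r.products.items():
                self._Ap[j, self._index[sp]] = s
        self._S = (self._Ap - self._Ar).T  # species x reactions
        self._K = np.array([s.K for s in self.species])
        self._chemostat = np.array([s.is_chemostat for s in self.species])
        self._dyn = np.flatnonzero(~self._chemostat)
        self._kappa = np.array([r.kappa for r in self.reactions])

    # ------------------------------------------------------------------ misc
    def _validate(self):
        errs = []
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            errs.append(f"duplicate species names: {dupes}")
        rnames = [r.name for r in self.reactions]
        if len(set(rnames)) != len(rnames):
            dupes = sorted({n for n in rnames if rnames.count(n) > 1})
            errs.append(f"duplicate reaction names: {dupes}")
        declared = set(names)
        for r in self.reactions:
            for sp in r.species:
                if sp not in declared:
                    errs.append(
                        f"reaction {r.name!r} references undeclared species {sp!r}"
                    )
        if errs:
            raise ModelValidationError(errs)

    @property
    def species_names(self) -> tuple:
        return tuple(s.name for s in self.species)

    @property
    def reaction_names(self) -> tuple:
        return tuple(r.name for r in self.reactions)

    @property
    def dynamic_species(self) -> tuple:
        """Names of the dynamic species, in state-vector order."""
        return tuple(self.species[i].name for i in self._dyn)

    @property
    def n_states(self) -> int:
        return len(self._dyn)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ModelValidationError(f"unknown species {name!r}") from None

    def reaction(self, name: str) -> Reaction:
        try:
            return self.reactions[self._r_index[name]]
        except KeyError:
            raise ModelValidationError(f"unknown reaction {name!r}") from None

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometric matrix (species x reactions), chemostats included."""
        return self._S.copy()

    # ----------------------------------------------------------- state plumbing
    def state_vector(self, state=None) -> np.ndarray:
        """Full amount vector over all species in declaration order.

        ``state`` may be None (declared amounts), a mapping (must cover every
        species) or a full-length sequence.
        """
        if state is None:
            return np.array([s.amount for s in self.species], float)
        if isinstance(state, Mapping):
            missing = [s.name for s in self.species if s.name not in state]
            if missing:
                raise ModelValidationError(
                    [f"state missing species {m!r}" for m in missing]
                )
            unknown = [k for k in state if k not in self._index]
            if unknown:
                raise ModelValidationError(
                    [f"state contains unknown species {u!r}" for u in unknown]
                )
            x = np.array([float(state[s.name]) for s in self.species])
        else:
            x = np.asarray(state, float)
            if x.shape != (len(self.species),):
                raise ModelValidationError(
                    f"state vector has shape {x.shape}, expected ({len(self.species)},)"
                )
            x = x.copy()
        if np.any(x < 0):
            bad = [self.species[i].name for i in np.flatnonzero(x < 0)]
            raise DomainError(f"negative amounts for species {bad}")
        return x

    def state_dict(self, x_full: np.ndarray) -> dict:
        return {s.name: float(v) for s, v in zip(self.species, x_full)}

    def full_from_dynamic(self, x_dyn: np.ndarray, base=None) -> np.ndarray:
        """Embed a dynamic-state vector into a full amount vector.

        Chemostat amounts come from ``base`` (default: declared amounts).
        """
        if base is None:
            x = np.array([s.amount for s in self.species], float)
        else:
            x = self.state_vector(base)
        x[self._dyn] = x_dyn
        return x

    def dynamic_part(self, x_full: np.ndarray) -> np.ndarray:
        return np.asarray(x_full, float)[self._dyn]

    # ------------------------------------------------------------------ physics
    def flux_values(self, x_full: np.ndarray) -> np.ndarray:
        """Net reaction fluxes at a full amount vector (fast path)."""
        a = self._K * x_full
        # 0**0 == 1 under np.power for these exponent matrices
        fwd = np.prod(np.power(a[None, :], self._Ar), axis=1)
        rev = np.prod(np.power(a[None, :], self._Ap), axis=1)
        return self._kappa * (fwd - rev)

    def flux_scale(self, x_full: np.ndarray) -> float:
        """Magnitude of the largest one-way (forward or reverse) flux.

        Net fluxes are differences of one-way fluxes, so this is the scale
        against which a steady-state residual is numerically meaningful.
        """
        a = self._K * x_full
        fwd = np.prod(np.power(a[None, :], self._Ar), axis=1) * self._kappa
        rev = np.prod(np.power(a[None, :], self._Ap), axis=1) * self._kappa
        return float(max(fwd.max(initial=0.0), rev.max(initial=0.0)))

    def reaction_flux(self, state=None) -> FluxVector:
        """Mass-action net flux of every reaction at ``state``."""
        x = self.state_vector(state)
        return FluxVector(self.reaction_names, self.flux_values(x))

    def flux_jacobian(self, x_full: np.ndarray) -> np.ndarray:
        """Analytic derivative of the flux vector w.r.t. every species amount.

        Returns an (n_reactions x n_species) array.  Mass action has closed
        form derivatives; amounts equal to zero are handled by evaluating the
        product excluding the differentiated species.
        """
        a = self._K * x_full
        nr, ns = self._Ar.shape
        J = np.zeros((nr, ns))
        for j in range(nr):
            for sign, A in ((1.0, self._Ar), (-1.0, self._Ap)):
                row = A[j]
                for i in np.flatnonzero(row):
                    s = row[i]
                    others = np.prod(np.power(
                        np.delete(a, i), np.delete(row, i)))
                    J[j, i] += sign * self._kappa[j] * s * self._K[i] \
                        * a[i] ** (s - 1) * others
        return J

    def rhs_dynamic(self, x_dyn: np.ndarray, base=None) -> np.ndarray:
        """Time derivative of the dynamic state (chemostats clamped)."""
        x = self.full_from_dynamic(np.asarray(x_dyn, float), base)
        v = self.flux_values(x)
        return self._S[self._dyn] @ v

    def state_derivative(self, state=None) -> np.ndarray:
        """dx/dt over the dynamic species; chemostat rows are omitted
        (they are identically zero by construction)."""
        x = self.state_vector(state)
        return self._S[self._dyn] @ self.flux_values(x)

    def jacobian_dynamic(self, x_full: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the dynamic RHS w.r.t. the dynamic state."""
        Jf = self.flux_jacobian(x_full)
        return self._S[self._dyn] @ Jf[:, self._dyn]

    def chemical_potential(self, state=None) -> dict:
        """phi = RT ln(K x) per species; requires strictly positive amounts."""
        x = self.state_vector(state)
        if np.any(x <= 0):
            bad = [self.species[i].name for i in np.flatnonzero(x <= 0)]
            raise DomainError(
                f"chemical potential undefined at zero/negative amount: {bad}"
            )
        return {
            s.name: self.RT * math.log(s.K * xi) for s, xi in zip(self.species, x)
        }

    def conserved_moieties(self) -> np.ndarray:
        """Basis of conservation vectors over the dynamic species.

        Each row ``g`` satisfies ``g @ S_dyn == 0`` where ``S_dyn`` is the
        stoichiometric matrix restricted to dynamic species; the rows span
        the left null space.  Computed exactly over the rationals and scaled
        to smallest integer form.
        """
        S_dyn = sympy.Matrix(self._S[self._dyn].astype(int))
        basis = S_dyn.T.nullspace()
        rows = []
        for vec in basis:
            denoms = [sympy.Rational(val).q for val in vec]
            scale = sympy.ilcm(*denoms) if denoms else 1
            v = np.array([float(val * scale) for val in vec])
            nz = v[np.nonzero(v)]
            if nz.size and nz[0] < 0:
                v = -v
            rows.append(v)
        if not rows:
            return np.zeros((0, len(self._dyn)))
        return np.array(rows)

    # -------------------------------------------------------------- rebuilding
    def with_chemostats(self, clamped: Mapping[str, float]) -> "Network":
        """Copy of the network with the given species clamped at given amounts."""
        new_species = []
        for s in self.species:
            if s.name in clamped:
                new_species.append(Species(s.name, s.K, float(clamped[s.name]), True))
            else:
                new_species.append(s)
        return Network(new_species, self.reactions, self.RT)

    def with_amounts(self, amounts: Mapping[str, float]) -> "Network":
        """Copy of the network with declared amounts updated."""
        new_species = [
            Species(s.name, s.K, float(amounts.get(s.name, s.amount)), s.is_chemostat)
            for s in self.species
        ]
        return Network(new_species, self.reactions, self.RT)

    def __repr__(self):
        return (f"Network({len(self.species)} species, "
                f"{len(self.reactions)} reactions, {self.n_states} states)")


@dataclass(frozen=True)
class LoopSpec:
    """Designation of the feedback loop to be broken.

    ``product`` is the species whose accumulation closes the loop;
    ``feedback_reactions`` are the reactions through which the product acts
    back on the network (the feedback-side port).  All remaining reactions
    involving the product form the output-side port.  The partition must be
    declared explicitly; it is not inferred.
    """

    product: str
    feedback_reactions: tuple

    def __post_init__(self):
        object.__setattr__(self, "feedback_reactions",
                           tuple(self.feedback_reactions))

    def validate(self, network: Network):
        errs = []
        if self.product not in network.species_names:
            errs.append(f"loop product {self.product!r} is not a declared species")
        elif network.species[network.species_index(self.product)].is_chemostat:
            errs.append(f"loop product {self.product!r} must be a dynamic species")
        if not self.feedback_reactions:
            errs.append("loop feedback_reactions is empty")
        rnames = set(network.reaction_names)
        for rn in self.feedback_reactions:
            if rn not in rnames:
                errs.append(f"feedback reaction {rn!r} is not declared")
            elif self.product in network.species_names and \
                    self.product not in network.reaction(rn).species:
                errs.append(
                    f"feedback reaction {rn!r} does not involve product "
                    f"{self.product!r}"
                )
        if errs:
            raise ModelValidationError(errs)

    def require_two_sides(self, network: Network):
        """Fail unless both ports are nonempty (needed for loop splitting;
        steady-state loop breaking tolerates a feedback-only product)."""
        self.validate(network)
        if not self.output_reactions(network):
            raise ModelValidationError(
                "loop output side is empty: every product reaction is on the "
                "feedback side"
            )

    def output_reactions(self, network: Network) -> tuple:
        """Reactions involving the product that are not on the feedback side."""
        fb = set(self.feedback_reactions)
        return tuple(
            r.name for r in network.reactions
            if self.product in r.species and r.name not in fb
        )
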