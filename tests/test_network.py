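"""Mass-action flux, state derivatives, moieties and potentials."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import null_space

from bondosc import (DomainError, ModelValidationError, Network, Reaction,
                     Species)
from conftest import make_random_network


def ecr_network(KE=1.0, kr=2.0, KA=3.0, KP=1.0):
    """Cooperative enzyme-catalysed conversion A + 2E <-> 2E + P."""
    return Network(
        [Species("A", K=KA, amount=1.0, is_chemostat=True),
         Species("E", K=KE, amount=2.0),
         Species("P", K=KP, amount=1.0)],
        [Reaction("r", kappa=kr, reactants={"A": 1, "E": 2},
                  products={"E": 2, "P": 1})],
    )


class TestReactionFlux:
    def test_symmetric_equilibrium_has_zero_flux(self):
        net = Network(
            [Species(n) for n in ("Act", "E0", "E", "Inh")],
            [Reaction("r", kappa=1.0, reactants={"Act": 1, "E0": 1},
                      products={"E": 1, "Inh": 1})],
        )
        assert net.reaction_flux()["r"] == 0.0

    def test_cooperative_conversion_flux_value(self):
        # v = kappa * (K_E x_E)^2 * (K_A x_A - K_P x_P) = 2 * 4 * (3 - 1)
        net = ecr_network()
        assert net.reaction_flux()["r"] == pytest.approx(16.0)

    def test_selkov_supply_flux_matches_throughput(self):
        # slow supply from a strong chemostat: v ~ kappa_rs * K_ATP0 ~ 0.6
        from bondosc import build_selkov

        net, _ = build_selkov()
        v = net.reaction_flux()["rs"]
        assert v == pytest.approx(0.6, rel=2e-3)

    def test_unknown_species_in_state_rejected(self):
        net = ecr_network()
        state = {s: 1.0 for s in net.species_names}
        state["Ghost"] = 1.0
        with pytest.raises(ModelValidationError):
            net.reaction_flux(state)

    def test_negative_amount_rejected(self):
        net = ecr_network()
        state = {s: 1.0 for s in net.species_names}
        state["E"] = -0.5
        with pytest.raises(DomainError):
            net.reaction_flux(state)

    @given(st.floats(0.1, 5.0), st.floats(0.1, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_flux_sign_follows_mass_action_imbalance(self, xA, xP):
        net = ecr_network()
        state = {"A": xA, "E": 1.3, "P": xP}
        v = net.reaction_flux(state)["r"]
        imbalance = 3.0 * xA - 1.0 * xP
        assert np.sign(v) == np.sign(imbalance)


class TestStateDerivative:
    def test_equilibrated_exchange_is_steady(self):
        net = Network(
            [Species("A", K=1.0, amount=2.0), Species("P", K=2.0, amount=1.0)],
            [Reaction("r", kappa=3.0, reactants={"A": 1}, products={"P": 1})],
        )
        assert np.allclose(net.state_derivative(), 0.0)

    def test_moiety_weighted_sum_vanishes_in_closed_network(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            net = make_random_network(rng)
            G = net.conserved_moieties()
            x = {n: float(rng.uniform(0.1, 3.0)) for n in net.species_names}
            dx = net.state_derivative(x)
            if G.size:
                assert np.allclose(G @ dx, 0.0, atol=1e-12 * max(1, np.max(np.abs(dx))))

    def test_reference_steady_state_is_near_stationary(self, illustrative):
        # printed 2-decimal state: residual small relative to flux scale
        net, _ = illustrative
        state = {"Act": 1.0, "E0": 1.0, "A": 1.0, "Zf": 1.0,
                 "E1": 0.17, "E2": 0.28, "E3": 0.79, "P": 5.94}
        dx = net.state_derivative(state)
        assert np.max(np.abs(dx)) < 1.0  # fluxes are O(100); rounding-level residual


class TestConservedMoieties:
    def test_pure_catalyst_has_singleton_conservation(self):
        net = ecr_network()
        G = net.conserved_moieties()
        # E is dynamic index 0, P index 1
        assert G.shape == (1, 2)
        assert np.allclose(G[0], [1.0, 0.0])

    def test_bound_unbound_enzyme_pair_is_conserved(self):
        net = Network(
            [Species("Act", is_chemostat=True), Species("E0"), Species("E"),
             Species("Inh", is_chemostat=True)],
            [Reaction("r", kappa=1.0, reactants={"Act": 1, "E0": 1},
                      products={"E": 1, "Inh": 1})],
        )
        G = net.conserved_moieties()
        assert G.shape == (1, 2)
        assert np.allclose(G[0], [1.0, 1.0])

    def test_basis_matches_dense_nullspace_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            net = make_random_network(rng)
            S_dyn = net.stoichiometric_matrix  # all species dynamic here
            oracle = null_space(S_dyn.T).T
            G = net.conserved_moieties()
            assert G.shape[0] == oracle.shape[0]
            if G.shape[0]:
                # same row space: each basis vector lies in the oracle span
                proj = oracle.T @ np.linalg.lstsq(oracle.T, G.T, rcond=None)[0]
                assert np.allclose(proj, G.T, atol=1e-9)


class TestChemicalPotential:
    def test_unit_activity_gives_zero_potential(self):
        net = ecr_network()
        phi = net.chemical_potential({"A": 1.0, "E": 1.0, "P": 1.0})
        assert phi["E"] == pytest.approx(0.0)

    def test_activity_e_gives_rt(self):
        net = Network([Species("X", K=1.0, amount=math.e)], [
            Reaction("r", kappa=1.0, reactants={"X": 1}, products={"X": 1})])
        assert net.chemical_potential()["X"] == pytest.approx(1.0)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_potential_increases_with_amount(self, x1, dx):
        net = ecr_network()
        lo = net.chemical_potential({"A": 1.0, "E": x1, "P": 1.0})["E"]
        hi = net.chemical_potential({"A": 1.0, "E": x1 + dx, "P": 1.0})["E"]
        assert hi > lo

    def test_zero_amount_is_a_domain_error(self):
        net = ecr_network()
        with pytest.raises(DomainError):
            net.chemical_potential({"A": 1.0, "E": 0.0, "P": 1.0})


class TestValidation:
    def test_undeclared_species_reported_by_name(self):
        with pytest.raises(ModelValidationError, match="Ghost"):
            Network([Species("A")], [Reaction("r", kappa=1.0,
                                              reactants={"A": 1},
                                              products={"Ghost": 1})])

    def test_all_offenses_reported_together(self):
        with pytest.raises(ModelValidationError) as exc:
            Network(
                [Species("A"), Species("A")],
                [Reaction("r", kappa=1.0, reactants={"A": 1},
                          products={"B": 1})],
            )
        assert len(exc.value.messages) >= 2

    def test_nonpositive_rate_constant_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction("r", kappa=0.0, reactants={"A": 1}, products={"B": 1})

    def test_fractional_stoichiometry_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction("r", kappa=1.0, reactants={"A": 1.5}, products={"B": 1})
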