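"""Split-loop linearization, transfer-function extraction and reduction."""

import numpy as np
import pytest

from bondosc import (LoopSpec, Network, Reaction, Species,
                     RationalTransferFunction, StateSpaceModel,
                     balanced_reduction, closed_loop_jacobian, linearize,
                     loop_gains, minimal_realization, split_loop)
from bondosc.errors import BondoscError
from bondosc.linearize import (finite_difference_jacobian, single_port_l0,
                               ss_to_zpk, zpk_to_ss)


def activation_inhibition_network(kr=1.3, KE=1.7, KInh=0.6, xE=0.9, xInh=1.4):
    """Act + E0 <-> E + Inh with all four species present."""
    return Network(
        [Species("Act", K=1.0, amount=1.0, is_chemostat=True),
         Species("E0", K=1.0, amount=1.0, is_chemostat=True),
         Species("E", K=KE, amount=xE),
         Species("Inh", K=KInh, amount=xInh)],
        [Reaction("r", kappa=kr, reactants={"Act": 1, "E0": 1},
                  products={"E": 1, "Inh": 1})],
    )


class TestFluxSensitivities:
    def test_activation_reaction_partials(self):
        # d f_r / d x_Inh = -kr K_E K_Inh x_E ; d f_r / d x_E = -kr K_E K_Inh x_Inh
        kr, KE, KInh, xE, xInh = 1.3, 1.7, 0.6, 0.9, 1.4
        net = activation_inhibition_network(kr, KE, KInh, xE, xInh)
        J = net.flux_jacobian(net.state_vector())
        iE, iInh = net.species_index("E"), net.species_index("Inh")
        assert J[0, iInh] == pytest.approx(-kr * KE * KInh * xE)
        assert J[0, iE] == pytest.approx(-kr * KE * KInh * xInh)

    def test_cooperative_conversion_partials(self):
        # d v_P/d x_E = 2 K_E^2 kr x_E (K_A x_A - K_P x_P)
        # d v_P/d x_P = -K_E^2 kr x_E^2 K_P - krf K_P
        KE, kr, KA, KP, krf = 1.2, 2.0, 3.0, 0.8, 0.5
        xE, xA, xP = 1.1, 1.0, 0.7
        net = Network(
            [Species("A", K=KA, amount=xA, is_chemostat=True),
             Species("Zf", K=1e-6, amount=1.0, is_chemostat=True),
             Species("E", K=KE, amount=xE),
             Species("P", K=KP, amount=xP)],
            [Reaction("r", kappa=kr, reactants={"A": 1, "E": 2},
                      products={"E": 2, "P": 1}),
             Reaction("rf", kappa=krf, reactants={"P": 1}, products={"Zf": 1})],
        )
        J = net.flux_jacobian(net.state_vector())
        iE, iP = net.species_index("E"), net.species_index("P")
        dvP_dxE = J[0, iE] - J[1, iE]
        dvP_dxP = J[0, iP] - J[1, iP]
        assert dvP_dxE == pytest.approx(
            2 * KE**2 * kr * xE * (KA * xA - KP * xP))
        assert dvP_dxP == pytest.approx(-KE**2 * kr * xE**2 * KP - krf * KP)

    @pytest.mark.parametrize("fixture", ["illustrative", "selkov"])
    def test_analytic_jacobian_matches_finite_differences(self, fixture,
                                                          request):
        net, _ = request.getfixturevalue(fixture)
        steady = request.getfixturevalue(fixture + "_steady")
        x_full = net.state_vector(steady.amounts)
        analytic = net.jacobian_dynamic(x_full)
        dyn = [net.species_index(s) for s in net.dynamic_species]

        def rhs(y):
            x = x_full.copy()
            x[dyn] = y
            return net.state_derivative(x)

        fd = finite_difference_jacobian(rhs, x_full[dyn])
        scale = np.max(np.abs(analytic))
        assert np.max(np.abs(analytic - fd)) < 1e-6 * scale


class TestSplitLoop:
    def test_requires_converged_steady_state(self, illustrative,
                                             illustrative_steady):
        from dataclasses import replace

        net, loop = illustrative
        bad = replace(illustrative_steady, converged=False)
        with pytest.raises(BondoscError):
            linearize(net, loop, bad)

    def test_cooperative_stage_has_no_reverse_coupling(self):
        # single ECR stage with separate enzyme input port: g11 = g12 = 0
        net = Network(
            [Species("A", K=100.0, amount=1.0, is_chemostat=True),
             Species("Zf", K=1e-6, amount=1.0, is_chemostat=True),
             Species("Ein", K=1.0, amount=1.0, is_chemostat=True),
             Species("E"), Species("P")],
            [Reaction("rex", kappa=1.0, reactants={"Ein": 1},
                      products={"E": 1}),
             Reaction("r", kappa=1.0, reactants={"A": 1, "E": 2},
                      products={"E": 2, "P": 1}),
             Reaction("rf", kappa=10.0, reactants={"P": 1},
                      products={"Zf": 1})],
        )
        loop = LoopSpec(product="P", feedback_reactions=("r",))
        from bondosc import solve_closed_loop

        ss = solve_closed_loop(net, loop)
        d = split_loop(net, loop, ss)
        # the product port of the conversion does not feed back on the
        # enzyme subsystem: input admittance and reverse gain vanish
        om = np.geomspace(1e-2, 1e3, 20)
        assert np.max(np.abs(d.g12.frequency_response(om))) < 1e-10
        assert d.g22.gain < 0

    def test_illustrative_matches_printed_two_port(self, illustrative_decomp):
        d = illustrative_decomp
        assert d.g11.gain == pytest.approx(-0.1685, rel=1e-3)
        assert abs(d.g11.poles[0] + 5.936) < 0.01
        assert d.g11.zeros[0] == pytest.approx(0.0, abs=1e-9)
        assert d.g12.gain == 0.0
        assert d.g21.gain == pytest.approx(-4.748e4, rel=1e-3)
        g21_poles = np.sort(np.abs(d.g21.poles))
        assert g21_poles == pytest.approx([5.936, 10.03, 10.08], rel=1e-3)
        assert d.g22.gain == pytest.approx(-10.0, rel=0.1)  # -10 at 2 s.f.

    def test_split_sum_equals_direct_single_port(self, illustrative,
                                                 illustrative_steady,
                                                 illustrative_decomp):
        net, loop = illustrative
        L0_direct = single_port_l0(net, loop, illustrative_steady)
        om = np.geomspace(1e-3, 1e3, 120)  # six decades
        a = illustrative_decomp.L0.frequency_response(om)
        b = L0_direct.frequency_response(om)
        assert np.max(np.abs(a - b) / np.abs(b)) < 1e-6

    def test_loop_gain_decomposition_identity(self, illustrative_decomp,
                                              selkov_decomp):
        for d in (illustrative_decomp, selkov_decomp):
            L, Lact, Lpas = loop_gains(d)
            om = np.geomspace(1e-3, 1e3, 120)
            total = Lact.frequency_response(om) + Lpas.frequency_response(om)
            ref = L.frequency_response(om)
            assert np.max(np.abs(total - ref) / np.abs(ref)) < 1e-8

    def test_integrator_appended_exactly(self, illustrative_decomp):
        L0, L = illustrative_decomp.L0, illustrative_decomp.L
        assert L.poles.size == L0.poles.size + 1
        assert np.min(np.abs(L.poles)) == 0.0

    def test_passive_gain_dominates_high_frequency(self, illustrative_decomp):
        # L0pas -> 10.80 at high frequency (input + output admittance)
        val = illustrative_decomp.Lpas(1e6j) * 1e6j
        assert val.real == pytest.approx(10.80, rel=1e-2)

    def test_open_loop_is_stable(self, illustrative_decomp, selkov_decomp):
        for d in (illustrative_decomp, selkov_decomp):
            nonzero = d.L.poles[np.abs(d.L.poles) > 1e-9]
            assert np.all(nonzero.real < 0)

    def test_linear_response_is_first_order_accurate(self, illustrative,
                                                     illustrative_steady):
        from bondosc import integrate_linear, integrate_nonlinear

        net, _ = illustrative
        J = closed_loop_jacobian(net, illustrative_steady)
        xbar = np.array([illustrative_steady.amounts[s]
                         for s in net.dynamic_species])
        devs = []
        for eps in (1e-2, 1e-3):
            x0 = dict(illustrative_steady.amounts)
            x0["P"] *= 1.0 + eps
            tn = integrate_nonlinear(net, x0, t_end=0.5, n_samples=100,
                                     rtol=1e-10, atol=1e-13)
            dx0 = np.array([x0[s] for s in net.dynamic_species]) - xbar
            tl = integrate_linear(J, dx0, 0.5, n_samples=100,
                                  species=net.dynamic_species)
            devs.append(np.max(np.abs(tn.states - (xbar + tl.states)))
                        / (eps * xbar[-1]))
        assert devs[1] < 0.5 * devs[0]  # deviation shrinks ~linearly in eps


class TestTransferFunctionExtraction:
    def test_pole_zero_gain_from_state_space(self):
        # G(s) = (s+2)/((s+1)(s+3)) in controllable canonical form
        tf = RationalTransferFunction([-2.0], [-1.0, -3.0], 1.0)
        ss = zpk_to_ss(tf)
        back = ss_to_zpk(ss)
        assert np.allclose(np.sort(back.zeros.real), [-2.0])
        assert np.allclose(np.sort(back.poles.real), [-3.0, -1.0])
        assert back.gain == pytest.approx(1.0)

    def test_unobservable_mode_is_pruned(self):
        A = np.diag([-1.0, -3.0, -3.0])
        B = np.ones((3, 1))
        C = np.array([[1.0, 1.0, 0.0]])
        tf = ss_to_zpk(StateSpaceModel(A, B, C, np.zeros((1, 1))))
        assert tf.poles.size == 2  # duplicated -3 mode dropped


class TestMinimalRealization:
    def test_exact_cancellation(self):
        tf = RationalTransferFunction([-1.0], [-1.0, -2.0], 1.0)
        red = minimal_realization(tf, tol=1e-7)
        assert red.zeros.size == 0
        assert np.allclose(red.poles.real, [-2.0])

    def test_near_cancellation_within_tolerance(self):
        tf = RationalTransferFunction([-1.000001], [-1.0, -2.0], 1.0)
        red = minimal_realization(tf, tol=1e-3)
        assert red.poles.size == 1

    def test_distant_pair_preserved(self):
        tf = RationalTransferFunction([-1.1], [-1.0, -2.0], 1.0)
        red = minimal_realization(tf, tol=1e-3)
        assert red.poles.size == 2 and red.zeros.size == 1

    def test_padded_duplicate_modes_recover_original_order(self):
        rng = np.random.default_rng(11)
        z = np.array([-2.0])
        p = np.array([-1.0, -4.0])
        tf = RationalTransferFunction(z, p, 1.5)
        padded = RationalTransferFunction(
            np.concatenate([z, [-3.0]]), np.concatenate([p, [-3.0]]), 1.5)
        red = minimal_realization(padded, tol=1e-9)
        om = np.geomspace(1e-2, 1e2, 30)
        assert np.allclose(red.frequency_response(om),
                           tf.frequency_response(om))
        assert red.poles.size == 2


class TestBalancedReduction:
    @staticmethod
    def random_stable_ss(rng, n=8):
        A = rng.normal(size=(n, n))
        A = A - (np.max(np.linalg.eigvals(A).real) + 1.0) * np.eye(n)
        return StateSpaceModel(A, rng.normal(size=(n, 1)),
                               rng.normal(size=(1, n)), np.zeros((1, 1)))

    def test_full_order_preserves_response(self):
        rng = np.random.default_rng(5)
        ss = self.random_stable_ss(rng)
        red, disc = balanced_reduction(ss, ss.n_states)
        om = np.geomspace(1e-2, 1e2, 60)
        G = np.array([ss.transfer(1j * w)[0, 0] for w in om])
        Gr = np.array([red.transfer(1j * w)[0, 0] for w in om])
        assert np.max(np.abs(G - Gr)) < 1e-8 * np.max(np.abs(G))

    @pytest.mark.parametrize("order", [2, 4, 6])
    def test_error_within_twice_discarded_hankel_sum(self, order):
        rng = np.random.default_rng(17)
        for _ in range(4):
            ss = self.random_stable_ss(rng)
            red, disc = balanced_reduction(ss, order)
            om = np.geomspace(1e-3, 1e3, 200)
            G = np.array([ss.transfer(1j * w)[0, 0] for w in om])
            Gr = np.array([red.transfer(1j * w)[0, 0] for w in om])
            err = np.max(np.abs(G - Gr))
            assert err <= 2.0 * np.sum(disc) * (1 + 1e-6) + 1e-12

    def test_unstable_model_rejected(self):
        A = np.array([[0.5]])
        ss = StateSpaceModel(A, [[1.0]], [[1.0]], [[0.0]])
        with pytest.raises(BondoscError):
            balanced_reduction(ss, 1)
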