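import numpy as np
import pytest
from dataclasses import replace

import columnet as cn
from columnet.cells import (
    CompartmentSpec,
    NeuronSpec,
    _lin_exp,
    baseline_neuron,
    build_neuron,
    characterize_adaptation,
    compartment_derivative,
    gate_steady_state,
    initial_state,
)
from columnet.engine import simulate_single_cell

from conftest import passive_cell


def isolated_passive(E_leak=-65.0):
    """Passive 3-compartment cell with core conductances removed, so each
    compartment is an independent RC circuit."""
    base = passive_cell("basket", E_leak=E_leak)
    comps = tuple(replace(c, g_core_neighbors={}) for c in base.compartments)
    return replace(base, compartments=comps)


class TestDerivative:
    def test_leak_only_fixed_point(self):
        spec = isolated_passive()
        state = initial_state(spec)
        d = compartment_derivative(state, spec)
        assert np.allclose(d["V"], 0.0)

    def test_nan_state_rejected(self):
        spec = isolated_passive()
        state = initial_state(spec)
        state["V"][0] = np.nan
        with pytest.raises(FloatingPointError):
            compartment_derivative(state, spec)

    def test_wrong_shape_rejected(self):
        spec = isolated_passive()
        state = initial_state(spec)
        state["V"] = state["V"][:2]
        with pytest.raises(ValueError):
            compartment_derivative(state, spec)

    def test_charge_conservation_core_fluxes_cancel(self, rng):
        # with arbitrary voltages, summing c dV/dt over all compartments of
        # a passive cell must equal the summed membrane (leak) currents:
        # the axial fluxes cancel pairwise across each junction
        spec = passive_cell("pyramidal")
        state = initial_state(spec)
        state["V"] = state["V"] + rng.uniform(-20, 20, len(state["V"]))
        d = compartment_derivative(state, spec)
        total_flux = sum(
            1000.0 * c.c_m * dv for c, dv in zip(spec.compartments, d["V"])
        )
        leak = sum(
            c.g_m * (c.E_leak - v) for c, v in zip(spec.compartments, state["V"])
        )
        assert total_flux == pytest.approx(leak, abs=1e-9)

    def test_rest_no_net_current(self):
        # at rest with no inputs the net current of every compartment is 0
        spec = passive_cell("pyramidal")
        d = compartment_derivative(initial_state(spec), spec)
        assert np.allclose(d["V"], 0.0, atol=1e-12)


class TestIntegrationOracles:
    def test_rc_steady_state_closed_form(self):
        # isolated RC compartment: V* = E_leak + I/g_m, reached within 0.1 mV
        spec = isolated_passive(E_leak=-65.0)
        soma = spec.compartment("soma")
        i_pA = 8.0
        _, traces = simulate_single_cell(spec, duration=400.0, i_inj=i_pA)
        v_end = traces.get(0, "soma", "V")[-1]
        assert v_end == pytest.approx(-65.0 + i_pA / soma.g_m, abs=0.1)

    def test_passive_cable_matches_matrix_exponential(self):
        # multi-compartment passive cell under a somatic step current:
        # trajectory must match the dense matrix-exponential solution of
        # the linear cable system to <= 0.5% of the voltage excursion
        import scipy.linalg

        spec = passive_cell("basket", E_leak=-65.0)
        i_pA = 20.0
        _, traces = simulate_single_cell(spec, duration=100.0, dt=0.05, i_inj=i_pA)

        labels = [c.label for c in spec.compartments]
        n = len(labels)
        idx = {l: i for i, l in enumerate(labels)}
        G = np.zeros((n, n))
        b = np.zeros(n)
        for i, c in enumerate(spec.compartments):
            G[i, i] -= c.g_m
            b[i] += c.g_m * c.E_leak
            for nbr, g in c.g_core_neighbors.items():
                G[i, idx[nbr]] += g
                G[i, i] -= g
        b[idx["soma"]] += i_pA
        C = np.diag([1000.0 * c.c_m for c in spec.compartments])
        M = np.linalg.solve(C, G)
        v_star = np.linalg.solve(G, -b)
        v0 = np.array([c.E_leak for c in spec.compartments])

        t_samples = traces.t
        excursion = abs(i_pA / spec.compartment("soma").g_m)
        for k, t in enumerate(t_samples):
            v_exact = v_star + scipy.linalg.expm(M * t) @ (v0 - v_star)
            v_sim = np.array(
                [traces.get(0, l, "V")[k] for l in labels]
            )
            assert np.max(np.abs(v_sim - v_exact)) <= 0.005 * excursion

    def test_subthreshold_engine_matches_reference_odes(self):
        # dual route: the vectorized engine against scipy's adaptive
        # integrator running the readable reference derivative
        from scipy.integrate import solve_ivp

        spec = baseline_neuron("pyramidal")
        i_pA = -5.0  # subthreshold (hyperpolarizing)
        state0 = initial_state(spec)
        n = len(spec.compartments)
        keys = ("V", "m", "h", "n", "s", "ca")
        y0 = np.concatenate([state0[k] for k in keys])
        inj = np.zeros(n)
        inj[0] = i_pA

        def rhs(t, y):
            st = {k: y[i * n:(i + 1) * n] for i, k in enumerate(keys)}
            d = compartment_derivative(st, spec, inj_current=inj)
            return np.concatenate([d[k] for k in keys])

        T = 60.0
        sol = solve_ivp(rhs, (0, T), y0, rtol=1e-8, atol=1e-10,
                        dense_output=True)
        _, traces = simulate_single_cell(spec, duration=T, dt=0.05, i_inj=i_pA)
        v_sim = traces.get(0, "soma", "V")
        v_ref = np.array([sol.sol(t)[0] for t in traces.t])
        assert np.max(np.abs(v_sim - v_ref)) < 0.15  # mV


class TestBuildNeuron:
    def test_identity_scaling(self):
        base = baseline_neuron("pyramidal")
        built = build_neuron("pyramidal", 1.0)
        for a, b in zip(base.compartments, built.compartments):
            assert a == b

    def test_size_scaling_preserves_time_constant(self):
        built = build_neuron("pyramidal", 1.1)
        base = baseline_neuron("pyramidal")
        for a, b in zip(base.compartments, built.compartments):
            assert b.c_m == pytest.approx(1.1 * a.c_m)
            assert b.g_m == pytest.approx(1.1 * a.g_m)
            assert b.c_m / b.g_m == pytest.approx(a.c_m / a.g_m)
        assert built.channels.g_na["soma"] == pytest.approx(
            1.1 * base.channels.g_na["soma"]
        )

    def test_size_factor_bounds_enforced(self):
        with pytest.raises(ValueError):
            build_neuron("pyramidal", 1.2)
        with pytest.raises(ValueError):
            build_neuron("pyramidal", 0.85)

    def test_unknown_cell_type(self):
        with pytest.raises(ValueError):
            build_neuron("chandelier", 1.0)

    def test_size_draws_uniform_pm_10_percent(self):
        # the network draws sizes from U(0.9, 1.1)
        spec = cn.NetworkSpec(
            n_hypercolumns=2,
            n_minicolumns_per_hc=17,
            connectivity=cn.network.ConnectivityParams(
                lr_pyr_in_degree=10, rsnp_lr_in_degree=5
            ),
        )
        net = cn.build_network(spec)
        s = net.size_factors
        assert len(s) >= 1000
        assert s.min() >= 0.9 and s.max() <= 1.1
        assert s.mean() == pytest.approx(1.0, abs=0.01)

    def test_compartment_counts_by_type(self):
        assert len(baseline_neuron("pyramidal").compartments) == 6
        assert len(baseline_neuron("basket").compartments) == 3
        assert len(baseline_neuron("RSNP").compartments) == 3

    def test_asymmetric_core_rejected(self):
        a = CompartmentSpec("soma", 0.005, 0.5, -65.0, {"basal": 10.0})
        b = CompartmentSpec("basal", 0.003, 0.3, -65.0, {"soma": 5.0})
        c = CompartmentSpec("initial_segment", 0.001, 0.1, -65.0, {})
        with pytest.raises(ValueError, match="asymmetric"):
            NeuronSpec("basket", (a, b, c), baseline_neuron("basket").channels)


class TestSpiking:
    def test_zero_current_no_spikes(self):
        for ct in ("pyramidal", "basket", "RSNP"):
            spikes, _ = simulate_single_cell(baseline_neuron(ct), duration=1000.0)
            assert len(spikes) == 0

    def test_adaptation_ordering_pyr_rsnp_basket(self):
        # pyramidal strongly adapting, RSNP intermediate, basket nearly
        # non-adapting (index ~ 1), under comparable suprathreshold drive
        idx = {}
        for ct, amp in (("pyramidal", 30.0), ("RSNP", 30.0), ("basket", 30.0)):
            res = characterize_adaptation(baseline_neuron(ct), amp, duration=1000.0)
            assert res.valid, f"{ct} did not spike enough at {amp} pA"
            idx[ct] = res.adaptation_index
        assert idx["pyramidal"] > idx["RSNP"] > idx["basket"]
        assert idx["basket"] == pytest.approx(1.0, abs=0.15)

    def test_subthreshold_step_flagged(self):
        res = characterize_adaptation(baseline_neuron("pyramidal"), 0.0,
                                      duration=300.0)
        assert not res.valid
        assert res.adaptation_index is None

    def test_fi_curve_monotone_nondecreasing(self):
        rates = []
        for amp in (0.0, 10.0, 25.0, 50.0):
            spikes, _ = simulate_single_cell(
                baseline_neuron("pyramidal"), duration=1000.0, i_inj=amp
            )
            rates.append(len(spikes))
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0


class TestGateKinetics:
    def test_lin_exp_continuous_through_zero(self):
        x = np.array([-1e-8, 0.0, 1e-8, 1e-3, -1e-3])
        y = _lin_exp(x)
        assert np.all(np.isfinite(y))
        assert y[1] == pytest.approx(1.0)
        assert _lin_exp(np.array([2.0]))[0] == pytest.approx(
            2.0 / (1 - np.exp(-2.0))
        )

    def test_steady_state_gates_in_unit_interval(self):
        g = gate_steady_state(np.linspace(-100, 50, 200))
        for k in ("m", "h", "n", "s"):
            assert np.all((g[k] >= 0) & (g[k] <= 1))
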