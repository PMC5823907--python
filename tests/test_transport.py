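"""Finite-volume diffusion: conservation, Dirichlet handling, analytic oracles."""

import numpy as np
import pytest

from poresim.fixtures import make_chain
from poresim.network import Channel, PoreNetwork
from poresim.transport import (
    BoundaryCondition,
    SubstrateParams,
    SubstrateState,
    assemble_operator,
    homogenize,
    port_flux,
    step_diffusion,
)

CITRATE = SubstrateParams.default("citrate")


def two_node_net():
    coords = np.array([[0.0, 0.0], [200e-6, 0.0]])
    # 5 ports are a lattice-level invariant; reuse both nodes for roles
    chans = [Channel(0, 0, 1)]
    ports = [(0, "central")] + [(1, "peripheral")] * 4
    return PoreNetwork(coords, chans, ports, port_volume=0.0)


def fresh_state(net, values):
    return SubstrateState({"citrate": np.array(values, dtype=float)})


class TestAssembleOperator:
    def test_conductance_value(self):
        net = two_node_net()
        op = assemble_operator(net, CITRATE, [], dt=1.0)
        # g = D * A / L for the default channel
        assert op.g[0] == pytest.approx(5.9e-10 * 6e-10 / 2e-4)
        assert op.g[0] == pytest.approx(1.77e-15)

    def test_flux_part_symmetric_conservative(self):
        net = two_node_net()
        op = assemble_operator(net, CITRATE, [], dt=1.0)
        A = op.matrix.toarray()
        flux = A - np.diag(op.volumes / op.dt)
        assert np.allclose(flux, flux.T)
        assert np.allclose(flux.sum(axis=1), 0.0)

    def test_dirichlet_row_returns_boundary_value(self):
        net = two_node_net()
        bc = [BoundaryCondition(0, "citrate", "dirichlet", 3.0)]
        op = assemble_operator(net, CITRATE, bc, dt=1.0)
        state = fresh_state(net, [3.0, 100.0])
        step_diffusion(state, op)
        assert state.conc["citrate"][0] == pytest.approx(3.0)

    def test_conflicting_bcs_rejected(self):
        net = two_node_net()
        bcs = [
            BoundaryCondition(0, "citrate", "dirichlet", 3.0),
            BoundaryCondition(0, "citrate", "dirichlet", 5.0),
        ]
        with pytest.raises(ValueError):
            assemble_operator(net, CITRATE, bcs, dt=1.0)

    def test_rejects_bad_dt_and_nodes(self):
        net = two_node_net()
        with pytest.raises(ValueError):
            assemble_operator(net, CITRATE, [], dt=0.0)
        with pytest.raises(ValueError):
            assemble_operator(
                net, CITRATE, [BoundaryCondition(9, "citrate", "dirichlet", 1.0)], 1.0
            )


class TestStepDiffusion:
    def test_two_nodes_equilibrate_to_mean(self):
        net = two_node_net()
        op = assemble_operator(net, CITRATE, [], dt=100.0)
        state = fresh_state(net, [1.0, 0.0])
        for _ in range(5000):
            step_diffusion(state, op)
        assert np.allclose(state.conc["citrate"], 0.5, atol=1e-9)

    def test_closed_system_mass_conserved(self, lattice3):
        op = assemble_operator(lattice3, CITRATE, [], dt=10.0)
        rng = np.random.default_rng(0)
        state = SubstrateState({"citrate": rng.uniform(0, 10, lattice3.n_nodes)})
        v = op.volumes
        m0 = (state.conc["citrate"] * v).sum()
        for _ in range(50):
            before = (state.conc["citrate"] * v).sum()
            step_diffusion(state, op)
            after = (state.conc["citrate"] * v).sum()
            assert after == pytest.approx(before, rel=1e-10)
        assert (state.conc["citrate"] * v).sum() == pytest.approx(m0, rel=1e-9)

    def test_steady_linear_profile_on_dirichlet_chain(self):
        net = make_chain(10)
        bcs = [
            BoundaryCondition(0, "citrate", "dirichlet", 10.0),
            BoundaryCondition(9, "citrate", "dirichlet", 0.0),
        ]
        op = assemble_operator(net, CITRATE, bcs, dt=1000.0)
        state = fresh_state(net, np.zeros(10))
        for _ in range(20000):
            step_diffusion(state, op)
        expected = 10.0 * (1 - np.arange(10) / 9.0)
        assert np.allclose(state.conc["citrate"], expected, atol=1e-6)

    def test_transient_chain_matches_series_oracle(self):
        # 1-D rod, ends held at 0, initial uniform C0: series solution
        # C(x,t) = sum_odd 4 C0/(n pi) sin(n pi x / l) exp(-(n pi / l)^2 D t)
        n_nodes = 81
        net = make_chain(n_nodes)
        length = (n_nodes - 1) * 200e-6
        D = CITRATE.D
        bcs = [
            BoundaryCondition(0, "citrate", "dirichlet", 0.0),
            BoundaryCondition(n_nodes - 1, "citrate", "dirichlet", 0.0),
        ]
        dt = 2.0
        op = assemble_operator(net, CITRATE, bcs, dt=dt)
        state = fresh_state(net, np.full(n_nodes, 1.0))
        state.conc["citrate"][[0, -1]] = 0.0
        t_end = 0.05 * length**2 / D
        for _ in range(int(round(t_end / dt))):
            step_diffusion(state, op)
        x = np.arange(n_nodes) * 200e-6
        series = np.zeros(n_nodes)
        for n in range(1, 400, 2):
            series += (
                4.0 / (n * np.pi)
                * np.sin(n * np.pi * x / length)
                * np.exp(-((n * np.pi / length) ** 2) * D * t_end)
            )
        mid = slice(10, n_nodes - 10)
        assert np.allclose(state.conc["citrate"][mid], series[mid], rtol=0.01)

    def test_discrete_maximum_principle(self, lattice3):
        bcs = [BoundaryCondition(lattice3.central_port, "citrate", "dirichlet", 4.0)]
        op = assemble_operator(lattice3, CITRATE, bcs, dt=50.0)
        rng = np.random.default_rng(3)
        state = SubstrateState({"citrate": rng.uniform(0, 8, lattice3.n_nodes)})
        lo = min(state.conc["citrate"].min(), 4.0)
        hi = max(state.conc["citrate"].max(), 4.0)
        for _ in range(200):
            step_diffusion(state, op)
            assert state.conc["citrate"].min() >= lo - 1e-12
            assert state.conc["citrate"].max() <= hi + 1e-12

    def test_explicit_sink_clamped_and_logged(self):
        net = two_node_net()
        op = assemble_operator(net, CITRATE, [], dt=10.0)
        state = fresh_state(net, [1e-6, 0.0])
        sinks = np.array([1.0, 0.0])  # absurdly large demand
        step_diffusion(state, op, sinks)
        assert np.all(state.conc["citrate"] >= 0.0)
        assert state.clamped["citrate"] > 0.0


class TestPortFlux:
    def test_uniform_field_zero(self, lattice3):
        state = SubstrateState({"citrate": np.full(lattice3.n_nodes, 2.0)})
        assert port_flux(lattice3, state, lattice3.central_port) == pytest.approx(0.0)

    def test_single_channel_value(self):
        net = two_node_net()
        state = fresh_state(net, [10.0, 0.0])
        flux = port_flux(net, state, 0, "citrate")
        assert flux == pytest.approx(1.77e-14, rel=1e-3)

    def test_steady_state_efflux_balances_sinks(self):
        net = make_chain(10)
        bcs = [BoundaryCondition(0, "citrate", "dirichlet", 10.0)]
        op = assemble_operator(net, CITRATE, bcs, dt=1000.0)
        state = fresh_state(net, np.zeros(10))
        sinks = np.zeros(10)
        sinks[5] = 5e-15  # mol/s, sustainable
        for _ in range(30000):
            step_diffusion(state, op, sinks)
        assert port_flux(net, state, 0) == pytest.approx(5e-15, rel=1e-6)

    def test_unknown_port_rejected(self, lattice3):
        state = SubstrateState({"citrate": np.zeros(lattice3.n_nodes)})
        with pytest.raises(ValueError):
            port_flux(lattice3, state, 3)


class TestConnectivityFlux:
    def test_central_port_flux_decreases_with_dilution(self):
        # diffusional capacity center -> periphery: steady flux with the
        # center held at 10 and the peripheral ports absorbing, averaged
        # over 5 dilution seeds per connectivity level
        from poresim.network import build_full_lattice, dilute

        full = build_full_lattice(5)

        def steady_flux(net):
            bcs = [BoundaryCondition(net.central_port, "citrate", "dirichlet", 10.0)]
            bcs += [
                BoundaryCondition(p, "citrate", "dirichlet", 0.0)
                for p in net.peripheral_ports
            ]
            op = assemble_operator(net, CITRATE, bcs, dt=1e5)
            state = SubstrateState({"citrate": np.zeros(net.n_nodes)})
            for _ in range(400):
                step_diffusion(state, op)
            return port_flux(net, state, net.central_port)

        means = []
        for frac in (1.0, 0.7, 0.4):
            fluxes = [
                steady_flux(dilute(full, frac, seed) if frac < 1.0 else full)
                for seed in range(5)
            ]
            means.append(np.mean(fluxes))
        assert means[0] > means[1] > means[2] > 0


class TestHomogenize:
    def test_uniform_unchanged_and_mass_conserved(self, lattice3):
        state = SubstrateState({"citrate": np.full(lattice3.n_nodes, 1.5)})
        homogenize(state, lattice3)
        assert np.allclose(state.conc["citrate"], 1.5)

    def test_two_equal_volume_nodes(self):
        net = two_node_net()
        state = fresh_state(net, [2.0, 0.0])
        homogenize(state, net)
        assert np.allclose(state.conc["citrate"], [1.0, 1.0])

    def test_mass_conserved_excluding_dirichlet(self, lattice3):
        rng = np.random.default_rng(5)
        state = SubstrateState({"citrate": rng.uniform(0, 3, lattice3.n_nodes)})
        v = lattice3.node_volumes()
        pinned = np.array([lattice3.central_port])
        free = np.ones(lattice3.n_nodes, bool)
        free[pinned] = False
        before = (state.conc["citrate"][free] * v[free]).sum()
        homogenize(state, lattice3, {"citrate": pinned})
        after = (state.conc["citrate"][free] * v[free]).sum()
        assert after == pytest.approx(before, rel=1e-12)
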