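"""Seeded, self-contained small networks and configs used across the tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ScenarioConfig
from .network import DEFAULT_L, Channel, PoreNetwork, build_full_lattice, dilute

__all__ = ["Fixture", "make_fixture", "make_chain", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("chain10", "ring1", "full_small", "diluted_small")


@dataclass
class Fixture:
    name: str
    net: PoreNetwork
    config: ScenarioConfig
    expected: dict


def make_chain(
    n_nodes: int, channel_length: float = DEFAULT_L, port_volume: float = 0.0
) -> PoreNetwork:
    """A linear chain of ``n_nodes - 1`` channels; ports at the two ends (the
    four peripheral roles collapse onto boundary nodes for testing).  Port
    volumes default to zero so chains match textbook 1-D diffusion rigs."""
    if n_nodes < 5:
        raise ValueError("chain needs >= 5 nodes to host 5 ports")
    coords = np.c_[np.arange(n_nodes) * channel_length, np.zeros(n_nodes)]
    channels = [Channel(i, i, i + 1, channel_length) for i in range(n_nodes - 1)]
    last = n_nodes - 1
    ports = [
        (0, "central"),
        (last, "peripheral"),
        (last - 1, "peripheral"),
        (last - 2, "peripheral"),
        (last - 3, "peripheral"),
    ]
    return PoreNetwork(coords, channels, ports, port_volume=port_volume)


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Deterministic test fixtures; identical (name, seed) gives identical
    serialized bytes."""
    if name == "chain10":
        net = make_chain(10)
        expected = {"n_nodes": 10, "n_channels": 9, "percolating": True}
    elif name == "ring1":
        net = build_full_lattice(1)
        expected = {"n_nodes": 7, "n_channels": 12, "percolating": True}
    elif name == "full_small":
        net = build_full_lattice(3)
        expected = {"n_nodes": 37, "n_channels": 90, "percolating": True}
    elif name == "diluted_small":
        full = build_full_lattice(3)
        net = dilute(full, 0.7, np.random.default_rng(seed))
        expected = {
            "n_nodes": 37,
            "n_channels": round(0.7 * full.n_channels),
            "percolating": True,
        }
    else:
        raise ValueError(f"unknown fixture {name!r}")
    config = ScenarioConfig(
        scenario="counter_gradient",
        rings=3,
        inoculum=(5, 5),
        duration=100.0,
        dt=10.0,
        realizations=1,
        seed=seed,
        snapshot_every=1,
    )
    return Fixture(name=name, net=net, config=config, expected=expected)
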