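"""Substrate diffusion on the pore network.

Solutes (citrate, oxygen, nitrate) diffuse along channels following Fick's
law; mass balance at each junction gives dC/dt = sum(J) - R, with J the
channel fluxes and R the local bacterial consumption.  The network is
discretized with finite volumes (node volume = half the incident channel
volume) and advanced with an unconditionally stable backward-Euler step;
consumption enters as an explicit sink taken from the previous step, so the
operator stays constant and is factorized once per run.

Dirichlet boundary nodes are pinned by row replacement, which has the same
fixed point as a mirror-node construction.  Concentrations are held in
mol m^-3, numerically identical to mM, the unit used for all kinetic
constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix, identity
from scipy.sparse.linalg import splu

from .network import PoreNetwork, is_percolating

__all__ = [
    "SubstrateParams",
    "BoundaryCondition",
    "SubstrateState",
    "DiffusionOperator",
    "assemble_operator",
    "step_diffusion",
    "port_flux",
    "homogenize",
    "DIFFUSIVITIES",
]

#: molecular diffusion coefficients in water, m^2 s^-1
DIFFUSIVITIES = {"citrate": 5.9e-10, "oxygen": 2e-9, "nitrate": 1.7e-9}

SUBSTRATES = ("citrate", "oxygen", "nitrate")


@dataclass(frozen=True)
class SubstrateParams:
    """Name and molecular diffusivity of one substrate."""

    name: str
    D: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion coefficient must be positive")

    @classmethod
    def default(cls, name: str) -> "SubstrateParams":
        return cls(name, DIFFUSIVITIES[name])


@dataclass(frozen=True)
class BoundaryCondition:
    """Boundary condition at one port node.

    ``kind`` is "dirichlet" (fixed concentration ``value``, mol m^-3) or
    "neumann_zero" (sealed, zero flux - the default behaviour of any plain
    node, listed explicitly for auditability).
    """

    node: int
    substrate: str
    kind: str = "dirichlet"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("dirichlet", "neumann_zero"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if self.kind == "dirichlet" and self.value < 0:
            raise ValueError("dirichlet value must be >= 0")


@dataclass
class SubstrateState:
    """Per-node concentrations (mol m^-3) of every substrate at time t."""

    conc: dict[str, np.ndarray]
    t: float = 0.0
    #: cumulative mass removed by negativity clamping, per substrate (mol)
    clamped: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "SubstrateState":
        return SubstrateState(
            {k: v.copy() for k, v in self.conc.items()}, self.t, dict(self.clamped)
        )


class DiffusionOperator:
    """Factorized backward-Euler operator for one substrate.

    Solves (V/dt) C' + L C' = (V/dt) C - R on non-Dirichlet rows, where L is
    the weighted graph Laplacian with channel conductance g = D*A/L and R the
    nodal sink in mol s^-1.  Dirichlet rows are identity rows returning the
    boundary value.
    """

    def __init__(self, net, params, dt, g, volumes, dirichlet_nodes, dirichlet_values):
        self.net = net
        self.params = params
        self.dt = float(dt)
        self.g = g
        self.volumes = volumes
        self.dirichlet_nodes = dirichlet_nodes
        self.dirichlet_values = dirichlet_values
        n = net.n_nodes
        a, b = net.channel_a, net.channel_b
        lap = coo_matrix(
            (
                np.concatenate([g, g, -g, -g]),
                (np.r_[a, b, a, b], np.r_[a, b, b, a]),
            ),
            shape=(n, n),
        ).tocsr()
        A = identity(n, format="csr").multiply(volumes[:, None] / dt) + lap
        if len(dirichlet_nodes):
            A = A.tolil()
            for node in dirichlet_nodes:
                A.rows[node] = [node]
                A.data[node] = [1.0]
            A = A.tocsr()
        self.matrix = A
        self._lu = splu(csc_matrix(A))
        self._free = np.ones(n, dtype=bool)
        self._free[dirichlet_nodes] = False

    def solve(self, conc: np.ndarray, sinks: np.ndarray | None) -> np.ndarray:
        rhs = self.volumes / self.dt * conc
        if sinks is not None:
            rhs = rhs - sinks
        rhs[~self._free] = self.dirichlet_values
        return self._lu.solve(rhs)


def assemble_operator(
    net: PoreNetwork,
    substrate_params: SubstrateParams,
    bcs: list[BoundaryCondition],
    dt: float,
) -> DiffusionOperator:
    """Build the reusable one-step diffusion operator for one substrate."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not is_percolating(net):
        raise ValueError("network must be percolating")
    seen: dict[int, BoundaryCondition] = {}
    for bc in bcs:
        if bc.substrate != substrate_params.name:
            continue
        if bc.node >= net.n_nodes or bc.node < 0:
            raise ValueError(f"boundary node {bc.node} not in network")
        if bc.node in seen and seen[bc.node] != bc:
            raise ValueError(f"conflicting boundary conditions at node {bc.node}")
        seen[bc.node] = bc
    dirichlet = sorted(n for n, bc in seen.items() if bc.kind == "dirichlet")
    values = np.array([seen[n].value for n in dirichlet])

    A_cs = np.array([c.cross_section for c in net.channels])
    g = substrate_params.D * A_cs / net.channel_length
    return DiffusionOperator(
        net, substrate_params, dt, g, net.node_volumes(), np.array(dirichlet, int), values
    )


def step_diffusion(
    state: SubstrateState,
    operator: DiffusionOperator,
    sinks: np.ndarray | None = None,
    dt: float | None = None,
) -> SubstrateState:
    """Advance one substrate by one backward-Euler step (in place).

    ``sinks`` is the nodal consumption in mol s^-1 computed from the previous
    step.  Any node driven negative by the explicit sink is clamped to zero
    and the removed mass is accumulated in ``state.clamped``.
    """
    if dt is not None and abs(dt - operator.dt) > 1e-12 * operator.dt:
        raise ValueError("dt differs from the dt the operator was assembled with")
    name = operator.params.name
    c_new = operator.solve(state.conc[name], sinks)
    neg = c_new < 0
    if np.any(neg):
        state.clamped[name] = state.clamped.get(name, 0.0) + float(
            -(c_new[neg] * operator.volumes[neg]).sum()
        )
        c_new[neg] = 0.0
    state.conc[name] = c_new
    state.t += operator.dt
    return state


def port_flux(net: PoreNetwork, state: SubstrateState, port: int,
              substrate: str = "citrate") -> float:
    """Signed diffusive flow (mol s^-1) leaving ``port`` through its incident
    channels; positive means out of the port into the network."""
    if port not in net.port_nodes:
        raise ValueError(f"node {port} is not a port")
    conc = state.conc[substrate]
    D = DIFFUSIVITIES[substrate]
    indptr, indices = net.incidence()
    total = 0.0
    for c in indices[indptr[port]:indptr[port + 1]]:
        ch = net.channels[c]
        other = ch.b if ch.a == port else ch.a
        g = D * ch.cross_section / ch.L
        total += g * (conc[port] - conc[other])
    return float(total)


def homogenize(
    state: SubstrateState,
    net: PoreNetwork,
    dirichlet_nodes: dict[str, np.ndarray] | None = None,
) -> SubstrateState:
    """Replace every non-Dirichlet nodal concentration by the volume-weighted
    network mean of its substrate (mass-conserving gradient removal)."""
    vol = net.node_volumes()
    for name, conc in state.conc.items():
        free = np.ones(net.n_nodes, dtype=bool)
        if dirichlet_nodes and name in dirichlet_nodes:
            free[dirichlet_nodes[name]] = False
        vfree = vol[free]
        if vfree.sum() > 0:
            conc[free] = (conc[free] * vfree).sum() / vfree.sum()
    return state
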