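"""Scenario configuration and the per-step scheduler.

One engine step executes, in this fixed order: (1) implicit diffusion of all
substrates with the consumption sinks recorded in the previous step, (2)
run-and-tumble motility, (3) growth and new consumption at the cells' current
nodes, (4) division and death.  Scenarios differ in boundary conditions and
switches:

counter_gradient  citrate + nitrate held at the central port, oxygen held at
                  the four peripheral ports (the aggregate-like default).
collocated        citrate, nitrate and oxygen all held at the peripheral
                  ports; inoculation remains central.
no_chemotaxis     counter-gradient with chi = 0 (unbiased tumbling).
homogenized       counter-gradient with all non-boundary concentrations reset
                  to their volume-weighted mean every step (no gradients).
well_mixed_oxic / well_mixed_anoxic
                  single-compartment batch culture, no motility (see
                  :func:`run_well_mixed`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import motility as mot
from . import population as pop
from . import transport as trans
from .network import PoreNetwork, build_full_lattice, dilute, is_percolating
from .population import AEROBE, ANAEROBE, Cells, SpeciesParams
from .transport import BoundaryCondition, SubstrateParams, SubstrateState

__all__ = ["ScenarioConfig", "RunResult", "run", "run_single", "run_well_mixed"]

SCENARIOS = (
    "counter_gradient",
    "collocated",
    "no_chemotaxis",
    "homogenized",
    "well_mixed_oxic",
    "well_mixed_anoxic",
)

#: Henry's-law oxygen solubility against air, mM
O2_SAT = 0.27
#: central-port citrate and nitrate, mM
SOURCE_CONC = 10.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of one simulation scenario.

    The network is either generated (``rings`` + ``connectivity``) or loaded
    from ``network_file``; dilution, inoculation, tumbling and division draws
    all derive from the per-realization seed.
    """

    scenario: str = "counter_gradient"
    rings: int = 35
    connectivity: float = 1.0
    network_file: str | None = None
    inoculum: tuple[int, int] = (500, 500)     # (aerobes, anaerobes)
    boundary_citrate: float = SOURCE_CONC      # mM
    boundary_nitrate: float = SOURCE_CONC      # mM
    boundary_oxygen: float = O2_SAT            # mM
    initial_citrate: float = 0.0               # mM
    initial_oxygen: float = 0.0                # mM (vacuum-saturated network)
    initial_nitrate: float = 0.0               # mM
    dt: float = 10.0                           # engine step, s
    duration: float = 7 * 86400.0              # s
    realizations: int = 8
    seed: int = 0
    snapshot_every: int = 360                  # steps between recorded summaries
    port_volume: float = 1e-9                  # m^3
    well_mixed_volume: float = 1e-9            # m^3 batch compartment
    well_mixed_duration: float = 72 * 3600.0   # s
    chi: float | None = None                   # override chemotactic sensitivity
    substep_dt: float = 1.0                    # motility substep, s

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n_steps = self.duration / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("duration must be a multiple of dt")
        if min(self.inoculum) < 0:
            raise ValueError("inoculum counts must be >= 0")
        if not 0 < self.connectivity <= 1:
            raise ValueError("connectivity must be in (0, 1]")
        for name in ("boundary_citrate", "boundary_nitrate", "boundary_oxygen",
                     "initial_citrate", "initial_oxygen", "initial_nitrate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chi is not None and self.chi < 0:
            raise ValueError("chi must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["inoculum"] = list(self.inoculum)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunResult:
    """Outputs of one realization."""

    config: ScenarioConfig
    seed: int
    net: PoreNetwork
    cells: Cells
    state: SubstrateState
    history: pd.DataFrame          # time_s, n_aerobe, n_anaerobe, central O2 ...
    clamped: dict[str, float]
    provenance: dict

    def cells_frame(self) -> pd.DataFrame:
        return self.cells.to_frame(self.net, time_s=self.state.t)

    def fields_frame(self) -> pd.DataFrame:
        frames = []
        for s, c in self.state.conc.items():
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": self.state.t,
                        "node": np.arange(self.net.n_nodes),
                        "substrate": s,
                        "conc_mol_m3": c,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.config.digest().encode())
        for arr in (self.cells.species, self.cells.mass, self.cells.channel,
                    self.cells.offset, self.cells.heading):
            h.update(np.ascontiguousarray(arr).tobytes())
        for s in sorted(self.state.conc):
            h.update(np.ascontiguousarray(self.state.conc[s]).tobytes())
        return h.hexdigest()


def _boundary_conditions(config: ScenarioConfig, net: PoreNetwork) -> list[BoundaryCondition]:
    c = net.central_port
    periph = net.peripheral_ports
    bcs: list[BoundaryCondition] = []
    if config.scenario in ("counter_gradient", "no_chemotaxis", "homogenized"):
        bcs.append(BoundaryCondition(c, "citrate", "dirichlet", config.boundary_citrate))
        bcs.append(BoundaryCondition(c, "nitrate", "dirichlet", config.boundary_nitrate))
        bcs.append(BoundaryCondition(c, "oxygen", "neumann_zero"))  # silicone seal
        for p in periph:
            bcs.append(BoundaryCondition(p, "oxygen", "dirichlet", config.boundary_oxygen))
    elif config.scenario == "collocated":
        for p in periph:
            bcs.append(BoundaryCondition(p, "citrate", "dirichlet", config.boundary_citrate))
            bcs.append(BoundaryCondition(p, "nitrate", "dirichlet", config.boundary_nitrate))
            bcs.append(BoundaryCondition(p, "oxygen", "dirichlet", config.boundary_oxygen))
    else:
        raise ValueError(f"{config.scenario} has no network boundary conditions")
    return bcs


def build_network(config: ScenarioConfig, seed: int) -> PoreNetwork:
    """Generate (or load) the scenario network for one realization seed."""
    if config.network_file is not None:
        return PoreNetwork.from_json(config.network_file)
    net = build_full_lattice(config.rings, port_volume=config.port_volume)
    if config.connectivity < 1.0:
        net = dilute(net, config.connectivity, np.random.default_rng(seed))
    return net


def run_single(config: ScenarioConfig, seed: int | None = None) -> RunResult:
    """Execute one realization of a spatial scenario."""
    if config.scenario.startswith("well_mixed"):
        raise ValueError("use run_well_mixed for well-mixed scenarios")
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)

    net = build_network(config, seed)
    if not is_percolating(net):
        raise ValueError("network is not percolating")

    params = (SpeciesParams.aerobe(), SpeciesParams.anaerobe())
    if config.scenario == "no_chemotaxis":
        chi = 0.0
    elif config.chi is not None:
        chi = config.chi
    else:
        chi = mot.MotilityParams().chi
    motility = mot.MotilityParams(chi=chi, substep_dt=config.substep_dt)

    bcs = _boundary_conditions(config, net)
    ops = {
        s: trans.assemble_operator(net, SubstrateParams.default(s), bcs, config.dt)
        for s in trans.SUBSTRATES
    }
    dirichlet = {s: ops[s].dirichlet_nodes for s in ops}

    n = net.n_nodes
    state = SubstrateState(
        {
            "citrate": np.full(n, config.initial_citrate, float),
            "oxygen": np.full(n, config.initial_oxygen, float),
            "nitrate": np.full(n, config.initial_nitrate, float),
        }
    )
    for s, op in ops.items():
        state.conc[s][op.dirichlet_nodes] = op.dirichlet_values

    if sum(config.inoculum) > 0:
        cells = Cells.inoculate(net, net.central_port, config.inoculum, rng, params)
    else:
        cells = Cells.empty()

    R = {s: None for s in trans.SUBSTRATES}
    records = []
    central = net.central_port

    def record(step: int) -> None:
        records.append(
            {
                "time_s": step * config.dt,
                "n_aerobe": int((cells.species == AEROBE).sum()),
                "n_anaerobe": int((cells.species == ANAEROBE).sum()),
                "central_oxygen_mM": float(state.conc["oxygen"][central]),
                "central_citrate_mM": float(state.conc["citrate"][central]),
            }
        )

    record(0)
    for step in range(1, config.n_steps + 1):
        # 1. diffusion with last step's consumption
        for s in trans.SUBSTRATES:
            trans.step_diffusion(state, ops[s], R[s])
        state.t = step * config.dt  # one engine step, not one per substrate
        if config.scenario == "homogenized":
            trans.homogenize(state, net, dirichlet)
        # 2. motility
        if len(cells):
            mot.advance_cells(cells, net, state.conc, config.dt, rng, params, motility)
        # 3. growth and new consumption
        if len(cells):
            R, factor, mu = pop.aggregate_sinks(
                cells, net, state.conc, config.dt, params, dirichlet
            )
            mu_maint = np.where(
                cells.species == AEROBE, params[AEROBE].mu_maint, params[ANAEROBE].mu_maint
            )
            cells.mass = pop.update_mass(cells.mass, factor * mu, mu_maint, config.dt)
            # 4. division and death
            cells = pop.divide_and_die(cells, rng, params)
        if step % config.snapshot_every == 0 or step == config.n_steps:
            record(step)
            if not all(np.all(np.isfinite(c)) for c in state.conc.values()) or (
                len(cells) and not np.all(np.isfinite(cells.mass))
            ):
                raise RuntimeError(f"non-finite state at step {step}")

    history = pd.DataFrame.from_records(records)
    return RunResult(
        config=config,
        seed=seed,
        net=net,
        cells=cells,
        state=state,
        history=history,
        clamped=dict(state.clamped),
        provenance={"config_digest": config.digest(), "seed": seed},
    )


def run(config: ScenarioConfig) -> list[RunResult]:
    """Execute ``config.realizations`` independent realizations with seeds
    ``seed, seed+1, ...``; no state is shared between realizations."""
    return [run_single(config, config.seed + k) for k in range(config.realizations)]


def run_well_mixed(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Single-compartment batch competition (no motility, no network).

    Oxygen is clamped at saturation (oxic) or zero (anoxic); citrate and
    nitrate start at the boundary source concentrations and deplete.  Returns
    hourly per-species counts.
    """
    if not config.scenario.startswith("well_mixed"):
        raise ValueError("scenario must be well_mixed_oxic or well_mixed_anoxic")
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    params = (SpeciesParams.aerobe(), SpeciesParams.anaerobe())
    o2 = config.boundary_oxygen if config.scenario == "well_mixed_oxic" else 0.0
    conc = {
        "citrate": config.boundary_citrate,
        "nitrate": config.boundary_nitrate,
        "oxygen": o2,
    }
    V = config.well_mixed_volume
    n_aer, n_an = config.inoculum
    species = np.r_[np.zeros(n_aer, np.int8), np.ones(n_an, np.int8)]
    mass = np.empty(species.size)
    for s in (AEROBE, ANAEROBE):
        sel = species == s
        mass[sel] = rng.uniform(params[s].m0, params[s].m_max, sel.sum())

    dt = config.dt
    n_steps = int(round(config.well_mixed_duration / dt))
    rec_every = max(1, int(round(3600.0 / dt)))
    records = []

    def record(step):
        n0 = int((species == AEROBE).sum())
        n1 = int((species == ANAEROBE).sum())
        tot = max(n0 + n1, 1)
        records.append(
            {
                "time_s": step * dt,
                "n_aerobe": n0,
                "n_anaerobe": n1,
                "frac_aerobe": n0 / tot,
                "frac_anaerobe": n1 / tot,
                "citrate_mM": conc["citrate"],
                "nitrate_mM": conc["nitrate"],
            }
        )

    record(0)
    for step in range(1, n_steps + 1):
        mu = np.where(
            species == AEROBE,
            pop.growth_rate_aerobe(conc["citrate"], conc["oxygen"], params[AEROBE]),
            pop.growth_rate_anaerobe(
                conc["citrate"], conc["oxygen"], conc["nitrate"], params[ANAEROBE]
            ),
        )
        demand = pop.consumption_demand(species, mass, mu, dt, params)
        factor = np.ones(species.size)
        for s in ("citrate", "nitrate"):
            total = float(demand[s].sum())
            avail = conc[s] * V
            if total > avail:
                f = avail / total
                factor[demand[s] > 0] = np.minimum(factor[demand[s] > 0], f)
        for s in ("citrate", "nitrate"):
            conc[s] = max(0.0, conc[s] - float((demand[s] * factor).sum()) / V)
        mu_maint = np.where(species == AEROBE, params[AEROBE].mu_maint, params[ANAEROBE].mu_maint)
        mass = pop.update_mass(mass, factor * mu, mu_maint, dt)
        # division and death
        m_max = np.where(species == AEROBE, params[AEROBE].m_max, params[ANAEROBE].m_max)
        m_crit = np.where(species == AEROBE, params[AEROBE].m_crit, params[ANAEROBE].m_crit)
        alive = mass > m_crit
        species, mass, m_max = species[alive], mass[alive], m_max[alive]
        div = mass >= m_max
        if np.any(div):
            mass[div] /= 2.0
            species = np.r_[species, species[div]]
            mass = np.r_[mass, mass[div]]
        if step % rec_every == 0 or step == n_steps:
            record(step)
    return pd.DataFrame.from_records(records)
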