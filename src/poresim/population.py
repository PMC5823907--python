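"""Per-cell growth, consumption, division and death.

Each agent is one bacterial cell of one of two species: an obligate aerobe
(carbon- and oxygen-limited Monod growth) or an obligate anaerobe (carbon-
and nitrate-limited, inhibited by oxygen).  Cell mass follows
dm/dt = (mu - mu_maint) * m with mu the local Monod rate and mu_maint a
maintenance rate of 10% of mu_max; a cell divides on reaching m_max and is
removed on shrinking to m_crit.

Consumption is tied to gross growth: citrate demand is mu*m*dt/Y, oxygen
(aerobes) and nitrate (anaerobes) follow by fixed stoichiometry.  Maintenance
burns biomass only, so the yield Y keeps its textbook meaning.  When the
summed demand at a node exceeds the dissolved mass available there, all
co-located cells are rescaled by the same factor (demand and growth alike).

Concentrations are in mM (= mol m^-3), masses in kg, rates in s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import PoreNetwork

__all__ = [
    "SpeciesParams",
    "Cells",
    "AEROBE",
    "ANAEROBE",
    "growth_rate_aerobe",
    "growth_rate_anaerobe",
    "node_growth_rates",
    "update_mass",
    "consumption_demand",
    "aggregate_sinks",
    "divide_and_die",
]

AEROBE = 0
ANAEROBE = 1
SPECIES_LABELS = ("aerobe", "anaerobe")

#: average single-cell mass, kg
M0 = 1e-15
#: mass at division, kg
M_MAX = 2 * M0 / 1.433
#: mass at cell death, kg
M_CRIT = 0.2 * M_MAX


@dataclass(frozen=True)
class SpeciesParams:
    """Kinetic, stoichiometric and motility constants of one species."""

    label: str
    mu_max: float                      # maximum specific growth rate, s^-1
    K_C_lim: float = 0.05              # citrate half-saturation, mM
    K_O2_lim: float = 0.0063           # oxygen half-saturation, mM (aerobe)
    K_O2_inh: float = 0.0063           # oxygen inhibition constant, mM (anaerobe)
    K_NO3_lim: float = 0.0351          # nitrate half-saturation, mM (anaerobe)
    Y: float = 0.06                    # biomass yield, kg per mol citrate
    S_O2_cit: float = 2.2              # mol O2 per mol citrate (aerobe)
    S_NO3_cit: float = 10.0            # mol NO3 per mol citrate (anaerobe)
    m0: float = M0
    m_max: float = M_MAX
    m_crit: float = M_CRIT
    mu_maint: float | None = None      # defaults to 0.1 * mu_max

    def __post_init__(self) -> None:
        if self.mu_maint is None:
            object.__setattr__(self, "mu_maint", 0.1 * self.mu_max)
        for name in ("mu_max", "K_C_lim", "K_O2_lim", "K_O2_inh", "K_NO3_lim",
                     "Y", "S_O2_cit", "S_NO3_cit", "m0", "m_max", "m_crit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.m_crit < self.m0 < self.m_max:
            raise ValueError("need m_crit < m0 < m_max")

    @classmethod
    def aerobe(cls, **overrides) -> "SpeciesParams":
        return cls(label="aerobe", mu_max=6.9e-6, **overrides)

    @classmethod
    def anaerobe(cls, **overrides) -> "SpeciesParams":
        return cls(label="anaerobe", mu_max=5.4e-6, **overrides)


def _check_nonneg(*concs) -> None:
    for c in concs:
        if np.any(np.asarray(c) < 0):
            raise ValueError("concentrations must be non-negative")


def growth_rate_aerobe(C_C, C_O2, p: SpeciesParams):
    """Monod growth rate of the obligate aerobe (s^-1): mu_max times the
    minimum of the citrate and oxygen limitation terms."""
    _check_nonneg(C_C, C_O2)
    C_C = np.asarray(C_C, float)
    C_O2 = np.asarray(C_O2, float)
    mu = p.mu_max * np.minimum(
        C_C / (p.K_C_lim + C_C), C_O2 / (p.K_O2_lim + C_O2)
    )
    return mu if mu.ndim else float(mu)


def growth_rate_anaerobe(C_C, C_O2, C_NO3, p: SpeciesParams):
    """Monod growth rate of the obligate anaerobe (s^-1): mu_max times the
    minimum of citrate limitation, oxygen inhibition and nitrate limitation."""
    _check_nonneg(C_C, C_O2, C_NO3)
    C_C = np.asarray(C_C, float)
    C_O2 = np.asarray(C_O2, float)
    C_NO3 = np.asarray(C_NO3, float)
    mu = p.mu_max * np.minimum.reduce(
        [
            C_C / (p.K_C_lim + C_C),
            p.K_O2_inh / (p.K_O2_inh + C_O2),
            C_NO3 / (p.K_NO3_lim + C_NO3),
        ]
    )
    return mu if mu.ndim else float(mu)


def node_growth_rates(conc: dict[str, np.ndarray],
                      params: tuple[SpeciesParams, SpeciesParams]) -> np.ndarray:
    """Growth rate of each species at every node; shape ``(2, n_nodes)``."""
    return np.stack(
        [
            growth_rate_aerobe(conc["citrate"], conc["oxygen"], params[AEROBE]),
            growth_rate_anaerobe(
                conc["citrate"], conc["oxygen"], conc["nitrate"], params[ANAEROBE]
            ),
        ]
    )


def update_mass(mass, mu, mu_maint, dt: float):
    """One explicit Euler step of dm/dt = (mu - mu_maint) m."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.asarray(mass, float) * (1.0 + (np.asarray(mu, float) - mu_maint) * dt)


def consumption_demand(species, mass, mu, dt: float,
                       params: tuple[SpeciesParams, SpeciesParams]) -> dict[str, np.ndarray]:
    """Per-cell substrate demand over one step (mol).

    Citrate demand is mu*m*dt/Y for both species; aerobes additionally demand
    S_O2_cit times that in oxygen, anaerobes S_NO3_cit times that in nitrate.
    """
    species = np.asarray(species)
    mass = np.asarray(mass, float)
    mu = np.asarray(mu, float)
    if np.any(mu < 0):
        raise ValueError("growth rates must be non-negative")
    Y = np.where(species == AEROBE, params[AEROBE].Y, params[ANAEROBE].Y)
    cit = mu * mass * dt / Y
    o2 = np.where(species == AEROBE, params[AEROBE].S_O2_cit * cit, 0.0)
    no3 = np.where(species == ANAEROBE, params[ANAEROBE].S_NO3_cit * cit, 0.0)
    return {"citrate": cit, "oxygen": o2, "nitrate": no3}


class Cells:
    """Structure-of-arrays container for the living cells.

    Attributes are parallel arrays: ``id``, ``species`` (0 aerobe, 1
    anaerobe), ``mass`` (kg), ``channel`` (channel index), ``offset`` (m along
    the channel from endpoint ``a``), ``heading`` (+1 toward ``b``).
    """

    def __init__(self, ids, species, mass, channel, offset, heading, next_id=None):
        self.id = np.asarray(ids, dtype=np.int64)
        self.species = np.asarray(species, dtype=np.int8)
        self.mass = np.asarray(mass, dtype=float)
        self.channel = np.asarray(channel, dtype=np.int64)
        self.offset = np.asarray(offset, dtype=float)
        self.heading = np.asarray(heading, dtype=np.int8)
        self.next_id = int(next_id if next_id is not None else
                           (self.id.max() + 1 if self.id.size else 0))

    def __len__(self) -> int:
        return self.id.size

    @classmethod
    def empty(cls) -> "Cells":
        z = np.empty(0)
        return cls(z, z, z, z, z, z, next_id=0)

    @classmethod
    def inoculate(
        cls,
        net: PoreNetwork,
        node: int,
        counts: tuple[int, int],
        rng: np.random.Generator,
        params: tuple[SpeciesParams, SpeciesParams],
    ) -> "Cells":
        """Place ``counts[species]`` cells of each species at ``node``.

        Cells are dropped at offset 0 of random channels incident to the node
        with random headings; initial masses are uniform in [m0, m_max) so
        division is not artificially synchronized.
        """
        indptr, indices = net.incidence()
        incident = indices[indptr[node]:indptr[node + 1]]
        if incident.size == 0:
            raise ValueError(f"node {node} has no incident channels")
        n = int(counts[0]) + int(counts[1])
        species = np.r_[
            np.zeros(int(counts[0]), np.int8), np.ones(int(counts[1]), np.int8)
        ]
        mass = np.empty(n)
        for s in (AEROBE, ANAEROBE):
            sel = species == s
            mass[sel] = rng.uniform(params[s].m0, params[s].m_max, sel.sum())
        channel = rng.choice(incident, size=n)
        a = np.array([net.channels[c].a for c in channel])
        # start at the node end of the chosen channel
        offset = np.where(a == node, 0.0, np.array([net.channels[c].L for c in channel]))
        heading = np.where(a == node, 1, -1).astype(np.int8)
        # headings randomized: half tumble into the channel either way
        flip = rng.random(n) < 0.5
        heading[flip] = -heading[flip]
        return cls(np.arange(n), species, mass, channel, offset, heading, next_id=n)

    def nearest_nodes(self, net: PoreNetwork) -> np.ndarray:
        """Node each cell is attributed to (nearest channel endpoint)."""
        if len(self) == 0:
            return np.empty(0, dtype=np.int64)
        a = net.channel_a[self.channel]
        b = net.channel_b[self.channel]
        L = net.channel_length[self.channel]
        return np.where(self.offset <= L / 2.0, a, b)

    def xy(self, net: PoreNetwork) -> np.ndarray:
        """Planar coordinates (m) of each cell, shape ``(n, 2)``."""
        if len(self) == 0:
            return np.empty((0, 2))
        pa = net.coords[net.channel_a[self.channel]]
        pb = net.coords[net.channel_b[self.channel]]
        f = (self.offset / net.channel_length[self.channel])[:, None]
        return pa * (1 - f) + pb * f

    def to_frame(self, net: PoreNetwork, time_s: float = 0.0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": time_s,
                "cell_id": self.id,
                "species": np.array(SPECIES_LABELS)[self.species],
                "channel": self.channel,
                "offset_m": self.offset,
                "node": self.nearest_nodes(net),
                "mass_kg": self.mass,
            }
        )

    def select(self, mask: np.ndarray) -> "Cells":
        return Cells(
            self.id[mask], self.species[mask], self.mass[mask],
            self.channel[mask], self.offset[mask], self.heading[mask],
            next_id=self.next_id,
        )

    def copy(self) -> "Cells":
        return self.select(np.ones(len(self), dtype=bool))


def aggregate_sinks(
    cells: Cells,
    net: PoreNetwork,
    conc: dict[str, np.ndarray],
    dt: float,
    params: tuple[SpeciesParams, SpeciesParams],
    dirichlet_nodes: dict[str, np.ndarray] | None = None,
    mu: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Sum per-cell demands to nodal sinks, limited by availability.

    Returns ``(R, factor, mu)`` where ``R`` maps substrate to nodal
    consumption rates (mol s^-1), ``factor`` is the per-cell rescaling applied
    when a node's demand exceeds the dissolved mass ``C*V`` available there
    (growth increments must be rescaled by the same factor), and ``mu`` is the
    per-cell gross Monod rate.  Dirichlet nodes are treated as inexhaustible.
    """
    n_nodes = net.n_nodes
    R = {s: np.zeros(n_nodes) for s in conc}
    if len(cells) == 0:
        return R, np.empty(0), np.empty(0)
    nodes = cells.nearest_nodes(net)
    if mu is None:
        mu_node = node_growth_rates(conc, params)
        mu = mu_node[cells.species, nodes]
    demand = consumption_demand(cells.species, cells.mass, mu, dt, params)

    vol = net.node_volumes()
    factor = np.ones(len(cells))
    node_factor = {}
    for s, dem in demand.items():
        total = np.bincount(nodes, weights=dem, minlength=n_nodes)
        avail = conc[s] * vol
        if dirichlet_nodes and s in dirichlet_nodes:
            avail = avail.copy()
            avail[dirichlet_nodes[s]] = np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(total > 0, np.minimum(1.0, avail / np.maximum(total, 1e-300)), 1.0)
        node_factor[s] = f
        consumes = dem > 0
        factor[consumes] = np.minimum(factor[consumes], f[nodes[consumes]])
    for s, dem in demand.items():
        R[s] = np.bincount(nodes, weights=dem * factor, minlength=n_nodes) / dt
    return R, factor, mu


def divide_and_die(
    cells: Cells,
    rng: np.random.Generator,
    params: tuple[SpeciesParams, SpeciesParams],
) -> Cells:
    """Apply division (m >= m_max splits 50/50, one daughter's heading
    re-randomized) and death (m <= m_crit removed); fresh ids for daughters."""
    if len(cells) == 0:
        return cells
    m_max = np.where(cells.species == AEROBE, params[AEROBE].m_max, params[ANAEROBE].m_max)
    m_crit = np.where(cells.species == AEROBE, params[AEROBE].m_crit, params[ANAEROBE].m_crit)

    alive = cells.mass > m_crit
    if not alive.all():
        cells = cells.select(alive)
        m_max = m_max[alive]

    dividing = cells.mass >= m_max
    if not np.any(dividing):
        return cells
    n_new = int(dividing.sum())
    cells.mass[dividing] /= 2.0
    new_heading = np.where(rng.random(n_new) < 0.5, 1, -1).astype(np.int8)
    daughters = Cells(
        np.arange(cells.next_id, cells.next_id + n_new),
        cells.species[dividing],
        cells.mass[dividing],
        cells.channel[dividing],
        cells.offset[dividing],
        new_heading,
    )
    return Cells(
        np.r_[cells.id, daughters.id],
        np.r_[cells.species, daughters.species],
        np.r_[cells.mass, daughters.mass],
        np.r_[cells.channel, daughters.channel],
        np.r_[cells.offset, daughters.offset],
        np.r_[cells.heading, daughters.heading],
        next_id=cells.next_id + n_new,
    )
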