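"""Biased run-and-tumble motility along channels.

Cells swim at constant speed v along the channel they occupy and reorient by
tumbling.  The tumbling rate is modulated by the gradient of the cell's own
growth-rate function along its heading,

    p = p0 * exp(-chi / (2 v mu_max) * dmu/dx),

so runs up-gradient last longer (chemotaxis); because mu depends on oxygen
with opposite sign for the two species, the same rule yields aerotaxis for
aerobes and oxygen avoidance for anaerobes.  An in-channel tumble reverses
the heading with probability 1/2; reaching a junction forces a tumble with a
uniformly random choice among all incident channels.

p is a rate (s^-1); at the 10 s engine step p0*dt exceeds 1, so motion is
integrated in substeps of ``substep_dt`` with per-substep tumble probability
1 - exp(-p dt).  The gradient stencil is the pair of nodes terminating the
occupied channel, the only locations where concentrations exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import advance_kernel
from .network import PoreNetwork
from .population import Cells, SpeciesParams, node_growth_rates

__all__ = [
    "MotilityParams",
    "growth_rate_gradient",
    "tumble_probability",
    "substep_tumble_probabilities",
    "advance_cells",
]


@dataclass(frozen=True)
class MotilityParams:
    """Run-and-tumble constants (shared by both species by default)."""

    p0: float = 0.25          # unbiased tumbling probability, s^-1
    chi: float = 2e-8         # chemotactic sensitivity, m^2 s^-1
    v: float = 2e-5           # swimming speed, m s^-1 (20 um/s)
    substep_dt: float = 1.0   # motility substep, s

    def __post_init__(self) -> None:
        if self.p0 <= 0 or self.substep_dt <= 0:
            raise ValueError("p0 and substep_dt must be positive")
        if self.chi < 0 or self.v < 0:
            raise ValueError("chi and v must be non-negative")

    def validate_against(self, min_channel_length: float) -> None:
        if self.v * self.substep_dt > min_channel_length / 2.0:
            raise ValueError(
                "substep too coarse: v*substep_dt must not exceed half a channel"
            )


def tumble_probability(grad, p: MotilityParams, mu_max: float):
    """Tumbling rate (s^-1) for a growth-rate gradient along the heading."""
    grad = np.asarray(grad, float)
    if p.chi == 0.0 or p.v == 0.0:  # no chemotactic modulation (or no motion)
        out = np.broadcast_to(np.float64(p.p0), grad.shape).copy()
    else:
        out = p.p0 * np.exp(-p.chi / (2.0 * p.v * mu_max) * grad)
    return out if out.ndim else float(out)


def growth_rate_gradient(
    cells: Cells,
    net: PoreNetwork,
    conc: dict[str, np.ndarray],
    params: tuple[SpeciesParams, SpeciesParams],
) -> np.ndarray:
    """Per-cell gradient of its own species' growth rate along its heading,
    (mu ahead - mu behind) / L, in s^-1 m^-1."""
    if len(cells) == 0:
        return np.empty(0)
    mu_node = node_growth_rates(conc, params)
    a = net.channel_a[cells.channel]
    b = net.channel_b[cells.channel]
    L = net.channel_length[cells.channel]
    mu_a = mu_node[cells.species, a]
    mu_b = mu_node[cells.species, b]
    return cells.heading * (mu_b - mu_a) / L


def substep_tumble_probabilities(
    net: PoreNetwork,
    mu_node: np.ndarray,
    params: tuple[SpeciesParams, SpeciesParams],
    motility: tuple[MotilityParams, MotilityParams],
) -> np.ndarray:
    """Per-substep tumble probabilities, shape ``(2, n_channels, 2)``.

    Entry ``[s, c, d]`` is the probability 1 - exp(-p * substep_dt) that a
    cell of species ``s`` on channel ``c`` heading toward endpoint ``b``
    (``d = 0``) or ``a`` (``d = 1``) tumbles within one substep.  Computing
    the exponentials once per channel rather than per cell keeps the inner
    loop cheap.
    """
    a, b, L = net.channel_a, net.channel_b, net.channel_length
    out = np.empty((2, net.n_channels, 2))
    for s in (0, 1):
        grad_fwd = (mu_node[s, b] - mu_node[s, a]) / L
        mp = motility[s]
        p_fwd = tumble_probability(grad_fwd, mp, params[s].mu_max)
        p_bwd = tumble_probability(-grad_fwd, mp, params[s].mu_max)
        out[s, :, 0] = 1.0 - np.exp(-p_fwd * mp.substep_dt)
        out[s, :, 1] = 1.0 - np.exp(-p_bwd * mp.substep_dt)
    return out


def advance_cells(
    cells: Cells,
    net: PoreNetwork,
    conc: dict[str, np.ndarray],
    dt: float,
    rng: np.random.Generator,
    params: tuple[SpeciesParams, SpeciesParams],
    motility: tuple[MotilityParams, MotilityParams] | MotilityParams,
    mu_node: np.ndarray | None = None,
) -> Cells:
    """Advance every cell through one engine step of run-and-tumble motion
    (in place).  ``dt`` must be an integer multiple of the substep."""
    if isinstance(motility, MotilityParams):
        motility = (motility, motility)
    if len(cells) == 0:
        return cells
    sub = motility[0].substep_dt
    if abs(motility[1].substep_dt - sub) > 1e-12:
        raise ValueError("both species must share one substep")
    n_sub = int(round(dt / sub))
    if n_sub < 1 or abs(n_sub * sub - dt) > 1e-9 * dt:
        raise ValueError("dt must be a positive multiple of substep_dt")
    motility[0].validate_against(float(net.channel_length.min()))

    if mu_node is None:
        mu_node = node_growth_rates(conc, params)
    tumble_p = substep_tumble_probabilities(net, mu_node, params, motility)
    if motility[0].v != motility[1].v:
        raise ValueError("species-specific speeds are not supported")
    indptr, indices = net.incidence()
    seed = int(rng.integers(2**31 - 1))
    advance_kernel(
        cells.channel,
        cells.offset,
        cells.heading,
        cells.species,
        tumble_p,
        net.channel_a,
        net.channel_b,
        net.channel_length,
        indptr,
        indices,
        motility[0].v * sub,
        n_sub,
        seed,
    )
    return cells
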