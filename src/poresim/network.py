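"""Pore-network geometry: triangular lattices, percolation-preserving dilution.

The habitat is a planar network of water-saturated rectangular micro-channels
(bonds) meeting at junctions (nodes).  A fully connected network is a
triangular lattice (every interior junction joins six channels, i.e. the nodes
sit on a hexagonal arrangement).  Connectivity is reduced by deleting a random
subset of channels while keeping the network percolating, meaning a swimming
cell (and a diffusing molecule) can still reach every retained junction from
anywhere.  Five access ports impose boundary conditions: one central port and
four peripheral ports spaced 90 degrees apart on the lattice boundary.

Coordinates are planar, in meters, with the origin at the central port.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "Channel",
    "PoreNetwork",
    "build_full_lattice",
    "dilute",
    "is_percolating",
    "shortest_path_distance",
    "node_volume",
]

#: default channel geometry (m): 200 um x 40 um x 15 um (L x W x H)
DEFAULT_L = 200e-6
DEFAULT_W = 40e-6
DEFAULT_H = 15e-6

#: default volume (m^3) assigned to port nodes on top of the half-channel
#: rule; 1e-9 m^3 = 1 uL, the scale of the physical inoculation wells.
DEFAULT_PORT_VOLUME = 1e-9


@dataclass(frozen=True)
class Channel:
    """One rectangular channel (bond) between two junctions."""

    id: int
    a: int
    b: int
    L: float = DEFAULT_L
    W: float = DEFAULT_W
    H: float = DEFAULT_H

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("channel endpoints must be distinct")
        if min(self.L, self.W, self.H) <= 0:
            raise ValueError("channel dimensions must be positive")

    @property
    def cross_section(self) -> float:
        """Cross-sectional area W*H in m^2."""
        return self.W * self.H

    @property
    def volume(self) -> float:
        """Channel volume L*W*H in m^3."""
        return self.L * self.W * self.H


class PoreNetwork:
    """A pore network: junctions, channels, and the five access ports.

    Parameters
    ----------
    coords
        ``(n_nodes, 2)`` array of planar node coordinates in meters.
    channels
        List of :class:`Channel` referencing node indices ``0..n_nodes-1``.
    ports
        List of ``(node, role)`` with role ``"central"`` or ``"peripheral"``.
        Exactly one central and four peripheral ports are required.
    n_full_channels
        Channel count of the undiluted parent lattice (denominator of
        ``connectivity_fraction``).  Defaults to ``len(channels)``.
    """

    def __init__(
        self,
        coords: np.ndarray,
        channels: list[Channel],
        ports: list[tuple[int, str]],
        n_full_channels: int | None = None,
        port_volume: float = DEFAULT_PORT_VOLUME,
        meta: dict | None = None,
    ) -> None:
        self.coords = np.asarray(coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be (n_nodes, 2)")
        self.channels = list(channels)
        self.ports = list(ports)
        roles = [r for _, r in self.ports]
        if roles.count("central") != 1 or roles.count("peripheral") != 4:
            raise ValueError("need exactly 1 central and 4 peripheral ports")
        self.n_full_channels = (
            len(self.channels) if n_full_channels is None else int(n_full_channels)
        )
        self.port_volume = float(port_volume)
        self.meta = dict(meta or {})
        self._cache: dict[str, object] = {}

    # -- basic properties -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def connectivity_fraction(self) -> float:
        return self.n_channels / self.n_full_channels

    @property
    def central_port(self) -> int:
        return next(n for n, r in self.ports if r == "central")

    @property
    def peripheral_ports(self) -> list[int]:
        return [n for n, r in self.ports if r == "peripheral"]

    @property
    def port_nodes(self) -> list[int]:
        return [n for n, _ in self.ports]

    # -- derived arrays (cached; the channel set is immutable) -------------

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if "arr" not in self._cache:
            a = np.array([c.a for c in self.channels], dtype=np.int64)
            b = np.array([c.b for c in self.channels], dtype=np.int64)
            L = np.array([c.L for c in self.channels], dtype=float)
            self._cache["arr"] = (a, b, L)
        return self._cache["arr"]  # type: ignore[return-value]

    @property
    def channel_a(self) -> np.ndarray:
        return self._arrays()[0]

    @property
    def channel_b(self) -> np.ndarray:
        return self._arrays()[1]

    @property
    def channel_length(self) -> np.ndarray:
        return self._arrays()[2]

    def adjacency(self, weights: np.ndarray | None = None) -> coo_matrix:
        """Symmetric sparse adjacency; entries are channel weights (default 1)."""
        a, b, _ = self._arrays()
        w = np.ones(len(a)) if weights is None else np.asarray(weights, float)
        n = self.n_nodes
        return coo_matrix(
            (np.r_[w, w], (np.r_[a, b], np.r_[b, a])), shape=(n, n)
        )

    def incidence(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR lists of channel indices incident to each node.

        Returns ``(indptr, indices)`` such that the channels touching node
        ``n`` are ``indices[indptr[n]:indptr[n+1]]``.
        """
        if "inc" not in self._cache:
            a, b, _ = self._arrays()
            nodes = np.r_[a, b]
            chan = np.r_[np.arange(len(a)), np.arange(len(a))]
            order = np.argsort(nodes, kind="stable")
            counts = np.bincount(nodes, minlength=self.n_nodes)
            indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
            np.cumsum(counts, out=indptr[1:])
            self._cache["inc"] = (indptr, chan[order].astype(np.int64))
        return self._cache["inc"]  # type: ignore[return-value]

    def degree(self) -> np.ndarray:
        a, b, _ = self._arrays()
        return np.bincount(np.r_[a, b], minlength=self.n_nodes)

    def node_volumes(self) -> np.ndarray:
        """Finite-volume node volumes (m^3): half the incident channel volume,
        plus the configured port volume at port nodes.  Cached."""
        if "vol" not in self._cache:
            vol = np.zeros(self.n_nodes)
            a, b, _ = self._arrays()
            cv = np.array([c.volume for c in self.channels])
            np.add.at(vol, a, cv / 2.0)
            np.add.at(vol, b, cv / 2.0)
            vol[list(set(self.port_nodes))] += self.port_volume
            self._cache["vol"] = vol
        return self._cache["vol"]  # type: ignore[return-value]

    def channel_midpoints(self) -> np.ndarray:
        a, b, _ = self._arrays()
        return 0.5 * (self.coords[a] + self.coords[b])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [
                {"id": int(i), "x": float(x), "y": float(y)}
                for i, (x, y) in enumerate(self.coords)
            ],
            "channels": [
                {
                    "id": int(c.id),
                    "a": int(c.a),
                    "b": int(c.b),
                    "L": c.L,
                    "W": c.W,
                    "H": c.H,
                }
                for c in self.channels
            ],
            "ports": [{"node": int(n), "role": r} for n, r in self.ports],
            "meta": {
                "connectivity_fraction": self.connectivity_fraction,
                "n_full_channels": self.n_full_channels,
                "port_volume": self.port_volume,
                **self.meta,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PoreNetwork":
        nodes = sorted(d["nodes"], key=lambda n: n["id"])
        coords = np.array([[n["x"], n["y"]] for n in nodes])
        channels = [
            Channel(c["id"], c["a"], c["b"], c["L"], c["W"], c["H"])
            for c in d["channels"]
        ]
        ports = [(p["node"], p["role"]) for p in d["ports"]]
        meta = dict(d.get("meta", {}))
        n_full = meta.pop("n_full_channels", None)
        port_volume = meta.pop("port_volume", DEFAULT_PORT_VOLUME)
        meta.pop("connectivity_fraction", None)
        return cls(coords, channels, ports, n_full, port_volume, meta)

    @classmethod
    def from_json(cls, source) -> "PoreNetwork":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))


# -- lattice construction --------------------------------------------------

_AXIAL_NEIGHBORS = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def build_full_lattice(
    rings: int,
    channel_length: float = DEFAULT_L,
    channel_width: float = DEFAULT_W,
    channel_height: float = DEFAULT_H,
    port_volume: float = DEFAULT_PORT_VOLUME,
) -> PoreNetwork:
    """Build the fully connected triangular lattice of the given radius.

    ``rings`` is the lattice radius in channels; the patch is the hexagonal
    set of axial coordinates with ``max(|q|, |r|, |q+r|) <= rings``, giving
    ``3*rings*(rings+1) + 1`` nodes with interior degree 6.  The central port
    sits at the origin; the four peripheral ports are the boundary nodes
    closest to 0, 90, 180 and 270 degrees.
    """
    if rings < 1:
        raise ValueError("rings must be >= 1")
    if channel_length <= 0:
        raise ValueError("channel_length must be positive")

    axial: list[tuple[int, int]] = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if max(abs(q), abs(r), abs(q + r)) <= rings:
                axial.append((q, r))
    # center first, then by angle-free deterministic order
    axial.sort(key=lambda qr: (max(abs(qr[0]), abs(qr[1]), abs(qr[0] + qr[1])), qr))
    index = {qr: i for i, qr in enumerate(axial)}
    coords = np.array(
        [
            [channel_length * (q + r / 2.0), channel_length * (r * math.sqrt(3) / 2.0)]
            for q, r in axial
        ]
    )

    channels: list[Channel] = []
    for (q, r), i in index.items():
        for dq, dr in _AXIAL_NEIGHBORS[:3]:  # each undirected edge once
            j = index.get((q + dq, r + dr))
            if j is not None:
                channels.append(
                    Channel(len(channels), i, j, channel_length, channel_width, channel_height)
                )

    boundary = [
        i
        for (q, r), i in index.items()
        if max(abs(q), abs(r), abs(q + r)) == rings
    ]
    ports: list[tuple[int, str]] = [(index[(0, 0)], "central")]
    for target in (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi):
        best = min(
            boundary,
            key=lambda i: (
                abs(
                    (math.atan2(coords[i, 1], coords[i, 0]) - target + math.pi)
                    % (2 * math.pi)
                    - math.pi
                ),
                i,
            ),
        )
        ports.append((best, "peripheral"))
    if len({n for n, _ in ports}) != 5:
        raise ValueError("rings too small to place 4 distinct peripheral ports")

    net = PoreNetwork(coords, channels, ports, port_volume=port_volume,
                      meta={"rings": rings})
    return net


# -- percolation and dilution ----------------------------------------------

def is_percolating(net: PoreNetwork) -> bool:
    """True iff the channel graph is one connected component covering every
    node (a cell can swim from any junction, ports included, to any other).

    A junction stripped of all its channels counts as unreachable, so the
    network is not percolating.
    """
    if net.n_channels == 0:
        return False
    if np.any(net.degree() == 0):
        return False
    n_comp, _ = connected_components(net.adjacency().tocsr(), directed=False)
    return n_comp == 1


def dilute(
    net: PoreNetwork,
    target_fraction: float,
    seed: int | np.random.Generator,
) -> PoreNetwork:
    """Randomly delete channels down to ``round(target_fraction * N_full)``
    while preserving percolation.

    Channels are visited in a seeded random permutation; a deletion that
    would disconnect the retained graph (or strand a port) is skipped.  The
    procedure fails loudly if the target cannot be reached.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise ValueError("target_fraction must be in (0, 1]")
    if not is_percolating(net):
        raise ValueError("input network must be percolating")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    n_target = int(round(target_fraction * net.n_full_channels))
    n_remove = net.n_channels - n_target
    if n_remove < 0:
        raise ValueError(
            f"target {n_target} channels exceeds current {net.n_channels}"
        )
    keep = [True] * net.n_channels
    if n_remove > 0:
        order = rng.permutation(net.n_channels)
        a, b = net.channel_a, net.channel_b
        removed = 0
        # union-find connectivity check over retained channels
        for cand in order:
            if removed == n_remove:
                break
            keep[cand] = False
            if _connected_without(net, keep, a, b):
                removed += 1
            else:
                keep[cand] = True
        if removed < n_remove:
            raise RuntimeError(
                f"dilution infeasible: removed {removed} of {n_remove} channels "
                "without breaking percolation"
            )

    new_channels = [
        Channel(i, c.a, c.b, c.L, c.W, c.H)
        for i, c in enumerate(c for k, c in zip(keep, net.channels) if k)
    ]
    out = PoreNetwork(
        net.coords.copy(),
        new_channels,
        list(net.ports),
        n_full_channels=net.n_full_channels,
        port_volume=net.port_volume,
        meta=dict(net.meta),
    )
    if not is_percolating(out):  # pragma: no cover - guarded by construction
        raise RuntimeError("dilution produced a non-percolating network")
    return out


def _connected_without(net, keep, a, b) -> bool:
    """Check that retained channels still span every node in one component."""
    mask = np.asarray(keep)
    aa, bb = a[mask], b[mask]
    covered = np.zeros(net.n_nodes, dtype=bool)
    covered[aa] = True
    covered[bb] = True
    if not covered.all():
        return False
    m = coo_matrix(
        (np.ones(aa.size), (aa, bb)), shape=(net.n_nodes, net.n_nodes)
    )
    n_comp, _ = connected_components(m, directed=False)
    return n_comp == 1


# -- metrics ----------------------------------------------------------------

def shortest_path_distance(net: PoreNetwork, source: int) -> np.ndarray:
    """Channel-length-weighted shortest-path distance (m) from ``source`` to
    every node.  Unreachable nodes get ``inf`` (cannot occur when the network
    percolates and they carry channels)."""
    graph = net.adjacency(weights=net.channel_length).tocsr()
    return dijkstra(graph, directed=False, indices=source)


def node_volume(net: PoreNetwork, node: int) -> float:
    """Finite-volume volume (m^3) of one node (half of incident channels,
    plus the port volume for port nodes)."""
    return float(net.node_volumes()[node])
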