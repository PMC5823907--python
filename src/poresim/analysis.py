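"""Quantification of simulated communities.

Spatial profiles follow the protocol used for the micrographs: cells are
attributed to their nearest junction, cells within 0.5 mm (Euclidean) of any
port are discarded (port artifacts), and the remainder are histogrammed along
the channel-weighted shortest-path distance from the central port in 20 equal
bins; each bin total is divided by the number of junctions whose distance
falls in the bin, giving an average cell count per node.  Abundances,
cross-connectivity t-tests, and a center-of-mass segregation statistic
operationalize the comparisons between scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import PoreNetwork, shortest_path_distance
from .population import AEROBE, ANAEROBE, SPECIES_LABELS, Cells

__all__ = [
    "BinnedProfile",
    "AbundanceSummary",
    "bin_by_shortest_path",
    "ensemble_profile",
    "relative_abundance",
    "abundance_over_realizations",
    "compare_density",
    "segregation_metrics",
    "uniformity_test",
]

DEFAULT_NBINS = 20
DEFAULT_EXCLUSION_RADIUS = 5e-4  # m


@dataclass
class BinnedProfile:
    """Average cells per node along shortest-path distance, for one species."""

    species: str
    edges: np.ndarray                 # (nbins+1,) m
    cells_per_bin: np.ndarray         # (nbins,) retained cells
    nodes_per_bin: np.ndarray         # (nbins,) junction count per bin
    n_retained: int
    n_dropped: int                    # cells excluded near ports

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def cells_per_node(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.cells_per_bin / self.nodes_per_bin
        return np.where(self.nodes_per_bin > 0, v, 0.0)


@dataclass
class AbundanceSummary:
    """Relative abundance of the two species, pooled over realizations."""

    counts: dict[str, float]
    fractions: dict[str, float]
    per_realization: pd.DataFrame | None = None
    mean: dict[str, float] | None = None
    sd: dict[str, float] | None = None
    defined: bool = True


def _node_distances(net: PoreNetwork) -> np.ndarray:
    return shortest_path_distance(net, net.central_port)


def bin_by_shortest_path(
    cells: Cells,
    net: PoreNetwork,
    nbins: int = DEFAULT_NBINS,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
) -> dict[str, BinnedProfile]:
    """Bin cells per species along shortest-path distance from the center.

    Cells within ``exclusion_radius`` (Euclidean) of any port are dropped;
    bin edges span 0 to the maximum finite node distance of this network.
    """
    if net.n_nodes == 0 or net.n_channels == 0:
        raise ValueError("empty network")
    dist = _node_distances(net)
    finite = np.isfinite(dist)
    edges = np.linspace(0.0, dist[finite].max(), nbins + 1)
    node_bin = np.clip(np.searchsorted(edges, dist[finite], side="right") - 1, 0, nbins - 1)
    nodes_per_bin = np.bincount(node_bin, minlength=nbins)

    nodes = cells.nearest_nodes(net)
    xy = cells.xy(net)
    keep = np.ones(len(cells), dtype=bool)
    for p in net.port_nodes:
        keep &= np.linalg.norm(xy - net.coords[p], axis=1) >= exclusion_radius

    out = {}
    finite_index = np.flatnonzero(finite)
    remap = -np.ones(net.n_nodes, dtype=int)
    remap[finite_index] = np.arange(finite_index.size)
    for s, label in enumerate(SPECIES_LABELS):
        sel = keep & (cells.species == s)
        cell_bins = node_bin[remap[nodes[sel]]]
        counts = np.bincount(cell_bins, minlength=nbins).astype(float)
        out[label] = BinnedProfile(
            species=label,
            edges=edges,
            cells_per_bin=counts,
            nodes_per_bin=nodes_per_bin,
            n_retained=int(sel.sum()),
            n_dropped=int(((~keep) & (cells.species == s)).sum()),
        )
    return out


def ensemble_profile(profiles: list[BinnedProfile]) -> pd.DataFrame:
    """Combine per-realization profiles of one species: per-bin mean cells
    per node with a per-bin envelope covering 95% of realization values."""
    if not profiles:
        raise ValueError("no profiles")
    edges = profiles[0].edges
    mat = np.vstack([p.cells_per_node for p in profiles])
    return pd.DataFrame(
        {
            "bin_lo_m": edges[:-1],
            "bin_hi_m": edges[1:],
            "species": profiles[0].species,
            "mean_cells_per_node": mat.mean(axis=0),
            "env_lo": np.percentile(mat, 2.5, axis=0),
            "env_hi": np.percentile(mat, 97.5, axis=0),
        }
    )


def relative_abundance(cells: Cells) -> AbundanceSummary:
    """Per-species fraction of living cells in one realization."""
    n_aer = int((cells.species == AEROBE).sum())
    n_an = int((cells.species == ANAEROBE).sum())
    total = n_aer + n_an
    if total == 0:
        return AbundanceSummary(
            counts={"aerobe": 0, "anaerobe": 0},
            fractions={"aerobe": float("nan"), "anaerobe": float("nan")},
            defined=False,
        )
    return AbundanceSummary(
        counts={"aerobe": n_aer, "anaerobe": n_an},
        fractions={"aerobe": n_aer / total, "anaerobe": n_an / total},
    )


def abundance_over_realizations(cells_list: list[Cells]) -> AbundanceSummary:
    """Pool realizations: per-realization fractions and their mean +- SD."""
    rows = []
    for k, cells in enumerate(cells_list):
        s = relative_abundance(cells)
        rows.append(
            {
                "realization": k,
                "n_aerobe": s.counts["aerobe"],
                "n_anaerobe": s.counts["anaerobe"],
                "frac_aerobe": s.fractions["aerobe"],
                "frac_anaerobe": s.fractions["anaerobe"],
            }
        )
    per = pd.DataFrame(rows)
    defined = per[["frac_aerobe", "frac_anaerobe"]].notna().all(axis=None)
    mean = {
        "aerobe": float(per["frac_aerobe"].mean()),
        "anaerobe": float(per["frac_anaerobe"].mean()),
    }
    sd = {
        "aerobe": float(per["frac_aerobe"].std(ddof=1)) if len(per) > 1 else 0.0,
        "anaerobe": float(per["frac_anaerobe"].std(ddof=1)) if len(per) > 1 else 0.0,
    }
    counts = {
        "aerobe": float(per["n_aerobe"].sum()),
        "anaerobe": float(per["n_anaerobe"].sum()),
    }
    tot = counts["aerobe"] + counts["anaerobe"]
    fractions = (
        {k: v / tot for k, v in counts.items()} if tot else
        {"aerobe": float("nan"), "anaerobe": float("nan")}
    )
    return AbundanceSummary(counts, fractions, per, mean, sd, defined=bool(defined))


def compare_density(counts_a, counts_b, welch: bool = False) -> tuple[float, float]:
    """Two-sample two-tailed t-test on per-realization totals.

    Pooled-variance by default (classic two-sample t); set ``welch`` for the
    unequal-variance variant.  Returns ``(t, p)``.
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0  # degenerate zero-variance identical groups
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def segregation_metrics(profiles: dict[str, BinnedProfile]) -> dict[str, float]:
    """Cell-weighted mean shortest-path distance per species and their
    difference (aerobe - anaerobe); positive means aerobes sit closer to the
    periphery."""
    means = {}
    for label, p in profiles.items():
        total = p.cells_per_bin.sum()
        if total == 0:
            raise ValueError(f"no retained {label} cells")
        means[label] = float((p.centers * p.cells_per_bin).sum() / total)
    return {
        "mean_distance_aerobe_m": means["aerobe"],
        "mean_distance_anaerobe_m": means["anaerobe"],
        "difference_m": means["aerobe"] - means["anaerobe"],
    }


def uniformity_test(
    cells: Cells,
    net: PoreNetwork,
    species: int | None = None,
    nbins: int = DEFAULT_NBINS,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of the binned profile against a spatially
    uniform population.

    The null expectation per bin is proportional to the summed node volume in
    the bin (a uniformly dispersed population samples channels per unit
    volume, so junction degree enters the expectation).  Returns
    ``(chi2, p)``.
    """
    dist = _node_distances(net)
    finite = np.isfinite(dist)
    edges = np.linspace(0.0, dist[finite].max(), nbins + 1)
    node_bin = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, nbins - 1)
    vol = net.node_volumes().copy()
    vol[net.port_nodes] -= net.port_volume  # ports excluded below anyway
    # drop nodes inside the port exclusion zones from the expectation
    node_keep = np.ones(net.n_nodes, dtype=bool)
    for p in net.port_nodes:
        node_keep &= np.linalg.norm(net.coords - net.coords[p], axis=1) >= exclusion_radius
    node_keep &= finite

    profiles = bin_by_shortest_path(cells, net, nbins, exclusion_radius)
    if species is None:
        observed = sum(p.cells_per_bin for p in profiles.values())
    else:
        observed = profiles[SPECIES_LABELS[species]].cells_per_bin
    expected_w = np.bincount(
        node_bin[node_keep], weights=vol[node_keep], minlength=nbins
    )
    use = expected_w > 0
    n = observed[use].sum()
    if n == 0:
        raise ValueError("no retained cells to test")
    expected = expected_w[use] / expected_w[use].sum() * n
    chi2, p = stats.chisquare(observed[use], expected)
    return float(chi2), float(p)
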