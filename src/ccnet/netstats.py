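"""Graph-level descriptors and seed-gene subnetwork extraction.

Summary statistics: giant connected component (GCC), mean shortest path over
the GCC (unit edge weights), edge density, discrete maximum-likelihood
power-law exponent of the degree distribution, and hub ranking.  The CSPNN
(connected shortest-path neighbor network) is the subnetwork induced by all
genes lying on any shortest path between a set of seed genes, plus the
seeds' direct neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.optimize
import scipy.special

from ccnet._util import log


def giant_connected_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the smallest lexicographic node id so the result
    is deterministic.
    """
    if net.number_of_nodes() == 0:
        return nx.Graph()
    comps = list(nx.connected_components(net))
    size = max(len(c) for c in comps)
    chosen = min((c for c in comps if len(c) == size), key=min)
    return net.subgraph(chosen).copy()


def average_shortest_path(net: nx.Graph) -> float:
    """Mean shortest-path length over unordered node pairs (unit weights).

    Intended to be called on a connected graph (typically the GCC); raises
    on fewer than 2 nodes or a disconnected input.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("average shortest path undefined for < 2 nodes")
    if not nx.is_connected(net):
        raise ValueError("graph is disconnected; compute on the GCC")
    return float(nx.average_shortest_path_length(net))


def edge_density(n_nodes: int, n_edges: int) -> float:
    """Fraction of possible pairs realised: ``2 e / (v (v - 1))``."""
    if n_nodes < 2:
        raise ValueError("edge density needs at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def power_law_fit(degrees, d_min: int = 1, method: str = "mle") -> float:
    """Power-law exponent of a degree sequence over degrees >= ``d_min``.

    ``method="mle"`` (default) maximises the discrete power-law likelihood
    numerically via the Hurwitz zeta normaliser and is unbiased for zeta
    samples at any ``d_min``.  ``method="approx"`` is the closed form
    ``alpha = 1 + n / sum(ln(d_i / (d_min - 0.5)))``, the usual continuous
    approximation, which underestimates the exponent when ``d_min`` is small.
    The value depends on the ``d_min`` convention, so exponents are
    comparable only under the same convention.
    """
    d = np.asarray([x for x in degrees if x >= max(d_min, 1)], dtype=float)
    if d.size < 10:
        raise ValueError("need at least 10 degrees >= d_min for a power-law fit")
    if np.all(d == d[0]):
        raise ValueError("degenerate degree sequence (all degrees equal)")
    if method == "approx":
        return float(1.0 + d.size / np.sum(np.log(d / (d_min - 0.5))))
    if method != "mle":
        raise ValueError(f"unknown method {method!r}")
    log_sum = float(np.sum(np.log(d)))
    n = d.size

    def nll(alpha: float) -> float:
        return n * np.log(scipy.special.zeta(alpha, max(d_min, 1))) + alpha * log_sum

    res = scipy.optimize.minimize_scalar(nll, bounds=(1.01, 20.0), method="bounded")
    return float(res.x)


def hub_table(net: nx.Graph, k: int = 10) -> list[tuple[str, int]]:
    """Top-``k`` genes by degree, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(net.degree, key=lambda t: (-t[1], t[0]))
    return [(g, int(d)) for g, d in ranked[:k]]


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    gcc_size: int
    avg_shortest_path: float
    edge_density: float
    powerlaw_exponent: float


def network_summary(net: nx.Graph, path_sample: int | None = None, seed: int = 0) -> NetworkSummary:
    """Standard descriptor bundle for one network.

    ``path_sample``: if set and the GCC is larger, the mean shortest path is
    approximated from that many uniformly sampled source nodes (flagged in
    the log); exact otherwise.
    """
    gcc = giant_connected_component(net)
    if gcc.number_of_nodes() >= 2:
        if path_sample is not None and gcc.number_of_nodes() > path_sample:
            log.warning("approximating mean shortest path from %d sources", path_sample)
            rng = np.random.default_rng(seed)
            nodes = sorted(gcc.nodes)
            sources = rng.choice(len(nodes), size=path_sample, replace=False)
            tot, cnt = 0.0, 0
            for s in sources:
                lengths = nx.single_source_shortest_path_length(gcc, nodes[s])
                tot += sum(lengths.values())
                cnt += len(lengths) - 1
            asp = tot / cnt
        else:
            asp = average_shortest_path(gcc)
    else:
        asp = float("nan")
    degrees = [d for _, d in net.degree]
    try:
        alpha = power_law_fit(degrees)
    except ValueError:
        alpha = float("nan")
    return NetworkSummary(
        n_nodes=net.number_of_nodes(),
        n_edges=net.number_of_edges(),
        gcc_size=gcc.number_of_nodes(),
        avg_shortest_path=float(asp),
        edge_density=edge_density(net.number_of_nodes(), net.number_of_edges())
        if net.number_of_nodes() >= 2
        else float("nan"),
        powerlaw_exponent=alpha,
    )


@dataclass
class CSPNN:
    """Connected shortest-path neighbor network around seed genes."""

    seed_genes: set[str]          # L1
    path_genes: set[str]          # L2: all genes on shortest paths among L1
    network: nx.Graph             # induced on L2 plus direct neighbors of L1

    def roles(self) -> dict[str, str]:
        out = {}
        for g in self.network.nodes:
            if g in self.seed_genes:
                out[g] = "seed"
            elif g in self.path_genes:
                out[g] = "path"
            else:
                out[g] = "neighbor"
        return out


def cspnn(net: nx.Graph, seeds) -> CSPNN:
    """Extract the CSPNN for a seed gene set.

    ``L2`` is the union, over all unordered seed pairs, of every node lying
    on *any* shortest path between the pair (a node x is on one iff
    ``d(a, x) + d(x, b) == d(a, b)``).  The result is the parent network's
    induced subgraph on ``L2`` together with all direct neighbors of seeds.
    Seeds absent from the network are dropped with a warning.
    """
    seeds = set(seeds)
    present = sorted(seeds & set(net.nodes))
    missing = seeds - set(present)
    if missing:
        log.warning("seeds absent from network dropped: %s", ", ".join(sorted(missing)))
    if not present:
        raise ValueError("no seed gene is present in the network")
    dist = {s: nx.single_source_shortest_path_length(net, s) for s in present}
    l2 = set(present)
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            if b not in dist[a]:
                continue  # unreachable pair contributes no path nodes
            d_ab = dist[a][b]
            l2.update(
                x for x, da in dist[a].items()
                if da <= d_ab and dist[b].get(x, np.inf) == d_ab - da
            )
    neighbors = set()
    for s in present:
        neighbors.update(net.neighbors(s))
    sub = net.subgraph(l2 | neighbors).copy()
    return CSPNN(seed_genes=set(present), path_genes=l2, network=sub)
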