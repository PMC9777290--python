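"""DEG-subnetwork construction and topology diagnostics.

The interaction network restricted to the DEG list is the backbone of the
crosstalk score: per-gene degree ("conn") and the total edge count
("conn_total") enter the score directly. This module also provides two
descriptive diagnostics — the degree distribution with a log-log CCDF
slope, and a census of connected 3-node motifs (open triads and triangles)
with z-scores against a degree-preserving rewired ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .formats_io import InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass
class DegSubnetwork:
    """Interaction network induced on the DEG list.

    Isolated DEG nodes (present in the network but with no surviving
    neighbour) are retained with degree 0 so that connectivity statistics
    refer to the same gene list everywhere.
    """

    graph: nx.Graph

    @property
    def conn(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @property
    def conn_total(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def induce_deg_network(net: InteractionNetwork, degs) -> DegSubnetwork:
    """Subgraph on degs ∩ network nodes, keeping isolated DEG nodes."""
    keep = [g for g in degs if g in net.graph]
    if not keep:
        logger.warning("no DEG appears in the interaction network")
    return DegSubnetwork(graph=nx.Graph(net.graph.subgraph(keep)))


def degree_distribution(sub: DegSubnetwork) -> tuple[dict[int, int], float | None]:
    """Degree histogram plus the log10 CCDF slope over degrees >= 1.

    The slope is a least-squares fit of log10 P(degree >= d) against
    log10 d and serves as a qualitative scale-free diagnostic only; with
    fewer than 10 positive-degree nodes it is omitted.
    """
    degrees = np.array([d for _, d in sub.graph.degree()], dtype=int)
    hist: dict[int, int] = {}
    for d in degrees:
        hist[int(d)] = hist.get(int(d), 0) + 1
    positive = np.sort(degrees[degrees >= 1])
    if positive.size < 10 or np.unique(positive).size < 2:
        logger.warning("too few positive-degree nodes for a power-law slope")
        return hist, None
    uniq = np.unique(positive)
    ccdf = np.array([(positive >= d).mean() for d in uniq])
    slope = float(np.polyfit(np.log10(uniq), np.log10(ccdf), 1)[0])
    return hist, slope


@dataclass
class MotifCensus:
    open_triads: int
    triangles: int
    z_scores: dict[str, float] | None
    n_rewired: int
    seed: int | None


def count_motifs(graph: nx.Graph) -> tuple[int, int]:
    """Exact counts of connected 3-node subgraphs: (open triads, triangles)."""
    triangles = sum(nx.triangles(graph).values()) // 3
    paths2 = sum(d * (d - 1) // 2 for _, d in graph.degree())
    return paths2 - 3 * triangles, triangles


def _rewired_sample(graph: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """One degree-preserving rewiring via attempted double-edge swaps."""
    g = nx.Graph(graph)
    n_edges = g.number_of_edges()
    if n_edges < 2:
        return g
    nswap = 10 * n_edges
    seed = int(rng.integers(0, 2**31 - 1))
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXError:
        pass  # too few swappable edges; keep whatever was achieved
    return g


def motif_census(
    sub: DegSubnetwork, n_rewired: int = 100, seed: int | None = None
) -> MotifCensus:
    """3-node motif counts with z-scores vs a degree-preserving null.

    The null ensemble is ``n_rewired`` copies of the subnetwork randomised
    by double-edge swaps (10 x |E| attempted swaps each), which preserves
    every node's degree exactly. With ``n_rewired < 2`` the z-scores are
    omitted.
    """
    if sub.graph.number_of_nodes() < 3:
        raise ValueError("motif census needs at least 3 nodes")
    open_triads, triangles = count_motifs(sub.graph)
    z_scores = None
    if n_rewired >= 2:
        rng = np.random.default_rng(seed)
        null = np.array(
            [count_motifs(_rewired_sample(sub.graph, rng)) for _ in range(n_rewired)],
            dtype=float,
        )
        z_scores = {}
        for i, name in enumerate(("open_triads", "triangles")):
            mu, sd = null[:, i].mean(), null[:, i].std(ddof=1)
            obs = (open_triads, triangles)[i]
            if sd == 0:
                z_scores[name] = 0.0 if obs == mu else float(np.sign(obs - mu) * np.inf)
            else:
                z_scores[name] = float((obs - mu) / sd)
    return MotifCensus(
        open_triads=open_triads,
        triangles=triangles,
        z_scores=z_scores,
        n_rewired=n_rewired,
        seed=seed,
    )
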