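"""Synthetic pipeline inputs with planted ground truth.

Emulates the shape of a two-group microarray study joined with a gene-set
collection and a functional-association network:

* expression — per-gene Normal(mu_g, 1) log2 intensities, with a planted
  subset of genes shifted by a fixed effect size (in SD units) in the
  target group;
* gene sets — decoy pathways drawn uniformly from the universe plus three
  planted pathways stuffed with planted DEGs so they must come out
  enriched: two of them ("A", "B") designated as the crosstalking pair,
  one ("C") isolated;
* network — a preferential-attachment backbone (scale-free degree
  structure) plus dense intra- and cross-edges between the DEG members of
  A and B, and with every edge from a C member to a non-member removed, so
  CT(·, C) = 0 holds by construction and (A, B) is the top crosstalk pair.

All randomness flows from ``FixtureSpec.seed``. The generator makes no
attempt to emulate probe-level artefacts, normalization residue, or
correlated noise between genes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .formats_io import (
    CONTROL,
    TARGET,
    ExpressionDataset,
    GeneSetCollection,
    InteractionNetwork,
)

PLANTED_A = "PATH_A"
PLANTED_B = "PATH_B"
PLANTED_C = "PATH_C"


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic inputs.

    Defaults follow the pipeline's reference scenario: 1000 genes measured
    in 10 + 10 samples, 50 planted DEGs shifted by 2 SD, three planted
    enriched pathways (each at least 60% planted DEGs) among 20 decoys,
    and a preferential-attachment network with densified crosstalk between
    the first two planted pathways.
    """

    n_genes: int = 1000
    n_samples_per_group: int = 10
    n_planted_degs: int = 50
    effect_size: float = 2.0
    n_decoy_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 30)
    planted_pathway_size: int = 20
    planted_deg_members: int = 15
    ab_overlap: int = 3
    pa_edges_per_node: int = 2
    intra_edge_prob: float = 0.6
    cross_edge_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_degs > self.n_genes:
            raise ValueError("more planted DEGs than genes")
        if self.planted_deg_members > self.planted_pathway_size:
            raise ValueError("planted DEG members exceed the pathway size")
        if self.planted_deg_members < 0.6 * self.planted_pathway_size:
            raise ValueError("planted pathways must be at least 60% planted DEGs")
        if 3 * self.planted_deg_members - self.ab_overlap > self.n_planted_degs:
            raise ValueError("overlap design needs more planted DEGs than available")


def gene_universe(spec: FixtureSpec) -> list[str]:
    return [f"G{i:04d}" for i in range(spec.n_genes)]


def _rng(spec: FixtureSpec, stream: str) -> np.random.Generator:
    # crc32 gives a process-independent stream id (str hash is randomized)
    tag = zlib.crc32(stream.encode()) % 2**31
    return np.random.default_rng(np.random.SeedSequence([spec.seed, tag]))


def _planted_gene_indices(spec: FixtureSpec) -> list[int]:
    rng = _rng(spec, "planted")
    return sorted(rng.choice(spec.n_genes, size=spec.n_planted_degs, replace=False))


def make_expression(spec: FixtureSpec) -> tuple[ExpressionDataset, dict]:
    """Two-group log2 expression matrix with planted differential genes.

    Control samples are Normal(mu_g, 1) per gene; target samples of the
    planted DEGs are shifted by ``effect_size`` SD (sign alternating so
    both up- and down-regulation occur). Returns the dataset and a truth
    table naming the planted genes.
    """
    rng = _rng(spec, "expression")
    genes = gene_universe(spec)
    n = spec.n_samples_per_group
    mu = rng.uniform(4.0, 12.0, size=spec.n_genes)
    control = rng.normal(mu[:, None], 1.0, size=(spec.n_genes, n))
    target = rng.normal(mu[:, None], 1.0, size=(spec.n_genes, n))
    planted = _planted_gene_indices(spec)
    signs = np.where(np.arange(spec.n_planted_degs) % 2 == 0, 1.0, -1.0)
    target[planted, :] += (spec.effect_size * signs)[:, None]

    samples = [f"C{i:02d}" for i in range(n)] + [f"T{i:02d}" for i in range(n)]
    values = pd.DataFrame(
        np.hstack([control, target]), index=genes, columns=samples
    )
    groups = pd.Series(
        [CONTROL] * n + [TARGET] * n, index=samples
    )
    truth = {"planted_degs": [genes[i] for i in planted]}
    return ExpressionDataset(values=values, groups=groups), truth


def make_genesets_and_network(
    spec: FixtureSpec,
) -> tuple[GeneSetCollection, InteractionNetwork, dict]:
    """Gene sets and interaction network with a planted crosstalk pair.

    The planted pathways reuse the planted DEGs of :func:`make_expression`
    under the same spec (the generators share the seed-derived gene
    assignment). Truth records the planted enriched pathways, the intended
    top crosstalk pair (A, B) and the isolated pathway C.
    """
    genes = gene_universe(spec)
    planted = [genes[i] for i in _planted_gene_indices(spec)]

    rng = _rng(spec, "sets")
    d = spec.planted_deg_members
    a_degs = planted[:d]
    b_degs = planted[d - spec.ab_overlap : 2 * d - spec.ab_overlap]
    c_degs = planted[2 * d - spec.ab_overlap : 3 * d - spec.ab_overlap]
    non_deg = [g for g in genes if g not in set(planted)]
    fill = spec.planted_pathway_size - d

    def pad(members: list[str], exclude: set[str]) -> frozenset[str]:
        pool = [g for g in non_deg if g not in exclude]
        extra = list(rng.choice(pool, size=fill, replace=False))
        return frozenset(members + extra)

    set_a = pad(a_degs, set())
    set_b = pad(b_degs, set(set_a))
    set_c = pad(c_degs, set(set_a) | set(set_b))

    sets: dict[str, tuple[str, frozenset[str]]] = {
        PLANTED_A: ("planted pathway A", set_a),
        PLANTED_B: ("planted pathway B", set_b),
        PLANTED_C: ("planted isolated pathway C", set_c),
    }
    lo, hi = spec.pathway_size_range
    for i in range(spec.n_decoy_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(non_deg, size=size, replace=False))
        sets[f"DECOY_{i:02d}"] = (f"decoy pathway {i}", members)
    collection = GeneSetCollection(sets=sets)

    # scale-free backbone over the whole universe
    net_seed = int(_rng(spec, "network").integers(0, 2**31 - 1))
    backbone = nx.barabasi_albert_graph(spec.n_genes, spec.pa_edges_per_node, seed=net_seed)
    g = nx.relabel_nodes(backbone, {i: genes[i] for i in range(spec.n_genes)})

    rng_net = _rng(spec, "edges")
    a_list, b_list = sorted(a_degs), sorted(b_degs)
    for nodes in (a_list, b_list):
        for x in range(len(nodes)):
            for y in range(x + 1, len(nodes)):
                if rng_net.random() < spec.intra_edge_prob:
                    g.add_edge(nodes[x], nodes[y])
    for x in a_list:
        for y in b_list:
            if x != y and rng_net.random() < spec.cross_edge_prob:
                g.add_edge(x, y)

    # isolate pathway C: its members keep only edges among themselves
    c_members = set(set_c)
    for node in sorted(c_members):
        for nb in list(g.adj[node]):
            if nb not in c_members:
                g.remove_edge(node, nb)
    for x in sorted(c_members):                       # keep C internally connected
        for y in sorted(c_members):
            if x < y and rng_net.random() < spec.intra_edge_prob:
                g.add_edge(x, y)

    net = InteractionNetwork(graph=g)
    truth = {
        "planted_enriched": [PLANTED_A, PLANTED_B, PLANTED_C],
        "top_crosstalk_pair": sorted([PLANTED_A, PLANTED_B]),
        "isolated_pathway": PLANTED_C,
    }
    return collection, net, truth


def make_all(spec: FixtureSpec):
    """Expression, gene sets, network and merged truth for one seed."""
    data, truth_e = make_expression(spec)
    sets, net, truth_n = make_genesets_and_network(spec)
    return data, sets, net, {**truth_e, **truth_n}
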