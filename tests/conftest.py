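import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gecip.formats_io import CONTROL, TARGET, ExpressionDataset, InteractionNetwork
from gecip.network import DegSubnetwork


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """3 genes x 4 samples, 2 control + 2 target, hand-written values."""
    values = pd.DataFrame(
        {
            "c1": [1.0, 5.0, 2.0],
            "c2": [2.0, 5.0, 2.5],
            "t1": [3.0, 5.0, 6.0],
            "t2": [4.0, 5.0, 6.5],
        },
        index=["TP53", "GAPDH", "MYC"],
    )
    groups = pd.Series(
        {"c1": CONTROL, "c2": CONTROL, "t1": TARGET, "t2": TARGET}
    )
    return ExpressionDataset(values=values, groups=groups)


def dataset_from_groups(control: np.ndarray, target: np.ndarray, genes=None) -> ExpressionDataset:
    """Build a dataset from genes x samples arrays for the two groups."""
    control = np.atleast_2d(np.asarray(control, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    n_genes = control.shape[0]
    genes = genes or [f"G{i:03d}" for i in range(n_genes)]
    cols = [f"c{i}" for i in range(control.shape[1])] + [
        f"t{i}" for i in range(target.shape[1])
    ]
    values = pd.DataFrame(np.hstack([control, target]), index=genes, columns=cols)
    groups = pd.Series(
        [CONTROL] * control.shape[1] + [TARGET] * target.shape[1], index=cols
    )
    return ExpressionDataset(values=values, groups=groups)


def subnetwork_from_edges(edges, extra_nodes=()) -> DegSubnetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return DegSubnetwork(graph=g)


def network_from_edges(edges) -> InteractionNetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    return InteractionNetwork(graph=g)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def bh_stepup_naive(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values straight from the step-up definition:

    q_i = min over j with p_j >= p_i of m * p_j / rank_j, capped at 1,
    where rank_j is p_j's 1-based position in the sorted order.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    rank = np.empty(m, dtype=int)
    rank[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        cands = [m * p[j] / rank[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(cands))
    return q


def hypergeom_tail_enumeration(k: int, N: int, m: int, n: int) -> float:
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws."""
    from itertools import combinations

    annotated = set(range(m))
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total


def naive_ct_degree(sub: DegSubnetwork, set_s, set_t, sharing) -> float:
    """Triple-loop crosstalk score over the full adjacency matrix."""
    order = sorted(sub.graph.nodes)
    adj = nx.to_numpy_array(sub.graph, nodelist=order, weight=None)
    conn = sub.conn
    c_total = sub.conn_total
    total = 0.0
    for i, gi in enumerate(order):
        for j, gj in enumerate(order):
            if i == j or adj[i, j] == 0:
                continue
            for src, dst in ((set_s, set_t), (set_t, set_s)):
                if gi in src and gj in dst:
                    total += conn[gi] * sharing[gi] * c_total / (conn[gi] + conn[gj])
    return total


def count_motifs_bruteforce(graph: nx.Graph) -> tuple[int, int]:
    """(open triads, triangles) by enumerating all node triples."""
    from itertools import combinations

    nodes = list(graph.nodes)
    open_triads = triangles = 0
    for trio in combinations(nodes, 3):
        n_edges = sum(graph.has_edge(a, b) for a, b in combinations(trio, 2))
        if n_edges == 3:
            triangles += 1
        elif n_edges == 2:
            open_triads += 1
    return open_triads, triangles
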