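"""Crosstalk degree (CTdegree) between pairs of enriched pathways.

For two enriched pathways s and t the crosstalk degree is a weighted sum
over the network edges joining a gene of s to a gene of t, evaluated on
the DEG-induced subnetwork:

    CT(s, t) = sum over ordered pairs (i in s, j in t, i != j, A_ij = 1) of
                 conn(i) * sharing(i) * C_total / (conn(i) + conn(j))
             + the mirrored sum over (i in t, j in s)

where conn(i) is gene i's degree within the DEG subnetwork, sharing(i) the
number of enriched pathways containing i, and C_total the subnetwork's
total edge count. Each adjacent cross-pathway pair contributes in both
orientations with the multiplicative factors taken from the source gene,
which makes the score symmetric by construction. Genes belonging to both
pathways contribute in both orientations; a gene never pairs with itself.
C_total is a common factor of every term, so it rescales the whole matrix
without changing the ranking of pairs — the normalized matrix (divided by
its maximum) is emitted alongside for cross-dataset comparison and edge
thickness scaling.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import DegSubnetwork

logger = logging.getLogger(__name__)


def pathway_sharing(enriched_sets: dict[str, frozenset[str]]) -> Counter:
    """gene -> number of enriched pathways containing it.

    Only genes appearing in at least one enriched pathway are present;
    sharing is defined over the enriched collection (pass all pathways to
    get the all-pathway variant).
    """
    sharing: Counter = Counter()
    for members in enriched_sets.values():
        for g in members:
            sharing[g] += 1
    return sharing


def ct_degree_pair(
    sub: DegSubnetwork,
    set_s: frozenset[str],
    set_t: frozenset[str],
    sharing,
    _ledger: list | None = None,
    _names: tuple[str, str] = ("s", "t"),
) -> float:
    """CTdegree between two gene sets over the DEG subnetwork.

    Raises for identical sets: within-pathway crosstalk is undefined.
    """
    if set_s == set_t:
        raise ValueError("self-crosstalk is undefined (identical gene sets)")
    return _ct_degree_pair_unchecked(sub, set_s, set_t, sharing, _ledger, _names)


def _ct_degree_pair_unchecked(
    sub: DegSubnetwork,
    set_s: frozenset[str],
    set_t: frozenset[str],
    sharing,
    _ledger: list | None = None,
    _names: tuple[str, str] = ("s", "t"),
) -> float:
    # two *distinct* pathways may share an identical membership; the guard
    # above only protects the public pair API against literal self-pairs
    graph = sub.graph
    conn = sub.conn
    c_total = sub.conn_total
    s_nodes = {g for g in set_s if g in conn}
    t_nodes = {g for g in set_t if g in conn}
    total = 0.0
    for src_set, dst_set, (name_src, name_dst) in (
        (s_nodes, t_nodes, _names),
        (t_nodes, s_nodes, _names[::-1]),
    ):
        for i in src_set:
            for j in graph.adj[i]:
                if j in dst_set and j != i:
                    term = conn[i] * sharing[i] * c_total / (conn[i] + conn[j])
                    total += term
                    if _ledger is not None:
                        _ledger.append((i, j, name_src, name_dst, term))
    return total


@dataclass
class CrosstalkResult:
    """Symmetric CTdegree matrix plus the per-term contribution ledger.

    ``ct`` has a zero diagonal by convention. ``contributions`` holds one
    row per ordered adjacent cross-pathway gene pair (gene_i is the source
    whose conn and sharing enter the term), which makes any alternative
    reading of the score recomputable and supports per-gene summaries.
    """

    ct: pd.DataFrame
    contributions: pd.DataFrame
    sub: DegSubnetwork
    sharing: Counter

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def normalized(self) -> pd.DataFrame:
        peak = self.ct.to_numpy().max()
        return self.ct / peak if peak > 0 else self.ct.copy()

    def pairs(self) -> pd.DataFrame:
        """Long-format table of unordered pathway pairs with CTdegree > 0."""
        ids = self.pathway_ids
        norm = self.normalized
        rows = []
        for a in range(len(ids)):
            for b in range(a + 1, len(ids)):
                val = self.ct.iloc[a, b]
                if val > 0:
                    rows.append((ids[a], ids[b], val, norm.iloc[a, b]))
        return pd.DataFrame(
            rows, columns=["pathway_s", "pathway_t", "ctdegree", "ctdegree_normalized"]
        )

    def ranked_pairs(self) -> pd.DataFrame:
        out = self.pairs().sort_values(
            ["ctdegree", "pathway_s", "pathway_t"], ascending=[False, True, True]
        )
        return out.reset_index(drop=True)


def ct_degree_all(
    sub: DegSubnetwork,
    enriched_sets: dict[str, frozenset[str]],
    sharing=None,
) -> CrosstalkResult:
    """CTdegree for every unordered pair of enriched pathways.

    ``sharing`` defaults to counts over ``enriched_sets`` themselves; pass
    a precomputed map (e.g. over all annotated pathways) to switch the
    sharing definition.
    """
    ids = list(enriched_sets)
    if len(ids) < 2:
        raise ValueError("crosstalk needs at least 2 enriched pathways")
    if sharing is None:
        sharing = pathway_sharing(enriched_sets)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    ledger_rows: list = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            s, t = ids[a], ids[b]
            val = _ct_degree_pair_unchecked(
                sub, enriched_sets[s], enriched_sets[t], sharing,
                _ledger=ledger_rows, _names=(s, t),
            )
            mat.loc[s, t] = mat.loc[t, s] = val
    contributions = pd.DataFrame(
        ledger_rows, columns=["gene_i", "gene_j", "pathway_s", "pathway_t", "term"]
    )
    return CrosstalkResult(ct=mat, contributions=contributions, sub=sub, sharing=sharing)


def top_contributors(result: CrosstalkResult, k: int | None = None) -> pd.DataFrame:
    """Genes ranked by summed term contribution across all pathway pairs.

    A gene's contribution is the sum of the terms in which it is the source
    node. Ties break by subnetwork degree (descending) then symbol.
    """
    ledger = result.contributions
    if ledger.empty:
        raise ValueError("contribution ledger is empty")
    totals = ledger.groupby("gene_i")["term"].sum()
    conn = result.sub.conn
    table = pd.DataFrame(
        {
            "gene": totals.index,
            "total_contribution": totals.to_numpy(),
            "conn": [conn.get(g, 0) for g in totals.index],
        }
    )
    table = table.sort_values(
        ["total_contribution", "conn", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table if k is None else table.head(k)


def permutation_null(
    sub: DegSubnetwork,
    enriched_sets: dict[str, frozenset[str]],
    n_permutations: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Optional permutation null: shuffle gene-to-pathway labels, recompute.

    Returns per-pair empirical p-values P(CT_perm >= CT_obs). Off by
    default in the pipeline — the score is reported raw — but available
    for calibration studies.
    """
    rng = np.random.default_rng(seed)
    obs = ct_degree_all(sub, enriched_sets)
    ids = obs.pathway_ids
    sizes = {pid: len(enriched_sets[pid]) for pid in ids}
    pool = sorted(set().union(*enriched_sets.values()))
    exceed = np.zeros((len(ids), len(ids)))
    for _ in range(n_permutations):
        perm_sets = {
            pid: frozenset(rng.choice(pool, size=sizes[pid], replace=False))
            for pid in ids
        }
        perm = ct_degree_all(sub, perm_sets)
        exceed += (perm.ct.to_numpy() >= obs.ct.to_numpy()).astype(float)
    pvals = (exceed + 1.0) / (n_permutations + 1.0)
    np.fill_diagonal(pvals, 1.0)
    out = pd.DataFrame(pvals, index=ids, columns=ids)
    return out
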