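from collections import Counter

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gecip import crosstalk as ct
from gecip.network import DegSubnetwork
from tests.conftest import naive_ct_degree, subnetwork_from_edges


class TestPathwaySharing:
    def test_counts_membership_across_enriched_sets(self):
        sets = {
            "P1": frozenset({"A", "B"}),
            "P2": frozenset({"A"}),
            "P3": frozenset({"A", "C"}),
            "P4": frozenset({"D"}),
            "P5": frozenset({"E"}),
        }
        sharing = ct.pathway_sharing(sets)
        assert sharing["A"] == 3
        assert sharing["B"] == 1
        assert "Z" not in sharing


class TestCtDegreePair:
    def test_hand_enumerated_path_graph(self):
        # path A-B-C: conn(A)=1, conn(B)=2, C_total=2; P1={A}, P2={B}
        # ordered terms: A->B: 1*1*2/(1+2) = 2/3; B->A: 2*1*2/(2+1) = 4/3
        sub = subnetwork_from_edges([("A", "B"), ("B", "C")])
        sharing = Counter({"A": 1, "B": 1})
        val = ct.ct_degree_pair(sub, frozenset({"A"}), frozenset({"B"}), sharing)
        assert val == pytest.approx(2.0)

    def test_disconnected_pathways_score_zero(self):
        sub = subnetwork_from_edges([("A", "B"), ("C", "D")])
        sharing = Counter({"A": 1, "C": 1})
        assert ct.ct_degree_pair(sub, frozenset({"A"}), frozenset({"C"}), sharing) == 0.0

    def test_conn_total_is_a_common_factor(self):
        # adding an edge elsewhere (D-E) doubles C_total without touching
        # the degrees of A and B, so CT doubles exactly
        sharing = Counter({"A": 1, "B": 1})
        small = subnetwork_from_edges([("A", "B")])
        big = subnetwork_from_edges([("A", "B"), ("D", "E")])
        ct_small = ct.ct_degree_pair(small, frozenset({"A"}), frozenset({"B"}), sharing)
        ct_big = ct.ct_degree_pair(big, frozenset({"A"}), frozenset({"B"}), sharing)
        assert ct_big == pytest.approx(2 * ct_small)

    def test_self_crosstalk_rejected(self):
        sub = subnetwork_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            ct.ct_degree_pair(sub, frozenset({"A"}), frozenset({"A"}), Counter())


def _random_instance(seed: int, max_genes: int = 50):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, max_genes + 1))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.05, 0.4)), seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"G{i:02d}" for i in g.nodes})
    nodes = sorted(g.nodes)
    n_sets = int(rng.integers(2, 6))
    sets = {}
    for s in range(n_sets):
        size = int(rng.integers(1, max(2, n // 2)))
        sets[f"P{s}"] = frozenset(rng.choice(nodes, size=size, replace=False))
    return DegSubnetwork(graph=g), sets


class TestCtDegreeAll:
    def test_matrix_consistent_with_pairwise_calls(self):
        sub, sets = _random_instance(0)
        sharing = ct.pathway_sharing(sets)
        res = ct.ct_degree_all(sub, sets)
        for a in sets:
            for b in sets:
                if a == b:
                    assert res.ct.loc[a, b] == 0.0
                else:
                    assert res.ct.loc[a, b] == pytest.approx(
                        ct.ct_degree_pair(sub, sets[a], sets[b], sharing)
                    )

    def test_symmetry_and_nonnegativity(self):
        for seed in range(10):
            sub, sets = _random_instance(seed)
            res = ct.ct_degree_all(sub, sets)
            mat = res.ct.to_numpy()
            np.testing.assert_allclose(mat, mat.T, atol=1e-12)
            assert (mat >= 0).all()
            assert np.diag(mat).sum() == 0.0

    def test_matches_naive_triple_loop_oracle(self):
        for seed in range(25):
            sub, sets = _random_instance(seed)
            sharing = ct.pathway_sharing(sets)
            res = ct.ct_degree_all(sub, sets)
            ids = list(sets)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    expected = naive_ct_degree(sub, sets[ids[i]], sets[ids[j]], sharing)
                    assert res.ct.loc[ids[i], ids[j]] == pytest.approx(
                        expected, abs=1e-9
                    )

    def test_pathway_order_only_relabels(self):
        sub, sets = _random_instance(3)
        res_fwd = ct.ct_degree_all(sub, sets)
        rev = dict(reversed(list(sets.items())))
        res_rev = ct.ct_degree_all(sub, rev)
        ids = list(sets)
        pd.testing.assert_frame_equal(
            res_fwd.ct.loc[ids, ids], res_rev.ct.loc[ids, ids]
        )

    def test_fewer_than_two_pathways_rejected(self):
        sub = subnetwork_from_edges([("A", "B")])
        with pytest.raises(ValueError):
            ct.ct_degree_all(sub, {"P": frozenset({"A"})})

    def test_ledger_sums_to_matrix_entries(self):
        sub, sets = _random_instance(4)
        res = ct.ct_degree_all(sub, sets)
        ledger = res.contributions
        ids = list(sets)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                s, t = ids[i], ids[j]
                # both orientations of a pair accumulate into the same cell
                mask = ((ledger["pathway_s"] == s) & (ledger["pathway_t"] == t)) | (
                    (ledger["pathway_s"] == t) & (ledger["pathway_t"] == s)
                )
                assert res.ct.loc[s, t] == pytest.approx(ledger.loc[mask, "term"].sum())

    def test_ledger_terms_nonnegative_so_terms_only_add(self):
        sub, sets = _random_instance(5)
        res = ct.ct_degree_all(sub, sets)
        assert (res.contributions["term"] >= 0).all()

    def test_removing_a_gene_removes_all_its_terms(self):
        sub, sets = _random_instance(6)
        res = ct.ct_degree_all(sub, sets)
        if res.contributions.empty:
            pytest.skip("degenerate random instance")
        gene = res.contributions["gene_i"].iloc[0]
        stripped = {
            pid: frozenset(m - {gene}) for pid, m in sets.items()
        }
        stripped = {pid: m for pid, m in stripped.items() if m}
        if len(stripped) < 2:
            pytest.skip("degenerate random instance")
        res2 = ct.ct_degree_all(sub, stripped)
        ledger = res2.contributions
        assert gene not in set(ledger["gene_i"]) | set(ledger["gene_j"])


class TestTopContributors:
    def test_hub_shared_by_many_pathways_ranks_first(self):
        # HUB is in 3 pathways and carries every cross edge
        edges = [("HUB", x) for x in ("A1", "B1", "C1", "D1")]
        sub = subnetwork_from_edges(edges)
        sets = {
            "PA": frozenset({"HUB", "A1"}),
            "PB": frozenset({"HUB", "B1"}),
            "PC": frozenset({"HUB", "C1"}),
        }
        res = ct.ct_degree_all(sub, sets)
        top = ct.top_contributors(res)
        assert top.iloc[0]["gene"] == "HUB"

    def test_k_larger_than_gene_count_returns_all(self):
        sub = subnetwork_from_edges([("A", "B")])
        sets = {"P1": frozenset({"A"}), "P2": frozenset({"B"})}
        res = ct.ct_degree_all(sub, sets)
        assert len(ct.top_contributors(res, k=100)) == 2

    def test_equal_contributions_rank_by_symbol(self):
        # two symmetric genes with identical degree and contribution
        sub = subnetwork_from_edges([("AAA", "ZZZ")])
        sets = {"P1": frozenset({"AAA"}), "P2": frozenset({"ZZZ"})}
        res = ct.ct_degree_all(sub, sets)
        top = ct.top_contributors(res)
        assert list(top["gene"]) == ["AAA", "ZZZ"]

    def test_empty_ledger_rejected(self):
        sub = subnetwork_from_edges([("A", "B"), ("C", "D")])
        sets = {"P1": frozenset({"A"}), "P2": frozenset({"C"})}
        res = ct.ct_degree_all(sub, sets)
        with pytest.raises(ValueError):
            ct.top_contributors(res)
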