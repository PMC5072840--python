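import itertools

import networkx as nx
import numpy as np
import pytest

from grfkit.dataio import GeneTimeSeries, InteractionMatrix, Kind, default_grid
from grfkit.fitting import FitResult
from grfkit.grf_models import GRFForm, GRFSpec
from grfkit.network_inference import (NetworkModel, NodeCandidateSet,
                                      enumerate_networks,
                                      is_strongly_connected,
                                      periodicity_score, rank_report,
                                      select_candidate_tfs)


def fit_stub(gene, inputs, score, form=None):
    ar = len(inputs)
    form = form or (GRFForm.ACT if ar == 1 else GRFForm.AND)
    spec = GRFSpec(form, b=0.1, alpha=1.0, K=(1.0,) * ar, n=(2.0,) * ar,
                   inputs=tuple(inputs))
    return FitResult(gene, tuple(inputs), spec, (0.05,) * ar, score)


def interactions(pairs):
    nodes = sorted({g for p in pairs for g in p})
    return InteractionMatrix(nodes=nodes, allowed=set(pairs))


def brute_force_prune(periodic, edges):
    alive = {g for g, f in periodic.items() if f}
    while True:
        keep = {g for g in alive
                if any((r, g) in edges and r in alive for r in alive)
                and any((g, t) in edges and t in alive for t in alive)}
        if keep == alive:
            return keep
        alive = keep


class TestCandidateSelection:
    def test_three_cycle_all_retained(self):
        mat = interactions({("A", "B"), ("B", "C"), ("C", "A")})
        flags = {g: True for g in "ABC"}
        assert select_candidate_tfs(flags, mat) == ["A", "B", "C"]

    def test_chain_fully_pruned(self):
        mat = interactions({("A", "B"), ("B", "C")})
        flags = {g: True for g in "ABC"}
        assert select_candidate_tfs(flags, mat) == []

    def test_non_periodic_node_breaks_cycle(self):
        mat = interactions({("A", "B"), ("B", "C"), ("C", "A")})
        flags = {"A": True, "B": False, "C": True}
        assert select_candidate_tfs(flags, mat) == []

    def test_matches_brute_force_on_random_digraphs(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(5, 21))
            genes = [f"N{i}" for i in range(n)]
            edges = {(genes[i], genes[j])
                     for i in range(n) for j in range(n)
                     if i != j and rng.random() < 0.15}
            flags = {g: bool(rng.random() < 0.8) for g in genes}
            mat = InteractionMatrix(nodes=genes, allowed=edges)
            assert set(select_candidate_tfs(flags, mat)) \
                == brute_force_prune(flags, edges)

    def test_merge_of_homologous_nodes(self):
        # B2 is absorbed into B; the merged node inherits B2's edges
        mat = interactions({("A", "B2"), ("B", "A"), ("C", "B"), ("B", "C")})
        flags = {g: True for g in ("A", "B", "B2", "C")}
        merged = select_candidate_tfs(flags, mat, merge={"B2": "B"})
        assert merged == ["A", "B", "C"]


class TestStrongConnectivity:
    def test_mutual_pair(self):
        g = nx.DiGraph([("A", "B"), ("B", "A")])
        assert is_strongly_connected(g)

    def test_dag_is_not(self):
        g = nx.DiGraph([("A", "B"), ("B", "C"), ("A", "C")])
        assert not is_strongly_connected(g)

    def test_matches_all_pairs_reachability(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            g = nx.gnp_random_graph(n, 0.3, directed=True,
                                    seed=int(rng.integers(2**31)))
            if g.number_of_nodes() == 0:
                continue
            reach = dict(nx.all_pairs_shortest_path_length(g))
            oracle = all(v in reach[u] for u in g for v in g)
            assert is_strongly_connected(g) == oracle

    def test_externals_not_in_graph(self):
        net = NetworkModel(
            nodes={"A": fit_stub("A", ("B",), 0.1),
                   "B": fit_stub("B", ("A", "EXT"), 0.2, GRFForm.ANDNOT)},
            externals=("EXT",))
        assert is_strongly_connected(net)
        assert "EXT" not in net.graph().nodes


class TestEnumerateNetworks:
    def _three_node_candidates(self):
        """3 genes, fully connected allowance: 3 candidate regulations per
        gene (2 singles + 1 pair), 27 combinations total."""
        genes = ["A", "B", "C"]
        rng = np.random.default_rng(4)
        cands = {}
        for g in genes:
            others = [o for o in genes if o != g]
            menu = [fit_stub(g, (others[0],), float(rng.random())),
                    fit_stub(g, (others[1],), float(rng.random())),
                    fit_stub(g, tuple(others), float(rng.random()))]
            cands[g] = NodeCandidateSet(g, menu)
        return cands

    def _brute_force(self, cands):
        genes = sorted(cands)
        combos = []
        for choice in itertools.product(*(cands[g].candidates for g in genes)):
            net = NetworkModel(nodes=dict(zip(genes, choice)))
            combos.append(net)
        sc = [n for n in combos if is_strongly_connected(n)]
        sc.sort(key=lambda n: n.score)
        return combos, sc

    def test_exhaustive_oracle_on_3node_toy(self):
        cands = self._three_node_candidates()
        combos, sc_sorted = self._brute_force(cands)
        assert len(combos) == 27
        got = list(enumerate_networks(cands))
        assert len(got) == len(sc_sorted)
        np.testing.assert_allclose([n.score for n in got],
                                   [n.score for n in sc_sorted])
        assert [n.topology() for n in got] == [n.topology() for n in sc_sorted]

    def test_scores_yielded_in_ascending_order(self):
        got = list(enumerate_networks(self._three_node_candidates()))
        scores = [n.score for n in got]
        assert scores == sorted(scores)

    def test_network_score_is_mean_of_node_scores(self):
        net = next(enumerate_networks(self._three_node_candidates()))
        assert net.score == pytest.approx(
            np.mean([f.score for f in net.nodes.values()]))

    def test_two_node_single_candidate(self):
        cands = {"A": NodeCandidateSet("A", [fit_stub("A", ("B",), 0.2)]),
                 "B": NodeCandidateSet("B", [fit_stub("B", ("A",), 0.1)])}
        nets = list(enumerate_networks(cands))
        assert len(nets) == 1
        assert is_strongly_connected(nets[0])

    def test_no_connected_combination_warns(self):
        cands = {"A": NodeCandidateSet("A", [fit_stub("A", ("B",), 0.2)]),
                 "B": NodeCandidateSet("B", [fit_stub("B", ("B",), 0.1)])}
        with pytest.warns(UserWarning, match="no strongly connected"):
            assert list(enumerate_networks(cands)) == []

    def test_constrained_optimum_not_better_than_unconstrained(self):
        cands = self._three_node_candidates()
        unconstrained = np.mean([min(f.score for f in cands[g].candidates)
                                 for g in cands])
        best = next(enumerate_networks(cands))
        assert best.score >= unconstrained - 1e-12


class TestRankReport:
    def test_top5_nondecreasing_with_diffs(self):
        cands = TestEnumerateNetworks()._three_node_candidates()
        report = rank_report(enumerate_networks(cands), top_k=5)
        assert len(report) == 5
        scores = [r["score"] for r in report]
        assert scores == sorted(scores)
        assert report[0]["differs_from_rank1_at"] == []
        assert any(r["differs_from_rank1_at"] for r in report[1:])

    def test_top_k_validated(self):
        with pytest.raises(ValueError):
            rank_report(iter([]), top_k=0)


class TestPeriodicityStandIn:
    def test_pure_60min_oscillation_scores_high(self):
        grid = default_grid()
        v = 1 + 0.5 * np.sin(2 * np.pi * grid.times / 60.0)
        s = GeneTimeSeries("G", Kind.mrna_level, v, grid)
        assert periodicity_score(s, period=60.0) > 0.8

    def test_aperiodic_scores_low(self):
        grid = default_grid()
        rng = np.random.default_rng(3)
        s = GeneTimeSeries("G", Kind.mrna_level, rng.random(42) + 1.0, grid)
        assert periodicity_score(s, period=60.0) < 0.5

    def test_constant_scores_zero(self):
        s = GeneTimeSeries("G", Kind.mrna_level, np.ones(42), default_grid())
        assert periodicity_score(s) == 0.0
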