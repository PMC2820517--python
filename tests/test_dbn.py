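"""Two-slice DBN learning: BIC closed forms, greedy search, consensus."""

import itertools
import math

import numpy as np
import pytest

from temponet import (CohortSpec, TwoSliceNetwork, consensus_network,
                      learn_inter_slice, node_bic_score, self_link_fraction,
                      simulate_cohort_panel, transition_rows)
from temponet.dbn import TransitionData, lagged_correlation_candidates
from temponet.preprocess import reference_to_baseline


def random_transitions(rng, n=200, genes=("a", "b", "c")):
    g = len(genes)
    return TransitionData(
        genes=list(genes),
        prev=rng.normal(size=(n, g)), curr=rng.normal(size=(n, g)),
        individual_idx=np.zeros(n, dtype=int), t_index=np.arange(n),
    )


def exhaustive_best(child, candidates, data):
    """Oracle: minimum BIC over all candidate subsets."""
    best = math.inf
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            s = node_bic_score(child, frozenset(), frozenset(subset), data)
            best = min(best, s)
    return best


class TestTransitionRows:
    def test_row_count_from_cohort_geometry(self, chain_panel):
        data = transition_rows(chain_panel)  # 40 individuals x 6 points
        assert data.n_rows == 40 * 5

    def test_single_transition(self, rng):
        from temponet import ExpressionPanel
        panel = ExpressionPanel(values=rng.normal(size=(2, 1, 2)),
                                gene_ids=["a", "b"], individual_ids=["i"],
                                timepoints=np.arange(2))
        assert transition_rows(panel).n_rows == 1

    def test_matches_brute_force_extraction(self, rng):
        from temponet import ExpressionPanel
        vals = rng.normal(size=(3, 2, 4))
        panel = ExpressionPanel(values=vals, gene_ids=["a", "b", "c"],
                                individual_ids=["i", "j"],
                                timepoints=np.arange(4))
        data = transition_rows(panel)
        row = 0
        for i in range(2):
            for t in range(1, 4):
                np.testing.assert_array_equal(data.prev[row], vals[:, i, t - 1])
                np.testing.assert_array_equal(data.curr[row], vals[:, i, t])
                row += 1


class TestNodeBIC:
    def test_matches_closed_form_for_empty_model(self, rng):
        data = random_transitions(rng)
        n = data.n_rows
        y = data.curr[:, 0]
        rss = ((y - y.mean())**2).sum()
        expected = n * math.log(rss / n) + 2 * math.log(n)
        score = node_bic_score("a", frozenset(), frozenset(), data)
        assert score == pytest.approx(expected, rel=1e-8)

    def test_exact_self_copy_dominates(self, rng):
        data = random_transitions(rng, n=50)
        data.curr[:, 0] = data.prev[:, 0]  # child equals its own lag
        with_self = node_bic_score("a", frozenset(), frozenset({"a"}), data)
        empty = node_bic_score("a", frozenset(), frozenset(), data)
        assert with_self == -math.inf < empty

    def test_irrelevant_parent_usually_raises_bic(self):
        worse = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            data = random_transitions(rng, n=200)
            empty = node_bic_score("a", frozenset(), frozenset(), data)
            extra = node_bic_score("a", frozenset(), frozenset({"b"}), data)
            worse += extra > empty
        assert worse >= 90

    def test_insufficient_rows_rejected(self, rng):
        data = random_transitions(rng, n=3)
        with pytest.raises(ValueError):
            node_bic_score("a", frozenset(), frozenset({"b", "c"}), data)


class TestGreedySearch:
    def test_forced_single_candidate_always_selected(self, rng):
        data = random_transitions(rng, n=100)
        data.curr[:, 1] = 0.9 * data.prev[:, 0] \
            + 0.1 * rng.normal(size=100)
        intra = TwoSliceNetwork(genes=data.genes)
        nets = learn_inter_slice(data, intra, candidates={"a": [], "b": ["a"],
                                                          "c": []},
                                 restarts=10, seed=3)
        assert all(("a", "b") in net.inter_edges for net in nets)

    def test_matches_exhaustive_search(self):
        # 20 seeded instances, <= 5 candidates per child
        matches = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = random_transitions(rng, n=120,
                                      genes=[f"g{i}" for i in range(6)])
            # plant two real effects so the instances are not all-null
            data.curr[:, 0] = 0.8 * data.prev[:, 1] + rng.normal(size=120)
            data.curr[:, 2] = 0.7 * data.prev[:, 3] + rng.normal(size=120)
            candidates = {g: [h for h in data.genes if h != g][:5]
                          for g in data.genes}
            intra = TwoSliceNetwork(genes=data.genes)
            nets = learn_inter_slice(data, intra, candidates=candidates,
                                     restarts=5, seed=seed)
            for net in nets:
                for child in data.genes:
                    total += 1
                    oracle = exhaustive_best(child, candidates[child], data)
                    matches += math.isclose(net.node_bic[child], oracle,
                                            rel_tol=1e-9, abs_tol=1e-9)
        assert matches / total >= 0.95

    def test_per_child_decomposability(self, rng):
        data = random_transitions(rng, n=100)
        intra = TwoSliceNetwork(genes=data.genes)
        net = learn_inter_slice(data, intra, restarts=1, seed=9)[0]
        parents = {g: frozenset(p for p, c in net.inter_edges if c == g)
                   for g in data.genes}
        total = sum(node_bic_score(g, frozenset(), parents[g], data)
                    for g in data.genes)
        assert net.total_bic == pytest.approx(total, rel=1e-12)

    def test_cyclic_intra_rejected(self, rng):
        with pytest.raises(ValueError):
            TwoSliceNetwork(genes=["a", "b"],
                            intra_edges={("a", "b"), ("b", "a")})

    def test_intra_parents_enter_regression(self, rng):
        # child fully explained by intra parent at t -> no inter parent added
        data = random_transitions(rng, n=100)
        data.curr[:, 1] = 2.0 * data.curr[:, 0] + 0.01 * rng.normal(size=100)
        intra = TwoSliceNetwork(genes=data.genes, intra_edges={("a", "b")})
        nets = learn_inter_slice(data, intra, restarts=5, seed=11)
        assert all(not any(c == "b" for _, c in net.inter_edges)
                   for net in nets)


class TestConsensus:
    def net(self, edges):
        return TwoSliceNetwork(genes=["a", "b", "c"],
                               inter_edges=frozenset(edges))

    def test_identical_structures_reproduced(self):
        nets = [self.net({("a", "a"), ("a", "b")})] * 10
        cons = consensus_network(nets, 0.3)
        assert cons.inter_edges == frozenset({("a", "a"), ("a", "b")})
        assert all(f == 1.0 for f in cons.frequencies.values())

    def test_threshold_is_inclusive(self):
        nets = [self.net({("a", "b")})] * 3 + [self.net(set())] * 7
        assert consensus_network(nets, 0.3).inter_edges == {("a", "b")}
        nets = [self.net({("a", "b")})] * 2 + [self.net(set())] * 8
        assert consensus_network(nets, 0.3).inter_edges == frozenset()

    def test_threshold_one_is_intersection(self):
        nets = [self.net({("a", "b"), ("b", "c")}), self.net({("a", "b")})]
        assert consensus_network(nets, 1.0).inter_edges == {("a", "b")}

    def test_consensus_within_union(self, rng):
        nets = [self.net({(x, y) for x, y in
                          zip(rng.choice(["a", "b", "c"], 3),
                              rng.choice(["a", "b", "c"], 3))})
                for _ in range(10)]
        union = frozenset().union(*(n.inter_edges for n in nets))
        assert consensus_network(nets, 0.3).inter_edges <= union

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            consensus_network([], 0.3)


class TestSelfLinks:
    def test_all_self_edges(self):
        net = TwoSliceNetwork(genes=["a", "b"],
                              inter_edges={("a", "a"), ("b", "b")})
        assert self_link_fraction(net) == 1.0

    def test_half_self_edges(self):
        net = TwoSliceNetwork(
            genes=["a", "b", "c"],
            inter_edges={("a", "a"), ("a", "b"), ("b", "b"), ("c", "b")})
        assert self_link_fraction(net) == 0.5

    def test_no_inter_edges_is_undefined(self):
        assert self_link_fraction(TwoSliceNetwork(genes=["a"])) is None


class TestCandidateScreen:
    def test_true_parents_pass_screen(self):
        genes = [f"g{i}" for i in range(8)]
        inter = {(g, g): 0.6 for g in genes}
        inter[("g0", "g1")] = 0.9
        spec = CohortSpec(genes=genes, inter_edges=inter, noise_sd=1.0)
        truth = simulate_cohort_panel(spec, 40, 7, seed=13)
        data = transition_rows(reference_to_baseline(truth.panel))
        cands = lagged_correlation_candidates(data)
        for parent, child in truth.true_inter_edges:
            assert parent in cands[child]

    def test_top_k_caps_list_length(self, rng):
        data = random_transitions(rng, n=100)
        cands = lagged_correlation_candidates(data, alpha=0.99, top_k=1)
        assert all(len(v) <= 1 for v in cands.values())
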