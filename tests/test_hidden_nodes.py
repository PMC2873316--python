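from collections import Counter

import numpy as np
import pytest

from netreg.hidden_nodes import (
    build_path_index,
    hidden_node_pvalue,
    rank_hidden_nodes,
    transcription_regulated_targets,
)
from netreg.network_model import GeneSet, Interaction, InteractionNetwork
from netreg.synthetic_data import SimulationConfig, generate_network

from conftest import brute_force_path_index, random_tiny_network


class TestBuildPathIndexChain(object):
    def test_chain_enumerates_four_paths(self, chain_net, chain_targets):
        idx = build_path_index(chain_net, chain_targets)
        assert idx.n_paths == 4  # one shortest path per source L, R, K, TF
        assert idx.paths_containing("K") == 3  # on the L-, R- and K-paths
        assert idx.paths_containing("T") == 4  # terminal counts as containing
        assert idx.paths_containing("TF") == 4
        assert idx.target_counts["T"] == 4

    def test_inhibitory_edge_breaks_even_parity(self, chain_net, chain_targets):
        net = InteractionNetwork(node_class=dict(chain_net.node_class))
        for e in chain_net.interactions:
            effect = "inhibition" if (e.source, e.target) == ("K", "TF") else e.effect
            net.add_interaction(Interaction(e.source, e.target, effect, e.mechanism))
        idx = build_path_index(net, chain_targets, parity="even")
        # every path through K->TF has exactly one inhibition: all excluded
        assert sorted(idx.paths) == [("TF", "T")]

    def test_odd_parity_reproduces_literal_rule(self, chain_net, chain_targets):
        net = InteractionNetwork(node_class=dict(chain_net.node_class))
        for e in chain_net.interactions:
            effect = "inhibition" if (e.source, e.target) == ("K", "TF") else e.effect
            net.add_interaction(Interaction(e.source, e.target, effect, e.mechanism))
        idx = build_path_index(net, chain_targets, parity="odd")
        assert sorted(idx.paths) == [
            ("K", "TF", "T"),
            ("L", "R", "K", "TF", "T"),
            ("R", "K", "TF", "T"),
        ]

    def test_unspecified_counts_as_activation(self, chain_net, chain_targets):
        net = InteractionNetwork(node_class=dict(chain_net.node_class))
        for e in chain_net.interactions:
            effect = "unspecified" if e.source == "R" else e.effect
            net.add_interaction(Interaction(e.source, e.target, effect, e.mechanism))
        idx = build_path_index(net, chain_targets, parity="even")
        assert idx.n_paths == 4
        idx2 = build_path_index(
            net, chain_targets, parity="even", exclude_unspecified=True
        )
        assert idx2.n_paths == 2  # K- and TF-paths only

    def test_two_equal_length_paths_both_enumerated(self):
        net = InteractionNetwork()
        net.set_node_class("S", "generic")
        net.set_node_class("A", "kinase")
        net.set_node_class("B", "kinase")
        net.set_node_class("TF", "transcription_factor")
        net.set_node_class("T", "generic")
        for s, t, m in [
            ("S", "A", "other"),
            ("S", "B", "other"),
            ("A", "TF", "other"),
            ("B", "TF", "other"),
            ("TF", "T", "transcription_regulation"),
        ]:
            net.add_interaction(Interaction(s, t, "activation", m))
        idx = build_path_index(net, GeneSet("s", {"T"}))
        from_s = [p for p in idx.paths if p[0] == "S"]
        assert sorted(from_s) == [("S", "A", "TF", "T"), ("S", "B", "TF", "T")]

    def test_target_without_tr_edge_skipped(self, chain_net):
        idx = build_path_index(chain_net, GeneSet("s", {"K"}))
        assert idx.n_paths == 0

    def test_max_len_cap(self, chain_net, chain_targets):
        idx = build_path_index(chain_net, chain_targets, max_len=2)
        assert sorted(idx.paths) == [("K", "TF", "T"), ("TF", "T")]


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(1, 21))
    def test_random_networks_match_exhaustive_enumerator(self, seed):
        net = random_tiny_network(seed)
        targets = transcription_regulated_targets(net)
        idx = build_path_index(net, targets)
        expected = brute_force_path_index(net, targets)
        assert idx.n_paths == len(expected)
        assert Counter(idx.paths) == Counter(tuple(p) for p in expected)
        expected_node_counts = Counter()
        for p in expected:
            for v in set(p):
                expected_node_counts[v] += 1
        assert idx.node_counts == expected_node_counts
        assert idx.target_counts == Counter(p[-1] for p in expected)

    @pytest.mark.parametrize("seed", [2, 9, 17])
    def test_every_indexed_path_is_admissible(self, seed):
        net = random_tiny_network(seed)
        targets = transcription_regulated_targets(net)
        idx = build_path_index(net, targets, max_len=5)
        by_pair = {}
        for p in idx.paths:
            assert len(p) - 1 <= 5
            assert len(set(p)) == len(p)  # simple
            assert p[-1] in targets
            # final edge must be TR from a TF-class node
            assert net.node_class.get(p[-2]) == "transcription_factor"
            assert any(
                e.is_tr
                for e in net.out_edges(p[-2])
                if e.target == p[-1]
            )
            # an even-inhibition assignment along the node sequence exists
            assert _has_even_parity_assignment(net, p)
            by_pair.setdefault((p[0], p[-1]), set()).add(len(p))
        for lengths in by_pair.values():
            assert len(lengths) == 1  # all shortest per (source, target)


def _has_even_parity_assignment(net, path):
    parities = {0}
    for u, v in zip(path, path[1:]):
        step = set()
        for e in net.out_edges(u):
            if e.target == v:
                step.add(1 if e.effect == "inhibition" else 0)
        parities = {p ^ s for p in parities for s in step}
    return 0 in parities


class TestHiddenNodePvalue:
    def test_node_absent_from_paths(self, chain_net, chain_targets):
        idx = build_path_index(chain_net, chain_targets)
        assert hidden_node_pvalue(idx, "nowhere", chain_targets) == 1.0

    def test_targets_equal_all_terminals_gives_one(self):
        net = InteractionNetwork()
        net.set_node_class("TF", "transcription_factor")
        for t in ("t1", "t2", "t3"):
            net.add_interaction(
                Interaction("TF", t, "activation", "transcription_regulation")
            )
        all_targets = GeneSet("all", {"t1", "t2", "t3"})
        idx = build_path_index(net, all_targets)
        for v in net.nodes:
            assert hidden_node_pvalue(idx, v, all_targets) == 1.0

    def test_two_layer_reduction(self):
        # TF->targets only: nodes not regulating the set get p = 1
        net = InteractionNetwork()
        for i, tf in enumerate(["TF0", "TF1", "TF2"]):
            net.set_node_class(tf, "transcription_factor")
            for j in range(3):
                net.add_interaction(
                    Interaction(
                        tf, f"t{i}_{j}", "activation", "transcription_regulation"
                    )
                )
        universe = transcription_regulated_targets(net)
        idx = build_path_index(net, universe)
        s = GeneSet("s", {"t0_0", "t0_1", "t0_2"})
        assert hidden_node_pvalue(idx, "TF1", s) == 1.0
        assert hidden_node_pvalue(idx, "TF2", s) == 1.0
        assert hidden_node_pvalue(idx, "TF0", s) < 0.05

    def test_enriched_node_matches_resampling_oracle(self):
        # uniform path-resampling null: target-bound paths are an
        # exchangeable draw of R from the N indexed paths
        net, truth = generate_network(SimulationConfig(seed=11, n_nodes=120))
        universe = transcription_regulated_targets(net)
        idx = build_path_index(net, universe)
        s = truth.planted_targets
        v = sorted(truth.planted_receptors)[0]
        p = hidden_node_pvalue(idx, v, s)
        assert p < 0.5

        rng = np.random.default_rng(11)
        contains_v = np.array([v in set(p_) for p_ in idx.paths])
        to_targets = np.array([p_[-1] in s for p_ in idx.paths])
        R = int(to_targets.sum())
        r_obs = int((contains_v & to_targets).sum())
        n_reps = 10_000
        draws = rng.random((n_reps, idx.n_paths)).argsort(axis=1)[:, :R]
        counts = contains_v[draws].sum(axis=1)
        p_hat = float((counts >= r_obs).mean())
        se = max(np.sqrt(p_hat * (1 - p_hat) / n_reps), 1 / n_reps)
        assert abs(p - p_hat) <= 2 * se + 1e-9


class TestRankHiddenNodes:
    def test_single_candidate(self, chain_net, chain_targets):
        rl = rank_hidden_nodes(chain_net, chain_targets, ["K"])
        assert len(rl) == 1

    def test_empty_candidates_rejected(self, chain_net, chain_targets):
        with pytest.raises(ValueError, match="empty"):
            rank_hidden_nodes(chain_net, chain_targets, lambda v: False)

    def test_output_is_permutation(self):
        net, truth = generate_network(SimulationConfig(seed=4, n_nodes=100))
        s = GeneSet("s", truth.planted_targets)
        rl = rank_hidden_nodes(net, s, "receptor")
        assert sorted(rl.nodes) == sorted(net.nodes_of_class("receptor"))

    def test_planted_receptor_ranks_first(self):
        # single planted cascade vs ~29 decoy receptors; the planted
        # receptor must rank first in >= 90% of 50 seeded simulations
        wins = 0
        for seed in range(1, 51):
            cfg = SimulationConfig(
                seed=seed, n_planted_receptors=1, isolate_cascade=True
            )
            net, truth = generate_network(cfg)
            s = GeneSet("targets", truth.planted_targets)
            rl = rank_hidden_nodes(net, s, "receptor")
            wins += rl.nodes[0] in truth.planted_receptors
        assert wins / 50 >= 0.90

    def test_prebuilt_index_matches_fresh(self):
        net, truth = generate_network(SimulationConfig(seed=8, n_nodes=100))
        s = GeneSet("s", truth.planted_targets)
        idx = build_path_index(net, transcription_regulated_targets(net))
        a = rank_hidden_nodes(net, s, "receptor")
        b = rank_hidden_nodes(net, s, "receptor", index=idx)
        assert a.nodes == b.nodes
        assert a.p_values == b.p_values
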