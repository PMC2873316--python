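import dataclasses
from collections import Counter

import pytest

from netreg.diffexpr import de_gene_set, median_normalize, paired_de_test
from netreg.hidden_nodes import rank_hidden_nodes
from netreg.integration_pipeline import (
    PipelineConfig,
    classify_receptors,
    find_common_tfs,
    pathway_linked,
    report_checksums,
    run_pipeline,
)
from netreg.network_model import GeneSet, Interaction, InteractionNetwork
from netreg.overconnectivity import RankedEntry, RankedList
from netreg.rank_aggregation import GAConfig
from netreg.synthetic_data import (
    SimulationConfig,
    classification_scenario,
    generate_expression,
    generate_network,
    write_simulation,
)

LIGHT_GA = GAConfig(seed=0, population=60, generations=150, convergence_window=25)


def two_block_net():
    """Six TFs in two blocks, each block regulating its own target set."""
    net = InteractionNetwork()
    for i in range(6):
        net.set_node_class(f"TF{i}", "transcription_factor")
    for i in range(3):
        for j in range(4):
            net.add_interaction(
                Interaction(
                    f"TF{i}", f"a{i}_{j}", "activation", "transcription_regulation"
                )
            )
            net.add_interaction(
                Interaction(
                    f"TF{i + 3}", f"b{i}_{j}", "activation", "transcription_regulation"
                )
            )
    return net


class TestFindCommonTfs:
    def test_identical_sets_intersection_is_aggregate(self):
        net, truth = generate_network(SimulationConfig(seed=5))
        s = GeneSet("s", truth.planted_targets)
        res = find_common_tfs(net, s, s, ga=LIGHT_GA)
        assert res.common_tfs == res.aggregated["transcriptomics"]
        assert res.aggregated["transcriptomics"] == res.aggregated["proteomics"]

    def test_disjoint_regulators_give_empty_intersection(self):
        net = two_block_net()
        set_a = GeneSet("a", {f"a{i}_{j}" for i in range(3) for j in range(4)})
        set_b = GeneSet("b", {f"b{i}_{j}" for i in range(3) for j in range(4)})
        res = find_common_tfs(net, set_a, set_b, k=3, ga=LIGHT_GA)
        assert res.common_tfs == []
        assert res.supplemental_tfs != []

    def test_shared_planted_tf_recovered(self):
        hits = 0
        n_reps = 50
        for seed in range(1, n_reps + 1):
            cfg = SimulationConfig(seed=seed, n_planted_tfs=1)
            net, truth = generate_network(cfg)
            de = paired_de_test(median_normalize(generate_expression(truth, cfg)))
            set_tx = de_gene_set(de)
            panel = GeneSet("prot", sorted(truth.planted_targets)[:10])
            res = find_common_tfs(
                net, set_tx, panel, ga=dataclasses.replace(LIGHT_GA, seed=seed)
            )
            hits += truth.planted_tfs <= set(res.common_tfs)
        assert hits / n_reps >= 0.90

    def test_empty_gene_set_rejected(self):
        net, _ = generate_network(SimulationConfig(seed=1))
        with pytest.raises(ValueError, match="empty"):
            find_common_tfs(net, GeneSet("x", []), GeneSet("y", {"GEN000"}))


class TestPathwayLinked:
    def test_direct_edge(self):
        net = InteractionNetwork()
        net.set_node_class("R", "receptor")
        net.set_node_class("TF", "transcription_factor")
        net.add_interaction(Interaction("R", "TF"))
        assert pathway_linked(net, "R", {"TF"})

    def test_separate_component(self):
        net = InteractionNetwork()
        net.add_interaction(Interaction("R", "x"))
        net.add_interaction(Interaction("y", "TF"))
        assert not pathway_linked(net, "R", {"TF"})

    def test_hop_cap_enforced(self):
        net = InteractionNetwork()
        chain = [f"c{i}" for i in range(9)]  # 8 hops from c0 to c8
        for u, v in zip(chain, chain[1:]):
            net.add_interaction(Interaction(u, v))
        assert pathway_linked(net, "c0", {"c8"}, max_len=8)
        assert not pathway_linked(net, "c0", {"c8"}, max_len=7)


def _ranking(entries):
    return RankedList(
        entries=[RankedEntry(node=n, p_value=p) for n, p in entries]
    )


class TestClassifyReceptors:
    @pytest.fixture
    def scenario(self):
        net, truth, x, expected = classification_scenario(seed=3)
        de = paired_de_test(median_normalize(x))
        ranking = rank_hidden_nodes(net, de_gene_set(de), "receptor")
        return net, truth, de, ranking, expected

    def test_exact_category_counts(self, scenario):
        net, truth, de, ranking, expected = scenario
        cls = classify_receptors(net, ranking, de, truth.planted_tfs)
        got = Counter(c.category for c in cls if c.retained)
        assert got == Counter(expected.values())
        by_receptor = {c.receptor: c.category for c in cls}
        for rec, want in expected.items():
            assert by_receptor[rec] == want

    def test_high_p_rejected_regardless_of_expression(self, scenario):
        net, truth, de, ranking, _ = scenario
        cls = classify_receptors(net, ranking, de, truth.planted_tfs, p_cut=1e-20)
        assert all(c.category == "rejected" for c in cls)

    def test_boundary_receptor_only(self):
        # p = 0.04 with own gene overexpressed and no passing ligand
        net, truth, x, expected = classification_scenario(seed=3)
        de = paired_de_test(median_normalize(x))
        ranking = _ranking([("REC000", 0.04), ("REC005", 0.06)])
        cls = classify_receptors(net, ranking, de, truth.planted_tfs)
        by_receptor = {c.receptor: c for c in cls}
        assert by_receptor["REC000"].category == "receptor_only"
        # p = 0.06 rejected even though both receptor and ligand pass DE
        assert by_receptor["REC005"].category == "rejected"

    def test_categories_partition_retained(self, scenario):
        net, truth, de, ranking, _ = scenario
        cls = classify_receptors(net, ranking, de, truth.planted_tfs)
        retained = [c for c in cls if c.retained]
        counts = Counter(c.category for c in retained)
        assert sum(counts.values()) == len(retained)
        assert set(counts) <= {"receptor_only", "ligand_only", "both"}
        for c in retained:
            assert (c.category == "both") == (
                c.receptor_overexpressed and c.ligand_overexpressed
            )

    def test_monotone_in_thresholds(self, scenario):
        net, truth, de, ranking, _ = scenario

        def retained(p_cut, fc_cut):
            return {
                c.receptor
                for c in classify_receptors(
                    net, ranking, de, truth.planted_tfs, p_cut=p_cut, fc_cut=fc_cut
                )
                if c.retained
            }

        base = retained(0.05, 2.5)
        assert retained(0.01, 2.5) <= base
        assert retained(0.05, 3.5) <= base
        assert base <= retained(0.10, 2.0)


@pytest.fixture(scope="module")
def sim_bundle(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("bundle")
    cfg = SimulationConfig(
        seed=11, plant_receptor_expression=True, plant_ligand_expression=True
    )
    write_simulation(cfg, tmp)
    return tmp


def pipeline_config(bundle, out_dir, seed=11):
    return PipelineConfig(
        network_edges=str(bundle / "network_edges.tsv"),
        network_nodes=str(bundle / "network_nodes.tsv"),
        expression=str(bundle / "expression.tsv"),
        pairs=str(bundle / "pairs.tsv"),
        protein_sets=str(bundle / "protein_panel.gmt"),
        out_dir=str(out_dir),
        seed=seed,
    )


class TestRunPipeline:
    def test_end_to_end_smoke(self, sim_bundle, tmp_path):
        results = run_pipeline(pipeline_config(sim_bundle, tmp_path / "out"))
        out = tmp_path / "out"
        for name in (
            "de_table.tsv",
            "common_tfs.tsv",
            "receptor_networks.tsv",
            "receptor_classification.tsv",
            "run_log.json",
        ):
            assert (out / name).exists()
        assert any(c.retained for c in results["classifications"])

    def test_missing_input_names_file(self, sim_bundle, tmp_path):
        cfg = pipeline_config(sim_bundle, tmp_path / "out")
        cfg = dataclasses.replace(cfg, expression=str(sim_bundle / "nope.tsv"))
        with pytest.raises(RuntimeError, match="load"):
            run_pipeline(cfg)

    def test_two_runs_byte_identical(self, sim_bundle, tmp_path):
        run_pipeline(pipeline_config(sim_bundle, tmp_path / "a"))
        run_pipeline(pipeline_config(sim_bundle, tmp_path / "b"))
        sums_a = report_checksums(tmp_path / "a")
        sums_b = report_checksums(tmp_path / "b")
        assert sums_a and sums_a == sums_b

    def test_yaml_config_round_trip(self, sim_bundle, tmp_path):
        import yaml

        cfg = pipeline_config(sim_bundle, tmp_path / "out")
        path = tmp_path / "config.yaml"
        path.write_text(yaml.safe_dump(dataclasses.asdict(cfg)))
        loaded = PipelineConfig.from_yaml(path)
        assert loaded == cfg

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("network_edges: x\nbogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            PipelineConfig.from_yaml(path)
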