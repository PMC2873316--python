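"""Synthetic signed regulatory networks and paired expression with ground truth.

The generator plants an all-activating causal cascade
(ligand -> receptor -> kinase -> TF -> TR targets) inside a class-respecting
preferential-attachment background, then simulates paired
lesional/non-lesional log-normal expression in which the planted targets
(and optionally the planted receptor/ligand genes) are overexpressed.
Every stage of the analysis pipeline can be run against these inputs and
checked against the returned ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import DEResult, PairedExpression
from .network_model import (
    GeneSet,
    Interaction,
    InteractionNetwork,
    write_gmt,
    write_network,
)
from .overconnectivity import RankedList

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_network",
    "generate_expression",
    "recovery_report",
    "classification_scenario",
    "write_simulation",
]

_CLASS_DEFAULTS = {
    "ligand": 0.10,
    "receptor": 0.15,
    "kinase": 0.20,
    "transcription_factor": 0.15,
    "generic": 0.40,
}

# class-respecting background edge rules: source class -> allowed target
# classes with (mechanism) implied by the pair
_EDGE_RULES = {
    "ligand": ("receptor",),
    "receptor": ("kinase", "transcription_factor"),
    "kinase": ("kinase", "transcription_factor"),
    "transcription_factor": ("generic",),
}


@dataclasses.dataclass
class SimulationConfig:
    n_nodes: int = 200
    class_proportions: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(_CLASS_DEFAULTS)
    )
    edge_factor: float = 2.0  # background edges ~= edge_factor * n_nodes
    pa_strength: float = 1.0  # preferential-attachment weight on in-degree
    tf_tr_rate: float = 3.0  # mean background TR out-degree per TF
    inhibition_prob: float = 0.2
    n_planted_receptors: int = 2
    n_planted_tfs: int = 2
    n_planted_kinases: int = 2
    n_planted_targets: int = 20
    n_planted_ligands: int = 2
    n_pairs: int = 28
    target_log2fc_mean: float = 2.0
    target_log2fc_sd: float = 0.3
    noise_sd: float = 0.5
    base_log2_mean: float = 6.0
    base_log2_sd: float = 1.0
    pair_effect_sd: float = 0.5
    plant_receptor_expression: bool = False
    plant_ligand_expression: bool = False
    # keep background edges off the planted cascade nodes, so decoy
    # regulators are true decoys (used by isolation-style benchmarks)
    isolate_cascade: bool = False
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        counts = self._class_counts()
        needed = {
            "ligand": self.n_planted_ligands,
            "receptor": self.n_planted_receptors,
            "kinase": self.n_planted_kinases,
            "transcription_factor": self.n_planted_tfs,
            "generic": self.n_planted_targets,
        }
        for cls, need in needed.items():
            if counts.get(cls, 0) < need:
                raise ValueError(
                    f"cannot plant {need} {cls} nodes; only {counts.get(cls, 0)} exist"
                )
        if self.n_pairs < 2:
            raise ValueError("need at least 2 sample pairs")
        return self

    def _class_counts(self) -> dict[str, int]:
        counts = {
            cls: int(round(frac * self.n_nodes))
            for cls, frac in self.class_proportions.items()
        }
        drift = self.n_nodes - sum(counts.values())
        counts["generic"] = counts.get("generic", 0) + drift
        return counts


@dataclasses.dataclass
class GroundTruth:
    planted_ligands: set[str]
    planted_receptors: set[str]
    planted_kinases: set[str]
    planted_tfs: set[str]
    planted_targets: set[str]
    planted_fold_changes: dict[str, float]  # gene -> true linear FC
    cascade_edges: set[Interaction]
    genes: list[str]  # full gene universe (all network nodes)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_ligands": sorted(self.planted_ligands),
            "planted_receptors": sorted(self.planted_receptors),
            "planted_kinases": sorted(self.planted_kinases),
            "planted_tfs": sorted(self.planted_tfs),
            "planted_targets": sorted(self.planted_targets),
            "planted_fold_changes": dict(sorted(self.planted_fold_changes.items())),
            "cascade_edges": [
                [e.source, e.target, e.effect, e.mechanism]
                for e in sorted(
                    self.cascade_edges, key=lambda e: (e.source, e.target)
                )
            ],
            "genes": self.genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _node_names(counts: dict[str, int]) -> dict[str, list[str]]:
    prefix = {
        "ligand": "LIG",
        "receptor": "REC",
        "kinase": "KIN",
        "transcription_factor": "TF",
        "generic": "GEN",
    }
    return {
        cls: [f"{prefix[cls]}{i:03d}" for i in range(counts.get(cls, 0))]
        for cls in prefix
    }


def generate_network(cfg: SimulationConfig) -> tuple[InteractionNetwork, GroundTruth]:
    """Sample a background network and wire the planted cascade into it.

    Background edges follow the class rules (ligand->receptor,
    receptor/kinase->kinase/TF, TF->generic via transcription_regulation)
    with targets drawn preferentially by in-degree.  The cascade is fully
    activating so that parity-even activation paths from every planted
    receptor to every planted target exist by construction.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    counts = cfg._class_counts()
    names = _node_names(counts)

    net = InteractionNetwork()
    for cls, nodes in names.items():
        for v in nodes:
            net.set_node_class(v, cls)

    planted = GroundTruth(
        planted_ligands=set(names["ligand"][: cfg.n_planted_ligands]),
        planted_receptors=set(names["receptor"][: cfg.n_planted_receptors]),
        planted_kinases=set(names["kinase"][: cfg.n_planted_kinases]),
        planted_tfs=set(names["transcription_factor"][: cfg.n_planted_tfs]),
        planted_targets=set(names["generic"][: cfg.n_planted_targets]),
        planted_fold_changes={},
        cascade_edges=set(),
        genes=sorted(net.nodes),
    )

    protected: set[str] = set()
    if cfg.isolate_cascade:
        protected = (
            planted.planted_receptors
            | planted.planted_kinases
            | planted.planted_tfs
            | planted.planted_targets
        )

    # background edges first (preferential attachment must not see the
    # planted cascade, or the planted targets would hog the TR edges and
    # blunt the path statistic's contrast)
    n_background = int(round(cfg.edge_factor * cfg.n_nodes))
    sources = [v for cls in _EDGE_RULES for v in names[cls]]
    existing: set[Interaction] = set()
    in_degree: dict[str, int] = {v: 0 for v in net.nodes}

    attempts = 0
    added = 0
    max_attempts = 50 * n_background
    while added < n_background and attempts < max_attempts:
        attempts += 1
        src = sources[int(rng.integers(len(sources)))]
        if src in protected:
            continue
        cls = net.node_class[src]
        tgt_cls = _EDGE_RULES[cls][int(rng.integers(len(_EDGE_RULES[cls])))]
        pool = names[tgt_cls]
        weights = np.array(
            [1.0 + cfg.pa_strength * in_degree[v] for v in pool], dtype=float
        )
        weights /= weights.sum()
        tgt = pool[int(rng.choice(len(pool), p=weights))]
        if tgt == src or tgt in protected:
            continue
        mechanism = (
            "transcription_regulation" if cls == "transcription_factor" else "other"
        )
        effect = "inhibition" if rng.random() < cfg.inhibition_prob else "activation"
        edge = Interaction(src, tgt, effect, mechanism)
        if edge in existing:
            continue
        net.add_interaction(edge)
        existing.add(edge)
        in_degree[tgt] += 1
        added += 1

    # background transcriptional programs: each TF regulates a Poisson
    # number of generic targets, so target-bound paths are not dominated
    # by the planted TFs' fan-out
    generics = names["generic"]
    for tf in names["transcription_factor"]:
        if tf in protected:
            continue
        fanout = int(rng.poisson(cfg.tf_tr_rate))
        for i in rng.choice(len(generics), size=min(fanout, len(generics)), replace=False):
            tgt = generics[int(i)]
            effect = (
                "inhibition" if rng.random() < cfg.inhibition_prob else "activation"
            )
            edge = Interaction(tf, tgt, effect, "transcription_regulation")
            if edge in existing or tgt == tf or tgt in protected:
                continue
            net.add_interaction(edge)
            existing.add(edge)
            in_degree[tgt] += 1

    def plant(src: str, dst: str, mechanism: str) -> None:
        e = Interaction(src, dst, "activation", mechanism)
        if e not in existing:
            net.add_interaction(e)
            existing.add(e)
        planted.cascade_edges.add(e)

    for lig in sorted(planted.planted_ligands):
        for rec in sorted(planted.planted_receptors):
            plant(lig, rec, "other")
    for rec in sorted(planted.planted_receptors):
        for kin in sorted(planted.planted_kinases):
            plant(rec, kin, "other")
        # direct receptor->TF signalling keeps the planted routes at the
        # minimal hop count, so background shortcuts cannot preempt them
        for tf in sorted(planted.planted_tfs):
            plant(rec, tf, "other")
    for kin in sorted(planted.planted_kinases):
        for tf in sorted(planted.planted_tfs):
            plant(kin, tf, "other")
    for tf in sorted(planted.planted_tfs):
        for tgt in sorted(planted.planted_targets):
            plant(tf, tgt, "transcription_regulation")

    log2fc = rng.normal(
        cfg.target_log2fc_mean, cfg.target_log2fc_sd, size=len(planted.planted_targets)
    )
    for gene, l2fc in zip(sorted(planted.planted_targets), log2fc):
        planted.planted_fold_changes[gene] = float(2.0 ** max(l2fc, 0.0))
    if cfg.plant_receptor_expression:
        for gene in sorted(planted.planted_receptors):
            planted.planted_fold_changes[gene] = float(2.0**cfg.target_log2fc_mean)
    if cfg.plant_ligand_expression:
        for gene in sorted(planted.planted_ligands):
            planted.planted_fold_changes[gene] = float(2.0**cfg.target_log2fc_mean)

    return net, planted


def generate_expression(truth: GroundTruth, cfg: SimulationConfig) -> PairedExpression:
    """Paired log-normal expression with planted overexpression.

    The pair-level random effect is a patient baseline added to both
    samples of a pair, so per-pair ratios are unaffected by it; with
    ``noise_sd == 0`` a planted gene's per-pair ratio equals its planted
    fold change exactly.
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    genes = list(truth.genes)
    n_genes, n_pairs = len(genes), cfg.n_pairs

    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=(n_genes, n_pairs))
    pair_effect = rng.normal(0.0, cfg.pair_effect_sd, size=n_pairs)
    noise = (
        rng.normal(0.0, cfg.noise_sd, size=(n_genes, n_pairs))
        if cfg.noise_sd > 0
        else np.zeros((n_genes, n_pairs))
    )
    l2fc = np.array(
        [np.log2(truth.planted_fold_changes.get(g, 1.0)) for g in genes]
    )[:, None]

    non = 2.0 ** (base + pair_effect[None, :])
    les = 2.0 ** (base + pair_effect[None, :] + l2fc + noise)

    les_ids = [f"L{i + 1:02d}" for i in range(n_pairs)]
    non_ids = [f"N{i + 1:02d}" for i in range(n_pairs)]
    values = pd.DataFrame(
        np.hstack([les, non]),
        index=pd.Index(genes, name="gene"),
        columns=les_ids + non_ids,
    )
    return PairedExpression(values=values, pair_map=list(zip(les_ids, non_ids)))


def recovery_report(
    truth: GroundTruth,
    tf_ranking: RankedList | None = None,
    receptor_ranking: RankedList | None = None,
    de_result: DEResult | None = None,
    classifications: list | None = None,
    expected_categories: dict[str, str] | None = None,
) -> dict:
    """Ground-truth recovery metrics for whichever outputs are supplied."""
    report: dict = {}
    if tf_ranking is not None:
        report["tf_ranks"] = {
            tf: (tf_ranking.rank_of(tf) if tf in tf_ranking.nodes else None)
            for tf in sorted(truth.planted_tfs)
        }
    if receptor_ranking is not None:
        report["receptor_ranks"] = {
            r: (receptor_ranking.rank_of(r) if r in receptor_ranking.nodes else None)
            for r in sorted(truth.planted_receptors)
        }
    if de_result is not None:
        called = set(de_result.passing_genes())
        planted = truth.planted_targets
        tp = len(called & planted)
        report["de_precision"] = tp / len(called) if called else 0.0
        report["de_recall"] = tp / len(planted) if planted else 0.0
        report["de_n_called"] = len(called)
    if classifications is not None and expected_categories is not None:
        matches = {}
        by_receptor = {c.receptor: c.category for c in classifications}
        for rec, want in expected_categories.items():
            matches[rec] = by_receptor.get(rec, "rejected") == want
        report["classification_matches"] = matches
    return report


def classification_scenario(
    seed: int = 3,
    n_receptor_only: int = 2,
    n_ligand_only: int = 3,
    n_both: int = 1,
    n_decoy_receptors: int = 8,
    noise_sd: float = 0.2,
    n_pairs: int = 28,
) -> tuple[InteractionNetwork, GroundTruth, PairedExpression, dict[str, str]]:
    """Deterministic fixture for the receptor-classification stage.

    Builds a hand-wired network with one ligand per receptor, a shared
    signalling kinase per branch, planted TFs regulating planted targets,
    and a decoy branch (decoy receptors -> decoy TFs -> decoy targets) so
    that the path universe is larger than the target-bound paths.  Planted
    overexpression follows the requested category of each receptor; decoy
    receptors get no overexpression and must end up rejected.

    Returns the network, ground truth, paired expression and the expected
    category per planted receptor.
    """
    n_planted = n_receptor_only + n_ligand_only + n_both
    net = InteractionNetwork()

    receptors = [f"REC{i:03d}" for i in range(n_planted)]
    ligands = [f"LIG{i:03d}" for i in range(n_planted)]
    decoy_receptors = [f"DREC{i:03d}" for i in range(n_decoy_receptors)]
    decoy_ligands = [f"DLIG{i:03d}" for i in range(n_decoy_receptors)]
    tfs = ["TF000", "TF001"]
    decoy_tfs = ["DTF000", "DTF001"]
    targets = [f"GEN{i:03d}" for i in range(10)]
    decoy_targets = [f"DGEN{i:03d}" for i in range(10)]

    for v in ligands + decoy_ligands:
        net.set_node_class(v, "ligand")
    for v in receptors + decoy_receptors:
        net.set_node_class(v, "receptor")
    net.set_node_class("KIN000", "kinase")
    net.set_node_class("DKIN000", "kinase")
    for v in tfs + decoy_tfs:
        net.set_node_class(v, "transcription_factor")
    for v in targets + decoy_targets:
        net.set_node_class(v, "generic")

    cascade: set[Interaction] = set()

    def wire(src: str, dst: str, mech: str = "other") -> None:
        e = Interaction(src, dst, "activation", mech)
        net.add_interaction(e)
        cascade.add(e)

    for lig, rec in zip(ligands, receptors):
        wire(lig, rec)
        wire(rec, "KIN000")
    for tf in tfs:
        wire("KIN000", tf)
        for t in targets:
            wire(tf, t, "transcription_regulation")
    for lig, rec in zip(decoy_ligands, decoy_receptors):
        net.add_interaction(Interaction(lig, rec, "activation", "other"))
        net.add_interaction(Interaction(rec, "DKIN000", "activation", "other"))
    for tf in decoy_tfs:
        net.add_interaction(Interaction("DKIN000", tf, "activation", "other"))
        for t in decoy_targets:
            net.add_interaction(
                Interaction(tf, t, "activation", "transcription_regulation")
            )

    expected: dict[str, str] = {}
    fold_changes: dict[str, float] = {t: 4.0 for t in targets}
    idx = 0
    for _ in range(n_receptor_only):
        fold_changes[receptors[idx]] = 4.0
        expected[receptors[idx]] = "receptor_only"
        idx += 1
    for _ in range(n_ligand_only):
        fold_changes[ligands[idx]] = 4.0
        expected[receptors[idx]] = "ligand_only"
        idx += 1
    for _ in range(n_both):
        fold_changes[receptors[idx]] = 4.0
        fold_changes[ligands[idx]] = 4.0
        expected[receptors[idx]] = "both"
        idx += 1

    truth = GroundTruth(
        planted_ligands=set(ligands),
        planted_receptors=set(receptors),
        planted_kinases={"KIN000"},
        planted_tfs=set(tfs),
        planted_targets=set(targets),
        planted_fold_changes=fold_changes,
        cascade_edges=cascade,
        genes=sorted(net.nodes),
    )
    cfg = SimulationConfig(
        n_nodes=len(net.nodes),
        n_pairs=n_pairs,
        noise_sd=noise_sd,
        seed=seed,
    )
    expression = generate_expression(truth, cfg)
    return net, truth, expression, expected


def write_simulation(
    cfg: SimulationConfig, out_dir: str | Path
) -> tuple[InteractionNetwork, GroundTruth, PairedExpression]:
    """Write a full simulated input bundle (network, sets, expression, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net, truth = generate_network(cfg)
    expression = generate_expression(truth, cfg)

    write_network(net, out / "network_edges.tsv", out / "network_nodes.tsv")
    write_gmt(
        [GeneSet("planted_targets", truth.planted_targets)],
        out / "planted_targets.gmt",
    )
    # emulated small proteomics panel: a slice of the planted targets
    panel = sorted(truth.planted_targets)[: min(10, len(truth.planted_targets))]
    write_gmt([GeneSet("protein_panel", panel)], out / "protein_panel.gmt")

    matrix = expression.values.copy()
    matrix.insert(0, "gene", matrix.index)
    matrix.to_csv(out / "expression.tsv", sep="\t", index=False, float_format="%.6g")
    with (out / "pairs.tsv").open("w", encoding="utf-8") as fh:
        fh.write("lesional\tnonlesional\n")
        for les, non in expression.pair_map:
            fh.write(f"{les}\t{non}\n")
    truth.to_json(out / "ground_truth.json")
    return net, truth, expression
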