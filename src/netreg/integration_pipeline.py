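"""End-to-end orchestration: common TFs, receptor screening, reporting.

Wires the stages together: paired differential expression produces the
transcriptomics list of interest; both topology statistics rank TF
candidates per data type and are combined by rank aggregation; the
aggregated lists are intersected into the common-TF set and topped up with
seeds of the best-enriched TF expansion networks; receptors ranked by the
path statistic are then filtered by overexpression of their gene or a
ligand and by pathway co-membership with a common TF, and classified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from .diffexpr import DEResult, median_normalize, paired_de_test, de_gene_set, read_expression
from .hidden_nodes import (
    ActivationPathIndex,
    build_path_index,
    rank_hidden_nodes,
    transcription_regulated_targets,
)
from .network_model import (
    GeneSet,
    InteractionNetwork,
    read_gmt,
    read_network,
    write_tsv_report,
)
from .overconnectivity import RankedList, rank_overconnected
from .rank_aggregation import AggregationProblem, GAConfig, aggregate
from .subnetworks import (
    build_receptor_network,
    expand_tf_network,
    rank_networks,
    score_networks,
    select_direct_tfs,
    select_receptors_by_ligand,
    write_summary,
)

__all__ = [
    "CommonRegulatorResult",
    "ReceptorClassification",
    "PipelineConfig",
    "find_common_tfs",
    "pathway_linked",
    "classify_receptors",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CommonRegulatorResult:
    """Per-data-type TF rankings, their aggregates, and the intersection."""

    overconnectivity: dict[str, RankedList]
    hidden: dict[str, RankedList]
    aggregated: dict[str, list[str]]
    common_tfs: list[str]
    supplemental_tfs: list[str]

    @property
    def all_tfs(self) -> list[str]:
        return self.common_tfs + [
            t for t in self.supplemental_tfs if t not in self.common_tfs
        ]


@dataclasses.dataclass
class ReceptorClassification:
    receptor: str
    hidden_p: float
    receptor_overexpressed: bool
    ligand_overexpressed: bool
    pathway_linked: bool
    category: str  # receptor_only | ligand_only | both | rejected

    @property
    def retained(self) -> bool:
        return self.category != "rejected"


def find_common_tfs(
    net: InteractionNetwork,
    set_tx: GeneSet,
    set_prot: GeneSet,
    k: int = 20,
    parity: str = "even",
    max_len: int = 6,
    ga: GAConfig | None = None,
    n_supplemental: int = 5,
    expansion_size: int = 50,
    index: ActivationPathIndex | None = None,
) -> CommonRegulatorResult:
    """Common-TF identification across two gene sets of interest.

    For each data type, TF candidates are ranked by overconnectivity and by
    the hidden-node path statistic, truncated to ``k`` and aggregated; the
    two aggregated lists are intersected.  Seeds of the ``n_supplemental``
    best-enriched TF expansion networks per data type that are not already
    present are appended as supplemental TFs.
    """
    for s in (set_tx, set_prot):
        if not len(s):
            raise ValueError(f"gene set {s.name!r} is empty")
    tf_candidates = net.nodes_of_class("transcription_factor")
    if not tf_candidates:
        raise ValueError("network has no transcription_factor nodes")
    ga = ga or GAConfig()

    if index is None:
        index = build_path_index(
            net, transcription_regulated_targets(net), parity=parity, max_len=max_len
        )

    datasets = {"transcriptomics": set_tx, "proteomics": set_prot}
    over: dict[str, RankedList] = {}
    hidden: dict[str, RankedList] = {}
    aggregated: dict[str, list[str]] = {}
    for name, geneset in datasets.items():
        over[name] = rank_overconnected(net, geneset, "transcription_factor")
        hidden[name] = rank_hidden_nodes(
            net, geneset, "transcription_factor", parity=parity,
            max_len=max_len, index=index,
        )
        k_eff = min(k, len(over[name]), len(hidden[name]))
        problem = AggregationProblem(
            input_lists=[over[name].top(k_eff), hidden[name].top(k_eff)],
            k=k_eff,
            ga=ga,
        )
        aggregated[name] = aggregate(problem)

    common = [t for t in aggregated["transcriptomics"] if t in set(aggregated["proteomics"])]
    if not common:
        logger.warning("aggregated TF lists are disjoint across data types")

    supplemental: list[str] = []
    present = set(common)
    for name, geneset in datasets.items():
        subnets = [
            expand_tf_network(net, tf, geneset, size=expansion_size)
            for tf in sorted(tf_candidates)
        ]
        ranked = rank_networks(score_networks(subnets, geneset, net))
        for sn in ranked[:n_supplemental]:
            if sn.seed not in present:
                supplemental.append(sn.seed)
                present.add(sn.seed)

    return CommonRegulatorResult(
        overconnectivity=over,
        hidden=hidden,
        aggregated=aggregated,
        common_tfs=common,
        supplemental_tfs=supplemental,
    )


def pathway_linked(
    net: InteractionNetwork,
    receptor: str,
    common_tfs: set[str] | list[str],
    max_len: int = 6,
) -> bool:
    """True iff a directed path of <= max_len hops reaches any common TF."""
    if receptor not in net.nodes:
        raise KeyError(f"unknown node {receptor!r}")
    goals = set(common_tfs)
    if receptor in goals:
        return True
    frontier = {receptor}
    seen = {receptor}
    for _ in range(max_len):
        nxt: set[str] = set()
        for v in frontier:
            nxt |= net.successors(v)
        nxt -= seen
        if nxt & goals:
            return True
        seen |= nxt
        frontier = nxt
        if not frontier:
            break
    return False


def classify_receptors(
    net: InteractionNetwork,
    hidden_ranking: RankedList,
    de: DEResult,
    common_tfs: set[str] | list[str],
    p_cut: float = 0.05,
    fc_cut: float = 2.5,
    max_len: int = 6,
) -> list[ReceptorClassification]:
    """Screen path-significant receptors by expression and pathway linkage.

    A receptor is retained when its path p-value is below ``p_cut``, its
    own gene or at least one ligand with an edge into it is overexpressed
    (fold change > ``fc_cut`` and passing the DE q threshold), and it can
    reach a common TF within ``max_len`` hops.  Everything else is
    reported with category 'rejected'.
    """
    results: list[ReceptorClassification] = []
    goals = set(common_tfs)
    for entry in hidden_ranking:
        receptor = entry.node
        rec_over = de.gene_passes(receptor, fc_cut=fc_cut)
        ligands = {
            e.source
            for e in net.in_edges(receptor)
            if net.node_class.get(e.source) == "ligand"
        }
        lig_over = any(de.gene_passes(lig, fc_cut=fc_cut) for lig in sorted(ligands))
        linked = pathway_linked(net, receptor, goals, max_len=max_len)

        if entry.p_value < p_cut and (rec_over or lig_over) and linked:
            if rec_over and lig_over:
                category = "both"
            elif rec_over:
                category = "receptor_only"
            else:
                category = "ligand_only"
        else:
            category = "rejected"
            if entry.p_value < p_cut and (rec_over or lig_over) and not linked:
                logger.warning(
                    "receptor %s rejected solely by the pathway co-membership "
                    "criterion (max_len=%d)", receptor, max_len,
                )
        results.append(
            ReceptorClassification(
                receptor=receptor,
                hidden_p=entry.p_value,
                receptor_overexpressed=rec_over,
                ligand_overexpressed=lig_over,
                pathway_linked=linked,
                category=category,
            )
        )
    if not any(c.retained for c in results):
        logger.warning("no receptor passed the classification filters")
    return results


# -- full pipeline -------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    network_edges: str
    network_nodes: str
    expression: str
    pairs: str
    protein_sets: str  # GMT with the proteomics list of interest
    out_dir: str = "results"
    fc_threshold: float = 2.5
    q_threshold: float = 0.01
    p_cut: float = 0.05
    k: int = 20
    expansion_size: int = 50
    parity: str = "even"
    max_len: int = 6
    seed: int = 0
    n_supplemental: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write TSV reports plus a run log.

    Returns a dict of in-memory stage results.  Identical config (including
    seed) reproduces byte-identical report files; wall-clock stage timings
    go to the run log only.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    results: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                logger.info("stage %s done (%.2fs)", name, timings[name])

        return _Timer()

    with stage("load"):
        net = read_network(config.network_edges, config.network_nodes)
        expression = read_expression(config.expression, config.pairs)
        protein_sets = read_gmt(config.protein_sets)
        if not protein_sets:
            raise ValueError(f"{config.protein_sets}: no gene sets found")
        set_prot = protein_sets[0]

    with stage("diffexpr"):
        normalized = median_normalize(expression)
        de = paired_de_test(
            normalized,
            fc_threshold=config.fc_threshold,
            q_threshold=config.q_threshold,
        )
        set_tx = de_gene_set(de)
        if not len(set_tx):
            raise ValueError("no differentially expressed genes; cannot continue")
        de.write_tsv(out / "de_table.tsv")
        results["de"] = de

    with stage("path_index"):
        index = build_path_index(
            net,
            transcription_regulated_targets(net),
            parity=config.parity,
            max_len=config.max_len,
        )

    with stage("common_tfs"):
        common = find_common_tfs(
            net,
            set_tx,
            set_prot,
            k=config.k,
            parity=config.parity,
            max_len=config.max_len,
            ga=GAConfig(seed=config.seed),
            n_supplemental=config.n_supplemental,
            expansion_size=config.expansion_size,
            index=index,
        )
        results["common"] = common
        for name in ("transcriptomics", "proteomics"):
            write_tsv_report(
                common.overconnectivity[name].to_rows(net.node_class),
                out / f"overconnectivity_tfs_{name}.tsv",
            )
            write_tsv_report(
                common.hidden[name].to_rows(net.node_class),
                out / f"hidden_tfs_{name}.tsv",
            )
            write_tsv_report(
                [
                    {"rank": i, "node": v}
                    for i, v in enumerate(common.aggregated[name], start=1)
                ],
                out / f"aggregated_tfs_{name}.tsv",
                columns=["rank", "node"],
            )
        write_tsv_report(
            [{"node": t, "origin": "common"} for t in common.common_tfs]
            + [{"node": t, "origin": "subnetwork"} for t in common.supplemental_tfs],
            out / "common_tfs.tsv",
            columns=["node", "origin"],
        )

    with stage("receptor_networks"):
        tfs = select_direct_tfs(net, set_tx)
        receptors = select_receptors_by_ligand(net, set_tx)
        subnets = []
        for rec in sorted(receptors):
            sn = build_receptor_network(net, rec, tfs, set_tx, max_len=config.max_len)
            if sn is not None:
                subnets.append(sn)
        ranked = rank_networks(score_networks(subnets, set_tx, net))
        write_summary(ranked, out / "receptor_networks.tsv")
        results["receptor_networks"] = ranked

    with stage("receptor_classification"):
        receptor_ranking = rank_hidden_nodes(
            net, set_tx, "receptor", parity=config.parity,
            max_len=config.max_len, index=index,
        )
        classifications = classify_receptors(
            net,
            receptor_ranking,
            de,
            common.all_tfs,
            p_cut=config.p_cut,
            fc_cut=config.fc_threshold,
            max_len=config.max_len,
        )
        write_tsv_report(
            [
                {
                    "receptor": c.receptor,
                    "hidden_p": c.hidden_p,
                    "receptor_overexpressed": c.receptor_overexpressed,
                    "ligand_overexpressed": c.ligand_overexpressed,
                    "pathway_linked": c.pathway_linked,
                    "category": c.category,
                }
                for c in classifications
            ],
            out / "receptor_classification.tsv",
            columns=[
                "receptor",
                "hidden_p",
                "receptor_overexpressed",
                "ligand_overexpressed",
                "pathway_linked",
                "category",
            ],
        )
        results["classifications"] = classifications

    log = {
        "config": dataclasses.asdict(config),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_interactions": net.n_interactions,
        "n_nodes": len(net.nodes),
        "n_de_genes": len(set_tx),
        "n_indexed_paths": index.n_paths,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1), encoding="utf-8")
    results["log"] = log
    return results


def report_checksums(out_dir: str | Path, exclude: tuple[str, ...] = ("run_log.json",)) -> dict[str, str]:
    """SHA-256 of every report file, for determinism checks (run log excluded:
    it contains wall-clock timings)."""
    out = Path(out_dir)
    sums = {}
    for path in sorted(out.glob("*.tsv")):
        if path.name in exclude:
            continue
        sums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return sums
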