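"""End-to-end orchestration: simulate -> quantify -> targetome -> network ->
enrich -> cluster -> echo-derive, driven by one YAML config.

Stages communicate via files under ``outdir`` and a manifest records
parameters, seeds, and per-file checksums/row counts; a rerun with the same
config reproduces byte-identical deterministic outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cardiomir import __version__
from cardiomir import io as cio
from cardiomir.cardiometrics import derive_echo_table, group_summary
from cardiomir.clustering import average_linkage_tree, fc_profiles, pearson_matrix
from cardiomir.enrichment import DEFAULT_FDR_GATE, DEFAULT_P_GATE, enrich
from cardiomir.expression import (
    DE_DOWN,
    DEFAULT_FC_CUTOFF,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_RPKM_THRESHOLD,
    GeneExpressionMatrix,
    quantify,
)
from cardiomir.network import (
    DEFAULT_SCORE_CUTOFF,
    CompartmentCatalogue,
    classify_nodes,
    compartmentalize,
    edge_table,
    extract_subnetwork,
    filter_edges,
    merge_multinet,
    node_table,
    read_string_edges,
    write_graphml,
)
from cardiomir.simulate import SimulationConfig, write_inputs
from cardiomir.targetome import Targetome, build_targetome, venn_counts

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every stage parameter with its study default, plus paths and seed."""

    outdir: str = "cardiomir_run"
    seed: int = 0
    simulate_inputs: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # provided-input paths (used when simulate_inputs is false)
    counts: str | None = None
    predictions: str | None = None
    homology: str | None = None
    ppi_edges: str | None = None
    compartments: str | None = None
    echo: str | None = None
    control_label: str = "cel-miR-67"
    mirnas: tuple[str, ...] = ("miR-106b", "miR-93", "miR-25")
    rpkm_threshold: float = DEFAULT_RPKM_THRESHOLD
    fc_cutoff: float = DEFAULT_FC_CUTOFF
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    score_cutoff: int = DEFAULT_SCORE_CUTOFF
    p_gate: float = DEFAULT_P_GATE
    fdr_gate: float = DEFAULT_FDR_GATE
    genes_of_interest: tuple[str, ...] = ()
    drop_isolated: bool = False
    echo_group_col: str = "group"

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        self.mirnas = tuple(self.mirnas)
        self.genes_of_interest = tuple(self.genes_of_interest)
        # the simulation inherits the pipeline seed and labels unless set apart
        self.simulation.seed = self.simulation.seed or self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["mirnas"] = list(self.mirnas)
        d["genes_of_interest"] = list(self.genes_of_interest)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
        "files": {},
    }

    def record(stage: str, name: str, path) -> None:
        manifest["files"][name] = cio.file_record(path)
        manifest["stages"].setdefault(stage, []).append(name)

    # --- stage: inputs ------------------------------------------------------
    stage = "simulate"
    try:
        if config.simulate_inputs:
            inputs = write_inputs(config.simulation, outdir / "inputs")
            for name, path in inputs.items():
                record(stage, name, path)
        else:
            inputs = {
                "counts": config.counts,
                "predictions": config.predictions,
                "homology": config.homology,
                "ppi_edges": config.ppi_edges,
                "compartments": config.compartments,
                "echo": config.echo,
            }
            missing = [k for k, v in inputs.items() if k != "echo" and not v]
            if missing:
                raise FileNotFoundError(f"missing input paths: {missing}")
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: quantify ----------------------------------------------------
    stage = "quantify"
    try:
        matrix = GeneExpressionMatrix.from_tsv(inputs["counts"], control=config.control_label)
        de = quantify(
            matrix,
            rpkm_threshold=config.rpkm_threshold,
            fc_cutoff=config.fc_cutoff,
            pseudocount=config.pseudocount,
        )
        de_path = outdir / "fold_changes.tsv"
        de_out = de.copy()
        de_out["log2fc"] = de_out["log2fc"].map(lambda v: f"{v:.6g}")
        de_out["rpkm_control"] = de_out["rpkm_control"].map(lambda v: f"{v:.6g}")
        de_out["rpkm_treatment"] = de_out["rpkm_treatment"].map(lambda v: f"{v:.6g}")
        cio.write_tsv(de_out, de_path)
        record(stage, "fold_changes", de_path)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: targetome ---------------------------------------------------
    stage = "targetome"
    try:
        predictions = cio.read_tsv(inputs["predictions"])
        homology = cio.read_tsv(inputs["homology"])
        targetomes: dict[str, Targetome] = {}
        for mirna in config.mirnas:
            t = build_targetome(predictions, homology, de, mirna)
            targetomes[mirna] = t
            path = outdir / f"targetome_{mirna.replace('/', '_')}.tsv"
            cio.write_gene_list(t.downregulated_targets, path)
            record(stage, f"targetome_{mirna}", path)
        venn = venn_counts({m: targetomes[m].downregulated_targets for m in config.mirnas})
        venn_path = outdir / "venn.json"
        cio.write_json(venn, venn_path)
        record(stage, "venn", venn_path)
        sizes_path = outdir / "targetome_sizes.json"
        cio.write_json(
            {
                m: {
                    "predicted_rat_genes": len(targetomes[m].predicted_rat_genes),
                    "downregulated_targets": len(targetomes[m].downregulated_targets),
                }
                for m in config.mirnas
            },
            sizes_path,
        )
        record(stage, "targetome_sizes", sizes_path)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: network -----------------------------------------------------
    stage = "network"
    try:
        edges = read_string_edges(inputs["ppi_edges"])
        rat_universe = set(matrix.counts.index)
        graph = filter_edges(edges, score_cutoff=config.score_cutoff, allowed_nodes=rat_universe)
        subnets = {}
        for mirna in config.mirnas:
            sub = de[de["mirna"] == mirna]
            de_genes = set(sub.loc[sub["de_status"].isin(["up", "down"]), "gene_id"])
            subnets[mirna] = extract_subnetwork(graph, de_genes, config.genes_of_interest)
        multinet = merge_multinet(subnets)
        classify_nodes(multinet, de, targetomes)
        catalogue = CompartmentCatalogue.from_gene_sets(cio.read_gmt(inputs["compartments"]))
        compartmentalize(multinet, catalogue)
        gml = outdir / "multinet.graphml"
        write_graphml(multinet, gml, drop_isolated=config.drop_isolated)
        record(stage, "multinet_graphml", gml)
        nodes_path = outdir / "multinet_nodes.tsv"
        cio.write_tsv(node_table(multinet), nodes_path)
        record(stage, "multinet_nodes", nodes_path)
        edges_path = outdir / "multinet_edges.tsv"
        cio.write_tsv(edge_table(multinet), edges_path)
        record(stage, "multinet_edges", edges_path)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: enrich ------------------------------------------------------
    stage = "enrich"
    try:
        background = set(
            de.loc[(de["mirna"] == config.mirnas[0]) & de["expressed"], "gene_id"]
        )
        frames = []
        for mirna in config.mirnas:
            sub = de[de["mirna"] == mirna]
            query = set(sub.loc[sub["de_status"] == DE_DOWN, "gene_id"]) & background
            result = enrich(
                query,
                catalogue.compartments,
                background,
                p_gate=config.p_gate,
                fdr_gate=config.fdr_gate,
            )
            result.insert(0, "mirna", mirna)
            frames.append(result)
        import pandas as pd

        enr = pd.concat(frames, ignore_index=True)
        enr["p_raw"] = enr["p_raw"].map(lambda v: f"{v:.6g}")
        enr["p_adjusted"] = enr["p_adjusted"].map(lambda v: f"{v:.6g}")
        enr_path = outdir / "enrichment.tsv"
        cio.write_tsv(enr, enr_path)
        record(stage, "enrichment", enr_path)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: cluster -----------------------------------------------------
    stage = "cluster"
    try:
        profiles = fc_profiles(de)
        corr = pearson_matrix(profiles)
        corr_path = outdir / "fc_correlation.tsv"
        corr.round(6).to_csv(corr_path, sep="\t", index_label="mirna")
        record(stage, "fc_correlation", corr_path)
        tree = average_linkage_tree(profiles)
        tree_path = outdir / "fc_tree.newick"
        tree_path.write_text(tree.to_newick() + "\n")
        record(stage, "fc_tree", tree_path)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage: echo-derive -------------------------------------------------
    stage = "echo_derive"
    if inputs.get("echo"):
        try:
            import pandas as pd

            echo = pd.read_csv(inputs["echo"])
            derived = derive_echo_table(echo, mode="per-animal", group_col=config.echo_group_col)
            derived = derived.round(6)
            derived_path = outdir / "echo_derived.csv"
            derived.to_csv(derived_path, index=False)
            record(stage, "echo_derived", derived_path)
            summary = group_summary(derived, group_col=config.echo_group_col).round(6)
            summary_path = outdir / "echo_groups.csv"
            summary.to_csv(summary_path, index=False)
            record(stage, "echo_groups", summary_path)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    cio.write_json(manifest, manifest_path)
    log.info("pipeline complete: %d files under %s", len(manifest["files"]), outdir)
    return manifest
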