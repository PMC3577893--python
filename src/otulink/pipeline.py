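"""End-to-end orchestration: simulate/load -> distances -> parsimony ->
boundaries -> optimize -> identify -> coverage, with every intermediate
artifact written to the output directory and a JSON run report.

Configuration is a plain INI file with one section per stage; every value
can be overridden from the command line.  All randomness flows through the
explicit seed recorded in the report.
"""

from __future__ import annotations

import configparser
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .boundaries import BoundaryConfig, mark_within_species, species_partition
from .clustering import ClusterParams, ReferencePartition, f_linkage_cluster, identify, optimize_params
from .coverage import sensitivity_grid
from .distances import p_distance_matrix
from .parsimony import CharMatrix, build_annotated_tree
from .seqio import (
    Msa,
    read_char_matrix,
    read_fasta,
    read_partition_tsv,
    write_char_matrix,
    write_fasta,
    write_newick,
    write_partition_tsv,
)
from .simulate import SimulatedDataset, SynthConfig, simulate_dataset
from .trees import Node

logger = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "distances", "parsimony", "boundaries", "optimize", "identify", "coverage"]


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    # inputs (used when the simulate stage is off)
    alignment: Optional[Path] = None
    char_matrix: Optional[Path] = None
    reference_partition: Optional[Path] = None
    metadata: Optional[Path] = None
    # parameters
    synth: SynthConfig = field(default_factory=SynthConfig)
    F_grid: tuple = (0.0, 0.5, 1.0)
    t_step: float = 0.0005
    metric: str = "modified_rand"
    identify_params: Optional[ClusterParams] = None
    coverage_thresholds: tuple = (0.01, 0.02, 0.03, 0.04, 0.05)
    boundary: BoundaryConfig = field(default_factory=BoundaryConfig)
    bootstrap_replicates: int = 0

    @classmethod
    def from_ini(cls, path, **overrides) -> "RunConfig":
        cp = configparser.ConfigParser()
        cp.read(str(path))
        run = cp["run"] if "run" in cp else {}
        kwargs: dict = {
            "outdir": Path(run.get("outdir", "otulink_out")),
            "seed": int(run.get("seed", 0)),
        }
        if "stages" in run:
            kwargs["stages"] = [s.strip() for s in run["stages"].split(",")]
        inputs = cp["inputs"] if "inputs" in cp else {}
        for key in ("alignment", "char_matrix", "reference_partition", "metadata"):
            if key in inputs:
                kwargs[key] = Path(inputs[key])
        if "simulate" in cp:
            synth_kwargs = {}
            for k, v in cp["simulate"].items():
                fieldtype = SynthConfig.__dataclass_fields__[k].type
                synth_kwargs[k] = float(v) if "float" in str(fieldtype) else int(v)
            kwargs["synth"] = SynthConfig(**synth_kwargs)
        if "optimize" in cp:
            sec = cp["optimize"]
            if "f_grid" in sec:
                kwargs["F_grid"] = tuple(float(x) for x in sec["f_grid"].split(","))
            if "t_step" in sec:
                kwargs["t_step"] = float(sec["t_step"])
            if "metric" in sec:
                kwargs["metric"] = sec["metric"]
        kwargs.update(overrides)
        for key in ("alignment", "char_matrix", "reference_partition", "metadata"):
            p = kwargs.get(key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input {key} does not exist: {p}")
        return cls(**kwargs)


class PipelineError(RuntimeError):
    pass


def _require(artifacts: dict, key: str, stage: str, produced_by: str):
    if key not in artifacts:
        raise PipelineError(f"stage {stage!r} requires the {key!r} artifact produced by the {produced_by!r} stage (or a configured input)")
    return artifacts[key]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the run report (also written
    to ``report.json`` in the output directory)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {}, "python": sys.version.split()[0]}

    # configured external inputs
    if cfg.alignment:
        artifacts["msa"] = Msa(read_fasta(cfg.alignment))
    if cfg.char_matrix:
        artifacts["char_matrix"] = read_char_matrix(cfg.char_matrix)
    if cfg.reference_partition:
        artifacts["reference"] = ReferencePartition(read_partition_tsv(cfg.reference_partition).assignment)
    if cfg.metadata:
        artifacts["meta"] = pd.read_csv(cfg.metadata, sep="\t")

    for stage in cfg.stages:
        logger.info("running stage %s", stage)
        if stage == "simulate":
            data = simulate_dataset(cfg.synth if cfg.synth.seed == cfg.seed else SynthConfig(**{**cfg.synth.__dict__, "seed": cfg.seed}))
            artifacts["msa"] = data.msa
            artifacts["meta"] = data.meta
            artifacts["char_matrix"] = data.char_matrix
            artifacts["truth"] = data.truth
            artifacts["reference"] = data.reference()
            write_fasta(data.msa.records, out / "alignment.fasta")
            data.meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
            write_char_matrix(data.char_matrix, out / "characters.csv")
            write_partition_tsv(data.truth.species, out / "true_species.tsv")
            report["stages"]["simulate"] = {
                "n_sequences": len(data.msa),
                "n_species_true": data.truth.species.n_clusters(),
                "n_labeled": len(data.labeled_ids),
            }
        elif stage == "distances":
            msa = _require(artifacts, "msa", stage, "simulate")
            D = p_distance_matrix(msa)
            artifacts["distances"] = D
            D.to_tsv(out / "distances.tsv")
            report["stages"]["distances"] = {"n": len(D), "max_distance": D.max_offdiag()}
        elif stage == "parsimony":
            matrix = _require(artifacts, "char_matrix", stage, "simulate")
            matrix = _representative_subset(matrix, artifacts)
            tree = build_annotated_tree(matrix, bootstrap_replicates=cfg.bootstrap_replicates, seed=cfg.seed)
            artifacts["tree"] = tree
            write_newick(tree, out / "parsimony_tree.nwk")
            _branch_table(tree).to_csv(out / "branch_table.tsv", sep="\t", index=False)
            report["stages"]["parsimony"] = {"n_taxa": len(tree.leaves())}
        elif stage == "boundaries":
            tree = _require(artifacts, "tree", stage, "parsimony")
            mark_within_species(tree, cfg.boundary)
            species = species_partition(tree, cfg.boundary)
            artifacts["species"] = species
            write_newick(tree, out / "marked_tree.nwk")
            write_partition_tsv(species, out / "species_partition.tsv")
            report["stages"]["boundaries"] = {"n_species": species.n_clusters()}
        elif stage == "optimize":
            D = _require(artifacts, "distances", stage, "distances")
            ref = artifacts.get("reference")
            if ref is None and "species" in artifacts:
                ref = ReferencePartition(artifacts["species"].assignment)
            if ref is None:
                raise PipelineError("stage 'optimize' requires a reference partition (from 'boundaries', simulation labels, or a configured input)")
            result = optimize_params(D, ref, cfg.F_grid, t_step=cfg.t_step, metric=cfg.metric)
            artifacts["optimization"] = result
            result.table.to_csv(out / "optimization.tsv", sep="\t", index=False)
            result.summary().to_csv(out / "optimization_summary.tsv", sep="\t", index=False)
            report["stages"]["optimize"] = {
                row["F"]: {"max_agreement": row["max_agreement"], "t_median": row["t_median"]}
                for row in result.summary().to_dict("records")
            }
        elif stage == "identify":
            D = _require(artifacts, "distances", stage, "distances")
            ref = _require(artifacts, "reference", stage, "simulate")
            params = cfg.identify_params
            if params is None:
                opt = _require(artifacts, "optimization", stage, "optimize")
                mid_F = sorted(cfg.F_grid)[len(cfg.F_grid) // 2]
                params = ClusterParams(t=opt.optimal(mid_F)["t_median"], F=mid_F)
            table = identify(D, ref, params)
            artifacts["identification"] = table
            table.to_csv(out / "identification.tsv", sep="\t", index=False)
            counts = table["status"].value_counts().to_dict()
            report["stages"]["identify"] = {"params": {"t": params.t, "F": params.F}, **counts}
        elif stage == "coverage":
            D = _require(artifacts, "distances", stage, "distances")
            meta = _require(artifacts, "meta", stage, "simulate")
            params_list = [ClusterParams(t=t, F=F) for F in cfg.F_grid for t in cfg.coverage_thresholds]
            if "optimization" in artifacts:
                for F in cfg.F_grid:
                    params_list.append(ClusterParams(t=artifacts["optimization"].optimal(F)["t_median"], F=F))
            grid = sensitivity_grid(D, meta, params_list, sorted(meta["deposition_year"].dropna().unique()))
            artifacts["coverage"] = grid
            grid.to_csv(out / "coverage.tsv", sep="\t", index=False)
            report["stages"]["coverage"] = {"n_param_combinations": len(params_list)}
        else:
            raise PipelineError(f"unknown stage {stage!r}")

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _representative_subset(matrix: CharMatrix, artifacts: dict) -> CharMatrix:
    """One representative taxon per labeled species, to keep the exact
    parsimony search within its enumeration bound (mirrors analysing one
    culture per host)."""
    if matrix.n_taxa <= 12:
        return matrix
    ref = artifacts.get("reference")
    if ref is None:
        raise PipelineError("parsimony on >12 taxa needs a reference partition to pick representatives")
    representatives = sorted(min(b) for b in ref.blocks())
    idx = [matrix.taxa.index(t) for t in representatives]
    return CharMatrix(
        [matrix.taxa[i] for i in idx],
        matrix.data[idx],
        matrix.ctypes,
        matrix.partitions,
        matrix.names,
    )


def _branch_table(tree: Node) -> pd.DataFrame:
    rows = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        row = {
            "branch": node.name or ("{" + ",".join(sorted(node.leaf_names())) + "}"),
            "total_length": node.total_changes,
        }
        for k, v in sorted(node.lengths.items()):
            row[f"length_{k}"] = v
        for k, v in sorted(node.bremer.items()):
            row[f"bremer_{k}"] = v
        row["bremer_total"] = node.total_bremer
        row["bootstrap"] = node.bootstrap
        row["within_species"] = node.within_species
        rows.append(row)
    return pd.DataFrame(rows)
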