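"""End-to-end orchestration with a machine-readable run report.

``run_state_analysis`` takes one or more conformational ensembles through
the full chain — optional replica-convergence diagnostics, concatenation,
interaction persistence, threshold estimation, network construction, hubs,
communication robustness and best pathways — writing TSV/GraphML/JSON
artifacts into an output directory. ``run_conservation_analysis`` takes hub
tables plus cluster alignments to conservation profiles, degree averaging
and the gated regression.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import communication, conservation, convergence, interactions, psn
from .io import Ensemble, MSA, Parameters, concatenate, write_graphml

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    schema_version: str = REPORT_SCHEMA_VERSION
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)   # stage -> summary / paths
    outputs: dict = field(default_factory=dict)  # name -> file path
    warnings: list = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "config": self.config,
            "stages": self.stages,
            "outputs": {k: str(v) for k, v in self.outputs.items()},
            "warnings": self.warnings,
            "started": self.started,
            "finished": self.finished,
            "failed_stage": self.failed_stage,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def validate(self) -> None:
        if self.schema_version != REPORT_SCHEMA_VERSION:
            raise ValueError("unknown report schema version")
        for name, p in self.outputs.items():
            if not Path(p).exists():
                raise ValueError(f"output {name!r} missing at {p}")


def run_state_analysis(ensembles: list[Ensemble], params: Parameters,
                       outdir: str | Path,
                       sources: list[str] | None = None,
                       targets: list[str] | None = None,
                       p_t: float | None = None,
                       run_convergence: bool | None = None) -> RunReport:
    """Ensembles → persistence → p_T → network → hubs → CR/pathways.

    Replicas are concatenated before the network stage; the convergence
    block runs whenever more than one ensemble is supplied (or on demand).
    A fixed ``p_t`` skips the cluster-curve estimation. ``sources`` and
    ``targets`` are node labels (e.g. the calcium-coordinating glutamates
    and the target-interface residues) for the communication stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=params.asdict(), started=time.time())
    stage = "setup"
    try:
        if not ensembles:
            raise ValueError("no ensembles given")
        if run_convergence is None:
            run_convergence = len(ensembles) > 1

        if run_convergence and len(ensembles) > 1:
            stage = "convergence"
            sub, lda = convergence.replica_diagnostics(
                ensembles, dimension=min(params.es_dimension,
                                         3 * len(ensembles[0].topology.ca_indices())))
            conv = {
                "es_fraction": sub.es_fraction,
                "dimension": sub.dimension,
                "rmsip": {f"{a}|{b}": v for (a, b), v in sub.rmsip.items()},
                "cosine_content": {str(k): v
                                   for k, v in sub.cosine_content.items()},
                "lda_all_consistent": lda.all_consistent,
                "lda_pairs": [
                    {"pair": list(p.labels), "misclassified": p.misclassified,
                     "consistent": p.consistent} for p in lda.pairs],
            }
            conv_path = outdir / "convergence.json"
            conv_path.write_text(json.dumps(conv, indent=2, sort_keys=True))
            report.stages["convergence"] = conv
            report.outputs["convergence"] = conv_path

        stage = "concatenation"
        ensemble = (ensembles[0] if len(ensembles) == 1
                    else concatenate(ensembles))
        report.stages["concatenation"] = {"n_frames": ensemble.n_frames,
                                          "n_replicas": len(ensembles)}

        stage = "persistence"
        table = interactions.persistence_table(ensemble, params)
        table_path = outdir / "persistence.tsv"
        table.to_tsv(table_path)
        report.stages["persistence"] = {"n_records": len(table.records),
                                        "frame_count": table.frame_count}
        report.outputs["persistence"] = table_path

        if p_t is None:
            stage = "threshold"
            curve = psn.cluster_curve(table, step=params.persistence_step)
            curve_path = outdir / "cluster_curve.tsv"
            curve.to_tsv(curve_path)
            fit = psn.estimate_persistence_threshold(
                curve, rounding=params.pt_rounding)
            p_t = fit.p_t
            report.stages["threshold"] = {
                "p_T": fit.p_t, "p0": fit.p0, "steepness": fit.steepness,
                "residual_norm": fit.residual_norm}
            report.outputs["cluster_curve"] = curve_path
        else:
            report.stages["threshold"] = {"p_T": p_t, "fixed": True}

        stage = "network"
        graph = psn.build_psn(table, p_t,
                              nodes=ensemble.topology.node_labels())
        psn.annotate_hubs(graph, params.hub_min_degree)
        graph_path = outdir / "psn.graphml"
        write_graphml(graph, graph_path)
        report.stages["network"] = {"n_nodes": graph.number_of_nodes(),
                                    "n_edges": graph.number_of_edges(),
                                    "p_T": p_t}
        report.outputs["network"] = graph_path

        stage = "hubs"
        hubs = psn.find_hubs(graph, params.hub_min_degree)
        hub_path = outdir / "hubs.tsv"
        psn.hubs_to_tsv(hubs, hub_path)
        report.stages["hubs"] = {"n_hubs": len(hubs),
                                 "max_degree": hubs[0].degree if hubs else 0}
        report.outputs["hubs"] = hub_path

        if sources and targets:
            stage = "communication"
            rows = communication.cr_table(graph, sources, targets,
                                          top_k=params.cr_top_k)
            cr_path = outdir / "cr_table.tsv"
            communication.cr_table_to_tsv(rows, cr_path)
            pathways = []
            for row in rows:
                if row["cr"] is None:
                    continue
                pw = communication.best_pathways(
                    graph, row["source"], row["target"],
                    max_paths=params.max_paths)
                pathways.append({"source": pw.source, "target": pw.target,
                                 "length": pw.length, "score": pw.score,
                                 "paths": [list(p) for p in pw.paths]})
            pw_path = outdir / "pathways.json"
            pw_path.write_text(json.dumps(pathways, indent=2))
            report.stages["communication"] = {
                "n_pairs": len(rows),
                "n_defined": sum(1 for r in rows if r["cr"] is not None)}
            report.outputs["cr_table"] = cr_path
            report.outputs["pathways"] = pw_path
        else:
            report.stages["communication"] = {"skipped": True,
                                              "reason": "no source/target "
                                                        "labels configured"}
    except Exception as exc:
        report.failed_stage = stage
        report.finished = time.time()
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        report.to_json(outdir / "run_report.json")
        raise StageError(stage, exc) from exc

    report.finished = time.time()
    report.to_json(outdir / "run_report.json")
    report.outputs["report"] = outdir / "run_report.json"
    report.validate()
    return report


def run_conservation_analysis(hub_tables: dict[str, list[list[psn.HubRecord]]],
                              msas: dict[str, MSA], params: Parameters,
                              outdir: str | Path) -> RunReport:
    """Hub tables + cluster alignments → profiles, degree points, regression.

    ``hub_tables`` maps protein label to its per-state hub tables;
    ``msas`` maps the same labels to their homolog-cluster alignments
    (seed id designated in each MSA).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=params.asdict(), started=time.time())
    stage = "setup"
    try:
        if set(hub_tables) - set(msas):
            missing = sorted(set(hub_tables) - set(msas))
            raise ValueError(f"no alignment for protein(s): {missing}")
        points: list[conservation.DegreeConservationPoint] = []
        for prot, tables in hub_tables.items():
            stage = f"profile:{prot}"
            profile = conservation.conservation_profile(
                msas[prot], mode=params.conservation_mode)
            prof_path = outdir / f"conservation_{prot}.tsv"
            profile.to_tsv(prof_path)
            report.outputs[f"profile_{prot}"] = prof_path
            stage = f"degrees:{prot}"
            dmap = conservation.max_degree_per_residue(tables)
            pts = conservation.degree_conservation_points(dmap, profile, prot)
            points.extend(pts)
            report.stages[f"protein:{prot}"] = {
                "cluster_size": profile.cluster_size,
                "n_hub_residues": len(dmap),
                "points": [{"degree": p.degree,
                            "mean_conservation": p.mean_conservation,
                            "n": p.n_residues} for p in pts]}
        pts_path = outdir / "degree_conservation.tsv"
        with open(pts_path, "w") as fh:
            fh.write("protein\tdegree\tmean_conservation\tn_residues\n")
            for p in points:
                fh.write(f"{p.protein}\t{p.degree}\t"
                         f"{p.mean_conservation:.4f}\t{p.n_residues}\n")
        report.outputs["degree_conservation"] = pts_path

        if len(points) >= 3:
            stage = "regression"
            reg = conservation.degree_regression(
                points, variance_test=params.variance_test)
            reg_path = outdir / "regression.json"
            reg_path.write_text(json.dumps(reg.to_dict(), indent=2,
                                           sort_keys=True))
            report.stages["regression"] = reg.to_dict()
            report.outputs["regression"] = reg_path
        else:
            report.stages["regression"] = {"skipped": True,
                                           "reason": "fewer than 3 points"}
    except Exception as exc:
        report.failed_stage = stage
        report.finished = time.time()
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        report.to_json(outdir / "run_report.json")
        raise StageError(stage, exc) from exc

    report.finished = time.time()
    report.to_json(outdir / "run_report.json")
    report.outputs["report"] = outdir / "run_report.json"
    report.validate()
    return report
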