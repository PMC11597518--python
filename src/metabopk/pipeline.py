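"""End-to-end orchestration of the pharmacometabolomics pipeline.

Stage order: simulate -> nca -> preprocess -> diffabund -> network(pre)
-> network(post) -> enrich -> report.  One config object carries every
stage parameter (thresholds default to the study's stated constants:
10% IQR floor, 20% QC-RSD, dCor >= 0.5, FDR 0.05, >= 2 pathway hits,
pathway size 5-150, QC every 10 injections) and one seed drives every
source of randomness; a manifest records the outputs and their hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import io as mio
from . import nca
from .datatypes import PKModelParams
from .diffabund import run_differential, select_features
from .enrich import filter_pathways, integrate_modules_pathways, overrepresentation_test, rollup_hierarchy
from .network import build_tripartite_graph, detect_communities, network_summary, signed_association_table
from .preprocess import run_preprocessing
from .simulate import (
    TARGET_CLASSES,
    characteristics_table,
    generate_pathway_fixture,
    realize_subject_params,
    simulate_cohort,
    simulate_concentration,
    simulate_feature_matrix,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("metabopk")

_DEFAULT_ASSOCIATIONS: list = [
    ["F0001", "Cmax", 0.8, 1],
    ["F0002", "AUC0-t", 0.8, 1],
    ["F0003", "T1/2", 0.7, 1],
    ["F0004", "Systolic pressure", 0.8, -1],
    ["F0005", "Serum creatinine", 0.7, 1],
    ["F0006", "Heart rate", 0.75, -1],
]


@dataclass
class RunConfig:
    """All stage parameters with study defaults; unknown keys are rejected."""

    seed: int = 1
    # synthetic cohort
    n_subjects: int = 35
    n_features: int = 500
    n_differential: int = 50
    qc_every: int = 10
    residual_cv: float = 0.05
    association_spec: list = field(default_factory=lambda: [list(a) for a in _DEFAULT_ASSOCIATIONS])
    drift_fraction: float = 0.5
    zero_fraction: float = 0.005
    n_pathways: int = 30
    # preprocessing
    drift_span: float = 0.75
    iqr_drop_fraction: float = 0.10
    rsd_threshold: float = 20.0
    # differential abundance
    alpha_diff: float = 0.05
    covariates: bool = True
    # association network
    d_threshold: float = 0.5
    alpha_network: float = 0.05
    # the add-one permutation p floors at 1/(n_perm+1); for any edge to
    # survive BH at alpha over m pairs with k signals one needs
    # m/(k*(n_perm+1)) <= alpha, so the pipeline default exceeds the
    # per-pair default of 1000
    n_perm: int = 5000
    resolution: float = 1.0
    max_network_metabolites: int = 40
    # enrichment
    run_enrichment: bool = True
    min_hits: int = 2
    pathway_size_min: int = 5
    pathway_size_max: int = 150
    alpha_enrich: float = 0.05

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _network_stage(
    scaled, metabolite_ids, targets, cfg: RunConfig, phase: str, outdir: Path, seed: int
) -> tuple[pd.DataFrame, object, object]:
    """Associations, tripartite graph, and Leiden modules for one phase."""
    abundance = scaled.phase_abundance(phase)[metabolite_ids]
    edges = signed_association_table(
        abundance,
        targets,
        phase=phase,
        target_classes=TARGET_CLASSES,
        d_threshold=cfg.d_threshold,
        alpha=cfg.alpha_network,
        n_perm=cfg.n_perm,
        seed=seed,
    )
    edges.to_csv(outdir / f"associations_{phase}.csv", index=False)
    graph = build_tripartite_graph(edges)
    partition = None
    if graph.number_of_nodes():
        nx.write_graphml(graph, outdir / f"network_{phase}.graphml")
        partition = detect_communities(graph, resolution=cfg.resolution, seed=seed)
        partition.summaries(graph).to_csv(outdir / f"modules_{phase}.csv", index=False)
        summary = network_summary(graph, partition)
    else:
        summary = {"n_metabolites": 0, "n_pk_parameters": 0, "n_characteristics": 0,
                   "n_edges": 0, "n_modules": 0}
    (outdir / f"network_summary_{phase}.json").write_text(json.dumps(summary, indent=2))
    return edges, graph, partition


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage, write all outputs plus a manifest; returns outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, list[str]] = {}
    cfg = config
    logger.info("effective config: %s", json.dumps(cfg.to_dict()))

    # --- stage 1: simulate ------------------------------------------------
    subjects = simulate_cohort(cfg.n_subjects, seed=cfg.seed)
    base = PKModelParams(residual_cv=cfg.residual_cv)
    rng = np.random.default_rng(cfg.seed + 1)
    profiles = [
        simulate_concentration(realize_subject_params(base, rng), subject_id=s.subject_id, rng=rng)
        for s in subjects
    ]
    pk_table = nca.analyze_study(profiles)
    pk_targets = pk_table[list(nca.SUMMARY_ROW_ORDER)]
    matrix, truth = simulate_feature_matrix(
        subjects,
        n_features=cfg.n_features,
        n_differential=cfg.n_differential,
        association_spec=[tuple(a) for a in cfg.association_spec],
        qc_every=cfg.qc_every,
        seed=cfg.seed + 2,
        targets=pk_targets,
        drift_fraction=cfg.drift_fraction,
        zero_fraction=cfg.zero_fraction,
    )
    fixture = generate_pathway_fixture(
        list(matrix.feature_ids),
        n_pathways=cfg.n_pathways,
        size_range=(cfg.pathway_size_min, min(cfg.pathway_size_max, cfg.n_features)),
        seed=cfg.seed + 3,
        enriched_members=sorted(truth.differential_features),
        n_enriched=cfg.n_pathways // 3,
    )
    chars = characteristics_table(subjects)
    mio.write_concentrations(profiles, out / "concentrations.csv")
    mio.write_feature_matrix(matrix, out / "feature_matrix.tsv")
    mio.write_characteristics(chars, out / "characteristics.csv")
    mio.write_pathway_fixture(fixture, out / "pathways.csv")
    mio.write_truth(truth, out / "truth.json")
    stages["simulate"] = [
        "concentrations.csv", "feature_matrix.tsv", "characteristics.csv",
        "pathways.csv", "truth.json",
    ]

    # --- stage 2: nca -----------------------------------------------------
    pk_table.to_csv(out / "pk_parameters.csv")
    nca.summarize_parameters(pk_table).to_csv(out / "pk_summary.csv")
    stages["nca"] = ["pk_parameters.csv", "pk_summary.csv"]

    # --- stage 3: preprocess ----------------------------------------------
    scaled, report = run_preprocessing(
        matrix,
        span=cfg.drift_span,
        iqr_drop_fraction=cfg.iqr_drop_fraction,
        rsd_threshold=cfg.rsd_threshold,
    )
    mio.write_feature_matrix(scaled, out / "feature_matrix_scaled.tsv")
    (out / "preprocess_report.json").write_text(json.dumps(report.to_json_dict(), indent=2))
    stages["preprocess"] = ["feature_matrix_scaled.tsv", "preprocess_report.json"]

    # --- stage 4: differential abundance -----------------------------------
    results = run_differential(scaled, subjects, alpha=cfg.alpha_diff, covariates=cfg.covariates)
    results.to_csv(out / "differential_results.csv")
    selected = select_features(results, alpha=cfg.alpha_diff)
    (out / "selected_features.txt").write_text("\n".join(selected) + "\n")
    stages["diffabund"] = ["differential_results.csv", "selected_features.txt"]

    # identified-metabolite set entering the network and enrichment stages;
    # capped for tractability, ordered by moderated-t evidence
    ordered = results.loc[selected].sort_values("p_raw").index
    metabolite_ids = list(ordered[: cfg.max_network_metabolites])
    targets = pd.concat(
        [pk_targets, chars.drop(columns=["sex", "age", "bmi", "period"])], axis=1
    ).loc[sorted(pk_targets.index)]

    # --- stages 5-6: association networks per phase -------------------------
    partitions = {}
    edge_tables = {}
    for i, phase in enumerate(("pre", "post")):
        edges, graph, partition = _network_stage(
            scaled, metabolite_ids, targets, cfg, phase, out, seed=cfg.seed + 4 + i
        )
        partitions[phase] = partition
        edge_tables[phase] = edges
    stages["network_pre"] = [
        "associations_pre.csv", "network_summary_pre.json"]
    stages["network_post"] = [
        "associations_post.csv", "network_summary_post.json"]

    # --- stage 7: enrichment ------------------------------------------------
    if cfg.run_enrichment:
        background = set(scaled.feature_ids)
        enr = overrepresentation_test(
            set(selected) & background, fixture, background,
            size_range=(cfg.pathway_size_min, cfg.pathway_size_max),
        )
        enr.to_csv(out / "enrichment.csv", index=False)
        retained = filter_pathways(
            enr, min_hits=cfg.min_hits,
            size_range=(cfg.pathway_size_min, cfg.pathway_size_max),
            alpha=cfg.alpha_enrich,
        )
        retained.to_csv(out / "enrichment_retained.csv", index=False)
        if len(retained):
            rollup_hierarchy(retained).to_csv(out / "enrichment_rollup.csv", index=False)
        stages["enrich"] = ["enrichment.csv", "enrichment_retained.csv"]
    else:
        # no enrichment: the report falls back to the literature label
        retained = pd.DataFrame(columns=["top_level", "sub_pathway", "hit_ids"])
        stages["enrich"] = []

    # --- stage 8: integrated report -----------------------------------------
    reports = []
    for phase in ("pre", "post"):
        partition = partitions[phase]
        if partition is None:
            continue
        reports.append(
            integrate_modules_pathways(partition, edge_tables[phase], retained, phase=phase)
        )
    integrated = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(columns=["parameter_or_characteristic", "phase", "metabolite",
                                   "module", "sign", "top_level_pathways"])
    )
    integrated.to_csv(out / "integrated_report.csv", index=False)
    stages["report"] = ["integrated_report.csv"]

    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {
            name: {f: _sha256(out / f) for f in files if (out / f).exists()}
            for name, files in stages.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
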