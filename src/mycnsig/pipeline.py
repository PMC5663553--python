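"""End-to-end study orchestration on synthetic or user-supplied data.

Discovery: two cohorts are scored for case-to-normal ratios, pathway
activation and per-feature AUC; markers passing the AUC gate in both cohorts
are intersected and the overlap tested against a random-subset null; the
double marker genes seed reconstruction of a connecting pathway over the
merged interaction networks. Validation: the reconstructed pathway is treated
as one gene set and its activation score per sample is evaluated as a
biomarker of amplification status on a held-out cohort, once per
normalization mode.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import cluster, cross_cohort, network, pas, screen, synthetic
from .io import (
    ExpressionMatrix,
    PathwayDB,
    SampleTable,
    write_expression,
    write_pathway_db,
    write_samples,
    write_sif,
)

__all__ = ["StudyConfig", "make_study", "run_discovery", "run_validation", "run_all"]

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Synthetic-study conditions and screening settings.

    Defaults emulate the shape of the real design at desk scale: two
    discovery cohorts measured on overlapping but non-identical gene
    universes, a ~20% amplified minority, a planted 4-fold (2 in log2) shift
    on 50 marker genes with log-normal noise, a pathway database partially
    enriched for the markers, a sparse connector subgraph in the interaction
    network, and a small held-out validation cohort with two normal-control
    sets.
    """

    seed: int = 0
    n_samples_a: int = 200
    n_samples_b: int = 200
    frac_amplified: float = 0.2
    n_genes_a: int = 2000
    n_genes_b: int = 2000
    universe_offset: int = 400  # cohort B's universe starts here; overlap = rest
    n_markers: int = 50
    effect_log2: float = 2.0
    noise_sd_log2: float = 0.7
    n_pathways: int = 150
    n_marker_pathways: int = 12
    marker_enrichment: float = 0.6
    pathway_size_range: tuple[int, int] = (8, 30)
    n_connectors: int = 10
    mean_degree: float = 2.0
    n_validation_samples: int = 41
    n_validation_amplified: int = 5
    n_controls_adrenal: int = 7
    n_controls_crest: int = 4
    auc_threshold: float = 0.8
    fold_threshold: float = 1.5
    n_reps: int = 10_000
    max_len: int = 4

    def universe_union(self) -> list[str]:
        n = max(self.n_genes_a, self.universe_offset + self.n_genes_b)
        return [f"G{i:05d}" for i in range(n)]


@dataclass
class Study:
    """Generated inputs of one synthetic study, plus the planted truth."""

    config: StudyConfig
    expr_a: ExpressionMatrix
    samples_a: SampleTable
    expr_b: ExpressionMatrix
    samples_b: SampleTable
    expr_val: ExpressionMatrix
    samples_val: SampleTable
    db: PathwayDB
    graph: nx.Graph
    truth: synthetic.PlantedTruth


def make_study(config: StudyConfig) -> Study:
    """Generate the full synthetic study from one seed.

    Marker genes are planted inside the shared part of the two gene
    universes so both platforms can measure them; the validation cohort is
    measured on the shared universe and carries two control sets.
    """
    union = config.universe_union()
    genes_a = tuple(union[: config.n_genes_a])
    genes_b = tuple(union[config.universe_offset : config.universe_offset + config.n_genes_b])
    shared = sorted(set(genes_a) & set(genes_b))
    if len(shared) < config.n_markers:
        raise ValueError("shared universe smaller than the marker set")
    # deterministic marker choice: evenly spaced across the shared universe
    step = len(shared) // config.n_markers
    markers = tuple(shared[i * step] for i in range(config.n_markers))

    common = dict(
        frac_amplified=config.frac_amplified,
        marker_genes=markers,
        effect_log2=config.effect_log2,
        noise_sd_log2=config.noise_sd_log2,
    )
    expr_a, samples_a, truth = synthetic.generate_cohort(
        synthetic.CohortSpec(
            n_samples=config.n_samples_a,
            n_genes=len(genes_a),
            gene_ids=genes_a,
            seed=config.seed * 8 + 1,
            cohort="cohortA",
            **common,
        )
    )
    expr_b, samples_b, _ = synthetic.generate_cohort(
        synthetic.CohortSpec(
            n_samples=config.n_samples_b,
            n_genes=len(genes_b),
            gene_ids=genes_b,
            seed=config.seed * 8 + 2,
            cohort="cohortB",
            **common,
        )
    )

    # validation cohort on the shared universe; both control sets are drawn
    # at the same per-gene baselines, then relabelled into two groups
    frac_val = config.n_validation_amplified / config.n_validation_samples
    expr_val, samples_val, _ = synthetic.generate_cohort(
        synthetic.CohortSpec(
            n_samples=config.n_validation_samples,
            frac_amplified=frac_val,
            n_genes=len(shared),
            gene_ids=tuple(shared),
            marker_genes=markers,
            effect_log2=config.effect_log2,
            noise_sd_log2=config.noise_sd_log2,
            n_controls=config.n_controls_adrenal + config.n_controls_crest,
            seed=config.seed * 8 + 3,
            cohort="validation",
            control_label="adrenal",
        )
    )
    frame = samples_val.data.copy()
    control_rows = frame.index[frame["group"] == "control"]
    frame.loc[control_rows[config.n_controls_adrenal:], "cohort"] = "crest"
    samples_val = SampleTable(frame)

    db, truth = synthetic.generate_pathway_db(
        union,
        truth,
        n_pathways=config.n_pathways,
        size_range=config.pathway_size_range,
        n_marker_pathways=config.n_marker_pathways,
        marker_enrichment=config.marker_enrichment,
        seed=config.seed * 8 + 5,
    )
    connectors = {f"X{i:03d}" for i in range(config.n_connectors)}
    truth = synthetic.PlantedTruth(
        marker_genes=truth.marker_genes,
        marker_pathways=truth.marker_pathways,
        connector_nodes=connectors,
        marker_directions=truth.marker_directions,
    )
    graph = synthetic.generate_network(
        union + sorted(connectors),
        truth,
        mean_degree=config.mean_degree,
        seed=config.seed * 8 + 6,
    )
    return Study(
        config=config,
        expr_a=expr_a,
        samples_a=samples_a,
        expr_b=expr_b,
        samples_b=samples_b,
        expr_val=expr_val,
        samples_val=samples_val,
        db=db,
        graph=graph,
        truth=truth,
    )


def _screen_cohort(
    expr: ExpressionMatrix,
    samples: SampleTable,
    db: PathwayDB,
    config: StudyConfig,
    mode: pas.NormalizationMode = pas.MEAN_TUMOR,
) -> dict:
    """CNR -> BTIF -> PAS -> AUC screening at both levels for one cohort."""
    cnr = pas.compute_cnr(expr, samples, mode)
    btif = pas.compute_btif(cnr, fold_threshold=config.fold_threshold)
    pas_matrix = pas.compute_pas(cnr, btif, db)
    gene_table = screen.screen(cnr, samples, threshold=config.auc_threshold, level="gene")
    pathway_table = screen.screen(
        pas_matrix, samples, threshold=config.auc_threshold, level="pathway"
    )
    return {
        "cnr": cnr,
        "pas": pas_matrix,
        "genes": gene_table,
        "pathways": pathway_table,
    }


def run_discovery(study: Study, out_dir: str | Path | None = None) -> dict:
    """Two-cohort discovery: screen, intersect with nulls, build the pathway.

    Returns a report dict; with ``out_dir`` every intermediate table is also
    written to disk so any stage can be re-run independently.
    """
    config = study.config
    res_a = _screen_cohort(study.expr_a, study.samples_a, study.db, config)
    res_b = _screen_cohort(study.expr_b, study.samples_b, study.db, config)

    gene_inter = cross_cohort.assess_intersection(
        screen.passed_features(res_a["genes"]),
        screen.passed_features(res_b["genes"]),
        res_a["genes"]["feature_id"],
        res_b["genes"]["feature_id"],
        n_reps=config.n_reps,
        seed=config.seed * 8 + 7,
    )
    pathway_inter = cross_cohort.assess_intersection(
        screen.passed_features(res_a["pathways"]),
        screen.passed_features(res_b["pathways"]),
        res_a["pathways"]["feature_id"],
        res_b["pathways"]["feature_id"],
        n_reps=config.n_reps,
        seed=config.seed * 8 + 8,
    )

    if gene_inter.double_markers:
        built = network.build_pathway(
            study.graph, set(gene_inter.double_markers), max_len=config.max_len
        )
    else:
        log.warning("empty double-marker set: pathway reconstruction skipped")
        built = None

    occurrence = (
        cross_cohort.gene_occurrence(pathway_inter.double_markers, study.db)
        if pathway_inter.double_markers
        else pd.DataFrame(columns=["gene_id", "occurrence"])
    )

    directions = dict(
        zip(res_a["genes"]["feature_id"], res_a["genes"]["direction"])
    )
    report = {
        "config": asdict(config),
        "cohort_a": {
            "n_gene_markers": int(res_a["genes"]["passed"].sum()),
            "n_pathway_markers": int(res_a["pathways"]["passed"].sum()),
        },
        "cohort_b": {
            "n_gene_markers": int(res_b["genes"]["passed"].sum()),
            "n_pathway_markers": int(res_b["pathways"]["passed"].sum()),
        },
        "gene_intersection": gene_inter.to_dict(),
        "pathway_intersection": pathway_inter.to_dict(),
        "reconstruction": built.summary() if built is not None else None,
    }

    result = {
        "report": report,
        "screens": {"a": res_a, "b": res_b},
        "gene_intersection": gene_inter,
        "pathway_intersection": pathway_inter,
        "pathway": built,
        "occurrence": occurrence,
        "marker_directions": directions,
    }
    if out_dir is not None:
        _write_discovery(study, result, Path(out_dir))
    return result


def _write_discovery(study: Study, result: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for tag in ("a", "b"):
        res = result["screens"][tag]
        res["pas"].to_csv(out_dir / f"pas_{tag}.tsv", sep="\t")
        res["genes"].to_csv(out_dir / f"markers_gene_{tag}.tsv", sep="\t", index=False)
        res["pathways"].to_csv(out_dir / f"markers_pathway_{tag}.tsv", sep="\t", index=False)
    np.savetxt(
        out_dir / "null_gene_cardinalities.tsv",
        result["gene_intersection"].sim_cardinalities,
        fmt="%d",
    )
    result["occurrence"].to_csv(out_dir / "gene_occurrence.tsv", sep="\t", index=False)
    if result["pathway"] is not None:
        network.write_pathway(result["pathway"], out_dir / "mycn_pathway")
    (out_dir / "report.json").write_text(
        json.dumps(result["report"], indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def run_validation(
    built: network.ReconstructedPathway,
    expr: ExpressionMatrix,
    samples: SampleTable,
    mode: pas.NormalizationMode,
    arr_override: dict[str, float] | None = None,
    fold_threshold: float = 1.5,
) -> dict:
    """Score the reconstructed pathway as a single-gene-set biomarker.

    ARR weights come from ``arr_override`` (typically discovery-cohort marker
    directions: up_in_amplified -> +1, down -> -1) with +1 for members
    without context. Members absent from the validation chip are ignored,
    mirroring cross-platform reality. Returns the oriented AUC of the
    pathway's activation score against MYCN status.
    """
    members = built.nodes
    measured = [g for g in members if g in expr.data.index]
    if len(measured) < 2:
        raise ValueError("fewer than 2 pathway genes measured in the validation cohort")
    arr_override = arr_override or {}
    records = pd.DataFrame(
        {
            "pathway": "MYCN_amplification_pathway",
            "gene": members,
            "arr": [float(arr_override.get(g, 1.0)) for g in members],
        }
    )
    db = PathwayDB(records)
    cnr = pas.compute_cnr(expr, samples, mode)
    btif = pas.compute_btif(cnr, fold_threshold=fold_threshold)
    pas_matrix = pas.compute_pas(cnr, btif, db)

    screening = samples.screening_samples()
    cols = [s for s in screening["sample_id"] if s in pas_matrix.columns]
    labels = samples.labels_for(cols)
    values = pas_matrix.loc["MYCN_amplification_pathway", cols]
    raw, oriented, direction = screen.auc_score(values.to_numpy(), labels)
    return {
        "auc": oriented,
        "raw_auc": raw,
        "direction": direction,
        "n_members_measured": len(measured),
        "pas": pas_matrix,
    }


def run_all(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Full synthetic study: discovery plus three-mode validation."""
    study = make_study(config)
    disc = run_discovery(study, out_dir=out_dir)
    report = disc["report"]
    report["validation"] = {}
    if disc["pathway"] is not None:
        arr = {
            g: (1.0 if d == "up_in_amplified" else -1.0)
            for g, d in disc["marker_directions"].items()
        }
        modes = {
            "mean_tumor": pas.MEAN_TUMOR,
            "control_adrenal": pas.control_group("adrenal"),
            "control_crest": pas.control_group("crest"),
        }
        for name, mode in modes.items():
            val = run_validation(
                disc["pathway"], study.expr_val, study.samples_val, mode,
                arr_override=arr, fold_threshold=config.fold_threshold,
            )
            report["validation"][name] = {
                "auc": val["auc"],
                "direction": val["direction"],
                "n_members_measured": val["n_members_measured"],
            }
    if out_dir is not None:
        (Path(out_dir) / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    disc["study"] = study
    return disc


def write_study(study: Study, out_dir: str | Path) -> None:
    """Persist all generated inputs in the standard formats plus the truth
    ledger, so every downstream stage can be re-run from disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(study.expr_a, out / "expr_a.tsv")
    write_samples(study.samples_a, out / "samples_a.tsv")
    write_expression(study.expr_b, out / "expr_b.tsv")
    write_samples(study.samples_b, out / "samples_b.tsv")
    write_expression(study.expr_val, out / "expr_validation.tsv")
    write_samples(study.samples_val, out / "samples_validation.tsv")
    write_pathway_db(study.db, out / "pathways.tsv")
    write_sif(study.graph, out / "network.sif")
    (out / "truth.json").write_text(
        json.dumps(study.truth.to_dict(), indent=2) + "\n", encoding="utf-8"
    )
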