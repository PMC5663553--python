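"""Synthetic cohorts, pathway databases and interaction networks with known
planted structure.

The expression model is deliberately the simplest one with the multiplicative
structure that case-to-normal ratios assume:

    log2 intensity = baseline(gene) + direction(gene) * effect_log2
                                        * 1[amplified and marker]
                     + Normal(0, noise_sd_log2)

with per-gene baselines uniform over ``baseline_log2_range`` and reported
intensities ``2**log2`` (hence strictly positive). Half the marker genes are
shifted up in amplified samples and half down, so screening must be
direction-agnostic. Normal-control samples are drawn at baseline.

One global seed per generator call; sub-streams are derived by fixed offsets
so regeneration is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PathwayDB, SampleTable, ALLOWED_ARR_WEIGHTS

__all__ = [
    "CohortSpec",
    "PlantedTruth",
    "generate_cohort",
    "generate_pathway_db",
    "generate_network",
]

# fixed sub-stream offsets (one global seed, no seed bookkeeping downstream)
_BASELINE_STREAM = 0
_NOISE_STREAM = 1
_PATHWAY_STREAM = 2
_NETWORK_STREAM = 3


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated cohort.

    ``frac_amplified`` emulates the real-world minority subgroup (~15-28% of
    neuroblastomas carry the amplification); ``effect_log2`` is the planted
    mean shift on marker genes in log2 units; noise is log-normal
    (Gaussian on the log2 scale).
    """

    n_samples: int
    frac_amplified: float
    n_genes: int
    marker_genes: tuple[str, ...]
    effect_log2: float = 2.0
    noise_sd_log2: float = 0.7
    baseline_log2_range: tuple[float, float] = (4.0, 12.0)
    n_controls: int = 0
    seed: int = 0
    gene_ids: tuple[str, ...] | None = None  # optional explicit universe
    cohort: str = "cohort"
    control_label: str | None = None  # cohort tag given to control samples

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if not 0.0 < self.frac_amplified < 1.0:
            raise ValueError("frac_amplified must lie strictly in (0, 1)")
        if not self.marker_genes:
            raise ValueError("marker gene set must be non-empty")
        if self.noise_sd_log2 <= 0:
            raise ValueError("noise_sd_log2 must be positive")
        if self.n_controls < 0:
            raise ValueError("n_controls must be non-negative")
        universe = self.universe
        if len(universe) != self.n_genes:
            raise ValueError("gene_ids length must equal n_genes")
        missing = set(self.marker_genes) - set(universe)
        if missing:
            raise ValueError(f"marker genes outside gene universe: {sorted(missing)[:5]}")

    @property
    def universe(self) -> tuple[str, ...]:
        if self.gene_ids is not None:
            return self.gene_ids
        return tuple(f"G{i:05d}" for i in range(self.n_genes))

    @property
    def n_amplified(self) -> int:
        # AUC needs both classes, hence the floor of 2
        return max(2, round(self.n_samples * self.frac_amplified))


@dataclass
class PlantedTruth:
    """Ground-truth ledger of what was planted.

    ``marker_directions`` maps each marker gene to +1 (up in amplified) or -1
    (down); it drives coherent ARR signs in marker pathways and serves as the
    sign context when the reconstructed pathway is scored.
    """

    marker_genes: set[str] = field(default_factory=set)
    marker_pathways: set[str] = field(default_factory=set)
    connector_nodes: set[str] = field(default_factory=set)
    marker_directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.connector_nodes & self.marker_genes:
            raise ValueError("connector_nodes must be disjoint from marker_genes")

    def to_dict(self) -> dict:
        return {
            "marker_genes": sorted(self.marker_genes),
            "marker_pathways": sorted(self.marker_pathways),
            "connector_nodes": sorted(self.connector_nodes),
            "marker_directions": {g: self.marker_directions[g] for g in sorted(self.marker_directions)},
        }


def marker_directions(marker_genes: Sequence[str]) -> dict[str, int]:
    """First half of the (sorted) marker set is up-regulated, second half down."""
    ordered = sorted(marker_genes)
    half = (len(ordered) + 1) // 2
    return {g: (1 if i < half else -1) for i, g in enumerate(ordered)}


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, SampleTable, PlantedTruth]:
    """Simulate one cohort under the planted-shift log-normal model.

    Deterministic for a fixed spec (seed included). Amplified tumor samples
    have expected log2 expression baseline + direction*effect_log2 on marker
    genes and baseline elsewhere; control samples sit at baseline.
    """
    genes = list(spec.universe)
    n_amp = spec.n_amplified
    n_tumor = spec.n_samples
    n_total = n_tumor + spec.n_controls

    rng_base = np.random.default_rng([spec.seed, _BASELINE_STREAM])
    rng_noise = np.random.default_rng([spec.seed, _NOISE_STREAM])

    lo, hi = spec.baseline_log2_range
    baseline = rng_base.uniform(lo, hi, size=spec.n_genes)

    directions = marker_directions(spec.marker_genes)
    shift = np.zeros(spec.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g, d in directions.items():
        shift[gene_pos[g]] = d * spec.effect_log2

    amplified = np.zeros(n_total, dtype=bool)
    amplified[:n_amp] = True
    amplified[n_tumor:] = False  # controls never amplified

    log2 = baseline[:, None] + np.where(amplified[None, :], shift[:, None], 0.0)
    log2 = log2 + rng_noise.normal(0.0, spec.noise_sd_log2, size=(spec.n_genes, n_total))
    intensities = np.exp2(log2)

    sample_ids = [f"{spec.cohort}_T{i:04d}" for i in range(n_tumor)] + [
        f"{spec.cohort}_N{i:04d}" for i in range(spec.n_controls)
    ]
    status = ["amplified" if amplified[i] else "wild_type" for i in range(n_tumor)]
    status += ["unknown"] * spec.n_controls
    group = ["tumor"] * n_tumor + ["control"] * spec.n_controls
    cohort_tag = [spec.cohort] * n_tumor + [
        spec.control_label or f"{spec.cohort}_controls"
    ] * spec.n_controls

    matrix = ExpressionMatrix(
        pd.DataFrame(intensities, index=genes, columns=sample_ids),
        platform=f"synthetic:{spec.cohort}",
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "mycn_status": status,
                "group": group,
                "cohort": cohort_tag,
            }
        )
    )
    truth = PlantedTruth(
        marker_genes=set(spec.marker_genes), marker_directions=directions
    )
    return matrix, samples, truth


def generate_pathway_db(
    universe: Sequence[str],
    truth: PlantedTruth,
    n_pathways: int,
    size_range: tuple[int, int] = (8, 30),
    n_marker_pathways: int = 0,
    marker_enrichment: float = 0.6,
    seed: int = 0,
) -> tuple[PathwayDB, PlantedTruth]:
    """Random role-annotated gene sets, some enriched for planted markers.

    Marker pathways draw at least ``marker_enrichment`` of their members from
    the planted marker genes, with ARR signs matching the planted direction
    (so their activation score shifts positive in amplified samples); other
    pathways draw members uniformly with random signs.
    """
    if size_range[0] < 2 or size_range[1] < size_range[0]:
        raise ValueError("size_range must be (lo, hi) with lo >= 2")
    if n_marker_pathways > n_pathways:
        raise ValueError("n_marker_pathways cannot exceed n_pathways")
    if not 0.0 <= marker_enrichment <= 1.0:
        raise ValueError("marker_enrichment must lie in [0, 1]")
    universe = list(universe)
    markers = sorted(truth.marker_genes & set(universe))
    min_markers = int(np.ceil(marker_enrichment * size_range[0]))
    if n_marker_pathways > 0 and len(markers) < min_markers:
        raise ValueError(
            f"enrichment infeasible: need >= {min_markers} marker genes in the "
            f"universe for marker_enrichment={marker_enrichment} at minimum "
            f"pathway size {size_range[0]}, have {len(markers)}"
        )

    rng = np.random.default_rng([seed, _PATHWAY_STREAM])
    magnitudes = np.array([0.5, 1.0])
    records: list[tuple[str, str, float]] = []
    marker_pathway_names: set[str] = set()

    for p in range(n_pathways):
        name = f"PW{p:04d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if p < n_marker_pathways:
            marker_pathway_names.add(name)
            n_from_markers = min(len(markers), int(np.ceil(marker_enrichment * size)))
            chosen = list(rng.choice(markers, size=n_from_markers, replace=False))
            rest_pool = [g for g in universe if g not in set(chosen)]
            n_rest = min(size - n_from_markers, len(rest_pool))
            chosen += list(rng.choice(rest_pool, size=n_rest, replace=False))
            for g in chosen:
                mag = float(rng.choice(magnitudes))
                if g in truth.marker_directions:
                    arr = mag * truth.marker_directions[g]  # coherent sign
                else:
                    arr = mag * int(rng.choice([-1, 1]))
                records.append((name, g, arr))
        else:
            size = min(size, len(universe))
            chosen = list(rng.choice(universe, size=size, replace=False))
            for g in chosen:
                arr = float(rng.choice(magnitudes)) * int(rng.choice([-1, 1]))
                records.append((name, g, arr))

    db = PathwayDB(pd.DataFrame(records, columns=["pathway", "gene", "arr"]))
    enriched = PlantedTruth(
        marker_genes=set(truth.marker_genes),
        marker_pathways=marker_pathway_names,
        connector_nodes=set(truth.connector_nodes),
        marker_directions=dict(truth.marker_directions),
    )
    return db, enriched


def generate_network(
    nodes: Sequence[str],
    truth: PlantedTruth,
    mean_degree: float = 0.0,
    seed: int = 0,
) -> nx.Graph:
    """Background Erdos-Renyi edges plus planted connector scaffolding.

    Planted edges guarantee every pair of marker genes is joined through at
    most two connector nodes: markers attach round-robin to connectors, and
    the connectors form a clique. With no connectors the markers are chained
    directly. Edge signs are random +/-1; provenance tags every edge
    'synthetic'.
    """
    nodes = list(nodes)
    node_set = set(nodes)
    markers = sorted(truth.marker_genes)
    connectors = sorted(truth.connector_nodes)
    missing = (set(markers) | set(connectors)) - node_set
    if missing:
        raise ValueError(f"marker/connector ids absent from node list: {sorted(missing)[:5]}")
    if mean_degree < 0:
        raise ValueError("mean_degree must be non-negative")

    rng = np.random.default_rng([seed, _NETWORK_STREAM])
    graph = nx.Graph(name="synthetic")
    graph.add_nodes_from(nodes)

    def _add(u: str, v: str) -> None:
        if u != v and not graph.has_edge(u, v):
            graph.add_edge(u, v, sign=int(rng.choice([-1, 1])), provenance=("synthetic",))

    # planted scaffold
    if connectors:
        for i, m in enumerate(markers):
            _add(m, connectors[i % len(connectors)])
        for i, c1 in enumerate(connectors):
            for c2 in connectors[i + 1:]:
                _add(c1, c2)
    else:
        for m1, m2 in zip(markers, markers[1:]):
            _add(m1, m2)

    # background noise edges
    n = len(nodes)
    if mean_degree > 0 and n > 1:
        p = min(1.0, mean_degree / (n - 1))
        upper = np.triu_indices(n, k=1)
        mask = rng.random(len(upper[0])) < p
        for i, j in zip(upper[0][mask], upper[1][mask]):
            _add(nodes[i], nodes[j])

    return graph
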