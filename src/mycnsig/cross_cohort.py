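"""Cross-cohort marker intersection with a random-subset simulation null.

Markers passing the AUC gate independently in two cohorts ("double markers")
are intersected; significance of the overlap is assessed by repeatedly
drawing random subsets of matching size from each cohort's own measured
feature universe, intersecting them, and approximating the resulting discrete
null by a normal distribution. The analytic expectation of the null is
k_a * k_b * |shared| / (|U_a| * |U_b|) for uniform draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import PathwayDB

__all__ = [
    "IntersectionResult",
    "intersect_markers",
    "simulate_null",
    "null_p_value",
    "assess_intersection",
    "gene_occurrence",
]


@dataclass
class IntersectionResult:
    """Observed double markers plus the simulated null of their count."""

    double_markers: list[str]
    k_a: int
    k_b: int
    universe_a: int
    universe_b: int
    shared_universe: int
    sim_cardinalities: np.ndarray
    null_mean: float
    null_sd: float
    p_value: float
    empirical_tail: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "double_markers": self.double_markers,
            "n_double": len(self.double_markers),
            "k_a": self.k_a,
            "k_b": self.k_b,
            "universe_a": self.universe_a,
            "universe_b": self.universe_b,
            "shared_universe": self.shared_universe,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
            "empirical_tail": self.empirical_tail,
            "n_reps": int(len(self.sim_cardinalities)),
            "seed": self.seed,
        }


def intersect_markers(markers_a, markers_b) -> list[str]:
    """Sorted intersection of two marker id sets."""
    return sorted(set(markers_a) & set(markers_b))


def simulate_null(
    universe_a,
    universe_b,
    k_a: int,
    k_b: int,
    n_reps: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """Cardinalities of ``n_reps`` random subset intersections.

    Each replicate draws k_a ids uniformly without replacement from universe
    A and k_b from universe B and records the intersection size. Universes
    may differ (cross-platform cohorts measure overlapping but non-identical
    gene sets); draws intersect on shared ids.
    """
    ua = np.asarray(sorted(set(universe_a)))
    ub = np.asarray(sorted(set(universe_b)))
    if not 0 <= k_a <= len(ua) or not 0 <= k_b <= len(ub):
        raise ValueError("subset sizes exceed universe sizes")
    shared = set(ua) & set(ub)
    # membership of each universe position in the shared id space
    shared_ids = {g: i for i, g in enumerate(sorted(shared))}
    map_a = np.array([shared_ids.get(g, -1) for g in ua])
    map_b = np.array([shared_ids.get(g, -1) for g in ub])

    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps, dtype=np.int64)
    n_shared = len(shared)
    mask_b = np.zeros(n_shared + 1, dtype=bool)  # slot -1 wraps to the spare cell
    for r in range(n_reps):
        draw_a = map_a[rng.choice(len(ua), size=k_a, replace=False)]
        draw_b = map_b[rng.choice(len(ub), size=k_b, replace=False)]
        mask_b[draw_b] = True
        mask_b[-1] = False
        counts[r] = int(mask_b[draw_a[draw_a >= 0]].sum())
        mask_b[draw_b] = False
    return counts


def null_p_value(observed: int, null_mean: float, null_sd: float,
                 sim_cardinalities: np.ndarray | None = None) -> float:
    """Upper-tail normal-approximation p at ``observed`` - 1/2 (continuity
    corrected); falls back to the empirical tail when the null is degenerate."""
    if null_sd > 0:
        return float(norm.sf((observed - 0.5 - null_mean) / null_sd))
    if sim_cardinalities is None:
        raise ValueError("null_sd = 0 and no simulated cardinalities to fall back on")
    return float(np.mean(sim_cardinalities >= observed))


def assess_intersection(
    markers_a,
    markers_b,
    universe_a,
    universe_b,
    n_reps: int = 10_000,
    seed: int = 0,
) -> IntersectionResult:
    """Intersect two marker sets and score the overlap against the null."""
    double = intersect_markers(markers_a, markers_b)
    shared = set(universe_a) & set(universe_b)
    if not shared and double:
        raise ValueError(
            "observed overlap with zero shared universe: feature ids are not harmonized"
        )
    sims = simulate_null(universe_a, universe_b, len(set(markers_a)),
                         len(set(markers_b)), n_reps=n_reps, seed=seed)
    null_mean = float(sims.mean())
    null_sd = float(sims.std(ddof=1)) if len(sims) > 1 else 0.0
    p = null_p_value(len(double), null_mean, null_sd, sims)
    empirical = float(np.mean(sims >= len(double)))
    return IntersectionResult(
        double_markers=double,
        k_a=len(set(markers_a)),
        k_b=len(set(markers_b)),
        universe_a=len(set(universe_a)),
        universe_b=len(set(universe_b)),
        shared_universe=len(shared),
        sim_cardinalities=sims,
        null_mean=null_mean,
        null_sd=null_sd,
        p_value=p,
        empirical_tail=empirical,
        seed=seed,
    )


def gene_occurrence(
    marker_pathways,
    db: PathwayDB,
    family_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Count, per gene, how many of the listed marker pathways contain it.

    With ``family_map`` (gene -> family name), genes are grouped into
    families and each family reports the maximum occurrence over its members
    — the grouped-row convention where co-occurring family members share one
    count rather than summing.
    """
    sets = db.gene_sets()
    unknown = [p for p in marker_pathways if p not in sets]
    if unknown:
        raise KeyError(f"unknown pathway names: {unknown[:5]}")
    counts: dict[str, int] = {}
    for p in marker_pathways:
        for gene in sets[p]:
            counts[gene] = counts.get(gene, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene_id", "occurrence"],
    )
    if family_map is not None:
        table["family"] = table["gene_id"].map(family_map).fillna(table["gene_id"])
        fam = (
            table.groupby("family", as_index=False)["occurrence"].max()
            .sort_values(["occurrence", "family"], ascending=[False, True])
            .reset_index(drop=True)
        )
        return fam
    return table
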