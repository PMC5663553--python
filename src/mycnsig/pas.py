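"""Case-to-normal ratios (CNR) and signed pathway activation strength (PAS).

CNR of gene *n* in sample *s* is the ratio of its expression to the average
expression over a reference set: either a designated normal-control group, or
the mean over all tumor samples of the cohort ("mean transcriptome"
normalization). PAS of a pathway is the role-weighted, significance-gated sum
of decimal-log CNRs over its member genes:

    PAS(p, s) = sum_n ARR(n, p) * BTIF(n, s) * log10 CNR(n, s)

where ARR is the signed activator/repressor role weight and BTIF a binary
flag marking changes large enough to count. Positive PAS means the pathway is
activated relative to the reference, negative means inhibited. The log base
only rescales PAS and leaves every downstream AUC unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PathwayDB, SampleTable

__all__ = [
    "NormalizationMode",
    "MEAN_TUMOR",
    "control_group",
    "compute_cnr",
    "compute_btif",
    "compute_pas",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationMode:
    """Reference set choice: ``mean_tumor`` or a labelled control group."""

    kind: str  # "mean_tumor" | "control_group"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mean_tumor", "control_group"):
            raise ValueError(f"unknown normalization mode {self.kind!r}")

    @classmethod
    def parse(cls, token: str) -> "NormalizationMode":
        if token == "mean_tumor":
            return MEAN_TUMOR
        if token.startswith("control:"):
            return cls("control_group", token.split(":", 1)[1] or None)
        if token == "control":
            return cls("control_group", None)
        raise ValueError(f"cannot parse normalization mode {token!r}")


MEAN_TUMOR = NormalizationMode("mean_tumor")


def control_group(label: str | None = None) -> NormalizationMode:
    return NormalizationMode("control_group", label)


def _reference_samples(samples: SampleTable, mode: NormalizationMode) -> list[str]:
    if mode.kind == "mean_tumor":
        ref = samples.tumor_samples()
    else:
        ref = samples.control_samples(mode.label)
    if not ref:
        raise ValueError(f"empty reference set for mode {mode}")
    return ref


def compute_cnr(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    mode: NormalizationMode = MEAN_TUMOR,
    geometric: bool = False,
) -> pd.DataFrame:
    """CNR[g, s] = expr[g, s] / mean over the reference set of expr[g, .].

    Computed for tumor samples only. Reference averaging is arithmetic on the
    linear scale by default (``geometric=True`` switches to the geometric
    mean). Genes with a zero reference mean are excluded with a warning.
    """
    ref_ids = _reference_samples(samples, mode)
    case_ids = [s for s in samples.tumor_samples() if s in matrix.data.columns]
    missing_ref = [s for s in ref_ids if s not in matrix.data.columns]
    if missing_ref:
        raise ValueError(f"reference samples absent from matrix: {missing_ref[:5]}")

    ref = matrix.data[ref_ids]
    if geometric:
        denom = np.exp(np.log(ref).mean(axis=1))
    else:
        denom = ref.mean(axis=1)
    usable = denom > 0
    if (~usable).any():
        log.warning("compute_cnr: excluding %d genes with zero reference mean", int((~usable).sum()))
    cnr = matrix.data.loc[usable, case_ids].div(denom[usable], axis=0)
    return cnr


def compute_btif(
    cnr: pd.DataFrame,
    rule: str = "fold",
    fold_threshold: float = 1.5,
    alpha: float = 0.05,
    expression: ExpressionMatrix | None = None,
    samples: SampleTable | None = None,
    mode: NormalizationMode = MEAN_TUMOR,
) -> pd.DataFrame:
    """Beyond-tolerance flags gating which genes contribute to PAS.

    Default ``fold`` rule: BTIF[g, s] = 1 iff |log10 CNR[g, s]| >=
    log10(fold_threshold), per cell. Alternative ``test`` rule: a two-sided
    two-sample t-test of gene g, tumor vs reference expression, at level
    ``alpha``, applied cohort-wide (one flag per gene).
    """
    if rule == "fold":
        if fold_threshold <= 1.0:
            raise ValueError("fold_threshold must exceed 1")
        flags = (np.abs(np.log10(cnr)) >= np.log10(fold_threshold)).astype(int)
        return flags
    if rule == "test":
        if expression is None or samples is None:
            raise ValueError("test rule needs the expression matrix and sample table")
        ref_ids = _reference_samples(samples, mode)
        if len(ref_ids) < 2:
            raise ValueError(
                "test rule needs >= 2 reference samples; use the fold rule instead"
            )
        case_ids = list(cnr.columns)
        genes = cnr.index
        case = np.log2(expression.data.loc[genes, case_ids].to_numpy())
        ref = np.log2(expression.data.loc[genes, ref_ids].to_numpy())
        _, pvals = stats.ttest_ind(case, ref, axis=1, equal_var=False)
        per_gene = (pvals < alpha).astype(int)
        return pd.DataFrame(
            np.repeat(per_gene[:, None], len(case_ids), axis=1),
            index=genes,
            columns=case_ids,
        )
    raise ValueError(f"unknown BTIF rule {rule!r}")


def compute_pas(cnr: pd.DataFrame, btif: pd.DataFrame, db: PathwayDB) -> pd.DataFrame:
    """Pathways x samples matrix of signed activation scores.

    Member genes absent from the CNR matrix contribute nothing; a pathway with
    zero measured members is omitted (never zero-filled). Gene-id matching is
    case-sensitive: silent mismatches are worse than loud ones.
    """
    if not cnr.index.equals(btif.index) or not cnr.columns.equals(btif.columns):
        btif = btif.reindex(index=cnr.index, columns=cnr.columns)
        if btif.isna().any().any():
            raise ValueError("BTIF flags do not cover the CNR matrix")
    terms = btif.to_numpy() * np.log10(cnr.to_numpy())
    gene_pos = {g: i for i, g in enumerate(cnr.index)}

    rows: dict[str, np.ndarray] = {}
    for pathway, members in db.gene_sets().items():
        idx, weights = [], []
        for gene, arr in members.items():
            pos = gene_pos.get(gene)
            if pos is not None:
                idx.append(pos)
                weights.append(arr)
        if not idx:
            continue  # no measured members
        rows[pathway] = np.asarray(weights) @ terms[idx, :]

    return pd.DataFrame.from_dict(rows, orient="index", columns=cnr.columns)
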